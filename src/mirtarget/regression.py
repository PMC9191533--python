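"""Per-pair miRNA -> mRNA regression with AIC-based family selection.

For each candidate pair the mRNA expression vector Y is regressed on one or
two miRNA expression vectors under one of five distribution families:

* gaussian            Y = b0 + b1*x1 (+ b2*x2 + b3*x1*x2) + e, identity link
* poisson             log E[Y] linear in the predictors
* negative_binomial   NB2 with ML dispersion
* zero_inflated_poisson / zero_inflated_negative_binomial
                      count component as above plus a logit-linked constant
                      zero-inflation probability

With ``family="auto"`` all applicable families are fitted and the converged
fit with the smallest AIC wins; AIC = 2k - 2 lnL with k counting every free
parameter (mean coefficients, the Gaussian sigma, the NB dispersion, the
zero-inflation constant) so it is comparable across families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.discrete.count_model import (
    ZeroInflatedNegativeBinomialP,
    ZeroInflatedPoisson,
)
from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson
from statsmodels.stats.multitest import multipletests

from .core_io import PairedDataset, PairList, PredictionTable

logger = logging.getLogger("mirtarget")

GAUSSIAN = "gaussian"
POISSON = "poisson"
NEGATIVE_BINOMIAL = "negative_binomial"
ZIP = "zero_inflated_poisson"
ZINB = "zero_inflated_negative_binomial"
AUTO = "auto"

#: Family order used everywhere, including AIC tie-breaking (simplest first).
FAMILY_ORDER = (GAUSSIAN, POISSON, NEGATIVE_BINOMIAL, ZIP, ZINB)
COUNT_FAMILIES = (POISSON, NEGATIVE_BINOMIAL, ZIP, ZINB)

UNIVARIATE = "univariate"
MULTIVARIATE = "multivariate"
INTERACTION = "interaction"
FORMULAS = (UNIVARIATE, MULTIVARIATE, INTERACTION)

#: Extra free parameters per family beyond the mean coefficients:
#: Gaussian sigma, NB dispersion alpha, zero-inflation logit constant.
_EXTRA_PARAMS = {GAUSSIAN: 1, POISSON: 0, NEGATIVE_BINOMIAL: 1, ZIP: 1, ZINB: 2}

_MAXITER = 200


class FitError(RuntimeError):
    """A per-pair fit could not be produced."""


@dataclass
class PairFit:
    """Result of one per-pair regression fit."""

    mrna_id: str
    mirna_ids: tuple[str, ...]
    family: str
    formula: str
    beta: np.ndarray          # b0, b1[, b2[, b3]]
    se: np.ndarray
    pvalues: np.ndarray       # per mean coefficient, Wald by default
    aic: float
    loglik: float
    r2: float
    converged: bool
    degenerate: bool = False
    n_params: int = 0

    @property
    def coef_of_interest(self) -> int:
        """Index into beta of the coefficient tested downstream."""
        return 3 if self.formula == INTERACTION else 1

    @property
    def p_of_interest(self) -> float:
        return float(self.pvalues[self.coef_of_interest])

    @property
    def direction(self) -> str:
        b = self.beta[self.coef_of_interest]
        if b > 0:
            return "positive"
        if b < 0:
            return "negative"
        return "zero"


@dataclass
class Part1Report:
    """Per-pair fit summaries with BH-adjusted p-values and co-prediction flags."""

    table: pd.DataFrame
    alpha: float
    direction: str
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _build_design(
    data: PairedDataset, mirna_ids: Sequence[str], formula: str, scale: float
) -> pd.DataFrame:
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula kind {formula!r}")
    n_needed = 1 if formula == UNIVARIATE else 2
    if len(mirna_ids) != n_needed:
        raise ValueError(
            f"{formula} formula requires exactly {n_needed} miRNA predictor(s), "
            f"got {len(mirna_ids)}"
        )
    if scale <= 0:
        raise ValueError("scale must be positive")
    cols = {"const": np.ones(data.n_samples)}
    for i, mid in enumerate(mirna_ids, start=1):
        cols[f"x{i}"] = data.mirna.row(mid) * scale
    if formula == INTERACTION:
        cols["x1:x2"] = cols["x1"] * cols["x2"]
    return pd.DataFrame(cols, index=data.sample_ids)


def _fitted_r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Squared Pearson correlation of fitted vs observed; 0 when undefined."""
    if not np.all(np.isfinite(fitted)):
        return 0.0
    if np.std(observed) == 0 or np.std(fitted) == 0:
        return 0.0
    r = np.corrcoef(observed, fitted)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def _degenerate_fit(
    mrna_id: str,
    mirna_ids: Sequence[str],
    family: str,
    formula: str,
    y: np.ndarray,
    n_coef: int,
) -> PairFit:
    """Fit returned for singular designs or zero-variance responses.

    The intercept carries the response location on the family's link scale,
    every other coefficient is exactly zero with p-value 1, and the AIC is
    +inf so auto-selection never prefers a degenerate fit.
    """
    mean = float(np.mean(y))
    if family == GAUSSIAN:
        b0 = mean
    else:
        b0 = float(np.log(mean)) if mean > 0 else -np.inf
    beta = np.zeros(n_coef)
    beta[0] = b0
    pvals = np.ones(n_coef)
    pvals[0] = np.nan
    return PairFit(
        mrna_id=mrna_id,
        mirna_ids=tuple(mirna_ids),
        family=family,
        formula=formula,
        beta=beta,
        se=np.full(n_coef, np.nan),
        pvalues=pvals,
        aic=np.inf,
        loglik=np.nan,
        r2=0.0,
        converged=True,
        degenerate=True,
        n_params=n_coef + _EXTRA_PARAMS[family],
    )


def _fit_family(y: np.ndarray, X: pd.DataFrame, family: str):
    """Fit one family; return (beta, se, pvalues, loglik, converged, fitted)."""
    names = list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == GAUSSIAN:
            res = sm.OLS(y, X).fit()
            conv = True
        elif family == POISSON:
            res = Poisson(y, X).fit(disp=0, maxiter=_MAXITER)
            conv = bool(res.mle_retvals.get("converged", True))
        elif family == NEGATIVE_BINOMIAL:
            res = NegativeBinomial(y, X, loglike_method="nb2").fit(disp=0, maxiter=_MAXITER)
            conv = bool(res.mle_retvals.get("converged", True))
        elif family == ZIP:
            res = ZeroInflatedPoisson(
                y, X, exog_infl=np.ones((len(y), 1)), inflation="logit"
            ).fit(disp=0, maxiter=_MAXITER)
            conv = bool(res.mle_retvals.get("converged", True))
        elif family == ZINB:
            res = ZeroInflatedNegativeBinomialP(
                y, X, exog_infl=np.ones((len(y), 1)), inflation="logit", p=2
            ).fit(disp=0, maxiter=_MAXITER)
            conv = bool(res.mle_retvals.get("converged", True))
        else:
            raise ValueError(f"unknown family {family!r}")
        params = pd.Series(res.params, index=res.params.index if hasattr(res.params, "index") else None)
        # ML count models prefix zero-inflation params; select mean coefficients by name.
        if hasattr(res.params, "index"):
            beta = np.array([res.params[n] for n in names], dtype=float)
            se = np.array([res.bse[n] for n in names], dtype=float)
            pvals = np.array([res.pvalues[n] for n in names], dtype=float)
        else:  # pragma: no cover - statsmodels keeps pandas index with DataFrame exog
            beta = np.asarray(res.params, dtype=float)[: len(names)]
            se = np.asarray(res.bse, dtype=float)[: len(names)]
            pvals = np.asarray(res.pvalues, dtype=float)[: len(names)]
        fitted = np.asarray(res.predict(), dtype=float)
        llf = float(res.llf)
    if not np.all(np.isfinite(beta)) or not np.isfinite(llf):
        conv = False
    return beta, se, pvals, llf, conv, fitted


def _lrt_pvalue(y: np.ndarray, X: pd.DataFrame, family: str, drop_col: str, llf_full: float) -> float:
    """Likelihood-ratio p-value for one coefficient (chi-square, 1 df)."""
    X_red = X.drop(columns=[drop_col])
    _, _, _, llf_red, conv, _ = _fit_family(y, X_red, family)
    if not conv or not np.isfinite(llf_red):
        return np.nan
    stat = max(0.0, 2.0 * (llf_full - llf_red))
    return float(scipy.stats.chi2.sf(stat, df=1))


def fit_pair(
    data: PairedDataset,
    mrna_id: str,
    mirna_ids: Sequence[str],
    family: str = GAUSSIAN,
    formula: str = UNIVARIATE,
    scale: float = 1.0,
    round_counts: bool = False,
    pvalue_method: str = "wald",
) -> PairFit:
    """Fit one miRNA(-pair) -> mRNA regression under a single family.

    Predictors are the miRNA expression rows multiplied by ``scale``.
    Coefficient p-values are Wald tests (t for gaussian, z for the ML
    families); ``pvalue_method="lrt"`` replaces the p-value of the coefficient
    of interest with a likelihood-ratio test. The reported r2 is the squared
    Pearson correlation between fitted and observed response, a
    family-agnostic goodness-of-fit summary.
    """
    if family not in FAMILY_ORDER:
        raise ValueError(f"unknown family {family!r} (use select_model for auto)")
    if pvalue_method not in ("wald", "lrt"):
        raise ValueError("pvalue_method must be 'wald' or 'lrt'")
    X = _build_design(data, mirna_ids, formula, scale)
    y = data.mrna.row(mrna_id)
    k_coef = X.shape[1]
    if data.n_samples < k_coef + 2:
        raise FitError(
            f"{data.n_samples} samples cannot support a {formula} fit "
            f"({k_coef} coefficients); need >= {k_coef + 2}"
        )
    if family in COUNT_FAMILIES:
        if round_counts:
            y = np.round(y)
        elif not np.allclose(y, np.round(y)):
            raise FitError(
                f"response for {mrna_id!r} is not integer-valued; count family "
                f"{family!r} requires counts — use the gaussian family or enable "
                "round_counts"
            )

    predictor_cols = [c for c in X.columns if c != "const"]
    singular = any(np.std(X[c].to_numpy()) == 0 for c in predictor_cols) or (
        np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]
    )
    if singular or np.std(y) == 0:
        return _degenerate_fit(mrna_id, mirna_ids, family, formula, y, k_coef)

    try:
        beta, se, pvals, llf, conv, fitted = _fit_family(y, X, family)
    except Exception as exc:
        logger.debug("fit failed for %s ~ %s under %s: %s", mrna_id, mirna_ids, family, exc)
        nan = np.full(k_coef, np.nan)
        return PairFit(
            mrna_id=mrna_id, mirna_ids=tuple(mirna_ids), family=family, formula=formula,
            beta=nan, se=nan.copy(), pvalues=nan.copy(), aic=np.inf, loglik=np.nan,
            r2=np.nan, converged=False, n_params=k_coef + _EXTRA_PARAMS[family],
        )

    n_params = k_coef + _EXTRA_PARAMS[family]
    aic = 2.0 * n_params - 2.0 * llf if np.isfinite(llf) else np.inf
    if pvalue_method == "lrt" and conv:
        interest_col = "x1:x2" if formula == INTERACTION else "x1"
        idx = list(X.columns).index(interest_col)
        pvals = pvals.copy()
        pvals[idx] = _lrt_pvalue(y, X, family, interest_col, llf)
    return PairFit(
        mrna_id=mrna_id,
        mirna_ids=tuple(mirna_ids),
        family=family,
        formula=formula,
        beta=beta,
        se=se,
        pvalues=pvals,
        aic=float(aic),
        loglik=llf,
        r2=_fitted_r2(y, fitted),
        converged=conv,
        n_params=n_params,
    )


def select_model(
    data: PairedDataset,
    mrna_id: str,
    mirna_ids: Sequence[str],
    formula: str = UNIVARIATE,
    scale: float = 1.0,
    round_counts: bool = False,
    pvalue_method: str = "wald",
) -> PairFit:
    """Fit every applicable family and return the smallest-AIC converged fit.

    Count families are skipped when the response is not integer-valued. Ties
    are broken by family order, simplest first.
    """
    y = data.mrna.row(mrna_id)
    integer_response = bool(np.allclose(y, np.round(y))) or round_counts
    best: Optional[PairFit] = None
    for family in FAMILY_ORDER:
        if family in COUNT_FAMILIES and not integer_response:
            continue
        try:
            fit = fit_pair(
                data, mrna_id, mirna_ids, family=family, formula=formula,
                scale=scale, round_counts=round_counts, pvalue_method=pvalue_method,
            )
        except FitError:
            continue
        if not fit.converged:
            continue
        if best is None or fit.aic < best.aic:
            best = fit
    if best is None:
        raise FitError(f"no family converged for {mrna_id!r} ~ {tuple(mirna_ids)}")
    return best


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values; NaNs pass through unadjusted."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "mrna_id", "mirna_id1", "mirna_id2", "family", "formula",
    "beta0", "beta1", "beta2", "beta3", "se1", "se2", "se3",
    "p_raw", "p_adj", "r2", "aic", "direction", "co_predicted",
    "converged", "significant",
]


def _normalize_pair(item, formula: str) -> tuple[tuple[str, ...], str]:
    """Accept (mirna, mrna) or (mirna1, mirna2, mrna) tuples or PairList entries."""
    item = tuple(item)
    if formula == UNIVARIATE:
        if len(item) != 2:
            raise ValueError(f"univariate pair must be (mirna_id, mrna_id), got {item}")
        return (item[0],), item[1]
    if len(item) != 3:
        raise ValueError(
            f"{formula} requires (mirna_id1, mirna_id2, mrna_id) tuples, got {item}"
        )
    return (item[0], item[1]), item[2]


def run_part1(
    data: PairedDataset,
    pairs,
    formula: str = UNIVARIATE,
    family: str = AUTO,
    scale: float = 1.0,
    alpha: float = 0.05,
    direction: str = "both",
    predictions: Optional[PredictionTable] = None,
    round_counts: bool = False,
    pvalue_method: str = "wald",
) -> Part1Report:
    """Fit all candidate pairs, BH-adjust, and flag significant relationships.

    A pair is significant when its fit converged, its BH-adjusted p-value for
    the coefficient of interest (b1; b3 for interaction fits) is below
    ``alpha``, and the coefficient's sign matches ``direction`` ("negative",
    "positive" or "both"). Per-pair fit failures become flagged rows; the
    batch never aborts.
    """
    if direction not in ("negative", "positive", "both"):
        raise ValueError("direction must be one of negative/positive/both")
    pair_items = list(pairs.pairs if isinstance(pairs, PairList) else pairs)
    if not pair_items:
        raise ValueError("no candidate pairs supplied")

    pred_pairs = predictions.pair_set() if predictions is not None else None
    rows = []
    for item in pair_items:
        mirna_ids, mrna_id = _normalize_pair(item, formula)
        try:
            if family == AUTO:
                fit = select_model(
                    data, mrna_id, mirna_ids, formula=formula, scale=scale,
                    round_counts=round_counts, pvalue_method=pvalue_method,
                )
            else:
                fit = fit_pair(
                    data, mrna_id, mirna_ids, family=family, formula=formula,
                    scale=scale, round_counts=round_counts, pvalue_method=pvalue_method,
                )
        except FitError as exc:
            logger.warning("pair (%s, %s) unfit: %s", mirna_ids, mrna_id, exc)
            rows.append({
                "mrna_id": mrna_id,
                "mirna_id1": mirna_ids[0],
                "mirna_id2": mirna_ids[1] if len(mirna_ids) > 1 else "",
                "family": family, "formula": formula,
                "beta0": np.nan, "beta1": np.nan, "beta2": np.nan, "beta3": np.nan,
                "se1": np.nan, "se2": np.nan, "se3": np.nan,
                "p_raw": np.nan, "r2": np.nan, "aic": np.nan,
                "direction": "", "converged": False,
            })
            continue
        beta = np.full(4, np.nan)
        beta[: len(fit.beta)] = fit.beta
        se = np.full(3, np.nan)
        se[: len(fit.se) - 1] = fit.se[1:]
        rows.append({
            "mrna_id": fit.mrna_id,
            "mirna_id1": fit.mirna_ids[0],
            "mirna_id2": fit.mirna_ids[1] if len(fit.mirna_ids) > 1 else "",
            "family": fit.family, "formula": fit.formula,
            "beta0": beta[0], "beta1": beta[1], "beta2": beta[2], "beta3": beta[3],
            "se1": se[0], "se2": se[1], "se3": se[2],
            "p_raw": fit.p_of_interest if fit.converged else np.nan,
            "r2": fit.r2, "aic": fit.aic,
            "direction": fit.direction, "converged": fit.converged,
        })

    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    if pred_pairs is not None:
        keys = list(zip(table["mirna_id1"], table["mrna_id"]))
        table["co_predicted"] = [k in pred_pairs for k in keys]
        if formula != UNIVARIATE:
            keys2 = list(zip(table["mirna_id2"], table["mrna_id"]))
            table["co_predicted"] = table["co_predicted"] | pd.Series(
                [k in pred_pairs for k in keys2]
            )
    else:
        table["co_predicted"] = False

    sign_ok = table["direction"] != "zero" if direction == "both" else table["direction"] == direction
    table["significant"] = (
        table["converged"] & table["p_adj"].notna() & (table["p_adj"] < alpha) & sign_ok
    )
    table = (
        table[_REPORT_COLUMNS]
        .sort_values(
            ["p_adj", "p_raw", "mirna_id1", "mrna_id"], na_position="last", kind="mergesort"
        )
        .reset_index(drop=True)
    )

    sig = table[table["significant"]]
    n_sig = int(len(sig))
    n_co = int(sig["co_predicted"].sum())
    summary = {
        "n_pairs": len(table),
        "n_converged": int(table["converged"].sum()),
        "n_significant": n_sig,
        "n_co_predicted": n_co,
        "pct_co_predicted": round(100.0 * n_co / n_sig, 2) if n_sig else 0.0,
    }
    logger.info("part1: %(n_pairs)d pairs, %(n_significant)d significant, "
                "%(n_co_predicted)d co-predicted", summary)
    return Part1Report(table=table, alpha=alpha, direction=direction, summary=summary)
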