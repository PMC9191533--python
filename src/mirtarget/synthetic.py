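"""Synthetic fixtures with known ground truth for every statistical path.

Three generators mirror the three analysis inputs: paired expression
matrices with regressions planted under any single distribution family,
fold-change tables with planted correlations and planted absolute
differences, and miRanda-style prediction tables covering planted pairs.
Every generator is a pure function of its seed and parameters.

Baseline miRNA expression is log-normal (meanlog 3, sdlog 1), mimicking the
scale heterogeneity of CPM/TPM data. Planted correlations are constructed
exactly: the mRNA vector is a linear combination of the standardized miRNA
vector and an orthogonalized noise vector, so the realized sample Pearson r
equals the requested value to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    FoldChangeTable,
    PairedDataset,
    PredictionTable,
)
from . import regression as reg

#: Log-normal baseline for miRNA expression (log-scale mean and sd).
BASELINE_MEANLOG = 3.0
BASELINE_SDLOG = 1.0

#: Default miRanda-style score range for generated prediction tables.
DEFAULT_SCORE_RANGE = (140.0, 189.0)

#: Spread (sd) of background log2 fold changes. Moderated/shrunken log2FC
#: estimates for the non-differential bulk of features concentrate near zero;
#: strongly differential features are represented by planted effects.
FC_BACKGROUND_SD = 0.5


@dataclass
class TruthRecord:
    """One planted effect: which pair, which statistic, what value."""

    mirna_id: str
    mrna_id: str
    effect: str                      # "beta1" | "beta3" | "r" | "d"
    value: float
    mirna_id2: Optional[str] = None  # second predictor for beta3 plantings
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect not in ("beta1", "beta3", "r", "d"):
            raise ValueError(f"unknown planted effect {self.effect!r}")
        if self.effect == "beta3" and self.mirna_id2 is None:
            raise ValueError("beta3 plantings need two miRNA ids")


@dataclass
class NoiseParams:
    """Family-specific noise/dispersion settings for paired-count simulation.

    sigma: Gaussian residual sd. nb_alpha: NB2 dispersion (var = mu +
    alpha*mu^2). zi_prob: structural-zero probability for the zero-inflated
    families; 0.3 keeps them AIC-distinguishable from their non-inflated
    counterparts at n = 100. beta0: intercept on the link scale; None picks a
    family-appropriate default (for Gaussian, large enough that planted
    responses stay non-negative).
    """

    sigma: float = 0.1
    nb_alpha: float = 0.5
    zi_prob: float = 0.3
    beta0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.nb_alpha < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0 <= self.zi_prob < 1:
            raise ValueError("zi_prob must lie in [0, 1)")


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    """Serialize truth records to a table (round-trips via the TSV writer)."""
    return pd.DataFrame([
        {
            "mirna_id": t.mirna_id, "mirna_id2": t.mirna_id2 or "",
            "mrna_id": t.mrna_id, "effect": t.effect, "value": t.value,
            "family": t.family or "",
        }
        for t in truth
    ], columns=["mirna_id", "mirna_id2", "mrna_id", "effect", "value", "family"])


def frame_to_truth(df: pd.DataFrame) -> list[TruthRecord]:
    out = []
    for row in df.itertuples(index=False):
        mid2 = getattr(row, "mirna_id2", "")
        fam = getattr(row, "family", "")
        out.append(TruthRecord(
            mirna_id=row.mirna_id, mrna_id=row.mrna_id, effect=row.effect,
            value=float(row.value),
            mirna_id2=str(mid2) if isinstance(mid2, str) and mid2 else None,
            family=str(fam) if isinstance(fam, str) and fam else None,
        ))
    return out


def _mirna_ids(n: int) -> list[str]:
    return [f"mir_{i:04d}" for i in range(1, n + 1)]


def _mrna_ids(n: int) -> list[str]:
    return [f"gene_{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Paired expression matrices (Part 1 fixtures)
# ---------------------------------------------------------------------------


def _count_response(rng: np.random.Generator, eta: np.ndarray, family: str,
                    noise: NoiseParams) -> np.ndarray:
    mu = np.exp(np.clip(eta, -30.0, 25.0))
    if family in (reg.NEGATIVE_BINOMIAL, reg.ZINB) and noise.nb_alpha > 0:
        shape = 1.0 / noise.nb_alpha
        lam = rng.gamma(shape, noise.nb_alpha * mu)
    else:
        lam = mu
    y = rng.poisson(lam).astype(float)
    if family in (reg.ZIP, reg.ZINB) and noise.zi_prob > 0:
        y[rng.random(len(y)) < noise.zi_prob] = 0.0
    return y


def simulate_paired_counts(
    n_samples: int,
    n_mirna: int,
    n_mrna: int,
    planted: Sequence[TruthRecord] = (),
    family: str = reg.GAUSSIAN,
    noise: Optional[NoiseParams] = None,
    seed: int = 0,
) -> tuple[PairedDataset, list[TruthRecord]]:
    """Paired miRNA/mRNA matrices with regressions planted under one family.

    miRNA values are log-normal draws (integer-rounded for count families).
    Each ``beta1`` planting generates its target mRNA through the family's
    canonical link from its miRNA predictor; ``beta3`` plantings use the
    product of two predictors. Non-planted mRNAs are independent of every
    miRNA. For Gaussian plantings with the default intercept, the intercept
    is raised until the noiseless response is comfortably positive, keeping
    the expression-matrix non-negativity invariant without truncation bias.
    """
    if family not in reg.FAMILY_ORDER:
        raise ValueError(f"family must be one of {reg.FAMILY_ORDER}, not {family!r}")
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    mirna_ids = _mirna_ids(n_mirna)
    mrna_ids = _mrna_ids(n_mrna)
    samples = [f"s{j:03d}" for j in range(1, n_samples + 1)]
    is_count = family in reg.COUNT_FAMILIES

    mirna_vals = rng.lognormal(BASELINE_MEANLOG, BASELINE_SDLOG, size=(n_mirna, n_samples))
    if is_count:
        mirna_vals = np.round(mirna_vals)
    mirna_df = pd.DataFrame(mirna_vals, index=mirna_ids, columns=samples)

    planted = list(planted)
    targets: dict[str, TruthRecord] = {}
    for t in planted:
        if t.effect not in ("beta1", "beta3"):
            raise ValueError(f"paired-count plantings must be beta1/beta3, not {t.effect!r}")
        for mid in filter(None, (t.mirna_id, t.mirna_id2)):
            if mid not in mirna_df.index:
                raise ValueError(f"planted miRNA {mid!r} outside generated id range")
        if t.mrna_id not in mrna_ids:
            raise ValueError(f"planted mRNA {t.mrna_id!r} outside generated id range")
        if t.mrna_id in targets:
            raise ValueError(f"contradictory plantings: mRNA {t.mrna_id!r} planted twice")
        targets[t.mrna_id] = t

    mrna_rows = np.empty((n_mrna, n_samples))
    for i, gid in enumerate(mrna_ids):
        t = targets.get(gid)
        if t is None:
            # Background: independent of all miRNAs, same family as planted rows.
            if is_count:
                eta = rng.normal(2.0, 0.5) * np.ones(n_samples)
                mrna_rows[i] = _count_response(rng, eta, family, noise)
            else:
                mrna_rows[i] = rng.lognormal(BASELINE_MEANLOG, BASELINE_SDLOG, n_samples)
            continue
        if t.effect == "beta1":
            pred = mirna_df.loc[t.mirna_id].to_numpy() * t.value
        else:
            pred = (mirna_df.loc[t.mirna_id].to_numpy()
                    * mirna_df.loc[t.mirna_id2].to_numpy() * t.value)
        if is_count:
            beta0 = noise.beta0 if noise.beta0 is not None else 2.0
            mrna_rows[i] = _count_response(rng, beta0 + pred, family, noise)
        else:
            if noise.beta0 is not None:
                beta0 = noise.beta0
            else:
                beta0 = max(10.0, 10.0 - float(np.min(pred)))
            y = beta0 + pred + rng.normal(0.0, noise.sigma, n_samples)
            mrna_rows[i] = np.clip(y, 0.0, None)

    mrna_df = pd.DataFrame(mrna_rows, index=mrna_ids, columns=samples)
    unit = "counts" if is_count else "tpm"
    dataset = PairedDataset(
        mirna=ExpressionMatrix(mirna_df, unit=unit),
        mrna=ExpressionMatrix(mrna_df, unit=unit),
    )
    truth = [TruthRecord(t.mirna_id, t.mrna_id, t.effect, t.value,
                         mirna_id2=t.mirna_id2, family=family) for t in planted]
    return dataset, truth


# ---------------------------------------------------------------------------
# Fold-change tables (Parts 2-3 fixtures)
# ---------------------------------------------------------------------------


def _exact_correlated_vector(rng: np.random.Generator, x: np.ndarray, r: float) -> np.ndarray:
    """A vector whose sample Pearson correlation with x equals r exactly."""
    n = len(x)
    xc = x - x.mean()
    xn = xc / np.linalg.norm(xc)
    z = rng.normal(0.0, 1.0, n)
    zc = z - z.mean()
    zc = zc - (zc @ xn) * xn          # orthogonal to x and to the constant
    nz = np.linalg.norm(zc)
    if nz < 1e-12:                     # pathological draw; retry deterministically
        return _exact_correlated_vector(rng, x, r)
    zn = zc / nz
    y = r * xn + np.sqrt(max(0.0, 1.0 - r * r)) * zn
    return y * FC_BACKGROUND_SD * np.sqrt(n) + rng.normal(0.0, 0.5)


def simulate_fc_tables(
    n_comparisons: int,
    n_mirna: int,
    n_mrna: int,
    planted_corr: Sequence[TruthRecord] = (),
    planted_diff: Sequence[TruthRecord] = (),
    seed: int = 0,
) -> tuple[FoldChangeTable, FoldChangeTable, list[TruthRecord]]:
    """Fold-change tables with planted pair correlations and differences.

    ``planted_corr`` records (effect "r") make the target mRNA's vector
    correlate with its miRNA's vector at exactly the requested r (needs
    >= 3 comparisons). ``planted_diff`` records (effect "d") set the first
    comparison column so |x - y| equals the requested d exactly, split
    symmetrically across the two features. Background features are i.i.d.
    normal with sd ``FC_BACKGROUND_SD``.
    """
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    planted_corr = list(planted_corr)
    planted_diff = list(planted_diff)
    if planted_corr and n_comparisons < 3:
        raise ValueError("planted correlations need >= 3 comparisons")

    mirna_ids = _mirna_ids(n_mirna)
    mrna_ids = _mrna_ids(n_mrna)
    labels = [f"cmp_{j}" for j in range(1, n_comparisons + 1)]
    rng = np.random.default_rng(seed)

    fc_m = rng.normal(0.0, FC_BACKGROUND_SD, size=(n_mirna, n_comparisons))
    fc_r = rng.normal(0.0, FC_BACKGROUND_SD, size=(n_mrna, n_comparisons))
    mirna_pos = {m: i for i, m in enumerate(mirna_ids)}
    mrna_pos = {g: i for i, g in enumerate(mrna_ids)}

    touched_mrna: set[str] = set()
    touched_mirna_diff: set[str] = set()
    for t in planted_corr:
        if t.effect != "r":
            raise ValueError("planted_corr records must carry effect 'r'")
        if not -1.0 <= t.value <= 1.0:
            raise ValueError(f"target correlation {t.value} outside [-1, 1]")
        if t.mirna_id not in mirna_pos or t.mrna_id not in mrna_pos:
            raise ValueError(f"planted pair ({t.mirna_id}, {t.mrna_id}) outside id range")
        if t.mrna_id in touched_mrna:
            raise ValueError(f"contradictory plantings on mRNA {t.mrna_id!r}")
        touched_mrna.add(t.mrna_id)
        x = fc_m[mirna_pos[t.mirna_id]]
        fc_r[mrna_pos[t.mrna_id]] = _exact_correlated_vector(rng, x, t.value)

    for t in planted_diff:
        if t.effect != "d":
            raise ValueError("planted_diff records must carry effect 'd'")
        if t.value < 0:
            raise ValueError("planted d must be >= 0")
        if t.mirna_id not in mirna_pos or t.mrna_id not in mrna_pos:
            raise ValueError(f"planted pair ({t.mirna_id}, {t.mrna_id}) outside id range")
        if t.mrna_id in touched_mrna or t.mirna_id in touched_mirna_diff:
            raise ValueError(
                f"contradictory plantings on pair ({t.mirna_id!r}, {t.mrna_id!r})"
            )
        touched_mrna.add(t.mrna_id)
        touched_mirna_diff.add(t.mirna_id)
        # Split the divergence symmetrically (miRNA up, mRNA down) so neither
        # single row dominates the background null on its own.
        base = rng.normal(0.0, 1.0)
        fc_m[mirna_pos[t.mirna_id], 0] = base + t.value / 2.0
        fc_r[mrna_pos[t.mrna_id], 0] = base - t.value / 2.0

    table_m = FoldChangeTable(pd.DataFrame(fc_m, index=mirna_ids, columns=labels))
    table_r = FoldChangeTable(pd.DataFrame(fc_r, index=mrna_ids, columns=labels))
    return table_m, table_r, planted_corr + planted_diff


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------


def simulate_prediction_table(
    truth: Sequence[TruthRecord],
    decoy_count: int = 0,
    score_range: tuple[float, float] = DEFAULT_SCORE_RANGE,
    seed: int = 0,
    mirna_pool: Optional[Sequence[str]] = None,
    mrna_pool: Optional[Sequence[str]] = None,
) -> PredictionTable:
    """A miRanda-style prediction table covering every truth pair.

    Scores are uniform in ``score_range`` (default the observed miRanda range
    140-189); folding energies are negative uniforms. ``decoy_count`` extra
    non-truth pairs are drawn from the given id pools, or synthesized with
    unmistakable decoy ids when no pools are supplied.
    """
    low, high = score_range
    if not low < high:
        raise ValueError("score_range must satisfy low < high")
    rng = np.random.default_rng(seed)
    truth_pairs = [(t.mirna_id, t.mrna_id) for t in truth]

    decoys: list[tuple[str, str]] = []
    if decoy_count > 0:
        taken = set(truth_pairs)
        if mirna_pool and mrna_pool:
            candidates = [
                (m, g) for m in mirna_pool for g in mrna_pool if (m, g) not in taken
            ]
            if len(candidates) < decoy_count:
                raise ValueError(
                    f"id pools admit only {len(candidates)} decoys, need {decoy_count}"
                )
            idx = rng.choice(len(candidates), size=decoy_count, replace=False)
            decoys = [candidates[i] for i in idx]
        else:
            decoys = [(f"decoy_mir_{i:04d}", f"decoy_gene_{i:04d}")
                      for i in range(1, decoy_count + 1)]

    pairs = truth_pairs + decoys
    n = len(pairs)
    df = pd.DataFrame({
        "mirna_id": [p[0] for p in pairs],
        "gene_id": [p[1] for p in pairs],
        "score": rng.uniform(low, high, n),
        "energy": rng.uniform(-35.0, -8.0, n),
        "seed_score": rng.uniform(120.0, 170.0, n),
        "align_score": rng.uniform(100.0, 200.0, n),
    })
    return PredictionTable(df, source="miranda")
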