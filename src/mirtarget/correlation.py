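"""Fold-change correlation across three or more comparisons (Part 2).

For each candidate pair the Pearson correlation r between the miRNA's and
the mRNA's log2 fold-change vectors is compared against a background null
distribution built by sampling random cross-pairs from the same tables.
P-values are rank-based with an add-one correction, so the smallest
attainable p is 1/(n_perm + 1) and p = 0 is impossible.

Two null constructions are available. ``per_pair`` (the default) draws a
fresh set of n_perm random cross-pairs for every tested pair, which makes
global-null p-values independent and uniform across a run at O(n_pairs *
n_perm) cost. ``shared`` reuses one n_perm-sized null for every pair — far
cheaper on very large candidate sets, but the reported p-values then share
the null's sampling error and are not jointly independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import FoldChangeTable, PairList, PredictionTable
from .regression import bh_adjust

logger = logging.getLogger("mirtarget")

NULL_CORRELATION = "correlation"
NULL_DIFFERENCE = "difference"

ALTERNATIVES = ("negative", "positive", "two_sided")

#: Resampling depth used when none is given. Documentation recommends >= 1000
#: for stable tail estimates; 100 keeps exploratory runs cheap.
DEFAULT_N_PERM = 100


class DegenerateVectorError(ValueError):
    """A correlation is undefined because one input vector is constant."""


@dataclass
class NullDistribution:
    """Resampled background statistic values."""

    values: np.ndarray
    seed: int
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in (NULL_CORRELATION, NULL_DIFFERENCE):
            raise ValueError(f"unknown null kind {self.kind!r}")

    @property
    def n_perm(self) -> int:
        return len(self.values)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Requires length >= 3 (fewer comparisons cannot anchor a correlation) and
    non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 comparisons for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateVectorError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def _usable_rows(table: FoldChangeTable) -> np.ndarray:
    """Row indices whose fold-change vectors are non-constant."""
    values = table.data.to_numpy(dtype=float)
    return np.flatnonzero(values.std(axis=1) > 0)


def build_null_corr(
    fc_mirna: FoldChangeTable,
    fc_mrna: FoldChangeTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> NullDistribution:
    """Background correlations of randomly drawn (miRNA, mRNA) cross-pairs.

    Pairs are drawn uniformly with replacement from the non-constant rows of
    each table; deterministic for a given seed.
    """
    if fc_mirna.comparison_labels != fc_mrna.comparison_labels:
        raise ValueError("fold-change tables must share the same comparison columns")
    if fc_mirna.n_comparisons < 3:
        raise ValueError("correlation null needs >= 3 comparisons")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    m_rows = _usable_rows(fc_mirna)
    r_rows = _usable_rows(fc_mrna)
    if len(m_rows) < 2 or len(r_rows) < 2:
        raise ValueError("need >= 2 non-constant features on each side to build a null")
    rng = np.random.default_rng(seed)
    m_vals = fc_mirna.data.to_numpy(dtype=float)
    r_vals = fc_mrna.data.to_numpy(dtype=float)
    mi = rng.choice(m_rows, size=n_perm, replace=True)
    ri = rng.choice(r_rows, size=n_perm, replace=True)
    xs = m_vals[mi]
    ys = r_vals[ri]
    xs_c = xs - xs.mean(axis=1, keepdims=True)
    ys_c = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xs_c**2).sum(axis=1) * (ys_c**2).sum(axis=1))
    values = (xs_c * ys_c).sum(axis=1) / denom
    return NullDistribution(values=values, seed=seed, kind=NULL_CORRELATION)


def corr_pvalue(r_obs: float, null: NullDistribution, alternative: str = "negative") -> float:
    """Rank-based permutation p-value with add-one correction.

    negative: p = (1 + #{r_null <= r_obs}) / (n_perm + 1); positive mirrors;
    two_sided counts |r_null| >= |r_obs|.
    """
    if null.kind != NULL_CORRELATION:
        raise ValueError("corr_pvalue requires a correlation null")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    n = null.n_perm
    if alternative == "negative":
        count = int(np.sum(null.values <= r_obs))
    elif alternative == "positive":
        count = int(np.sum(null.values >= r_obs))
    else:
        count = int(np.sum(np.abs(null.values) >= abs(r_obs)))
    return (1 + count) / (n + 1)


def _per_pair_corr_pvalues(
    fc_mirna: FoldChangeTable,
    fc_mrna: FoldChangeTable,
    r_obs: np.ndarray,
    n_perm: int,
    seed: int,
    alternative: str,
    chunk: int = 512,
) -> np.ndarray:
    """Add-one rank p-values, each against its own resampled cross-pair null."""
    m_rows = _usable_rows(fc_mirna)
    r_rows = _usable_rows(fc_mrna)
    if len(m_rows) < 2 or len(r_rows) < 2:
        raise ValueError("need >= 2 non-constant features on each side to build a null")

    def _unit_rows(values: np.ndarray, rows: np.ndarray) -> np.ndarray:
        v = values[rows]
        v = v - v.mean(axis=1, keepdims=True)
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    mu = _unit_rows(fc_mirna.data.to_numpy(dtype=float), m_rows)
    ru = _unit_rows(fc_mrna.data.to_numpy(dtype=float), r_rows)
    rng = np.random.default_rng(seed)
    counts = np.empty(len(r_obs), dtype=np.int64)
    for start in range(0, len(r_obs), chunk):
        stop = min(start + chunk, len(r_obs))
        size = (stop - start, n_perm)
        null = np.einsum(
            "pnc,pnc->pn",
            mu[rng.integers(len(mu), size=size)],
            ru[rng.integers(len(ru), size=size)],
        )
        obs = r_obs[start:stop, None]
        if alternative == "negative":
            counts[start:stop] = (null <= obs).sum(axis=1)
        elif alternative == "positive":
            counts[start:stop] = (null >= obs).sum(axis=1)
        else:
            counts[start:stop] = (np.abs(null) >= np.abs(obs)).sum(axis=1)
    return (1 + counts) / (n_perm + 1)


def run_part2(
    fc_mirna: FoldChangeTable,
    fc_mrna: FoldChangeTable,
    pairs: Optional[PairList] = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alternative: str = "negative",
    alpha: float = 0.05,
    r_max: Optional[float] = None,
    predictions: Optional[PredictionTable] = None,
    null_mode: str = "per_pair",
) -> pd.DataFrame:
    """Correlate every candidate pair's fold-change vectors against a resampled null.

    Returns a table with columns mirna_id, mrna_id, r, p, p_adj,
    n_comparisons, prediction_score, significant. Pairs with a constant
    vector are skipped and logged. Optional filters: keep only r <= r_max
    (e.g. -0.85 for strong repression candidates) and/or pairs present in a
    prediction table. ``null_mode`` chooses between an independent resampled
    null per pair (default; global-null p-values are then iid uniform) and a
    single shared null for the whole run (cheapest on huge candidate sets).
    """
    if fc_mirna.comparison_labels != fc_mrna.comparison_labels:
        raise ValueError("fold-change tables must share the same comparison columns")
    if null_mode not in ("per_pair", "shared"):
        raise ValueError("null_mode must be 'per_pair' or 'shared'")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    n_comp = fc_mirna.n_comparisons
    if n_comp < 3:
        raise ValueError("correlation analysis needs >= 3 shared comparisons")

    if pairs is None:
        pair_items = [(m, g) for m in fc_mirna.feature_ids for g in fc_mrna.feature_ids]
    else:
        pair_items = list(pairs)
    score_by_pair = predictions.score_lookup() if predictions is not None else None
    if score_by_pair is not None:
        pair_items = [p for p in pair_items if p in score_by_pair]

    rows = []
    skipped = []
    for mirna_id, mrna_id in pair_items:
        x = fc_mirna.row(mirna_id)
        y = fc_mrna.row(mrna_id)
        try:
            r = pearson_r(x, y)
        except DegenerateVectorError:
            skipped.append((mirna_id, mrna_id, "constant fold-change vector"))
            continue
        rows.append({
            "mirna_id": mirna_id,
            "mrna_id": mrna_id,
            "r": r,
            "n_comparisons": n_comp,
            "prediction_score": (
                score_by_pair[(mirna_id, mrna_id)] if score_by_pair is not None else np.nan
            ),
        })
    if rows:
        r_obs = np.array([row["r"] for row in rows])
        if null_mode == "shared":
            null = build_null_corr(fc_mirna, fc_mrna, n_perm=n_perm, seed=seed)
            pvals = np.array([corr_pvalue(r, null, alternative) for r in r_obs])
        else:
            pvals = _per_pair_corr_pvalues(
                fc_mirna, fc_mrna, r_obs, n_perm, seed, alternative
            )
        for row, p in zip(rows, pvals):
            row["p"] = p
    if skipped:
        logger.warning("part2: skipped %d pair(s) with constant vectors", len(skipped))

    table = pd.DataFrame(
        rows, columns=["mirna_id", "mrna_id", "r", "p", "n_comparisons", "prediction_score"]
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    if r_max is not None and len(table):
        table = table[table["r"] <= r_max]
    table["significant"] = (table["p_adj"] < alpha) if len(table) else []
    table = (
        table[["mirna_id", "mrna_id", "r", "p", "p_adj", "n_comparisons",
               "prediction_score", "significant"]]
        .sort_values(["p_adj", "p", "r", "mirna_id", "mrna_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    table.attrs["skipped"] = skipped
    table.attrs["null_seed"] = seed
    return table
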