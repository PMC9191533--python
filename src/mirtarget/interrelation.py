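"""Two-timepoint interrelation analysis (Part 3).

For a single comparison interval (e.g. 4h vs 24h) each candidate pair is
scored by d = |x - y|, the absolute difference between the miRNA's and the
mRNA's log2 fold change over that interval. Large d marks pairs whose
fold changes diverge far more than random cross-pairs do; significance is
the upper tail of a resampled background of random-pair differences.
Independently of the test, each pair is classified by the sign pattern of
its two fold changes (repression-like opposite signs vs coregulation).
"""

from __future__ import annotations

import enum
import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core_io import FoldChangeTable, PairList, PredictionTable
from .correlation import NULL_DIFFERENCE, NullDistribution
from .regression import bh_adjust

logger = logging.getLogger("mirtarget")


class RegulationClass(str, enum.Enum):
    """Sign-pattern classes of a (miRNA FC, mRNA FC) pair."""

    MIRNA_UP_MRNA_DOWN = "mirna_up_mrna_down"
    MIRNA_DOWN_MRNA_UP = "mirna_down_mrna_up"
    COREGULATION_INCREASE = "coregulation_increase"
    COREGULATION_DECREASE = "coregulation_decrease"
    NO_CHANGE = "no_change"


#: Human-readable display labels applied at serialization time. The mapping
#: is configurable because published usage of "inverse" vs "negative"
#: regulation is not consistent; the sign-pattern enum is authoritative.
DISPLAY_LABELS: dict[RegulationClass, str] = {
    RegulationClass.MIRNA_UP_MRNA_DOWN: "Inverse Regulation",
    RegulationClass.MIRNA_DOWN_MRNA_UP: "Negative Regulation",
    RegulationClass.COREGULATION_INCREASE: "Coregulation (increase)",
    RegulationClass.COREGULATION_DECREASE: "Coregulation (reduction)",
    RegulationClass.NO_CHANGE: "No Change",
}


def difference_stat(x: float, y: float) -> float:
    """Interrelation statistic d = |x - y| for two log2 fold changes."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("fold changes must be finite")
    return abs(float(x) - float(y))


def classify_regulation(
    log2fc_mirna: float, log2fc_mrna: float, zero_tol: float = 0.0
) -> RegulationClass:
    """Classify a pair by the signs of its two fold changes.

    Values within ``zero_tol`` of zero count as no change (useful for
    shrunken fold-change inputs); the default tolerance is exact zero.
    """
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    sx = 0 if abs(log2fc_mirna) <= zero_tol else (1 if log2fc_mirna > 0 else -1)
    sy = 0 if abs(log2fc_mrna) <= zero_tol else (1 if log2fc_mrna > 0 else -1)
    if sx == 0 or sy == 0:
        return RegulationClass.NO_CHANGE
    if sx > 0 and sy < 0:
        return RegulationClass.MIRNA_UP_MRNA_DOWN
    if sx < 0 and sy > 0:
        return RegulationClass.MIRNA_DOWN_MRNA_UP
    if sx > 0:
        return RegulationClass.COREGULATION_INCREASE
    return RegulationClass.COREGULATION_DECREASE


def build_null_diff(
    fc_mirna: FoldChangeTable,
    fc_mrna: FoldChangeTable,
    n_perm: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Background |x - y| values from uniformly random cross-pairs."""
    if fc_mirna.comparison_labels != fc_mrna.comparison_labels:
        raise ValueError("fold-change tables must share the same comparison column")
    if fc_mirna.n_comparisons != 1:
        raise ValueError("interrelation analysis uses exactly one comparison column")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    x = fc_mirna.data.to_numpy(dtype=float)[:, 0]
    y = fc_mrna.data.to_numpy(dtype=float)[:, 0]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("fold-change tables must be non-empty")
    rng = np.random.default_rng(seed)
    values = np.abs(x[rng.integers(len(x), size=n_perm)] - y[rng.integers(len(y), size=n_perm)])
    return NullDistribution(values=values, seed=seed, kind=NULL_DIFFERENCE)


def diff_pvalue(d_obs: float, null: NullDistribution) -> float:
    """Upper-tail rank p-value with add-one correction."""
    if null.kind != NULL_DIFFERENCE:
        raise ValueError("diff_pvalue requires a difference null")
    return (1 + int(np.sum(null.values >= d_obs))) / (null.n_perm + 1)


def _per_pair_diff_pvalues(
    fc_mirna: FoldChangeTable,
    fc_mrna: FoldChangeTable,
    d_obs: np.ndarray,
    n_perm: int,
    seed: int,
    chunk: int = 512,
) -> np.ndarray:
    """Upper-tail add-one p-values, each against its own resampled null."""
    x = fc_mirna.data.to_numpy(dtype=float)[:, 0]
    y = fc_mrna.data.to_numpy(dtype=float)[:, 0]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("fold-change tables must be non-empty")
    rng = np.random.default_rng(seed)
    counts = np.empty(len(d_obs), dtype=np.int64)
    for start in range(0, len(d_obs), chunk):
        stop = min(start + chunk, len(d_obs))
        size = (stop - start, n_perm)
        null = np.abs(x[rng.integers(len(x), size=size)] - y[rng.integers(len(y), size=size)])
        counts[start:stop] = (null >= d_obs[start:stop, None]).sum(axis=1)
    return (1 + counts) / (n_perm + 1)


def run_part3(
    fc_mirna: FoldChangeTable,
    fc_mrna: FoldChangeTable,
    pairs: Optional[PairList] = None,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    zero_tol: float = 0.0,
    predictions: Optional[PredictionTable] = None,
    display_labels: Optional[Mapping[RegulationClass, str]] = None,
    null_mode: str = "per_pair",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every candidate pair's fold-change divergence over one interval.

    Returns ``(table, matrix)``: a long-format result table with columns
    mirna_id, mrna_id, log2fc_mirna, log2fc_mrna, d, p, p_adj, regulation,
    prediction_score, significant; and a wide miRNA x mRNA matrix of d values
    with non-significant cells blank (NaN), suitable for heatmap rendering.
    ``display_labels`` optionally maps the sign-pattern classes onto
    publication-style labels in the serialized regulation column.
    ``null_mode`` chooses between an independent resampled null per pair
    (default; global-null p-values are then iid uniform) and a single shared
    null for the whole run.
    """
    if fc_mirna.n_comparisons != 1 or fc_mrna.n_comparisons != 1:
        raise ValueError("interrelation analysis uses exactly one comparison column")
    if fc_mirna.comparison_labels != fc_mrna.comparison_labels:
        raise ValueError("fold-change tables must share the same comparison column")
    if null_mode not in ("per_pair", "shared"):
        raise ValueError("null_mode must be 'per_pair' or 'shared'")

    if pairs is None:
        pair_items = [(m, g) for m in fc_mirna.feature_ids for g in fc_mrna.feature_ids]
    else:
        pair_items = list(pairs)
    score_by_pair = predictions.score_lookup() if predictions is not None else None
    if score_by_pair is not None:
        pair_items = [p for p in pair_items if p in score_by_pair]

    labels = dict(display_labels) if display_labels is not None else None

    rows = []
    for mirna_id, mrna_id in pair_items:
        x = float(fc_mirna.row(mirna_id)[0])
        y = float(fc_mrna.row(mrna_id)[0])
        d = difference_stat(x, y)
        cls = classify_regulation(x, y, zero_tol=zero_tol)
        rows.append({
            "mirna_id": mirna_id,
            "mrna_id": mrna_id,
            "log2fc_mirna": x,
            "log2fc_mrna": y,
            "d": d,
            "regulation": labels[cls] if labels is not None else cls.value,
            "prediction_score": (
                score_by_pair[(mirna_id, mrna_id)] if score_by_pair is not None else np.nan
            ),
        })
    if rows:
        d_obs = np.array([row["d"] for row in rows])
        if null_mode == "shared":
            null = build_null_diff(fc_mirna, fc_mrna, n_perm=n_perm, seed=seed)
            pvals = np.array([diff_pvalue(d, null) for d in d_obs])
        else:
            pvals = _per_pair_diff_pvalues(fc_mirna, fc_mrna, d_obs, n_perm, seed)
        for row, p in zip(rows, pvals):
            row["p"] = p

    table = pd.DataFrame(
        rows,
        columns=["mirna_id", "mrna_id", "log2fc_mirna", "log2fc_mrna", "d", "p",
                 "regulation", "prediction_score"],
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["significant"] = (table["p_adj"] < alpha) if len(table) else []
    table = (
        table[["mirna_id", "mrna_id", "log2fc_mirna", "log2fc_mrna", "d", "p",
               "p_adj", "regulation", "prediction_score", "significant"]]
        .sort_values(["p_adj", "p", "mirna_id", "mrna_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    sig = table[table["significant"]]
    if len(sig):
        matrix = sig.pivot(index="mrna_id", columns="mirna_id", values="d")
    else:
        matrix = pd.DataFrame(index=pd.Index([], name="mrna_id"),
                              columns=pd.Index([], name="mirna_id"))
    logger.info("part3: %d pair(s), %d significant at alpha=%g", len(table), len(sig), alpha)
    return table, matrix
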