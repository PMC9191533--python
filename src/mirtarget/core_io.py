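"""Tabular input/output, validation and candidate-pair enumeration.

All expression, fold-change and target-prediction inputs are tab-separated
text with a header row. Matrices are held as pandas DataFrames wrapped in
thin dataclasses that enforce the invariants the statistical modules rely
on (no negative expression, unique ids, aligned samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirtarget")

EXPRESSION_UNITS = ("counts", "cpm", "tpm", "rpkm")
PREDICTION_SOURCES = ("miranda", "targetscan")

#: Columns of a miRanda-style prediction TSV. ``energy`` is the folding
#: energy in kcal/mol (non-positive for a real duplex), ``seed_score`` and
#: ``align_score`` are the seed-match and alignment components of the total.
MIRANDA_COLUMNS = ("mirna_id", "gene_id", "score", "energy", "seed_score", "align_score")
MIRANDA_REQUIRED = ("mirna_id", "gene_id", "score")
TARGETSCAN_REQUIRED = ("mirna_id", "gene_id", "context_score_percentile")

#: Significant digits used when serializing numeric result columns.
RESULT_SIGNIFICANT_DIGITS = 10


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A feature x sample matrix of non-negative expression values.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with sample ids as columns.
    unit:
        One of ``counts``, ``cpm``, ``tpm``, ``rpkm``.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValidationError(
                f"unknown expression unit {self.unit!r}; expected one of {EXPRESSION_UNITS}"
            )
        _check_unique(self.data.index, "feature id")
        _check_unique(self.data.columns, "sample id")
        self.data.index.name = "feature_id"
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric cells")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"non-numeric or missing cell at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value {values[r, c]} at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def row(self, feature_id: str) -> np.ndarray:
        """Return one feature's values across samples as a float vector."""
        if feature_id not in self.data.index:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return self.data.loc[feature_id].to_numpy(dtype=float)


@dataclass
class PairedDataset:
    """miRNA and mRNA expression matrices over the same ordered samples."""

    mirna: ExpressionMatrix
    mrna: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.mirna.sample_ids != self.mrna.sample_ids:
            raise ValidationError(
                "paired matrices must share identical, identically ordered sample ids; "
                "use align_paired() first"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.mirna.sample_ids

    @property
    def n_samples(self) -> int:
        return self.mirna.n_samples


@dataclass
class FoldChangeTable:
    """Feature x comparison table of log2 fold changes."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature id")
        _check_unique(self.data.columns, "comparison label")
        self.data.index.name = "feature_id"
        if self.data.shape[1] < 1:
            raise ValidationError("fold-change table needs at least one comparison column")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
            raise ValidationError("fold-change table contains non-finite or non-numeric values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def comparison_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_comparisons(self) -> int:
        return self.data.shape[1]

    def row(self, feature_id: str) -> np.ndarray:
        if feature_id not in self.data.index:
            raise KeyError(f"feature {feature_id!r} not in fold-change table")
        return self.data.loc[feature_id].to_numpy(dtype=float)


@dataclass
class PredictionTable:
    """Canonicalized (miRNA, gene) target-prediction records.

    One row per (mirna_id, gene_id) pair; duplicates are collapsed on
    construction keeping the best-scoring site. For ``targetscan`` sources the
    ``score`` column carries the context score percentile in [0, 100].
    """

    data: pd.DataFrame
    source: str = "miranda"

    def __post_init__(self) -> None:
        if self.source not in PREDICTION_SOURCES:
            raise ValidationError(f"unknown prediction source {self.source!r}")
        for col in MIRANDA_REQUIRED:
            if col not in self.data.columns:
                raise ValidationError(f"prediction table missing mandatory column {col!r}")
        df = self.data
        if df.duplicated(subset=["mirna_id", "gene_id"]).any():
            df = (
                df.sort_values("score", kind="mergesort")
                .drop_duplicates(subset=["mirna_id", "gene_id"], keep="last")
                .sort_index()
            )
        self.data = df.reset_index(drop=True)
        if "energy" in self.data.columns:
            bad = self.data["energy"].dropna() > 0
            if bad.any():
                logger.warning(
                    "%d prediction record(s) have positive folding energy; values kept",
                    int(bad.sum()),
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def scores(self) -> np.ndarray:
        return self.data["score"].to_numpy(dtype=float)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.data["mirna_id"], self.data["gene_id"]))

    def score_lookup(self) -> dict[tuple[str, str], float]:
        return dict(zip(zip(self.data["mirna_id"], self.data["gene_id"]), self.data["score"]))


@dataclass
class PairList:
    """Ordered, unique (mirna_id, mrna_id) candidate pairs."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("pair list contains duplicate (mirna, mrna) tuples")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _check_unique(index: Iterable, what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate {what}: {dup!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={0: str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"cannot parse TSV {path}: {exc}") from exc


def read_expression_matrix(path, unit: str) -> ExpressionMatrix:
    """Read a feature x sample expression TSV.

    The first column holds feature ids (header ``feature_id``); the remaining
    headers are sample ids. Values must be non-negative numbers.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expression matrix needs feature ids plus >=1 sample")
    df = df.set_index(df.columns[0])
    df.index.name = "feature_id"
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), unit=unit)


def read_fold_change_table(path) -> FoldChangeTable:
    """Read a feature x comparison log2 fold-change TSV."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: fold-change table needs feature ids plus >=1 comparison")
    df = df.set_index(df.columns[0])
    df.index.name = "feature_id"
    return FoldChangeTable(df.apply(pd.to_numeric, errors="raise").astype(float))


def read_prediction_table(path, source: str = "miranda") -> PredictionTable:
    """Read a miRanda-style or TargetScan target-prediction TSV.

    The miranda dialect expects columns ``mirna_id, gene_id, score`` and
    optionally ``energy, seed_score, align_score``. The targetscan dialect
    expects ``mirna_id, gene_id, context_score_percentile``; the percentile is
    mapped into ``score``.
    """
    df = _read_tsv(path)
    if source == "targetscan":
        for col in TARGETSCAN_REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"{path}: missing mandatory column {col!r}")
        df = df.rename(columns={"context_score_percentile": "score"})
        out_of_range = (df["score"] < 0) | (df["score"] > 100)
        if out_of_range.any():
            raise ValidationError(
                f"{path}: context score percentile outside [0, 100] "
                f"({df.loc[out_of_range, 'score'].iloc[0]})"
            )
    else:
        for col in MIRANDA_REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"{path}: missing mandatory column {col!r}")
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    return PredictionTable(df, source=source)


# ---------------------------------------------------------------------------
# Alignment and filtering
# ---------------------------------------------------------------------------

MIN_SHARED_SAMPLES = 3


def align_paired(mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> PairedDataset:
    """Subset both matrices to their shared samples, in miRNA-matrix order.

    Samples present on only one side are dropped and logged. Fewer than three
    shared samples is an error — regression on fewer is meaningless.
    """
    shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValidationError(
            f"only {len(shared)} shared sample(s) between miRNA and mRNA matrices; "
            f"need >= {MIN_SHARED_SAMPLES}"
        )
    dropped = sorted(set(mirna.sample_ids).symmetric_difference(mrna.sample_ids))
    if dropped:
        logger.info("align_paired: dropped unmatched samples %s", dropped)
    return PairedDataset(
        mirna=ExpressionMatrix(mirna.data[shared], unit=mirna.unit),
        mrna=ExpressionMatrix(mrna.data[shared], unit=mrna.unit),
    )


def filter_predictions(
    table: PredictionTable,
    min_score: Optional[float] = None,
    percentile: Optional[float] = None,
) -> PredictionTable:
    """Filter prediction records by an absolute or percentile score cutoff.

    ``min_score`` keeps records with score >= min_score (inclusive floor, the
    conventional ">=140" usage). ``percentile`` computes the given percentile
    (linear interpolation) over all scores in the table and keeps records
    strictly above it (the "above the 99th percentile" usage). Exactly one of
    the two must be supplied.
    """
    if (min_score is None) == (percentile is None):
        raise ValueError("supply exactly one of min_score / percentile")
    if min_score is not None:
        kept = table.data[table.data["score"] >= min_score]
    else:
        if not 0 <= percentile <= 100:
            raise ValueError("percentile must lie in [0, 100]")
        if len(table) == 0:
            raise ValidationError("cannot take a percentile of an empty prediction table")
        cutoff = float(np.percentile(table.scores, percentile))
        kept = table.data[table.data["score"] > cutoff]
    return PredictionTable(kept.reset_index(drop=True), source=table.source)


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------


def count_pairs(
    mirna_ids: Sequence[str],
    mrna_ids: Sequence[str],
    predictions: Optional[PredictionTable] = None,
) -> int:
    """Number of candidate pairs without materializing them.

    Without predictions this is simply ``len(mirna_ids) * len(mrna_ids)``;
    with predictions it is the size of the intersection of the Cartesian
    product with the prediction records.
    """
    if predictions is None:
        return len(mirna_ids) * len(mrna_ids)
    mirna_set = set(mirna_ids)
    mrna_set = set(mrna_ids)
    return sum(
        1 for m, g in predictions.pair_set() if m in mirna_set and g in mrna_set
    )


def enumerate_pairs(
    mirna_ids: Sequence[str],
    mrna_ids: Sequence[str],
    predictions: Optional[PredictionTable] = None,
) -> PairList:
    """Enumerate candidate (miRNA, mRNA) pairs in miRNA-major order.

    Without a prediction table the result is the full Cartesian product; with
    one, only pairs present in the (filtered) table are kept, in the same
    deterministic order.
    """
    if predictions is None:
        pairs = [(m, g) for m in mirna_ids for g in mrna_ids]
    else:
        allowed = predictions.pair_set()
        pairs = [(m, g) for m in mirna_ids for g in mrna_ids if (m, g) in allowed]
    logger.info("enumerate_pairs: %d candidate pair(s)", len(pairs))
    return PairList(pairs)


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a per-pair result table as TSV.

    Numeric fields are serialized at 10 significant digits, which round-trips
    the statistics reported by this package losslessly at that precision;
    values that are exact small integers (p = 1) serialize without noise.
    """
    if results is None:
        raise ValueError("results must not be None")
    results.to_csv(
        path, sep="\t", index=False, float_format=f"%.{RESULT_SIGNIFICANT_DIGITS}g"
    )


def read_results_table(path) -> pd.DataFrame:
    """Re-read a TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write an expression matrix in the TSV dialect read_expression_matrix expects."""
    matrix.data.to_csv(path, sep="\t", index_label="feature_id",
                       float_format=f"%.{RESULT_SIGNIFICANT_DIGITS}g")


def write_fold_change_table(table: FoldChangeTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id",
                      float_format=f"%.{RESULT_SIGNIFICANT_DIGITS}g")


def write_prediction_table(table: PredictionTable, path) -> None:
    write_results_table(table.data, path)
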