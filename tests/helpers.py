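"""Shared test utilities, independent of the library's fitting code paths."""

import numpy as np
import pandas as pd

from mirtarget import ExpressionMatrix, PairedDataset


def make_paired(x: np.ndarray, y: np.ndarray, unit: str = "tpm",
                extra_mirna: dict | None = None) -> PairedDataset:
    """Minimal paired dataset with one miRNA row 'mir' and one mRNA row 'gene'."""
    samples = [f"s{i}" for i in range(len(x))]
    mirna_rows = {"mir": x, **(extra_mirna or {})}
    mirna = pd.DataFrame(mirna_rows, index=samples).T
    mrna = pd.DataFrame({"gene": y}, index=samples).T
    return PairedDataset(
        mirna=ExpressionMatrix(mirna, unit=unit),
        mrna=ExpressionMatrix(mrna, unit=unit),
    )


def ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple-regression solution, independent of the fitting path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    b1 = sxy / sxx
    b0 = y.mean() - b1 * x.mean()
    return b0, b1


def pearson_oracle(x, y) -> float:
    """Direct sum-of-products Pearson formula, distinct from the library path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    num = float(np.sum((x - xm) * (y - ym)))
    den = float(np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)))
    return num / den
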