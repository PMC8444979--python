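"""Between-sample normalization: TMM scaling factors and CPM.

TMM (trimmed mean of M-values) computes, per sample, a robust log-ratio
against a reference library after removing genes with extreme expression
ratios (M) or extreme average expression (A). The trim rule used here:

* reference sample: the library whose log library size is closest to the
  mean log library size;
* per sample, only genes with positive counts in both the sample and the
  reference enter ("doubly expressed");
* drop the lowest and highest ``floor(0.30 * n)`` genes by M and the
  lowest and highest ``floor(0.05 * n)`` by A (intersection kept);
* the factor is 2 to the precision-weighted mean of the surviving M
  values, with the standard delta-method weights 1/var(M);
* factors are rescaled to geometric mean one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["tmm_factors", "cpm", "scale_counts"]


def _keep_central(x: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping ranks strictly inside the trimmed range."""
    n = x.size
    k = int(np.floor(n * trim))
    order = np.argsort(x, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[k : n - k]] = True
    return keep


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean one.

    Parameters
    ----------
    counts
        Gene x sample matrix of non-negative values (raw counts, or any
        linear abundance measure).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero = np.flatnonzero(lib <= 0)
    if zero.size:
        raise ValueError(f"all-zero sample(s): {list(counts.columns[zero])}")
    log_lib = np.log(lib)
    ref = int(np.argmin(np.abs(log_lib - log_lib.mean())))
    pr = mat[:, ref] / lib[ref]

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        pj = mat[:, j] / lib[j]
        both = (mat[:, j] > 0) & (mat[:, ref] > 0)
        if both.sum() == 0:
            continue
        m = np.log2(pj[both] / pr[both])
        a = 0.5 * np.log2(pj[both] * pr[both])
        # delta-method variance of M for count data
        w = (lib[j] - mat[both, j]) / (lib[j] * mat[both, j]) + (
            lib[ref] - mat[both, ref]
        ) / (lib[ref] * mat[both, ref])
        keep = _keep_central(m, trim_m) & _keep_central(a, trim_a)
        if keep.sum() == 0 or not np.any(w[keep] > 0):
            continue
        factors[j] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on effective library sizes (lib size x factor)."""
    lib = counts.sum(axis=0)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    return counts.div(lib, axis=1) * 1e6


def scale_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """TMM-normalized CPM in one step (the default pre-processing scale)."""
    return cpm(counts, tmm_factors(counts))
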