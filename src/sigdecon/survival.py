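"""Survival stratification: median splits, Kaplan-Meier, log-rank, BH.

Bulk samples are stratified by the median of a continuous marker (a
deconvolved cell-type fraction or a gene's expression) into low (L) and
high (H) groups — or into four groups (L/L, L/H, H/L, H/H) for two
markers jointly — and group survival is compared with the product-limit
estimator and the log-rank (Mantel-Cox) test, with Benjamini-Hochberg
adjustment across a test family. Ties at the median go to L (strict >
for H), fixed for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Stratification",
    "KMResult",
    "median_split",
    "two_factor_strata",
    "km_estimate",
    "logrank_test",
    "bh_adjust",
    "correlate_features",
]


@dataclass
class Stratification:
    labels: pd.Series                 # sample -> group label
    scheme: str                       # "single" or "two-factor"
    split_values: dict[str, float]    # factor name -> median used

    @property
    def groups(self) -> list[str]:
        return sorted(self.labels.unique())

    def counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class KMResult:
    """Per-group product-limit curves plus the global log-rank statistic."""

    curves: dict[str, pd.DataFrame]   # group -> columns: time, survival, at_risk
    logrank_chi2: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    medians: dict[str, float] = field(default_factory=dict)


def median_split(values: pd.Series, factor: str = "value") -> Stratification:
    """Label samples H iff value > median, else L.

    Raises on constant input (degenerate split) or fewer than 2 samples.
    """
    if len(values) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = float(np.median(values.to_numpy(dtype=float)))
    labels = pd.Series(np.where(values > med, "H", "L"), index=values.index)
    if labels.nunique() < 2:
        raise ValueError(f"degenerate median split on factor {factor!r} (constant values?)")
    return Stratification(labels=labels, scheme="single", split_values={factor: med})


def two_factor_strata(
    x: pd.Series, y: pd.Series, x_name: str = "x", y_name: str = "y"
) -> Stratification:
    """Compose two independent median splits into L/L, L/H, H/L, H/H."""
    if not x.index.equals(y.index):
        x, y = x.align(y, join="inner")
        if len(x) == 0:
            raise ValueError("x and y share no samples")
    sx = median_split(x, factor=x_name)
    sy = median_split(y, factor=y_name)
    labels = sx.labels.str.cat(sy.labels, sep="/")
    return Stratification(
        labels=labels,
        scheme="two-factor",
        split_values={**sx.split_values, **sy.split_values},
    )


def _check_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    df = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df


def km_estimate(clinical: pd.DataFrame, strat: Stratification) -> KMResult:
    """Product-limit survival curve per stratum (with global log-rank when
    there are >= 2 groups)."""
    df = _check_clinical(clinical)
    missing = strat.labels.index.difference(df.index)
    if len(missing):
        raise ValueError(f"stratified samples without clinical data: {list(missing)[:5]}")
    curves: dict[str, pd.DataFrame] = {}
    for group in strat.groups:
        ids = strat.labels.index[strat.labels == group]
        if len(ids) == 0:
            raise ValueError(f"empty stratum {group!r}")
        sub = df.loc[ids]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tbl = kmf.event_table
        curves[group] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    result = KMResult(curves=curves, medians=dict(strat.split_values))
    if len(curves) >= 2:
        chi2, p = logrank_test(clinical, strat)
        result.logrank_chi2, result.p_value = chi2, p
    return result


def logrank_test(clinical: pd.DataFrame, strat: Stratification) -> tuple[float, float]:
    """Log-rank (Mantel-Cox) chi-square across strata, k-1 df."""
    if len(strat.groups) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    df = _check_clinical(clinical).loc[strat.labels.index]
    res = multivariate_logrank_test(
        df["time"], strat.labels.to_numpy(), df["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def correlate_features(
    expr_rows: pd.DataFrame,
    fractions: pd.DataFrame,
    method: str = "pearson",
    log1p: bool = True,
) -> pd.DataFrame:
    """Gene-expression x cell-type-fraction correlation matrix.

    Rows of ``expr_rows`` are genes (columns samples); ``fractions`` is
    samples x cell types. Expression is log1p-transformed by default.
    Zero-variance features give NaN coefficients and are listed in
    ``result.attrs['undefined']`` rather than raising.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError("method must be 'pearson' or 'spearman'")
    shared = expr_rows.columns.intersection(fractions.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    E = expr_rows[shared].T.astype(float)
    if log1p:
        E = np.log1p(E)
    F = fractions.loc[shared].astype(float)
    flat_genes = (E.max() - E.min()) == 0
    flat_types = (F.max() - F.min()) == 0
    undefined = [("gene", g) for g in E.columns[flat_genes]] + [
        ("cell_type", c) for c in F.columns[flat_types]
    ]
    if method == "spearman":
        from scipy.stats import rankdata

        E = E.apply(lambda c: rankdata(c), axis=0)
        F = F.apply(lambda c: rankdata(c), axis=0)
    A = E.to_numpy() - E.to_numpy().mean(axis=0, keepdims=True)
    B = F.to_numpy() - F.to_numpy().mean(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(
            np.outer((A**2).sum(axis=0), (B**2).sum(axis=0))
        )
        vals = (A.T @ B) / denom
    vals[flat_genes.to_numpy(), :] = np.nan  # undefined, not an error
    vals[:, flat_types.to_numpy()] = np.nan
    corr = pd.DataFrame(vals, index=expr_rows.index, columns=fractions.columns)
    corr.attrs["method"] = method
    corr.attrs["log1p"] = log1p
    corr.attrs["n_samples"] = int(len(shared))
    corr.attrs["undefined"] = undefined
    return corr
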