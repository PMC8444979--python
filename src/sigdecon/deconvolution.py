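"""Signature-based bulk deconvolution via nu-support-vector regression.

The estimator follows the CIBERSORT scheme: for each bulk sample the
mixture vector and the signature matrix are restricted to their shared
genes and z-scored, a linear-kernel nu-SVR is fitted for each nu in a
small grid, the fit with the lowest reconstruction RMSE is kept, and its
coefficients — negative values clipped to zero — are renormalized to a
simplex of cell-type fractions. Because both sides are standardized the
result is invariant to the overall scale of the input sample.

Quantile normalization (the classic array-era CIBERSORT default) is not
applied; inputs are assumed to be RNA-seq-style linear abundances
(TMM-scaled CPM or TPM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .normalize import cpm, scale_counts, tmm_factors  # noqa: F401  (module surface)

__all__ = ["ProportionEstimate", "deconvolve", "tmm_factors", "cpm", "scale_counts"]

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class ProportionEstimate:
    """Per-sample cell-type fractions plus fit diagnostics.

    fractions: samples x cell types, each row a simplex.
    diagnostics: per sample rmse, corr (Pearson between reconstruction and
    z-scored mixture over signature genes) and the chosen nu.
    """

    fractions: pd.DataFrame
    diagnostics: pd.DataFrame

    def to_tsv(self, fractions_path, diagnostics_path=None) -> None:
        self.fractions.rename_axis("sample").to_csv(fractions_path, sep="\t")
        if diagnostics_path is not None:
            self.diagnostics.rename_axis("sample").to_csv(diagnostics_path, sep="\t")


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def deconvolve(
    bulk: pd.DataFrame,
    sig: pd.DataFrame,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    min_gene_overlap: float = 0.5,
) -> ProportionEstimate:
    """Estimate cell-type fractions for every bulk sample.

    Parameters
    ----------
    bulk
        Gene x sample matrix on a linear scale (counts should be
        TMM/CPM-scaled first; TPM is used as-is).
    sig
        Signature matrix, genes x cell types, linear scale.

    Raises
    ------
    ValueError
        If fewer than ``min_gene_overlap`` of the signature genes are
        present in the bulk matrix, or a mixture vector is constant.
    """
    if sig.index.duplicated().any():
        raise ValueError("signature matrix has duplicate genes")
    shared = sig.index.intersection(bulk.index)
    coverage = len(shared) / len(sig.index)
    if coverage < min_gene_overlap:
        raise ValueError(
            f"only {coverage:.0%} of signature genes found in bulk "
            f"(need >= {min_gene_overlap:.0%})"
        )
    X_raw = sig.loc[shared].to_numpy(dtype=float)
    X = (X_raw - X_raw.mean()) / X_raw.std()  # global z-score keeps column scale ratios

    frac_rows, diag_rows = [], []
    for sample in bulk.columns:
        y_raw = bulk.loc[shared, sample].to_numpy(dtype=float)
        if y_raw.std() == 0:
            raise ValueError(f"mixture vector for sample {sample!r} is constant")
        y = _zscore(y_raw)
        best = None
        for nu in nu_grid:
            model = NuSVR(kernel="linear", nu=nu, C=1.0, tol=1e-4, max_iter=1_000_000)
            model.fit(X, y)
            if getattr(model, "fit_status_", 0) != 0:
                raise RuntimeError(f"nu-SVR failed to converge (sample {sample!r}, nu={nu})")
            w = model.coef_.ravel()
            recon = X @ w + model.intercept_
            rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
            if best is None or rmse < best[0]:
                corr = float(np.corrcoef(recon, y)[0, 1])
                best = (rmse, corr, nu, w)
        rmse, corr, nu, w = best
        w = np.clip(w, 0.0, None)
        total = w.sum()
        fracs = w / total if total > 0 else np.full(w.size, 1.0 / w.size)
        frac_rows.append(fracs)
        diag_rows.append((rmse, corr, nu))

    fractions = pd.DataFrame(frac_rows, index=bulk.columns, columns=sig.columns)
    diagnostics = pd.DataFrame(
        diag_rows, index=bulk.columns, columns=["rmse", "corr", "nu_chosen"]
    )
    return ProportionEstimate(fractions=fractions, diagnostics=diagnostics)
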