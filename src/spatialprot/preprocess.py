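"""PSM filtering, variance-stabilizing normalization, protein summarization,
and the label-free fold-change path.

The normalization is a deliberately simplified affine-calibration +
generalized-log transform: per-channel scale ``a_j`` and offset ``b_j`` are
estimated by an iterative least-trimmed-squares calibration instead of the
full maximum-likelihood machinery of vsn-style packages.  Same model class
(affine calibration, glog), transparent estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ProteinMatrix, PsmTable, ValidationError

_LN2 = np.log(2.0)


def glog(x):
    """Generalized log: ln(x + sqrt(x^2 + 1)) / ln 2 = asinh(x) / ln 2.

    Strictly increasing on all reals, glog(0) = 0, and glog(x) - log2(2x) -> 0
    for x >> 1 (log2-like at large intensities).
    """
    return np.arcsinh(x) / _LN2


def glog_inv(y):
    """Inverse of :func:`glog`: sinh(y * ln 2)."""
    return np.sinh(np.asarray(y, dtype=float) * _LN2)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_psms(
    psm: PsmTable, relevant_channels: set[str], min_intensity: float = 1000.0
) -> PsmTable:
    """Keep PSMs that are neither contaminant nor decoy and exceed
    ``min_intensity`` (strictly) in *every* relevant channel.

    Row order is preserved; the operation is idempotent.
    """
    relevant = list(relevant_channels)
    if not relevant:
        raise ValueError("relevant_channels must be non-empty")
    unknown = [c for c in relevant if c not in psm.channels]
    if unknown:
        raise ValueError(f"channels not in table: {unknown}")
    df = psm.df
    keep = (
        ~df["is_contaminant"].to_numpy(dtype=bool)
        & ~df["is_decoy"].to_numpy(dtype=bool)
        & (df[relevant].to_numpy(dtype=float) > min_intensity).all(axis=1)
    )
    return PsmTable(df=df.loc[keep].reset_index(drop=True), channels=psm.channels)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationFit:
    """Per-channel affine calibration feeding the glog transform.

    transform(x)_j = glog((x - b_j) / a_j), a_j > 0.
    """

    channels: list[str]
    a: np.ndarray
    b: np.ndarray
    converged: bool = True
    n_iter: int = 0
    warnings: list[str] = field(default_factory=list)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return glog((np.asarray(values, dtype=float) - self.b[None, :]) / self.a[None, :])

    @classmethod
    def identity(cls, channels: list[str]) -> "NormalizationFit":
        k = len(channels)
        return cls(channels=channels, a=np.ones(k), b=np.zeros(k))


def _trimmed_ls(x: np.ndarray, y: np.ndarray, keep_frac: float = 0.75,
                n_refit: int = 3) -> tuple[float, float]:
    """Least-trimmed-squares line fit y ~ slope*x + intercept.

    Approximated by iterated refitting on the ``keep_frac`` rows with the
    smallest squared residuals.
    """
    def ols(xs, ys):
        xm, ym = xs.mean(), ys.mean()
        dx = xs - xm
        denom = float(dx @ dx)
        slope = float(dx @ (ys - ym)) / denom if denom > 0 else 1.0
        return slope, float(ym - slope * xm)

    slope, intercept = ols(x, y)
    n_keep = max(2, int(np.ceil(keep_frac * len(x))))
    for _ in range(n_refit):
        resid = (y - slope * x - intercept) ** 2
        keep = np.argsort(resid, kind="stable")[:n_keep]
        slope, intercept = ols(x[keep], y[keep])
    return slope, intercept


def fit_normalization(
    psm: PsmTable,
    min_rows: int = 50,
    max_iter: int = 50,
    rel_tol: float = 1e-6,
    trim: float = 0.75,
) -> NormalizationFit:
    """Estimate per-channel scales and offsets by iterative robust calibration.

    Initialization: ``b_j = 0``, ``a_j`` = channel median / grand median.
    Iteration: transform, center each row, then re-estimate ``(a_j, b_j)`` by
    least-trimmed-squares regression of raw channel values on the inverse-glog
    of the row means, keeping the central ``trim`` fraction of rows.  Stops
    when the maximum relative parameter change is below ``rel_tol``; records a
    warning (and returns the last iterate) on non-convergence.
    """
    x = psm.intensities.to_numpy(dtype=float)
    n, k = x.shape
    if n < min_rows:
        raise ValueError(f"need >= {min_rows} PSM rows to fit normalization, got {n}")
    ch_median = np.median(x, axis=0)
    grand = np.median(x)
    if grand <= 0:
        raise ValueError("grand median intensity must be positive")
    a = np.clip(ch_median / grand, 1e-12, None)
    b = np.zeros(k)
    # (a, b) are identifiable only up to a common scale: pin the geometric
    # mean of a to its initial value so the iteration cannot drift
    a_gmean_target = float(np.exp(np.mean(np.log(a))))
    fit_warnings: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        h = glog((x - b[None, :]) / a[None, :])
        row_means = h.mean(axis=1)
        target = glog_inv(row_means)  # raw-scale common signal g_i
        # x_ij ~ a_j * g_i + b_j with noise roughly proportional to g_i, so
        # regress x_ij / g_i on 1 / g_i: the intercept estimates a_j and the
        # slope estimates b_j on an (approximately) homoscedastic scale
        ok = target > np.finfo(float).tiny
        if ok.sum() < max(10, int(0.5 * n)):
            fit_warnings.append(f"common-signal collapse at iteration {it}")
            break
        g = target[ok]
        u = 1.0 / g
        a_new = np.empty(k)
        b_new = np.empty(k)
        for j in range(k):
            y = x[ok, j] / g
            slope_b, intercept_a = _trimmed_ls(u, y, keep_frac=trim)
            a_new[j] = intercept_a if intercept_a > 0 else a[j]
            if intercept_a <= 0:
                fit_warnings.append(
                    f"channel {psm.channels[j]}: non-positive scale at iteration "
                    f"{it}; kept previous value"
                )
            b_new[j] = slope_b
        rescale = a_gmean_target / float(np.exp(np.mean(np.log(a_new))))
        a_new *= rescale
        # damp the fixed-point update: the trimmed regression's kept set can
        # flip between iterations, which makes the undamped map oscillate
        a_new = 0.5 * a_new + 0.5 * a
        b_new = 0.5 * b_new + 0.5 * b
        scale = np.abs(a) + np.abs(b) + 1e-12
        delta = max(
            float(np.max(np.abs(a_new - a) / scale)),
            float(np.max(np.abs(b_new - b) / scale)),
        )
        a, b = a_new, b_new
        if delta < rel_tol:
            converged = True
            break
    if not converged:
        fit_warnings.append(f"calibration did not converge in {max_iter} iterations")
    return NormalizationFit(
        channels=list(psm.channels), a=a, b=b,
        converged=converged, n_iter=it, warnings=fit_warnings,
    )


def apply_normalization(psm: PsmTable, fit: NormalizationFit) -> pd.DataFrame:
    """Elementwise affine + glog transform of the intensity matrix.

    Returns a PSM-row x channel DataFrame on the transformed (log2-like)
    scale.  glog is defined on all reals, so values below ``b_j`` need no
    special handling.
    """
    if list(fit.channels) != list(psm.channels):
        raise ValueError("fit channels do not match table channels")
    out = fit.transform(psm.intensities.to_numpy(dtype=float))
    return pd.DataFrame(out, index=psm.df.index, columns=psm.channels)


# ---------------------------------------------------------------------------
# Protein summarization
# ---------------------------------------------------------------------------

def summarize_proteins(
    peptide_matrix: pd.DataFrame,
    psm: PsmTable,
    min_peptides: int = 2,
    proteotypic_only: bool = True,
) -> ProteinMatrix:
    """Median-summarize transformed peptide data into protein groups.

    PSMs of the same peptide are first collapsed by median, then protein
    values are the median over contributing peptides.  ``n_peptides`` counts
    distinct contributing peptides; proteins below ``min_peptides`` are
    dropped.  Medians use the midpoint convention for even counts.
    """
    if not peptide_matrix.index.equals(psm.df.index):
        raise ValueError("peptide_matrix rows must align with the PSM table")
    meta = psm.df
    if proteotypic_only:
        mask = meta["proteotypic"].to_numpy(dtype=bool)
        meta = meta.loc[mask]
        peptide_matrix = peptide_matrix.loc[mask]
    if meta.empty:
        empty = pd.DataFrame(columns=psm.channels, dtype=float)
        empty.index.name = "protein_group"
        return ProteinMatrix(
            values=empty, n_peptides=pd.Series(dtype=int, index=empty.index)
        )
    keys = meta[["protein_group", "peptide_id"]]
    by_peptide = peptide_matrix.groupby(
        [keys["protein_group"], keys["peptide_id"]], sort=True
    ).median()
    by_protein = by_peptide.groupby(level="protein_group", sort=True).median()
    n_pep = by_peptide.groupby(level="protein_group", sort=True).size()
    keep = n_pep[n_pep >= min_peptides].index
    values = by_protein.loc[keep]
    values.index.name = "protein_group"
    return ProteinMatrix(values=values, n_peptides=n_pep.loc[keep].astype(int))


# ---------------------------------------------------------------------------
# Label-free path
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization: every column's sorted values are replaced by the
    mean of row-wise sorted values; tied values receive the mean of the
    reference values at their would-be positions.  No missing values allowed.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile_normalize requires a complete-case matrix")
    n, k = x.shape
    if n == 1:
        return pd.DataFrame(
            np.full((1, k), x.mean()), index=matrix.index, columns=matrix.columns
        )
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(k):
        order = np.argsort(x[:, j], kind="stable")
        col_sorted = x[order, j]
        assigned = np.empty(n)
        i = 0
        while i < n:
            m = i
            while m + 1 < n and col_sorted[m + 1] == col_sorted[i]:
                m += 1
            assigned[i : m + 1] = ref[i : m + 1].mean()
            i = m + 1
        out[order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def lfq_fold_changes(matrix: pd.DataFrame, control_samples: set[str]) -> pd.DataFrame:
    """Per-protein log2 fold change of each test sample against the mean of
    the control samples.  Proteins missing in any control are excluded."""
    controls = [c for c in matrix.columns if c in set(control_samples)]
    if not controls:
        raise ValueError("control_samples must be non-empty and present in the matrix")
    tests = [c for c in matrix.columns if c not in set(control_samples)]
    complete = matrix[controls].notna().all(axis=1)
    sub = matrix.loc[complete]
    ctrl_mean = sub[controls].mean(axis=1)
    return sub[tests].sub(ctrl_mean, axis=0)
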