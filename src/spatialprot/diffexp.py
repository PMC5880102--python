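"""Replicate-free differential expression via a two-component empirical-null
model on centered log2 ratios, plus recurrence, averaged-fold-change analysis
and transcriptome concordance.

The mixture model treats the absolute centered ratios ``|z|`` as a mixture
``eta0 * halfnormal(sigma0) + (1 - eta0) * alternative``.  The null sd is a
truncated maximum-likelihood fit to the central bulk, the mixture density is
the Grenander (monotone non-increasing) estimator, and significance is
reported both as local fdr and as a tail-area q-value.  Proteins with q-value
below the threshold (strict) belong to the alternative component and are
called differential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

# ---------------------------------------------------------------------------
# Ratio vectors
# ---------------------------------------------------------------------------


@dataclass
class RatioVector:
    """Median-centered log2 ratios for one contrast of one patient."""

    z: pd.Series  # protein_group -> centered ratio
    centering: float
    patient: str = ""
    contrast: tuple[str, str] = ("", "")

    @classmethod
    def from_values(
        cls,
        values: pd.Series,
        patient: str = "",
        contrast: tuple[str, str] = ("", ""),
    ) -> "RatioVector":
        values = values.dropna().astype(float)
        center = float(values.median())
        return cls(z=values - center, centering=center, patient=patient, contrast=contrast)

    def __len__(self) -> int:
        return len(self.z)


def center_ratios(pm, design, patient: str, contrast: tuple[str, str],
                  min_proteins: int = 20) -> RatioVector:
    """Median-centered per-protein difference between the two samples of
    ``contrast`` for ``patient`` (transformed scale, so a log2-like ratio)."""
    region_a, region_b = contrast
    ch_a = design.channel_for(patient, region_a)
    ch_b = design.channel_for(patient, region_b)
    vals = pm.values[[ch_a, ch_b]].dropna()
    if len(vals) < min_proteins:
        raise ValueError(
            f"only {len(vals)} proteins quantified in both samples of "
            f"{patient} {contrast}; need >= {min_proteins}"
        )
    raw = vals[ch_a] - vals[ch_b]
    rv = RatioVector.from_values(raw, patient=patient, contrast=contrast)
    return rv


# ---------------------------------------------------------------------------
# Grenander estimator
# ---------------------------------------------------------------------------


@dataclass
class GrenanderDensity:
    """Monotone non-increasing density on [0, max(x)]: the left derivative of
    the least concave majorant of the empirical CDF, via weighted PAVA."""

    knots: np.ndarray  # increasing, first element > 0; support is (0, knots[-1]]
    heights: np.ndarray  # density on (prev_knot, knot]; non-increasing

    def pdf(self, v) -> np.ndarray:
        """Density at v (left-continuous at knots: value of the interval
        (knot_{i-1}, knot_i] containing v; 0 beyond the support)."""
        v = np.atleast_1d(np.asarray(v, dtype=float))
        idx = np.searchsorted(self.knots, v, side="left")
        out = np.zeros_like(v)
        inside = v <= self.knots[-1]
        out[inside] = self.heights[np.minimum(idx[inside], len(self.heights) - 1)]
        return out

    def cdf(self, v) -> np.ndarray:
        v = np.atleast_1d(np.asarray(v, dtype=float))
        edges = np.concatenate([[0.0], self.knots])
        seg = np.concatenate([[0.0], np.cumsum(self.heights * np.diff(edges))])
        idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(self.heights))
        lo = edges[idx]
        h = np.concatenate([self.heights, [0.0]])[idx]
        return np.clip(seg[idx] + h * (np.clip(v, 0, edges[-1]) - lo), 0.0, 1.0)


def grenander_density(x) -> GrenanderDensity:
    """Grenander estimator for non-negative data.

    Slopes of the ECDF segments (anchored at (0, 0)) are pooled by weighted
    PAVA into a non-increasing sequence; the result integrates to 1 over
    [0, max(x)].  All-identical data yields a degenerate single-step density.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    if np.any(x < 0):
        raise ValueError("data must be non-negative")
    n = len(x)
    u, counts = np.unique(x, return_counts=True)
    if u[0] == 0.0:
        # probability mass cannot sit at 0 for a density on (0, max];
        # fold zeros into the first positive segment
        if len(u) == 1:
            raise ValueError("all values are zero; density is degenerate at 0")
        counts = counts.copy()
        counts[1] += counts[0]
        u, counts = u[1:], counts[1:]
    ecdf = np.cumsum(counts) / n
    edges = np.concatenate([[0.0], u])
    widths = np.diff(edges)
    increments = np.diff(np.concatenate([[0.0], ecdf]))
    slopes = increments / widths
    # weighted PAVA for a non-increasing sequence; blocks remember how many
    # original segments they pool so heights can be expanded afterwards
    blocks: list[list[float]] = []  # [value, weight, n_segments]
    for s, w in zip(slopes, widths):
        blocks.append([float(s), float(w), 1])
        while len(blocks) > 1 and blocks[-2][0] < blocks[-1][0]:
            v2, w2, c2 = blocks.pop()
            v1, w1, c1 = blocks.pop()
            blocks.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2, c1 + c2])
    heights = np.repeat(
        [b[0] for b in blocks], [b[2] for b in blocks]
    ).astype(float)
    return GrenanderDensity(knots=u, heights=heights)


# ---------------------------------------------------------------------------
# Two-component fit
# ---------------------------------------------------------------------------


@dataclass
class TwoComponentFit:
    """Empirical-null fit of a centered ratio vector."""

    sigma0: float
    eta0: float
    z0: float
    fhat: GrenanderDensity
    z: pd.Series
    lfdr: pd.Series
    qval: pd.Series
    patient: str = ""
    contrast: tuple[str, str] = ("", "")
    warnings: list[str] = field(default_factory=list)


def _halfnormal_truncated_mle(t: np.ndarray, z0: float, rel_tol: float = 1e-8) -> float:
    """MLE of sigma for a half-normal truncated to [0, z0], fitted to t."""
    t = np.asarray(t, dtype=float)
    n = len(t)
    ss = float(t @ t)

    def neg_ll(sigma: float) -> float:
        trunc_mass = stats.norm.cdf(z0 / sigma) - 0.5
        if trunc_mass <= 0:
            return np.inf
        return n * np.log(sigma) + ss / (2 * sigma**2) + n * np.log(trunc_mass)

    raw_sd = max(np.sqrt(ss / n), 1e-12)
    lo, hi = raw_sd * 1e-3, max(z0, raw_sd) * 50
    res = optimize.minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": rel_tol * raw_sd},
    )
    if not res.success:
        raise RuntimeError("sigma0 search failed to converge")
    return float(res.x)


def fit_two_component(rv: RatioVector, trunc_quantile: float = 0.75) -> TwoComponentFit:
    """Fit the two-component empirical-null model to a centered ratio vector.

    Steps: truncation point z0 at the ``trunc_quantile`` of |z|; truncated
    half-normal MLE for sigma0 on {|z| <= z0}; moment-matched null proportion
    eta0; Grenander mixture density on |z|; local fdr and tail-area q-values
    (survivor functions evaluated just below each |z| via the empirical count
    of values >= |z|, so the denominator is never zero), with q forced
    monotone non-increasing in |z| by a running minimum from the largest |z|
    inward.
    """
    z = rv.z.astype(float)
    a = z.abs().to_numpy()
    n = len(a)
    if n < 20:
        raise ValueError(f"need >= 20 ratios to fit, got {n}")
    if float(np.ptp(a)) == 0.0:
        raise ValueError("constant ratio vector: two-component fit is degenerate")
    z0 = float(np.quantile(a, trunc_quantile))
    if z0 <= 0:
        # more than trunc_quantile of the mass at exactly 0
        z0 = float(np.min(a[a > 0]))
    t = a[a <= z0]
    sigma0 = _halfnormal_truncated_mle(t, z0)
    fit_warnings: list[str] = []
    p_null_below = 2 * stats.norm.cdf(z0 / sigma0) - 1
    eta0_raw = (len(t) / n) / p_null_below
    if eta0_raw > 1.2:
        fit_warnings.append(
            f"eta0 estimate {eta0_raw:.3f} > 1.2 before clipping: model misfit"
        )
    eta0 = min(1.0, eta0_raw)

    fhat = grenander_density(a)
    f0 = stats.norm.pdf(a / sigma0) * 2 / sigma0
    denom_f = np.maximum(fhat.pdf(a), 1e-300)
    lfdr = np.minimum(1.0, eta0 * f0 / denom_f)

    surv0 = 2 * stats.norm.sf(a / sigma0)
    order = np.argsort(a, kind="stable")
    # empirical survivor just below |z|: #{|z_j| >= |z_i|} / n
    surv_hat = np.empty(n)
    sorted_a = a[order]
    surv_hat[order] = (n - np.searchsorted(sorted_a, sorted_a, side="left")) / n
    qraw = np.minimum(1.0, eta0 * surv0 / surv_hat)
    # BH-style monotonization: the q at a point is the minimum raw tail-area
    # Fdr over all rejection thresholds at or below its |z|, so q is
    # non-increasing in |z| (running minimum accumulated from the least
    # extreme point toward the most extreme)
    asc = np.argsort(a, kind="stable")
    q = np.empty(n)
    q[asc] = np.minimum.accumulate(qraw[asc])

    return TwoComponentFit(
        sigma0=sigma0,
        eta0=eta0,
        z0=z0,
        fhat=fhat,
        z=z,
        lfdr=pd.Series(lfdr, index=z.index),
        qval=pd.Series(q, index=z.index),
        patient=rv.patient,
        contrast=rv.contrast,
        warnings=fit_warnings,
    )


def call_differential(fit: TwoComponentFit, q_threshold: float = 0.2) -> pd.DataFrame:
    """Table of per-protein calls: ``called`` iff qval < q_threshold (strict)."""
    return pd.DataFrame(
        {
            "protein_group": fit.z.index,
            "patient": fit.patient,
            "contrast": f"{fit.contrast[0]}:{fit.contrast[1]}",
            "z": fit.z.to_numpy(),
            "lfdr": fit.lfdr.to_numpy(),
            "qval": fit.qval.to_numpy(),
            "called": fit.qval.to_numpy() < q_threshold,
        }
    )


# ---------------------------------------------------------------------------
# Cross-specimen aggregation
# ---------------------------------------------------------------------------


def recurrence(
    calls: dict[str, pd.DataFrame], min_specimens: int = 2
) -> tuple[set[str], pd.Series]:
    """Proteins called differential in at least ``min_specimens`` patients.

    ``calls`` maps patient -> call table from :func:`call_differential`.
    Returns the recurrent set and per-protein specimen counts (all proteins
    called at least once).
    """
    if len(calls) < 2:
        raise ValueError("recurrence needs calls from >= 2 patients")
    counts: dict[str, int] = {}
    for table in calls.values():
        hit = table.loc[table["called"], "protein_group"]
        for p in hit:
            counts[p] = counts.get(p, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    recurrent = set(series.index[series >= min_specimens])
    return recurrent, series


def average_fc_analysis(
    ratio_vectors: dict[str, RatioVector],
    exclude_patients: set[str] = frozenset(),
    trunc_quantile: float = 0.75,
) -> TwoComponentFit:
    """Two-component fit on per-protein mean ratios across retained patients.

    Only proteins present in every retained vector enter; the mean vector is
    re-centered before fitting.
    """
    retained = {p: rv for p, rv in ratio_vectors.items() if p not in exclude_patients}
    if len(retained) < 2:
        raise ValueError("need >= 2 retained patients")
    frame = pd.DataFrame({p: rv.z for p, rv in retained.items()}).dropna()
    mean_z = frame.mean(axis=1)
    rv = RatioVector.from_values(
        mean_z, patient="+".join(sorted(retained)),
        contrast=next(iter(retained.values())).contrast,
    )
    return fit_two_component(rv, trunc_quantile=trunc_quantile)


def protein_only_filter(
    avg_calls: pd.DataFrame,
    transcript_fc: dict[str, float],
    max_abs_transcript_log2: float,
) -> dict[str, set[str]]:
    """Among called proteins, retain those whose transcript-level change is
    no larger than ``max_abs_transcript_log2``; proteins lacking transcript
    data are reported separately, never silently retained."""
    called = set(avg_calls.loc[avg_calls["called"], "protein_group"])
    retained, no_transcript = set(), set()
    for p in called:
        if p not in transcript_fc:
            no_transcript.add(p)
        elif abs(transcript_fc[p]) <= max_abs_transcript_log2:
            retained.add(p)
    return {"retained": retained, "no_transcript": no_transcript}


@dataclass
class ConcordanceResult:
    pearson_r: float
    n: int
    sign_consistent_count: int


def concordance(
    protein_fc: dict[str, float],
    reference_fc: dict[str, float],
    subset: set[str] | None = None,
) -> ConcordanceResult:
    """Pearson correlation and strict sign-consistency count between protein
    and reference fold changes over shared proteins (zeros count as
    inconsistent)."""
    shared = sorted(set(protein_fc) & set(reference_fc))
    if subset is not None:
        shared = sorted(set(shared) & subset)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared proteins, got {len(shared)}")
    x = np.array([protein_fc[p] for p in shared])
    y = np.array([reference_fc[p] for p in shared])
    r = float(stats.pearsonr(x, y).statistic)
    sign_consistent = int(np.sum((np.sign(x) == np.sign(y)) & (x != 0) & (y != 0)))
    return ConcordanceResult(pearson_r=r, n=len(shared), sign_consistent_count=sign_consistent)
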