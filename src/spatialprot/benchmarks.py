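"""Self-contained calibration benchmarks: each function regenerates its
synthetic inputs from a seed, runs the relevant pipeline stages, and measures
performance against the generator's ground truth or an independent oracle."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform as _squareform

from . import diffexp, preprocess, spatial
from .annotation import compartment_shift, mhg_exact_pvalue, mhg_statistic
from .core import AnnotationSet
from .qpcr import delta_delta_ct
from .simulate import (
    DEFAULT_QPCR_REFERENCE,
    DEFAULT_QPCR_TARGETS,
    SimulationConfig,
    simulate_experiment,
    simulate_qpcr,
    simulate_ratios,
)

# ---------------------------------------------------------------------------
# Differential-expression calibration (z-level)
# ---------------------------------------------------------------------------

FDR_SIM = dict(n=5000, pi1=0.10, effect_mean=1.5, effect_sd=0.3, null_sd=0.5)


def fdr_calibration(n_seeds: int = 20, seed: int = 0, q_threshold: float = 0.2) -> dict:
    """Realized false-discovery proportion, sensitivity, and sigma0 recovery
    over ``n_seeds`` synthetic contrasts (5000 proteins, 10% differential,
    effects +/-N(1.5, 0.3^2), null sd 0.5)."""
    fdps, senss, sigma_rel_errs = [], [], []
    for k in range(n_seeds):
        z, is_diff = simulate_ratios(
            FDR_SIM["n"], FDR_SIM["pi1"], FDR_SIM["effect_mean"],
            FDR_SIM["effect_sd"], FDR_SIM["null_sd"], seed=seed + k,
        )
        fit = diffexp.fit_two_component(
            diffexp.RatioVector.from_values(pd.Series(z))
        )
        called = diffexp.call_differential(fit, q_threshold)["called"].to_numpy()
        n_called = int(called.sum())
        fdps.append(float((called & ~is_diff).sum() / max(n_called, 1)))
        senss.append(float((called & is_diff).sum() / is_diff.sum()))
        sigma_rel_errs.append(abs(fit.sigma0 / FDR_SIM["null_sd"] - 1.0))
    return {
        "mean_fdp": float(np.mean(fdps)),
        "mean_sensitivity": float(np.mean(senss)),
        "median_sigma0_rel_err": float(np.median(sigma_rel_errs)),
        "n_seeds": n_seeds,
    }


def pure_null_recovery(n: int = 5000, seed: int = 2) -> dict:
    """sigma0 and eta0 on pure-null N(0,1) centered ratios."""
    z, _ = simulate_ratios(n, 0.0, 0.0, 0.0, 1.0, seed=seed)
    fit = diffexp.fit_two_component(diffexp.RatioVector.from_values(pd.Series(z)))
    return {"sigma0": fit.sigma0, "eta0": fit.eta0, "n": n}


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------

def grenander_oracle_heights(x: np.ndarray) -> np.ndarray:
    """Quadratic brute-force least-concave-majorant density (steepest
    remaining slope from each hull point)."""
    n = len(x)
    u, counts = np.unique(x, return_counts=True)
    if u[0] == 0.0:
        counts = counts.copy()
        counts[1] += counts[0]
        u, counts = u[1:], counts[1:]
    pts = [(0.0, 0.0)] + list(zip(u, np.cumsum(counts) / n))
    hull = [pts[0]]
    i = 0
    while i < len(pts) - 1:
        slopes = [
            ((pts[j][1] - pts[i][1]) / (pts[j][0] - pts[i][0]), j)
            for j in range(i + 1, len(pts))
        ]
        best = max(s for s, _ in slopes)
        j = max(j for s, j in slopes if s >= best - 1e-15)
        hull.append(pts[j])
        i = j
    heights = np.empty(len(u))
    for seg in range(1, len(hull)):
        (x0, _), (x1, _) = hull[seg - 1], hull[seg]
        slope = (hull[seg][1] - hull[seg - 1][1]) / (x1 - x0)
        for k, uk in enumerate(u):
            if x0 < uk <= x1:
                heights[k] = slope
    return heights


def grenander_vs_oracle(n_instances: int = 100, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, 51))
        x = np.round(rng.exponential(1.0, n), 2) + 0.01
        g = diffexp.grenander_density(x)
        worst = max(worst, float(np.max(np.abs(g.heights - grenander_oracle_heights(x)))))
    return {"max_abs_density_diff": worst, "n_instances": n_instances}


def mhg_vs_enumeration(max_n: int = 8) -> dict:
    """Exhaustive check of the mHG statistic and exact p-value for all
    membership vectors with N <= max_n."""
    worst_p = 0.0
    n_checked = 0
    for N in range(2, max_n + 1):
        for B in range(1, N + 1):
            arrangements = []
            for pos in combinations(range(N), B):
                v = [i in pos for i in range(N)]
                s, _, _ = mhg_statistic(v)
                arrangements.append(s)
            for s in set(arrangements):
                p_dp = mhg_exact_pvalue(s, N, B)
                p_brute = np.mean([sv <= s * (1 + 1e-12) for sv in arrangements])
                worst_p = max(worst_p, abs(p_dp - p_brute))
                n_checked += 1
    return {"max_abs_pvalue_diff": float(worst_p), "n_checked": n_checked}


def hcluster_vs_oracle(n_instances: int = 30, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 9))
        m = rng.normal(size=(n, 12))
        corr = pd.DataFrame(
            np.corrcoef(m),
            index=[f"s{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(n)],
        )
        dend = spatial.hcluster(corr)
        z = _scipy_linkage(_squareform(1 - corr.to_numpy(), checks=False), "average")
        diff = np.max(
            np.abs(np.sort([h for _, _, h in dend.merges]) - np.sort(z[:, 2]))
        )
        worst = max(worst, float(diff))
    return {"max_abs_height_diff": worst, "n_instances": n_instances}


def _qnorm_oracle(x: np.ndarray) -> np.ndarray:
    n, k = x.shape
    ref = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(k):
        order = sorted(range(n), key=lambda i: x[i, j])
        for value in set(x[:, j]):
            positions = [r for r, i in enumerate(order) if x[i, j] == value]
            avg = float(np.mean([ref[p] for p in positions]))
            for p in positions:
                out[order[p], j] = avg
    return out


def qnorm_vs_oracle(n_instances: int = 100, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        x = np.round(rng.normal(size=(5, 4)), 1)
        out = preprocess.quantile_normalize(pd.DataFrame(x)).to_numpy()
        worst = max(worst, float(np.max(np.abs(out - _qnorm_oracle(x)))))
    return {"max_abs_diff": worst, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# Recurrence recovery (full pipeline)
# ---------------------------------------------------------------------------

def recurrence_recovery(seed: int = 5, n_proteins: int = 1000) -> dict:
    """Full PSM-level pipeline on a 5-patient fixture with ~50 shared true
    effects; fraction of truly differential proteins recovered by the
    q < 0.2 in >= 2 specimens rule at default thresholds."""
    cfg = SimulationConfig(
        n_proteins=n_proteins, pi1=0.05, peptides_min=2,
        null_sd=0.28, sd_eta=0.1, seed=seed,
    )
    exp = simulate_experiment(cfg)
    filt = preprocess.filter_psms(exp.psm, set(exp.psm.channels))
    fit = preprocess.fit_normalization(filt)
    pm = preprocess.summarize_proteins(
        preprocess.apply_normalization(filt, fit), filt
    )
    calls = {}
    for patient in exp.design.patients:
        rv = diffexp.center_ratios(pm, exp.design, patient, ("tumor", "peritumor"))
        calls[patient] = diffexp.call_differential(diffexp.fit_two_component(rv))
    recurrent, _ = diffexp.recurrence(calls, min_specimens=2)
    truth = exp.truth.differential
    return {
        "recovery": float(len(recurrent & truth) / len(truth)),
        "n_true_effects": len(truth),
        "n_recurrent": len(recurrent),
        "n_false_recurrent": len(recurrent - truth),
    }


# ---------------------------------------------------------------------------
# Compartment shift
# ---------------------------------------------------------------------------

def compartment_shift_recovery(
    n: int = 4000, planted_shift: float = -1.0, frac: float = 0.15, seed: int = 6
) -> dict:
    rng = np.random.default_rng(seed)
    n_in = int(frac * n)
    members = [f"M{i}" for i in range(n_in)]
    rest = [f"O{i}" for i in range(n - n_in)]
    ann = AnnotationSet(compartment={m: "mitochondrion" for m in members})
    fc = {m: float(rng.normal(planted_shift, 0.5)) for m in members}
    fc.update({o: float(rng.normal(0.0, 0.5)) for o in rest})
    res = compartment_shift(fc, ann, "mitochondrion")
    return {"median_shift": res.median_shift, "p_value": res.p_value, "n": n}


def compartment_shift_type1(n_seeds: int = 20, seed: int = 0) -> dict:
    hits = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        members = [f"M{i}" for i in range(60)]
        rest = [f"O{i}" for i in range(340)]
        ann = AnnotationSet(compartment={m: "mitochondrion" for m in members})
        fc = {p: float(v) for p, v in zip(members + rest, rng.normal(0, 0.5, 400))}
        if compartment_shift(fc, ann, "mitochondrion").p_value < 0.05:
            hits += 1
    return {"n_false_positive": hits, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# Spatial clustering
# ---------------------------------------------------------------------------

def gradient_cluster_recovery(
    n_per: int = 150, n_sectors: int = 6, noise: float = 0.05, seed: int = 13
) -> dict:
    """Two planted monotone center->periphery profile shapes; fuzzy c-means
    membership recovery and elbow selection of the planted c = 2."""
    rng = np.random.default_rng(seed)
    up = np.linspace(1.0, 3.0, n_sectors)
    rows = np.vstack(
        [shape + rng.normal(0, noise, (n_per, n_sectors)) for shape in (up, up[::-1])]
    )
    df = pd.DataFrame(
        rows,
        index=[f"G{i}" for i in range(2 * n_per)],
        columns=[f"TS{j}" for j in range(n_sectors)],
    )
    labels = np.repeat([0, 1], n_per)
    std, _ = spatial.standardize_profiles(df, list(df.columns))
    fit = spatial.fuzzy_cmeans(std, 2, seed=seed)
    hard = fit.membership.to_numpy().argmax(axis=1)
    if (hard == labels).mean() < 0.5:
        hard = 1 - hard
    elbow = spatial.select_c_elbow(std, (1, 5), seed=seed)
    history = np.array(fit.objective_history)
    return {
        "frac_high_membership": float((fit.membership.max(axis=1) > 0.9).mean()),
        "frac_correct_cluster": float((hard == labels).mean()),
        "c_star": elbow.c_star,
        "membership_rows_sum_ok": bool(
            np.allclose(fit.membership.sum(axis=1), 1.0, atol=1e-9)
        ),
        "objective_non_increasing": bool(np.all(np.diff(history) <= 1e-9)),
        "n_profiles": len(std),
    }


# ---------------------------------------------------------------------------
# Delta-delta-Ct closed forms
# ---------------------------------------------------------------------------

def ddct_closed_forms(seed: int = 0) -> dict:
    worst = 0.0
    for ratio in (-1.3, -1.0, 0.0, 0.7):
        table, pairs = simulate_qpcr(4, ratio, 0.0, seed=seed)
        results, _ = delta_delta_ct(
            table, list(DEFAULT_QPCR_TARGETS), DEFAULT_QPCR_REFERENCE, pairs
        )
        worst = max(worst, max(abs(r.log2_fc - ratio) for r in results))
    # efficiency-shift invariance
    table, pairs = simulate_qpcr(2, -0.8, 0.0, seed=seed)
    base, _ = delta_delta_ct(
        table, list(DEFAULT_QPCR_TARGETS), DEFAULT_QPCR_REFERENCE, pairs
    )
    shifted = table.df.copy()
    shifted.loc[shifted["sample"] == pairs[0][0], "ct"] += 2.0
    from .core import QpcrTable

    shifted_res, _ = delta_delta_ct(
        QpcrTable(df=shifted), list(DEFAULT_QPCR_TARGETS),
        DEFAULT_QPCR_REFERENCE, pairs,
    )
    shift_dev = max(
        abs(a.log2_fc - b.log2_fc) for a, b in zip(base, shifted_res)
    )
    swapped, _ = delta_delta_ct(
        table, list(DEFAULT_QPCR_TARGETS), DEFAULT_QPCR_REFERENCE,
        [(p, t) for t, p in pairs],
    )
    swap_dev = max(abs(a.log2_fc + b.log2_fc) for a, b in zip(base, swapped))
    return {
        "max_recovery_err": float(worst),
        "efficiency_shift_dev": float(shift_dev),
        "pair_swap_dev": float(swap_dev),
    }


# ---------------------------------------------------------------------------
# Filtering determinism
# ---------------------------------------------------------------------------

def toy_filter_counts() -> dict:
    """Hand-countable toy PSM table: 12 rows of which 2 contaminant, 1 decoy,
    1 sub-threshold, 1 exactly at threshold -> 7 survivors; one protein (3
    proteotypic peptides) survives the >= 2-proteotypic-peptide rule."""
    from .core import PSM_META_COLUMNS, PsmTable

    channels = ["c1", "c2"]
    rows = [
        ("p1a", "P1", True, False, False, 5000.0, 6000.0),
        ("p1b", "P1", True, False, False, 4000.0, 3000.0),
        ("p1c", "P1", True, False, False, 2000.0, 2500.0),
        ("p2a", "P2", True, False, False, 999.9, 5000.0),
        ("p2b", "P2", True, False, False, 3000.0, 3000.0),
        ("p3a", "P3", True, False, False, 2000.0, 2000.0),
        ("p3b", "P3", False, False, False, 2500.0, 2500.0),
        ("p4a", "P4", True, True, False, 1e6, 1e6),
        ("p4b", "P4", True, True, False, 1e6, 1e6),
        ("p5a", "P5", True, False, True, 1e6, 1e6),
        ("p6a", "P6", True, False, False, 1000.0, 4000.0),
        ("p6b", "P6", True, False, False, 1500.0, 1500.0),
    ]
    df = pd.DataFrame(rows, columns=list(PSM_META_COLUMNS) + channels)
    psm = PsmTable(df=df, channels=channels)
    filtered = preprocess.filter_psms(psm, set(channels), min_intensity=1000.0)
    mat = filtered.intensities.astype(float)
    pm = preprocess.summarize_proteins(mat, filtered, min_peptides=2)
    return {
        "n_rows_in": len(psm),
        "n_rows_surviving": len(filtered),
        "n_proteins": len(pm.proteins),
        "proteins": sorted(pm.proteins),
    }
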