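import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialprot.core import DesignTable, ProteinMatrix
from spatialprot.diffexp import (
    RatioVector,
    average_fc_analysis,
    call_differential,
    center_ratios,
    concordance,
    fit_two_component,
    grenander_density,
    protein_only_filter,
    recurrence,
)
from spatialprot.simulate import simulate_ratios


def make_pm(values: dict, n_peptides: int = 2) -> ProteinMatrix:
    df = pd.DataFrame(values)
    df.index = [f"P{i}" for i in range(len(df))]
    df.index.name = "protein_group"
    return ProteinMatrix(
        values=df, n_peptides=pd.Series(n_peptides, index=df.index)
    )


DESIGN = DesignTable(mapping={"chA": ("P1", "tumor"), "chB": ("P1", "peritumor")})


class TestCenterRatios:
    def test_equal_samples_all_zero(self):
        vals = {"chA": np.linspace(1, 30, 30), "chB": np.linspace(1, 30, 30)}
        rv = center_ratios(make_pm(vals), DESIGN, "P1", ("tumor", "peritumor"))
        assert np.allclose(rv.z, 0.0)
        assert rv.centering == 0.0

    def test_median_subtraction(self):
        base = np.zeros(21)
        diff = np.concatenate([[1.0, 2.0, 3.0], np.full(18, 2.0)])
        rv = center_ratios(
            make_pm({"chA": base + diff, "chB": base}),
            DESIGN,
            "P1",
            ("tumor", "peritumor"),
        )
        assert rv.centering == 2.0
        assert sorted(rv.z.iloc[:3]) == [-1.0, 0.0, 1.0]
        assert abs(float(rv.z.median())) < 1e-12

    def test_too_few_proteins_error(self):
        vals = {"chA": np.ones(5), "chB": np.zeros(5)}
        with pytest.raises(ValueError, match="20"):
            center_ratios(make_pm(vals), DESIGN, "P1", ("tumor", "peritumor"))

    def test_missing_proteins_dropped_from_contrast(self):
        a = np.linspace(0, 1, 25)
        b = np.zeros(25)
        a[3] = np.nan
        rv = center_ratios(
            make_pm({"chA": a, "chB": b}), DESIGN, "P1", ("tumor", "peritumor")
        )
        assert "P3" not in rv.z.index
        assert len(rv) == 24


def _grenander_oracle(x):
    """Quadratic brute-force least-concave-majorant construction: from each
    hull point take the steepest remaining slope (farthest point on ties)."""
    x = np.asarray(x, dtype=float)
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
        (x0, y0), (x1, y1) = hull[seg - 1], hull[seg]
        slope = (y1 - y0) / (x1 - x0)
        for k, uk in enumerate(u):
            if x0 < uk <= x1:
                heights[k] = slope
    return u, heights


class TestGrenander:
    def test_hand_computed_lcm(self):
        g = grenander_density([1.0, 1.0, 1.0, 2.0])
        assert np.allclose(g.knots, [1.0, 2.0])
        assert np.allclose(g.heights, [0.75, 0.25])

    def test_uniform_grid_flat(self):
        g = grenander_density([0.25, 0.5, 0.75, 1.0])
        assert np.allclose(g.heights, 1.0)

    def test_integrates_to_one(self, rng):
        x = rng.exponential(1.0, 200)
        g = grenander_density(x)
        edges = np.concatenate([[0.0], g.knots])
        assert np.sum(g.heights * np.diff(edges)) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_non_increasing(self, rng):
        x = rng.gamma(2.0, 1.0, 500)
        g = grenander_density(x)
        assert np.all(np.diff(g.heights) <= 1e-12)

    def test_degenerate_identical(self):
        g = grenander_density([2.0, 2.0, 2.0])
        assert np.allclose(g.knots, [2.0])
        assert np.allclose(g.heights, [0.5])  # mass 1 over (0, 2]

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_matches_quadratic_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 51))
        x = np.round(r.exponential(1.0, n), 2) + 0.01
        g = grenander_density(x)
        u, heights = _grenander_oracle(x)
        assert np.allclose(g.knots, u)
        assert np.max(np.abs(g.heights - heights)) < 1e-10

    def test_cdf_pdf_consistency(self, rng):
        x = rng.exponential(1.0, 100)
        g = grenander_density(x)
        assert g.cdf(g.knots[-1])[0] == pytest.approx(1.0, abs=1e-12)
        assert g.cdf(0.0)[0] == 0.0


class TestTwoComponentFit:
    def test_pure_null_recovery(self):
        z, _ = simulate_ratios(5000, 0.0, 0.0, 0.0, 1.0, seed=2)
        fit = fit_two_component(RatioVector.from_values(pd.Series(z)))
        assert 0.95 <= fit.sigma0 <= 1.05
        assert fit.eta0 >= 0.9

    def test_mixture_recovery_and_extreme_q(self):
        rng = np.random.default_rng(2)
        n = 5000
        is_alt = rng.random(n) < 0.1
        z = np.where(
            is_alt,
            rng.choice([-2.0, 2.0], n) + rng.normal(0, 0.2, n),
            rng.normal(0, 0.5, n),
        )
        fit = fit_two_component(RatioVector.from_values(pd.Series(z)))
        assert 0.45 <= fit.sigma0 <= 0.55
        extreme = fit.z.abs() > 1.8
        assert (fit.qval[extreme] < 0.2).all()

    def test_constant_vector_degenerate(self):
        rv = RatioVector.from_values(pd.Series(np.full(50, 3.0)))
        with pytest.raises(ValueError, match="constant"):
            fit_two_component(rv)

    def test_qval_monotone_in_abs_z(self):
        z, _ = simulate_ratios(2000, 0.1, 1.5, 0.3, 0.5, seed=4)
        fit = fit_two_component(RatioVector.from_values(pd.Series(z)))
        order = fit.z.abs().sort_values().index
        q = fit.qval.loc[order].to_numpy()
        assert np.all(np.diff(q) <= 1e-12)

    def test_lfdr_and_qval_in_unit_interval(self):
        z, _ = simulate_ratios(1000, 0.2, 1.0, 0.3, 0.5, seed=5)
        fit = fit_two_component(RatioVector.from_values(pd.Series(z)))
        assert ((fit.lfdr >= 0) & (fit.lfdr <= 1)).all()
        assert ((fit.qval > 0) & (fit.qval <= 1)).all()

    def test_order_invariance(self):
        z, _ = simulate_ratios(500, 0.1, 1.5, 0.3, 0.5, seed=6)
        s = pd.Series(z, index=[f"P{i}" for i in range(500)])
        fit1 = fit_two_component(RatioVector.from_values(s))
        shuffled = s.sample(frac=1.0, random_state=1)
        fit2 = fit_two_component(RatioVector.from_values(shuffled))
        calls1 = call_differential(fit1)
        calls2 = call_differential(fit2)
        set1 = set(calls1.loc[calls1["called"], "protein_group"])
        set2 = set(calls2.loc[calls2["called"], "protein_group"])
        assert set1 == set2
        pd.testing.assert_series_equal(
            fit1.qval.sort_index(), fit2.qval.sort_index(), atol=1e-12
        )


class TestCallDifferential:
    def _fit_with_qvals(self, qvals):
        z, _ = simulate_ratios(100, 0.0, 0.0, 0.0, 1.0, seed=0)
        fit = fit_two_component(RatioVector.from_values(pd.Series(z)))
        fit.qval = pd.Series(qvals, index=fit.z.index[: len(qvals)])
        fit.z = fit.z.iloc[: len(qvals)]
        fit.lfdr = fit.lfdr.iloc[: len(qvals)]
        return fit

    def test_strict_threshold(self):
        fit = self._fit_with_qvals([0.05, 0.19, 0.21])
        calls = call_differential(fit, q_threshold=0.2)
        assert list(calls["called"]) == [True, True, False]

    def test_threshold_zero_calls_nothing(self):
        fit = self._fit_with_qvals([0.0001, 0.5])
        assert not call_differential(fit, q_threshold=0.0)["called"].any()

    def test_threshold_one_calls_sub_one(self):
        fit = self._fit_with_qvals([0.5, 1.0])
        assert list(call_differential(fit, q_threshold=1.0)["called"]) == [True, False]


def _call_table(proteins, called_set, patient="P"):
    return pd.DataFrame(
        {
            "protein_group": proteins,
            "patient": patient,
            "contrast": "tumor:peritumor",
            "z": 0.0,
            "lfdr": 0.0,
            "qval": [0.1 if p in called_set else 0.9 for p in proteins],
            "called": [p in called_set for p in proteins],
        }
    )


class TestRecurrence:
    def test_called_in_two_of_five(self):
        proteins = ["A", "B", "C"]
        calls = {
            f"P{i}": _call_table(proteins, {"A"} if i in (2, 4) else set(), f"P{i}")
            for i in range(1, 6)
        }
        recurrent, counts = recurrence(calls, min_specimens=2)
        assert recurrent == {"A"}
        assert counts["A"] == 2

    def test_single_specimen_excluded(self):
        calls = {
            "P1": _call_table(["A"], {"A"}, "P1"),
            "P2": _call_table(["A"], set(), "P2"),
        }
        recurrent, counts = recurrence(calls)
        assert recurrent == set()
        assert counts["A"] == 1

    def test_needs_two_patients(self):
        with pytest.raises(ValueError):
            recurrence({"P1": _call_table(["A"], {"A"})})


class TestAverageFc:
    def _rv(self, values, patient):
        return RatioVector.from_values(
            pd.Series(values, index=[f"P{i}" for i in range(len(values))]),
            patient=patient,
        )

    def test_opposite_effects_cancel(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.3, 100)
        v1, v2 = base.copy(), base.copy()
        v1[0] += 3.0
        v2[0] -= 3.0
        fit = average_fc_analysis({"A": self._rv(v1, "A"), "B": self._rv(v2, "B")})
        calls = call_differential(fit)
        assert not calls.set_index("protein_group").at["P0", "called"]

    def test_exclusion_uses_exactly_retained(self):
        rng = np.random.default_rng(1)
        rvs = {
            f"T{i}": self._rv(rng.normal(0, 0.5, 200), f"T{i}") for i in range(5)
        }
        fit = average_fc_analysis(rvs, exclude_patients={"T0"})
        assert "T0" not in fit.patient
        assert all(f"T{i}" in fit.patient for i in range(1, 5))

    def test_consistent_effect_called(self):
        rng = np.random.default_rng(8)
        rvs = {}
        for i in range(4):
            v = rng.normal(0, 0.5, 300)
            v[:10] += 1.5
            rvs[f"T{i}"] = self._rv(v, f"T{i}")
        fit = average_fc_analysis(rvs)
        calls = call_differential(fit, q_threshold=0.2).set_index("protein_group")
        assert calls.loc[[f"P{i}" for i in range(10)], "called"].mean() >= 0.9

    def test_empty_retention_error(self):
        rvs = {"A": self._rv(np.zeros(30), "A")}
        with pytest.raises(ValueError):
            average_fc_analysis(rvs, exclude_patients={"A"})


class TestProteinOnlyFilter:
    def _calls(self):
        return _call_table(["A", "B", "C"], {"A", "B", "C"})

    def test_zero_transcript_retained(self):
        out = protein_only_filter(self._calls(), {"A": 0.0, "B": 0.0, "C": 0.0}, 0.5)
        assert out["retained"] == {"A", "B", "C"}

    def test_large_transcript_removed(self):
        out = protein_only_filter(self._calls(), {"A": 3.0, "B": 0.1, "C": -0.2}, 0.5)
        assert out["retained"] == {"B", "C"}

    def test_missing_transcript_reported(self):
        out = protein_only_filter(self._calls(), {"A": 0.0}, 0.5)
        assert out["retained"] == {"A"}
        assert out["no_transcript"] == {"B", "C"}

    def test_planted_protein_only_effects(self):
        rng = np.random.default_rng(4)
        proteins = [f"P{i}" for i in range(200)]
        calls = _call_table(proteins, set(proteins))
        transcript = {}
        for i, p in enumerate(proteins):
            if i < 30:  # protein-only: transcript quiet
                transcript[p] = float(rng.normal(0, 0.1))
            else:
                transcript[p] = float(rng.choice([-1, 1]) * rng.normal(2.0, 0.3))
        out = protein_only_filter(calls, transcript, 0.5)
        planted = set(proteins[:30])
        assert planted <= out["retained"]
        assert len(out["retained"] - planted) <= 5


class TestConcordance:
    def test_identity_reference(self):
        fc = {"A": 1.0, "B": -2.0, "C": 0.5}
        res = concordance(fc, dict(fc))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.sign_consistent_count == 3

    def test_negated_reference(self):
        fc = {"A": 1.0, "B": -2.0, "C": 0.5}
        res = concordance(fc, {k: -v for k, v in fc.items()})
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.sign_consistent_count == 0

    def test_hand_computed(self):
        # x=(1,-2,3), y=(2,-1,-3): r = -33/sqrt(114*114) = -11/38
        res = concordance(
            {"A": 1.0, "B": -2.0, "C": 3.0}, {"A": 2.0, "B": -1.0, "C": -3.0}
        )
        assert res.pearson_r == pytest.approx(-11 / 38, abs=1e-12)
        assert res.sign_consistent_count == 2

    def test_zero_counts_inconsistent(self):
        res = concordance(
            {"A": 0.0, "B": 1.0, "C": 1.0}, {"A": 1.0, "B": 2.0, "C": 3.0}
        )
        assert res.sign_consistent_count == 2

    def test_too_few_shared(self):
        with pytest.raises(ValueError):
            concordance({"A": 1.0, "B": 2.0}, {"A": 1.0, "B": 2.0})
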