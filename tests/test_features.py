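"""QC feature metrics: frozen closed-form values, brute-force oracles,
scale/shift invariances and registry contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakqc.datamodel import Label, group_traces
from peakqc.errors import (ConstantHalf, ConstantTrace, SingletonGroup,
                           TooFewPoints, ZeroPeak)
from peakqc.features import (KEY_COLUMNS, N_FEATURES, REGISTRY,
                             area_ratio_features, assemble_features,
                             boundary_intensity, build_context,
                             compute_features, compute_isotope_level,
                             feature_names, fwhm, jaggedness, modality,
                             peak_area, retention_time_features, shift,
                             similarity, symmetry)

from conftest import make_trace


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_jaggedness(y):
    """Direction-change fraction by direct enumeration of interior points."""
    y = list(map(float, y))
    n = len(y)
    # direction before/after each interior point, flat steps inheriting the
    # previous direction (leading flats take the first real direction)
    diffs = [y[i + 1] - y[i] for i in range(n - 1)]
    dirs = []
    for d in diffs:
        if d > 0:
            dirs.append(1)
        elif d < 0:
            dirs.append(-1)
        else:
            dirs.append(0)
    first = next((d for d in dirs if d != 0), 0)
    if first == 0:
        return 0.0
    filled, last = [], first
    for d in dirs:
        if d == 0:
            d = last
        filled.append(d)
        last = d
    apex = y.index(max(y))
    count = 0
    for i in range(1, n - 1):
        if filled[i] != filled[i - 1] and i != apex:
            count += 1
    return count / (n - 2)


def brute_modality(y):
    """Largest interior dip by direct enumeration."""
    y = list(map(float, y))
    best = 0.0
    for i in range(1, len(y) - 1):
        left = max(y[: i + 1])
        right = max(y[i:])
        best = max(best, min(left, right) - y[i])
    return best / max(y)


class TestJaggedness:
    @pytest.mark.parametrize("y,expected", [
        ([0, 1, 2, 3, 2, 1, 0], 0.0),        # smooth unimodal peak
        ([0, 2, 1, 3, 0], 2 / 3),            # two interior flips, apex excluded
        ([0, 2, 0, 2, 0, 2, 0], 0.8),        # saw-tooth, 4 of 5 interior flip
        ([1, 2, 2, 3, 2, 1], 0.0),           # mid-rise plateau inherits sign
        # apex plateau: the down-turn registers on the plateau's trailing
        # point, which is not the (first-index) apex -> one counted flip
        ([1, 1, 2, 2, 1, 1], 0.25),
        ([5, 5, 5, 5], 0.0),                 # perfectly flat trace
    ])
    def test_frozen_values(self, y, expected):
        assert jaggedness(y) == pytest.approx(expected, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(TooFewPoints):
            jaggedness([0, 1, 0])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(4, 12))
            y = rng.integers(0, 6, size=n).astype(float)
            assert jaggedness(y) == pytest.approx(brute_jaggedness(y), abs=1e-12)


class TestSimilarity:
    def test_identical_traces(self):
        y = [0, 1, 4, 2, 0]
        assert similarity(y, y) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_correlation(self):
        # direct correlation formula gives 10.2 / 11.2
        assert similarity([0, 1, 4, 2, 0], [0, 2, 4, 1, 0]) == pytest.approx(
            10.2 / 11.2, abs=1e-12)

    def test_antisymmetric(self):
        y = np.array([0.0, 1, 4, 2, 0])
        assert similarity(y, 5 - y) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_trace_missing(self):
        with pytest.raises(ConstantTrace):
            similarity([1, 1, 1, 1], [0, 1, 2, 1])


class TestSymmetry:
    def test_mirror_symmetric_is_one(self):
        assert symmetry([0, 1, 4, 4, 1, 0]) == pytest.approx(1.0, abs=1e-12)
        assert symmetry([0, 2, 5, 9, 5, 2, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_odd_length(self):
        # midpoint excluded: corr([0,1,4], [0,1,3])
        expected = 57.0 / math.sqrt(78.0 * 42.0)
        assert symmetry([0, 1, 4, 5, 3, 1, 0]) == pytest.approx(expected, abs=1e-12)

    def test_ramp_is_negative(self):
        assert symmetry([1, 2, 3, 4, 5, 6]) < 0

    def test_constant_half_missing(self):
        with pytest.raises(ConstantHalf):
            symmetry([1, 1, 1, 5, 2, 3])


class TestFwhm:
    def test_triangle(self):
        w, r = fwhm([0, 1, 2, 3, 4, 5, 6], [0, 1, 2, 3, 2, 1, 0], 0, 6)
        assert w == pytest.approx(3.0, abs=1e-12)
        assert r == pytest.approx(0.5, abs=1e-12)

    def test_gaussian_closed_form(self):
        sigma = 0.1
        t = np.arange(-0.5, 0.5, 0.001)
        y = np.exp(-0.5 * (t / sigma) ** 2)
        w, _ = fwhm(t, y, -0.5, 0.5)
        assert w == pytest.approx(2 * math.sqrt(2 * math.log(2)) * sigma,
                                  rel=1e-3)

    def test_plateau_no_crossing(self):
        w, r = fwhm([0, 1, 2], [1, 1, 1], 0, 2)
        assert (w, r) == (2, 1.0)

    def test_zero_peak_missing(self):
        with pytest.raises(ZeroPeak):
            fwhm([0, 1, 2], [0, 0, 0], 0, 2)


class TestModality:
    @pytest.mark.parametrize("y,expected", [
        ([0, 1, 2, 3, 2, 1, 0], 0.0),  # strictly unimodal
        ([2, 0, 2], 1.0),              # dip spans full height
        ([0, 3, 1, 2, 0], 1 / 3),      # largest dip 1 below min(3, 2), height 3
        ([0, 2, 1, 3, 1, 2, 0], 1 / 3),
    ])
    def test_frozen_values(self, y, expected):
        assert modality(y) == pytest.approx(expected, abs=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            y = rng.integers(0, 6, size=n).astype(float)
            if y.max() == 0:
                y[int(rng.integers(0, n))] = 1.0
            assert modality(y) == pytest.approx(brute_modality(y), abs=1e-12)


class TestShiftAndBoundary:
    def test_zero_when_coeluting(self):
        assert shift(10.2, [10.2, 10.2, 10.2], 0.5) == 0.0

    def test_frozen_arithmetic(self):
        assert shift(10.30, [10.15, 10.20, 10.25], 0.5) == pytest.approx(0.2)

    def test_singleton_group_missing(self):
        with pytest.raises(SingletonGroup):
            shift(10.0, [], 0.5)

    @pytest.mark.parametrize("y,expected", [
        ([0, 5, 0], 0.0), ([2, 5, 1], 0.3), ([3, 3, 3], 1.0),
    ])
    def test_boundary_intensity(self, y, expected):
        assert boundary_intensity(y) == pytest.approx(expected, abs=1e-12)

    def test_boundary_intensity_zero_peak(self):
        with pytest.raises(ZeroPeak):
            boundary_intensity([0, 0, 0])


class TestPeakArea:
    def test_trapezoid(self):
        assert peak_area([0, 1, 2, 3], [0, 2, 2, 0]) == pytest.approx(4.0)

    def test_linearity(self):
        y = np.array([0.0, 1, 3, 1, 0])
        t = np.arange(5.0)
        assert peak_area(t, 2 * y) == pytest.approx(2 * peak_area(t, y))


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

peak_vectors = st.lists(st.integers(0, 100), min_size=6, max_size=30).filter(
    lambda y: len(set(y)) > 1 and max(y) > 0
    and len(set(y[: len(y) // 2])) > 1 and len(set(y[-(len(y) // 2):])) > 1)


class TestInvariances:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(y=peak_vectors, c=st.floats(0.1, 1000))
    def test_scale_invariance(self, y, c):
        y = np.array(y, dtype=float)
        t = np.arange(len(y), dtype=float)
        assert jaggedness(c * y) == pytest.approx(jaggedness(y), abs=1e-9)
        assert modality(c * y) == pytest.approx(modality(y), abs=1e-9)
        assert symmetry(c * y) == pytest.approx(symmetry(y), abs=1e-9)
        assert boundary_intensity(c * y) == pytest.approx(
            boundary_intensity(y), abs=1e-9)
        w0, r0 = fwhm(t, y, t[0], t[-1])
        w1, r1 = fwhm(t, c * y, t[0], t[-1])
        assert (w1, r1) == pytest.approx((w0, r0), abs=1e-9)
        assert peak_area(t, c * y) == pytest.approx(c * peak_area(t, y),
                                                    rel=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(y=peak_vectors, dt=st.floats(-100, 100))
    def test_time_shift_invariance(self, y, dt):
        y = np.array(y, dtype=float)
        t = np.arange(len(y), dtype=float)
        w0, r0 = fwhm(t, y, t[0], t[-1])
        w1, r1 = fwhm(t + dt, y, t[0] + dt, t[-1] + dt)
        assert (w1, r1) == pytest.approx((w0, r0), abs=1e-9)
        assert peak_area(t + dt, y) == pytest.approx(peak_area(t, y), rel=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(y=peak_vectors)
    def test_score_ranges(self, y):
        y = np.array(y, dtype=float)
        t = np.arange(len(y), dtype=float)
        assert 0.0 <= jaggedness(y) <= 1.0
        assert 0.0 <= modality(y) <= 1.0
        assert 0.0 <= boundary_intensity(y) <= 1.0
        assert -1.0 <= symmetry(y) <= 1.0
        _, ratio = fwhm(t, y, t[0], t[-1])
        assert 0.0 <= ratio <= 1.0


# ---------------------------------------------------------------------------
# registry and assembly contracts
# ---------------------------------------------------------------------------

class TestRegistry:
    def test_registry_counts(self):
        assert len(REGISTRY) == 32
        assert sum(e.label_specific for e in REGISTRY) == 20
        assert N_FEATURES == 52

    def test_label_specific_iff_transition_or_isotope(self):
        for e in REGISTRY:
            assert e.label_specific == (e.level in ("transition", "isotope"))

    def test_nine_groups_covered(self):
        groups = {e.group for e in REGISTRY}
        assert groups == {"jaggedness", "similarity", "symmetry", "fwhm",
                          "modality", "shift", "intensity", "area_ratio",
                          "retention_time"}

    def test_names_unique_and_ordered(self):
        names = feature_names()
        assert len(names) == len(set(names)) == 52
        for e in REGISTRY:
            if e.label_specific:
                assert e.name + ".endo" in names and e.name + ".std" in names
            else:
                assert e.name in names


class TestAssembly:
    def test_assembled_vector_has_52_entries(self, clean_groups):
        ctx = build_context(clean_groups)
        group = clean_groups[0]
        pair = group.complete_pairs()[0]
        fv = assemble_features(pair, group, ctx)
        assert len(fv) == 52
        assert list(fv.values) == feature_names()

    def test_zero_std_trace_keeps_shape(self, clean_groups):
        import copy
        group = copy.deepcopy(clean_groups[0])
        pair = group.complete_pairs()[0]
        pair.std.intensities[:] = 0.0
        ctx = build_context([group])
        fv = assemble_features(pair, group, ctx)
        assert len(fv) == 52
        assert any(fv.missing_mask.values())
        assert fv.missing_mask["area_ratio.isotope_ratio.transition_pair"]

    def test_compute_features_frame_shape(self, clean_groups):
        df = compute_features(clean_groups)
        assert list(df.columns) == KEY_COLUMNS + feature_names()
        n_pairs = sum(len(g.complete_pairs()) for g in clean_groups)
        assert len(df) == n_pairs

    def test_clean_dataset_scores(self, clean_groups):
        """Defect-free peaks: near-perfect shape scores everywhere."""
        df = compute_features(clean_groups)
        assert df["jaggedness.score.transition.endo"].mean() < 0.05
        assert df["similarity.pair.transition_pair"].min() > 0.98
        assert df["modality.score.transition.endo"].max() < 0.05
        # mild intrinsic EMG tailing keeps clean symmetry high but below 1
        assert df["symmetry.score.transition.endo"].mean() > 0.9

    def test_isotope_level_aggregates(self, clean_groups):
        group = clean_groups[0]
        out = compute_isotope_level(group, Label.ENDOGENOUS)
        # fragments of a clean group share shape -> mean similarity ~ 1
        assert out["similarity_mean"] == pytest.approx(1.0, abs=0.01)

    def test_singleton_fragment_similarity_missing(self):
        traces = [make_trace([0, 1, 5, 1, 0], fragment="y4", label=lab)
                  for lab in Label]
        group = list(group_traces(traces).values())[0]
        out = compute_isotope_level(group, Label.ENDOGENOUS)
        assert math.isnan(out["similarity_mean"])


class TestCrossRunContext:
    def test_pair_ratio_consistency_zero_when_equal(self, clean_groups):
        ctx = build_context(clean_groups)
        group = clean_groups[0]
        pair = group.complete_pairs()[0]
        out = area_ratio_features(pair, group, ctx)
        # clean light/heavy traces share shape -> fractions nearly equal
        assert out["pair_ratio_consistency"] == pytest.approx(0.0, abs=0.01)

    def test_ratio_at_median_has_zero_consistency(self):
        # two identical runs: every ratio equals the cross-run median
        traces = []
        for run in ("run01", "run02"):
            for frag in ("y4", "y5", "y6"):
                for lab, scale in ((Label.ENDOGENOUS, 1.0), (Label.STANDARD, 3.0)):
                    traces.append(make_trace(
                        scale * np.array([0, 1, 5, 9, 5, 1, 0.0]),
                        run=run, fragment=frag, label=lab))
        groups = list(group_traces(traces).values())
        ctx = build_context(groups)
        out = area_ratio_features(groups[0].complete_pairs()[0], groups[0], ctx)
        assert out["isotope_ratio_consistency"] == pytest.approx(0.0, abs=1e-12)
        assert out["isotope_ratio"] == pytest.approx(1 / 3, rel=1e-9)

    def test_proportional_areas_give_unit_correlation(self):
        # endo areas exactly proportional to std areas across >= 3 runs
        rng = np.random.default_rng(0)
        traces = []
        for i, run in enumerate(("run01", "run02", "run03", "run04")):
            h = 1.0 + i + rng.random()
            for frag in ("y4", "y5", "y6"):
                for lab, scale in ((Label.ENDOGENOUS, h), (Label.STANDARD, 2.5 * h)):
                    traces.append(make_trace(
                        scale * np.array([0, 1, 5, 9, 5, 1, 0.0]),
                        run=run, fragment=frag, label=lab))
        groups = list(group_traces(traces).values())
        ctx = build_context(groups)
        out = area_ratio_features(groups[0].complete_pairs()[0], groups[0], ctx)
        assert out["area_correlation"] == pytest.approx(1.0, abs=1e-9)

    def test_retention_time_features_at_median(self, clean_groups):
        ctx = build_context(clean_groups)
        group = clean_groups[0]
        trace = group.traces[0]
        out = retention_time_features(trace, ctx)
        # per-run jitter is tiny; deviation from median stays below it
        assert out["apex_consistency"] < 0.05
        assert out["fwhm_consistency"] < 0.2
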