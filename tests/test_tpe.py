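"""TPE classification rules, grid classification and sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from ricetpe.matrices import SeasonSlice
from ricetpe.tpe import (
    TPE_LABELS,
    classify_environment,
    classify_grid,
    class_proportions,
    f75_frequency,
    genotype_count_sensitivity,
    severity_class,
    suitability_map,
    timing_class,
)


def make_slice(ratios=None, av=0.9, ar=0.9, env_id="e", py=8.0, ay_jv=None, varieties=None):
    """Slice with prescribed rainfed:irrigated ratios (flattened row-major)."""
    if ay_jv is None:
        ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
        py_jv = np.full_like(ratios, py)
        ay_jv = py_jv * ratios
    else:
        ay_jv = np.asarray(ay_jv, dtype=float)
        py_jv = np.full_like(ay_jv, py)
    j, v = ay_jv.shape
    return SeasonSlice(
        env_id=env_id,
        varieties=varieties or [f"v{k}" for k in range(v)],
        years=2000 + np.arange(j),
        py_jv=py_jv,
        ay_jv=ay_jv,
        av_jv=np.full((j, v), av),
        ar_jv=np.full((j, v), ar),
    )


class TestF75:
    def test_no_reduction_gives_zero(self):
        assert f75_frequency(make_slice([[1.0, 1.0], [1.0, 1.0]])) == 0.0

    def test_half_below(self):
        assert f75_frequency(make_slice([[0.5, 1.0], [0.5, 1.0]])) == 0.5

    def test_strict_inequality_at_threshold(self):
        # only 0.74 counts: 0.75 itself does not
        assert f75_frequency(make_slice([[0.74, 0.75], [0.76, 1.0]])) == 0.25

    def test_empty_slice_raises(self):
        s = make_slice([[1.0]])
        s.ay_jv = s.py_jv = np.empty((0, 0))
        with pytest.raises(ValueError):
            f75_frequency(s)


class TestSeverity:
    @pytest.mark.parametrize(
        "f75, expected",
        [(0.60, "S"), (0.50, "S"), (0.49, "M"), (0.25, "M"), (0.249, "L"), (0.10, "L"), (0.0, "L"), (1.0, "S")],
    )
    def test_boundaries_as_published(self, f75, expected):
        assert severity_class(f75) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            severity_class(1.2)

    def test_monotone_in_f75(self):
        order = {"L": 0, "M": 1, "S": 2}
        grid = np.linspace(0, 1, 101)
        codes = [order[severity_class(f)] for f in grid]
        assert codes == sorted(codes)


class TestTiming:
    @pytest.mark.parametrize(
        "av, ar, expected",
        [
            (0.5, 0.8, 1),  # vegetative: av < ar
            (0.9, 0.7, 2),  # reproductive: ar < 0.9 * av
            (0.9, 0.85, 3),  # mixed: between
            (1.0, 1.0, 3),  # no stress falls through to mixed
        ],
    )
    def test_rule_order(self, av, ar, expected):
        assert timing_class(av, ar) == expected


class TestClassifyEnvironment:
    def test_severe_reproductive(self):
        s = make_slice(np.full((4, 3), 0.5), av=0.9, ar=0.5)
        assert classify_environment(s).label == "S2"

    def test_no_stress_is_l3(self):
        s = make_slice(np.ones((4, 3)), av=1.0, ar=1.0)
        assert classify_environment(s).label == "L3"

    def test_emits_one_of_nine_labels(self, classified_grid):
        _, _, _, slices = classified_grid
        for s in slices.values():
            assert classify_environment(s).label in TPE_LABELS

    def test_invariant_under_year_and_variety_permutation(self, rng):
        ay = rng.uniform(2, 9, size=(6, 5))
        s = make_slice(ay_jv=ay, av=0.7, ar=0.65)
        base = classify_environment(s)
        shuffled = make_slice(ay_jv=ay[rng.permutation(6)][:, rng.permutation(5)], av=0.7, ar=0.65)
        other = classify_environment(shuffled)
        assert (base.label, base.f75) == (other.label, other.f75)


def test_taxonomy_is_severity_cross_timing():
    assert len(TPE_LABELS) == 9
    assert set(TPE_LABELS) == {f"{s}{t}" for s in "LMS" for t in "123"}


class TestClassifyGrid:
    def test_identical_environments_single_class(self):
        s = make_slice(np.full((3, 2), 0.5), av=0.9, ar=0.5)
        table = classify_grid({"a": s, "b": s})
        assert set(table["label"]) == {"S2"}
        props = class_proportions(table)
        assert props["S2"] == 1.0 and props.sum() == pytest.approx(1.0)

    def test_empty_grid(self):
        table = classify_grid({})
        assert table.empty
        assert class_proportions(table).sum() == 0.0

    def test_recovers_designed_regimes(self, classified_grid):
        envs, _, _, slices = classified_grid
        table = classify_grid(slices)
        truth = {e.env_id: e.true_label for e in envs}
        table["truth"] = table["env_id"].map(truth)
        assert (table["label"] == table["truth"]).mean() >= 0.95


class TestGenotypeCountSensitivity:
    def test_full_panel_equals_full_classification_with_zero_dispersion(self, classified_grid):
        envs, cubes, _, slices = classified_grid
        full = class_proportions(classify_grid(slices))
        out = genotype_count_sensitivity(cubes, [11], n_replicates=5, seed=0)
        for _, row in out.iterrows():
            assert row["sd_proportion"] == 0.0
            assert row["mean_proportion"] == pytest.approx(full[row["label"]])

    def test_single_genotype_disperses_more_than_full(self, classified_grid):
        _, cubes, _, _ = classified_grid
        out = genotype_count_sensitivity(cubes, [1, 11], n_replicates=30, seed=1)
        d = out.groupby("n_genotypes")["sd_proportion"].mean()
        assert d[1] >= d[11]
        assert d[11] == 0.0

    def test_seeded_reproducibility(self, classified_grid):
        _, cubes, _, _ = classified_grid
        a = genotype_count_sensitivity(cubes, [2, 5], n_replicates=10, seed=3)
        b = genotype_count_sensitivity(cubes, [2, 5], n_replicates=10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_bad_sizes(self, classified_grid):
        _, cubes, _, _ = classified_grid
        with pytest.raises(ValueError):
            genotype_count_sensitivity(cubes, [0], n_replicates=2, seed=0)


class TestSuitabilityMap:
    def _slices(self, focal_vals, check_vals):
        out = {}
        for k, (f, c) in enumerate(zip(focal_vals, check_vals)):
            ay = np.column_stack([np.full(3, f), np.full(3, c)])
            out[f"e{k}"] = make_slice(ay_jv=ay, varieties=["focal", "check"])
        return out

    def test_identical_focal_and_check_scores_zero(self):
        table = suitability_map(self._slices([5, 5], [5, 5]), "focal", ["check"])
        assert (table["score"] == 0.0).all()

    def test_uniform_one_tonne_advantage(self):
        table = suitability_map(self._slices([6, 6], [5, 5]), "focal", ["check"], thresholds=(0.25, 1.0))
        assert (table["score"] == 1.0).all()
        assert set(table["category"]) == {"high"}

    def test_regional_advantage_localised(self):
        table = suitability_map(self._slices([6, 4], [5, 5]), "focal", ["check"])
        scores = dict(zip(table["env_id"], table["score"]))
        assert scores["e0"] > 0 > scores["e1"]

    def test_missing_variety_raises(self):
        with pytest.raises(KeyError):
            suitability_map(self._slices([5], [5]), "nope", ["check"])
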