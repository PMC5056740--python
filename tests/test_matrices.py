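"""Cleaning, RY/CV computation and best-season selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ricetpe.matrices import (
    CombinedPanels,
    NoSuitableSeasonError,
    best_season_slice,
    clean_unsuitable_dates,
    cv_by_date,
    mean_rainfed_yield_by_date,
    select_best_season,
)


def make_panels(py, ay=None, av=None, ar=None, env_id="env"):
    py = np.asarray(py, dtype=float)
    nv, ni, nj = py.shape
    ay = py * 0.8 if ay is None else np.asarray(ay, dtype=float)
    av = np.full_like(py, 0.9) if av is None else np.asarray(av, dtype=float)
    ar = np.full_like(py, 0.8) if ar is None else np.asarray(ar, dtype=float)
    return CombinedPanels(
        env_id=env_id,
        varieties=[f"v{k}" for k in range(nv)],
        sowing_index=np.arange(1, ni + 1),
        sowing_doys=1 + 15 * np.arange(ni),
        years=2000 + np.arange(nj),
        py=py,
        ay=ay,
        av=av,
        ar=ar,
    )


class TestCleaning:
    def test_all_positive_is_unchanged(self):
        panels = make_panels(np.full((2, 4, 3), 5.0))
        cleaned = clean_unsuitable_dates(panels)
        assert cleaned.n_dates == 4
        np.testing.assert_array_equal(cleaned.py, panels.py)

    def test_single_zero_removes_row_from_all_four_panels(self):
        py = np.full((2, 4, 3), 5.0)
        py[1, 2, 0] = 0.0  # one zero at sowing date 3
        panels = make_panels(py)
        cleaned = clean_unsuitable_dates(panels)
        assert list(cleaned.sowing_index) == [1, 2, 4]
        for arr in (cleaned.py, cleaned.ay, cleaned.av, cleaned.ar):
            assert arr.shape == (2, 3, 3)
        assert np.all(cleaned.py > 0)

    def test_no_surviving_date_raises(self):
        py = np.zeros((1, 3, 2))
        with pytest.raises(NoSuitableSeasonError):
            clean_unsuitable_dates(make_panels(py))


class TestRyCv:
    def test_constant_panel(self):
        panels = make_panels(np.full((2, 3, 4), 5.0), ay=np.full((2, 3, 4), 3.0))
        np.testing.assert_allclose(mean_rainfed_yield_by_date(panels), 3.0)
        np.testing.assert_allclose(cv_by_date(panels), 0.0)

    def test_known_values(self):
        # m=2 years, c=2 varieties, one sowing date with values {4,6,8,2}
        ay = np.array([[[4.0, 6.0]], [[8.0, 2.0]]])
        panels = make_panels(np.full((2, 1, 2), 9.0), ay=ay)
        assert mean_rainfed_yield_by_date(panels)[0] == pytest.approx(5.0)

    def test_cv_is_population_sd_over_mean(self):
        ay = np.array([[[4.0, 6.0]]])  # values {4, 6}: sd 1, mean 5
        panels = make_panels(np.full((1, 1, 2), 9.0), ay=ay)
        assert cv_by_date(panels)[0] == pytest.approx(0.2)

    def test_cv_scale_invariance(self):
        rng = np.random.default_rng(0)
        ay = rng.uniform(1, 9, size=(3, 4, 5))
        panels = make_panels(np.full((3, 4, 5), 10.0), ay=ay)
        scaled = make_panels(np.full((3, 4, 5), 10.0), ay=3.5 * ay)
        np.testing.assert_allclose(cv_by_date(panels), cv_by_date(scaled))

    def test_zero_ry_raises(self):
        panels = make_panels(np.full((1, 2, 2), 5.0), ay=np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            cv_by_date(panels)

    @given(
        ay=arrays(
            np.float64,
            shape=(2, 3, 4),
            elements=st.floats(0.1, 20.0, allow_nan=False),
        )
    )
    def test_matches_double_loop_oracle(self, ay):
        panels = make_panels(np.full((2, 3, 4), 25.0), ay=ay)
        ry = mean_rainfed_yield_by_date(panels)
        cv = cv_by_date(panels)
        nv, ni, nj = ay.shape
        for i in range(ni):
            vals = [ay[v, i, j] for v in range(nv) for j in range(nj)]
            mean = sum(vals) / len(vals)
            sd = (sum((x - mean) ** 2 for x in vals) / len(vals)) ** 0.5
            assert ry[i] == pytest.approx(mean, abs=1e-10)
            assert cv[i] == pytest.approx(sd / mean, abs=1e-10)


def panels_with(ry_targets, cv_targets):
    """Two-year one-variety panels with exact per-date mean and CV."""
    ni = len(ry_targets)
    ay = np.zeros((1, ni, 2))
    for i, (m, c) in enumerate(zip(ry_targets, cv_targets)):
        ay[0, i] = [m * (1 + c), m * (1 - c)]  # mean m, population cv c
    return make_panels(np.full((1, ni, 2), 99.0), ay=ay)


class TestBestSeason:
    def test_smallest_cv_among_top_three_ry(self):
        panels = panels_with([7, 6, 5, 1], [0.3, 0.2, 0.1, 0.0])
        best = select_best_season(panels)
        # date 4 has the smallest CV overall but is not in the top-3 RY
        assert best.sowing_index == 3
        assert best.ry == pytest.approx(5.0)
        assert best.cv == pytest.approx(0.1)

    def test_single_surviving_date(self):
        panels = panels_with([4.0], [0.5])
        assert select_best_season(panels).sowing_index == 1

    def test_cv_tie_goes_to_earlier_date(self):
        panels = panels_with([7, 7, 7], [0.2, 0.2, 0.2])
        assert select_best_season(panels).sowing_index == 1

    def test_invariant_under_variety_permutation(self):
        rng = np.random.default_rng(4)
        ay = rng.uniform(1, 9, size=(5, 6, 3))
        panels = make_panels(np.full((5, 6, 3), 12.0), ay=ay)
        perm = rng.permutation(5)
        shuffled = make_panels(np.full((5, 6, 3), 12.0), ay=ay[perm])
        assert select_best_season(panels) == select_best_season(shuffled)


def test_best_season_slice_shape_and_values():
    rng = np.random.default_rng(8)
    ay = rng.uniform(1, 9, size=(3, 4, 5))
    panels = make_panels(np.full((3, 4, 5), 11.0), ay=ay)
    best = select_best_season(panels)
    s = best_season_slice(panels, best)
    i = best.sowing_index - 1
    assert s.ay_jv.shape == (5, 3)  # (years, varieties)
    np.testing.assert_array_equal(s.ay_jv, ay[:, i, :].T)
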