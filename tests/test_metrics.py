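"""Noise metrics, summaries, rankings and the saturation audit."""

import numpy as np
import pandas as pd
import pytest

from fflnoise import (
    ParameterSet,
    build_model,
    cv_percent,
    fano,
    integrate,
    layer_cv_profile,
    rank_models,
    saturation_check,
    slope,
    summarize,
)
from fflnoise.metrics import ModelSummary
from fflnoise.pipeline import RunConfig, stationary_plateau_frame


class TestScalarMetrics:
    def test_cv_percent(self):
        assert cv_percent(4.0, 1.0) == pytest.approx(25.0)
        assert cv_percent(6.0, 6.0) == pytest.approx(100 / np.sqrt(6))  # Poisson
        assert cv_percent(6.0, 1.83 * 6) == pytest.approx(55.23, abs=0.01)

    def test_cv_requires_positive_mean(self):
        with pytest.raises(ValueError):
            cv_percent(0.0, 1.0)

    def test_fano(self):
        assert fano(7.0, 7.0) == pytest.approx(1.0)
        assert fano(6.0, 1.83 * 6) == pytest.approx(1.83)
        assert fano(10.0, 60 * (1 / 6) * (5 / 6)) == pytest.approx(5 / 6)

    def test_slope_cases(self):
        x = [2, 3, 4, 5, 6]
        assert slope(x, [5 * v for v in x]) == pytest.approx(5.0)
        assert slope(x, [7, 7, 7, 7, 7]) == pytest.approx(0.0)
        assert slope(x, [10, 8, 6, 4, 2]) < 0

    def test_slope_validation(self):
        with pytest.raises(ValueError):
            slope([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            slope([1, 2], [1, 2, 3])


@pytest.fixture(scope="module")
def frame(c1_or, protocol):
    return stationary_plateau_frame(c1_or, protocol)


class TestSummaries:
    def test_summary_structure(self, frame):
        s = summarize(frame, scheme="one-step", family="isolated")
        assert s.model_id == "c1-OR"
        assert set(s.cv_percent_output) == {2.0, 3.0, 4.0, 5.0, 6.0}
        assert s.slope == pytest.approx(s.slope_down, rel=1e-6)
        assert s.slope > 0

    def test_good_reducer_cv_decreases_with_input(self, frame):
        s = summarize(frame)
        cvs = [s.cv_percent_output[l] for l in (2.0, 3.0, 4.0, 5.0, 6.0)]
        assert all(b < a for a, b in zip(cvs, cvs[1:]))

    def test_missing_output_species(self, frame):
        with pytest.raises(ValueError):
            summarize(frame, output="W_a")


class TestRanking:
    def _mk(self, mid, cv, sl, scheme="one-step"):
        return ModelSummary(
            model_id=mid, scheme=scheme, family="isolated", method="lna",
            cv_percent_output={6.0: cv}, fano_output={6.0: 1.0},
            slope=sl, slope_down=sl,
        )

    def test_sorted_by_cv_with_correlation(self):
        table, corr = rank_models(
            [self._mk("a", 20.0, 0.1), self._mk("b", 5.0, 1.0), self._mk("c", 10.0, 0.5)]
        )
        assert list(table.model_id) == ["b", "c", "a"]
        assert corr < 0

    def test_mixed_schemes_rejected(self):
        with pytest.raises(ValueError):
            rank_models([self._mk("a", 1.0, 1.0), self._mk("b", 2.0, 2.0, "two-step")])


class TestLayerProfile:
    def test_good_reducer_attenuates_monotonically(self, c1_or, protocol):
        rows = layer_cv_profile(integrate(c1_or, protocol))
        names = [r[0] for r in rows]
        cvs = [r[1] for r in rows]
        assert names == ["S", "X_a", "Y_a", "Z_a"]
        assert all(b < a for a, b in zip(cvs, cvs[1:]))

    def test_bad_reducer_quietest_at_middle_layer(self, protocol):
        crn = build_model("c3-OR")
        rows = layer_cv_profile(integrate(crn, protocol))
        by_name = dict(rows)
        assert by_name["Y_a"] < by_name["X_a"]
        assert by_name["Y_a"] < by_name["Z_a"]


class TestSaturationCheck:
    def test_default_model_passes(self, c1_or, protocol):
        frame = stationary_plateau_frame(c1_or, protocol)
        assert saturation_check(frame, 60.0).empty

    def test_overdriven_model_flagged_by_species(self, protocol):
        crn = build_model("c1-OR", params=ParameterSet(kp=1000.0))
        frame = stationary_plateau_frame(crn, protocol)
        bad = saturation_check(frame, 60.0)
        assert not bad.empty
        assert "X_a" in set(bad.species)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            saturation_check(pd.DataFrame(), 60.0)
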