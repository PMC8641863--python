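"""Noise and signal-transduction measures derived from moment results.

Two numbers summarize every model:

* the coefficient of variation of the output in percent,
  ``%CV = 100 * sd / mean`` — the signal-to-noise measure reported per
  plateau (a Poisson process has ``%CV = 100 / sqrt(mean)``); and
* the *slope* of the mean-output vs mean-input relation across the five
  ascending plateau levels — the signal-transduction measure, with negative
  slopes flagging signal inversion.

The Fano factor (variance / mean, 1 for Poisson) is carried alongside.
Model comparisons (rankings, gate comparisons, layer profiles, the
saturation audit) all operate on a tidy per-plateau DataFrame so that LNA
and SSA results are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lna import LNAResult
from .ssa import EnsembleStats

OUTPUT_SPECIES = "Z_a"
UP_LEVELS = (2.0, 3.0, 4.0, 5.0, 6.0)
REFERENCE_INPUT = 6.0


def cv_percent(mean: float, variance: float) -> float:
    """Coefficient of variation in percent, 100*sd/mean."""
    if mean <= 0:
        raise ValueError("cv_percent requires a positive mean")
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    return 100.0 * np.sqrt(variance) / mean


def fano(mean: float, variance: float) -> float:
    """Fano factor, variance/mean (1 for a Poisson process)."""
    if mean <= 0:
        raise ValueError("fano requires a positive mean")
    return variance / mean


def slope(plateau_means_in, plateau_means_out) -> float:
    """Ordinary least-squares slope of mean output against mean input."""
    x = np.asarray(plateau_means_in, dtype=float)
    y = np.asarray(plateau_means_out, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("input levels are degenerate")
    return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# tidy per-plateau statistics
# ---------------------------------------------------------------------------


def plateau_frame(result: LNAResult | EnsembleStats) -> pd.DataFrame:
    """Per-plateau, per-species means and variances as a tidy DataFrame.

    LNA results contribute end-of-plateau moments; SSA ensembles contribute
    their equilibrated-window statistics.  Columns: model_id, method, level,
    phase, species, mean, var.
    """
    rows = []
    if isinstance(result, LNAResult):
        for level, phase, state in result.plateau_end_states():
            for i, name in enumerate(result.species_names):
                rows.append(
                    (result.model_id, "lna", level, phase, name,
                     state.mu[i], max(state.sigma[i, i], 0.0))
                )
    elif isinstance(result, EnsembleStats):
        for seg in range(len(result.plateau_levels)):
            for i, name in enumerate(result.species_names):
                rows.append(
                    (result.model_id, "ssa", result.plateau_levels[seg],
                     result.plateau_phase[seg], name,
                     result.mean[seg, i], result.var[seg, i])
                )
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")
    return pd.DataFrame(
        rows, columns=["model_id", "method", "level", "phase", "species", "mean", "var"]
    )


@dataclass
class ModelSummary:
    """Per-model noise and transduction summary over the staircase."""

    model_id: str
    scheme: str
    family: str
    method: str
    cv_percent_output: dict[float, float]  # up-phase plateau level -> %CV of Z_a
    fano_output: dict[float, float]
    slope: float  # up-phase OLS slope
    slope_down: float  # down-phase consistency diagnostic
    layer_cv_profile: dict[str, float] = field(default_factory=dict)

    @property
    def cv_at_reference(self) -> float:
        return self.cv_percent_output[REFERENCE_INPUT]


def summarize(
    frame: pd.DataFrame,
    scheme: str = "one-step",
    family: str = "",
    output: str = OUTPUT_SPECIES,
) -> ModelSummary:
    """Condense a plateau frame into the headline per-model measures."""
    z = frame[frame.species == output]
    if z.empty:
        raise ValueError(f"no output species {output!r} in frame")
    up = z[(z.phase == "up") & z.level.isin(UP_LEVELS)].sort_values("level")
    down = z[(z.phase == "down") & z.level.isin(UP_LEVELS)]
    peak = max(UP_LEVELS)
    if peak not in set(down.level):
        # the peak plateau is the turning point: its end state starts the descent
        down = pd.concat([down, up[up.level == peak]])
    down = down.sort_values("level")
    cvs = {r.level: cv_percent(r.mean, r.var) for r in up.itertuples()}
    fns = {r.level: fano(r.mean, r.var) for r in up.itertuples()}
    ref = frame[(frame.level == REFERENCE_INPUT) & (frame.phase == "up")]
    profile = {
        r.species: cv_percent(r.mean, r.var)
        for r in ref.itertuples()
        if r.species == "S" or r.species.endswith("_a")
    }
    return ModelSummary(
        model_id=frame.model_id.iloc[0],
        scheme=scheme,
        family=family,
        method=frame.method.iloc[0],
        cv_percent_output=cvs,
        fano_output=fns,
        slope=slope(up.level, up["mean"]),
        slope_down=slope(down.level, down["mean"]) if len(down) >= 2 else np.nan,
        layer_cv_profile=profile,
    )


# ---------------------------------------------------------------------------
# catalog-level comparisons
# ---------------------------------------------------------------------------


def rank_models(summaries: list[ModelSummary]) -> tuple[pd.DataFrame, float]:
    """Ranking table sorted by output %CV at the reference input.

    Returns the table (with the slope column — the %CV-vs-slope scatter
    data) and the Pearson correlation between %CV and slope across models,
    which the motif comparison predicts to be negative: better noise
    reducers tend to be better transducers.
    """
    schemes = {s.scheme for s in summaries}
    if len(schemes) > 1:
        raise ValueError(f"mixed schemes in ranking: {sorted(schemes)}")
    df = pd.DataFrame(
        {
            "model_id": [s.model_id for s in summaries],
            "family": [s.family for s in summaries],
            "scheme": [s.scheme for s in summaries],
            "cv_percent": [s.cv_at_reference for s in summaries],
            "slope": [s.slope for s in summaries],
        }
    ).sort_values("cv_percent", kind="mergesort", ignore_index=True)
    corr = float(np.corrcoef(df.cv_percent, df.slope)[0, 1])
    return df, corr


def layer_cv_profile(result: LNAResult | EnsembleStats, at_input: float = REFERENCE_INPUT):
    """%CV of the input and every active form at one plateau, by layer.

    Good noise reducers attenuate monotonically down the cascade (S -> X ->
    Y -> Z); in poor reducers the minimum often sits at the middle layer.
    """
    frame = plateau_frame(result)
    ref = frame[(frame.level == at_input) & (frame.phase == "up")]
    if ref.empty:
        raise ValueError(f"no plateau at input {at_input}")
    order = {"S": 0, "X": 1, "Y": 2, "Z": 3}
    rows = [
        (r.species, cv_percent(r.mean, r.var))
        for r in ref.itertuples()
        if r.species == "S" or r.species.endswith("_a")
    ]
    rows.sort(key=lambda t: (order[t[0][0]], t[0]))
    return rows


def saturation_check(
    frame: pd.DataFrame, total: float, band: tuple[float, float] = (0.02, 0.98)
) -> pd.DataFrame:
    """Audit that no pool saturates or empties across the staircase.

    Returns the violating (model, species, level) rows — mean active
    fraction outside ``band`` — empty if the model passes everywhere.
    """
    if frame.empty:
        raise ValueError("empty result frame")
    act = frame[frame.species.str.endswith("_a")].copy()
    act["active_fraction"] = act["mean"] / total
    bad = act[(act.active_fraction <= band[0]) | (act.active_fraction >= band[1])]
    return bad[["model_id", "species", "level", "phase", "active_fraction"]].reset_index(
        drop=True
    )
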