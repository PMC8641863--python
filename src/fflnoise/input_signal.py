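"""The noisy input signal S: calibrated super-Poissonian kinetics and the
five-step staircase protocol.

The input species is produced basally (rate ``a``), autocatalytically
(``b*S``, the linear stand-in for a bimolecular production term) and decays
in first order (``d*S``).  For ``b < d`` the copy number is stationary with

    mean = a / (d - b),        Fano factor = d / (d - b),

both exact, because the system is linear.  The Fano factor is independent of
``a``, so stepping the basal rate through a staircase of plateaus changes the
mean while keeping the relative noise mechanism fixed — the driver used for
every motif model: five plateau levels up, then mirrored back down.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

DEFAULT_FANO = 1.83
DEFAULT_LEVELS = (2.0, 3.0, 4.0, 5.0, 6.0)
DEFAULT_BASELINE = 1.0
DEFAULT_DURATION = 20.0

#: Input-noise scales explored when testing robustness of the output noise
#: to the input mechanism (reduced / default / increased Fano factor).
NOISE_SCALES = {"reduced": 1.2, "default": DEFAULT_FANO, "increased": 3.0}


@dataclass(frozen=True)
class InputMechanism:
    """Birth/autocatalysis/decay rates of the input species.

    ``basal_rate`` is the plateau-dependent knob; ``autocatalytic_rate`` and
    ``decay_rate`` set the Fano factor and are held fixed across plateaus.
    """

    basal_rate: float
    autocatalytic_rate: float
    decay_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.autocatalytic_rate < self.decay_rate:
            raise ValueError("need 0 <= autocatalytic rate < decay rate")
        if self.basal_rate < 0:
            raise ValueError("basal rate must be nonnegative")

    @property
    def stationary_mean(self) -> float:
        return self.basal_rate / (self.decay_rate - self.autocatalytic_rate)

    @property
    def stationary_fano(self) -> float:
        return self.decay_rate / (self.decay_rate - self.autocatalytic_rate)

    def at_mean(self, mean: float) -> "InputMechanism":
        """Same noise mechanism, basal rate retuned to a new plateau mean."""
        return replace(
            self, basal_rate=mean * (self.decay_rate - self.autocatalytic_rate)
        )


def calibrate_input(
    target_fano: float = DEFAULT_FANO, mean: float = DEFAULT_BASELINE
) -> InputMechanism:
    """Choose (a, b, d) hitting a target stationary Fano factor and mean.

    The relaxation rate is normalized to ``d - b = 1``, so ``a = mean``,
    ``d = target_fano`` and ``b = target_fano - 1``.  Super-Poissonian input
    requires ``target_fano > 1``; the Poisson limit is approached as
    ``target_fano -> 1`` (``b -> 0``).
    """
    if target_fano <= 1.0:
        raise ValueError("the autocatalytic mechanism is strictly super-Poissonian")
    if mean <= 0:
        raise ValueError("mean must be positive")
    return InputMechanism(
        basal_rate=mean, autocatalytic_rate=target_fano - 1.0, decay_rate=target_fano
    )


def set_input_noise(scale: str = "default", mean: float = DEFAULT_BASELINE) -> InputMechanism:
    """Input mechanism at a named noise scale with unchanged mean."""
    if scale not in NOISE_SCALES:
        raise ValueError(f"unknown noise scale {scale!r}; choose from {sorted(NOISE_SCALES)}")
    return calibrate_input(NOISE_SCALES[scale], mean)


@dataclass(frozen=True)
class InputProtocol:
    """Piecewise-constant staircase of plateau means for the input.

    ``plateaus`` lists the mean level of every segment in order (baseline,
    five ascending levels, mirrored descent, final baseline); every segment
    lasts ``plateau_duration``.
    """

    plateaus: tuple[float, ...]
    plateau_duration: float

    @property
    def total_time(self) -> float:
        return self.plateau_duration * len(self.plateaus)

    def segments(self) -> list[tuple[float, float, float]]:
        """(t_start, t_end, plateau mean) for every segment."""
        out = []
        for i, level in enumerate(self.plateaus):
            out.append((i * self.plateau_duration, (i + 1) * self.plateau_duration, level))
        return out

    def level_at(self, t: float) -> float:
        idx = min(int(t / self.plateau_duration), len(self.plateaus) - 1)
        return self.plateaus[idx]


def staircase(
    levels: Sequence[float] = DEFAULT_LEVELS,
    duration: float = DEFAULT_DURATION,
    baseline: float = DEFAULT_BASELINE,
) -> InputProtocol:
    """Five-step up-then-down staircase: baseline, ascent, mirrored descent.

    The default plateau sequence is [1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1].
    """
    if len(levels) != 5:
        raise ValueError("the staircase protocol uses exactly five plateau levels")
    lv = [float(x) for x in levels]
    if any(b <= a for a, b in zip(lv, lv[1:])):
        raise ValueError("plateau levels must be strictly increasing")
    if duration <= 0:
        raise ValueError("plateau duration must be positive")
    plateaus = (float(baseline), *lv, *lv[-2::-1], float(baseline))
    return InputProtocol(plateaus=plateaus, plateau_duration=float(duration))
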