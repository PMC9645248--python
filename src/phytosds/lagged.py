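"""Time-lagged division/loss dynamics: blooms and size succession.

In a tightly coupled plankton food web the loss rate on a phytoplankton
class tracks its division rate with a delay ``j`` (days), so the
realized net rate of biomass change reduces to

    r(t) = (1/P)·dP/dt = mu(t) − mu(t − j).

Biomass therefore accumulates only while division rates accelerate, and
declines while they decelerate.  The lag grows with cell size (predators
of large cells have longer life cycles and handling times), so a
sustained acceleration favours larger classes and tilts the
size-distribution slope above the stable −4 attractor — the essence of
bloom succession from small to large species.

Division-rate trajectories are prescribed per class as uniformly
sampled series, clipped into each class's [mu_min, mu_max] band; mu_max
is a hard cap that ends a class's acceleration phase.  Before the series
starts the system is assumed at steady state: mu(t − j) for t − j below
the first sample evaluates to the initial value.  Integration advances
ln P with the trapezoidal rule, which preserves positivity and makes
the j = 0 case exactly biomass-conserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import IntegrationError
from .size_grid import SizeBinning

__all__ = [
    "DivisionRateSeries",
    "LaggedClass",
    "BloomScenario",
    "BloomTrajectory",
    "lagged_rate",
    "simulate_bloom",
    "simulate_scenario",
    "succession_order",
    "sds_timeseries",
    "default_lag",
]

#: Default lag model j(d) = j0·(d/1 µm)^theta: lags grow with cell size.
DEFAULT_LAG_J0_DAYS = 1.0
DEFAULT_LAG_EXPONENT = 0.5


def default_lag(diameter_um: float, j0: float = DEFAULT_LAG_J0_DAYS,
                theta: float = DEFAULT_LAG_EXPONENT) -> float:
    """Predator–prey lag (d) at a given cell diameter, j0·d^theta."""
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    return j0 * diameter_um**theta


@dataclass
class DivisionRateSeries:
    """Uniformly sampled division-rate trajectory mu(t) (d⁻¹)."""

    times: np.ndarray
    mu_values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mu_values = np.asarray(self.mu_values, dtype=float)
        if self.times.size < 2 or self.times.shape != self.mu_values.shape:
            raise ValueError("need matching time and mu arrays with >= 2 samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0) or np.max(np.abs(steps - steps[0])) > 1e-9 * steps[0]:
            raise ValueError("times must be uniformly spaced and increasing")
        if np.any(self.mu_values < 0):
            raise ValueError("division rates must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __call__(self, t):
        """mu at time(s) t, linearly interpolated; clamped to mu(t0) before start."""
        t = np.asarray(t, dtype=float)
        if np.any(t > self.times[-1] + 1e-9):
            raise ValueError("requested time beyond the end of the series")
        out = np.interp(t, self.times, self.mu_values)
        return float(out) if out.ndim == 0 else out


def lagged_rate(series: DivisionRateSeries, j: float, t) -> float | np.ndarray:
    """Net biomass rate r(t) = mu(t) − mu(t − j) (d⁻¹).

    Lag history before the series start uses the initial division rate
    (steady-state pre-history).
    """
    if j < 0:
        raise ValueError("lag j must be >= 0")
    return series(t) - series(np.asarray(t, dtype=float) - j)


@dataclass
class LaggedClass:
    """One phytoplankton size class in a bloom scenario.

    acceleration (d⁻²) is the scenario ramp rate used by generators; it
    does not enter the integration directly (the mu series does).
    """

    label: str
    diameter: float  # µm
    j: float  # predator-prey lag, d
    mu_min: float = 0.0  # d⁻¹, pre-bloom floor
    mu_max: float = np.inf  # d⁻¹, ceiling ending the acceleration phase
    acceleration: float = 0.0  # d⁻²

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.j < 0:
            raise ValueError("lag j must be >= 0")
        if not (0 <= self.mu_min <= self.mu_max):
            raise ValueError("require 0 <= mu_min <= mu_max")


@dataclass
class BloomScenario:
    """A runnable scenario: classes, their mu(t) series, and initial biomass."""

    classes: list[LaggedClass]
    series: list[DivisionRateSeries]
    P0: np.ndarray
    dt: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        self.P0 = np.asarray(self.P0, dtype=float)
        if not (len(self.classes) == len(self.series) == self.P0.size):
            raise ValueError("classes, series, and P0 must align")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "dt": self.dt,
            "classes": [
                {
                    "label": c.label,
                    "diameter_um": c.diameter,
                    "lag_days": c.j,
                    "mu_min": c.mu_min,
                    "mu_max": None if np.isinf(c.mu_max) else c.mu_max,
                    "acceleration": c.acceleration,
                    "P0": float(p0),
                    "mu_breakpoints": [
                        [float(t), float(m)] for t, m in zip(s.times, s.mu_values)
                    ],
                }
                for c, s, p0 in zip(self.classes, self.series, self.P0)
            ],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "BloomScenario":
        classes, series, P0 = [], [], []
        for c in obj["classes"]:
            classes.append(
                LaggedClass(
                    label=c["label"],
                    diameter=c["diameter_um"],
                    j=c["lag_days"],
                    mu_min=c.get("mu_min", 0.0),
                    mu_max=np.inf if c.get("mu_max") is None else c["mu_max"],
                    acceleration=c.get("acceleration", 0.0),
                )
            )
            bp = np.asarray(c["mu_breakpoints"], dtype=float)
            series.append(DivisionRateSeries(times=bp[:, 0], mu_values=bp[:, 1]))
            P0.append(c["P0"])
        return cls(
            classes=classes,
            series=series,
            P0=np.asarray(P0),
            dt=obj.get("dt", 0.05),
            label=obj.get("label", ""),
        )


@dataclass
class BloomTrajectory:
    """Simulated bloom: per-class biomass P(t) and realized rate r(t)."""

    times: np.ndarray
    P: np.ndarray  # (n_times, n_classes)
    r: np.ndarray  # (n_times, n_classes), d⁻¹
    classes: list[LaggedClass] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.classes]

    @property
    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.classes])


def simulate_bloom(
    classes: Sequence[LaggedClass],
    series: Sequence[DivisionRateSeries],
    P0: np.ndarray,
    dt: float = 0.05,
) -> BloomTrajectory:
    """Advance each class under r(t) = mu_eff(t) − mu_eff(t − j).

    mu_eff clips the class's series into [mu_min, mu_max].  ln P is
    stepped with the trapezoidal rule; a step with |r|·dt > 0.5 is
    rejected as unresolved.
    """
    P0 = np.asarray(P0, dtype=float)
    if np.any(P0 <= 0):
        raise ValueError("initial biomass must be strictly positive")
    if len(classes) != len(series) or P0.size != len(classes):
        raise ValueError("classes, series, and P0 must align")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t0 = series[0].times[0]
    t_end = min(s.times[-1] for s in series)
    times = np.arange(t0, t_end + 0.5 * dt, dt)
    n_t, n_c = times.size, len(classes)
    r = np.empty((n_t, n_c))
    for k, (cls, s) in enumerate(zip(classes, series)):
        mu_now = np.clip(s(times), cls.mu_min, cls.mu_max)
        mu_lag = np.clip(s(np.maximum(times - cls.j, t0)), cls.mu_min, cls.mu_max)
        r[:, k] = mu_now - mu_lag
    if np.max(np.abs(r)) * dt > 0.5:
        raise IntegrationError(
            f"time step too coarse: max |r|*dt = {np.max(np.abs(r)) * dt:.3f} > 0.5"
        )
    lnP = np.empty((n_t, n_c))
    lnP[0] = np.log(P0)
    increments = 0.5 * (r[:-1] + r[1:]) * dt
    lnP[1:] = lnP[0] + np.cumsum(increments, axis=0)
    return BloomTrajectory(times=times, P=np.exp(lnP), r=r, classes=list(classes))


def simulate_scenario(scenario: BloomScenario) -> BloomTrajectory:
    """Run :func:`simulate_bloom` on a :class:`BloomScenario`."""
    return simulate_bloom(scenario.classes, scenario.series, scenario.P0, scenario.dt)


def succession_order(trajectory: BloomTrajectory) -> list[tuple[str, float | None]]:
    """Classes ordered by time of peak biomass.

    A class whose biomass is still rising at the end of the horizon (its
    maximum sits on the final sample) has no resolved peak and is
    reported with time ``None``, sorted last.  Ties break by diameter,
    ascending.
    """
    if len(trajectory.classes) < 1:
        raise ValueError("trajectory has no classes")
    entries = []
    for k, cls in enumerate(trajectory.classes):
        i_max = int(np.argmax(trajectory.P[:, k]))
        if i_max == trajectory.times.size - 1 and trajectory.P[-1, k] > trajectory.P[0, k]:
            entries.append((cls.label, None, cls.diameter))
        else:
            entries.append((cls.label, float(trajectory.times[i_max]), cls.diameter))
    entries.sort(key=lambda e: (e[1] is None, e[1] if e[1] is not None else 0.0, e[2]))
    return [(label, t) for label, t, _ in entries]


def sds_timeseries(
    trajectory: BloomTrajectory,
    binning: SizeBinning,
    carbon_density: float = 1.0,
) -> np.ndarray:
    """Instantaneous size-distribution slope at every time step.

    Each class is mapped to the bin containing its diameter; classes
    must occupy at least 3 distinct bins.  At each step the per-bin
    biomass is converted to abundance density and the slope refit, so a
    lag-driven shift toward large classes appears as a shallowing SDS.
    """
    idx = np.array([binning.bin_index(d) for d in trajectory.diameters])
    if np.unique(idx).size < 3:
        raise ValueError("need classes in >= 3 distinct bins to fit an SDS")
    if np.unique(idx).size != idx.size:
        raise ValueError("each class must map to its own bin")
    # biomass -> density in the occupied bins only; vectorized over time
    from .size_grid import cell_biomass

    centers = binning.centers[idx]
    widths = binning.widths[idx]
    density = trajectory.P / (cell_biomass(centers, carbon_density) * widths)
    x = np.log10(centers)
    x_c = x - x.mean()
    slopes = (np.log10(density) @ x_c) / (x_c @ x_c)
    return slopes
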