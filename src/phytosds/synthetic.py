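"""Synthetic field-style size spectra and bloom scenario fixtures.

Observed phytoplankton size spectra are, to first order, power laws in
cell diameter with multiplicative lognormal scatter spanning decades of
abundance.  The generators here emulate exactly that structure — a
power-law abundance density over ~0.5–100 µm at slopes in the observed
−3.4 to −4.8 range, with configurable scatter in dex — so every stage of
the analysis can be exercised without any field data.  What they do not
emulate: instrument-specific sizing biases, patchiness, or deviations
from a single power law.

Scenario fixtures encode three canonical bloom environments as
division-rate ramps shared by a small / mid / large class triplet whose
lags and accelerations are size-ordered:

* ``deep_mixing`` — a deep winter-mixing regime: low pre-bloom division
  rates and a long improvement window, allowing the full small-to-large
  succession with large cells dominating peak biomass;
* ``shallow_mixing`` — elevated pre-bloom rates and a short window, so
  the climax is reached before large classes can accumulate;
* ``si_limited`` — as deep mixing but the large (diatom-like) class's
  ceiling is cut, truncating the succession.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lagged import (
    BloomScenario,
    DivisionRateSeries,
    LaggedClass,
    default_lag,
)
from .size_grid import (
    DEFAULT_D_MAX,
    DEFAULT_D_MIN,
    DEFAULT_N_BINS,
    SizeBinning,
    make_proportional_bins,
)
from .spectrum import (
    REF_CELLS_PER_ML,
    REF_DIAMETER_UM,
    SizeSpectrum,
    normalize_to_reference,
)

__all__ = [
    "SpectrumGeneratorConfig",
    "generate_spectrum",
    "generate_stable_vs_bloom_pair",
    "generate_scenario_fixture",
    "SCENARIO_KINDS",
    "DEFAULT_NOISE_SD_DEX",
]

#: Default lognormal scatter of synthetic spectra, in dex (decades).
DEFAULT_NOISE_SD_DEX = 0.1

#: Target slopes of the stable/bloom pair.
STABLE_SLOPE = -4.0
BLOOM_SLOPE = -3.4


def _default_binning() -> SizeBinning:
    return make_proportional_bins(DEFAULT_D_MIN, DEFAULT_D_MAX, DEFAULT_N_BINS)


@dataclass
class SpectrumGeneratorConfig:
    """Recipe for one synthetic spectrum.

    ``ref_value`` anchors the noise-free envelope: the bin containing
    ``REF_DIAMETER_UM`` holds that many cells·ml⁻¹ before scatter is
    applied (so the anchor is median-, not mean-, exact under noise).
    """

    slope: float
    ref_value: float = REF_CELLS_PER_ML
    noise_sd_dex: float = DEFAULT_NOISE_SD_DEX
    binning: SizeBinning = field(default_factory=_default_binning)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_dex < 0:
            raise ValueError("noise_sd_dex must be >= 0")
        if self.ref_value <= 0:
            raise ValueError("ref_value must be > 0")


def generate_spectrum(config: SpectrumGeneratorConfig) -> SizeSpectrum:
    """Draw one power-law spectrum with multiplicative lognormal noise.

    density_i = A·center_i^slope·10^ε_i with ε_i ~ N(0, noise_sd_dex²),
    A chosen so the reference bin matches ``config.ref_value``.
    Deterministic for a fixed seed.
    """
    binning = config.binning
    rng = np.random.default_rng(config.seed)
    idx = binning.bin_index(REF_DIAMETER_UM) if binning.edges[0] <= REF_DIAMETER_UM else 0
    centers = binning.centers
    amplitude = config.ref_value / (centers[idx] ** config.slope * binning.widths[idx])
    eps = rng.normal(0.0, config.noise_sd_dex, size=binning.n_bins)
    density = amplitude * centers**config.slope * 10.0**eps
    return SizeSpectrum(binning=binning, density=density,
                        label=f"synthetic slope={config.slope}")


def generate_stable_vs_bloom_pair(
    seed: int,
    binning: SizeBinning | None = None,
    noise_sd_dex: float = DEFAULT_NOISE_SD_DEX,
) -> tuple[SizeSpectrum, SizeSpectrum]:
    """A stable (−4) and a bloom-tilted (−3.4) spectrum, jointly seeded.

    Both are renormalized after the noise draw so their reference bins
    hold exactly 10⁴ cells·ml⁻¹; the bloom spectrum therefore exceeds
    the stable one only at large diameters.
    """
    binning = binning or _default_binning()
    child_seeds = np.random.SeedSequence(seed).generate_state(2)
    out = []
    for slope, child in zip((STABLE_SLOPE, BLOOM_SLOPE), child_seeds):
        spec = generate_spectrum(
            SpectrumGeneratorConfig(
                slope=slope, binning=binning, noise_sd_dex=noise_sd_dex, seed=int(child)
            )
        )
        spec = normalize_to_reference(spec)
        spec.label = "stable" if slope == STABLE_SLOPE else "bloom"
        out.append(spec)
    return out[0], out[1]


# --- scenario fixtures -------------------------------------------------

SCENARIO_KINDS = ("deep_mixing", "shallow_mixing", "si_limited")

# Small / mid / large class triplet: diameters (µm), ramp accelerations
# (d⁻², slower for larger cells), and division-rate ceilings (d⁻¹,
# higher for the large bloom-formers).
_CLASS_DIAMETERS = (2.0, 10.0, 50.0)
_CLASS_ACCEL = (0.5, 0.25, 0.1)
_CLASS_MU_MAX = (1.2, 1.6, 2.0)
_CLASS_LABELS = ("small", "mid", "large")

# Environment settings: pre-bloom division-rate floor (d⁻¹), improvement
# window (d), and simulation horizon (d).
_ENVIRONMENTS = {
    "deep_mixing": {"mu_min": 0.1, "window": 40.0, "horizon": 90.0},
    "shallow_mixing": {"mu_min": 0.5, "window": 4.0, "horizon": 40.0},
    "si_limited": {"mu_min": 0.1, "window": 40.0, "horizon": 90.0},
}
_SI_LIMITED_LARGE_MU_MAX = 0.8
_SERIES_STEP = 0.25  # d, sampling of the mu(t) breakpoint series


def generate_scenario_fixture(kind: str, seed: int = 0) -> BloomScenario:
    """Build a runnable three-class bloom scenario of the given kind.

    Each class's division rate ramps from the environment's floor at the
    class's own acceleration, is clipped at the class ceiling, and
    descends symmetrically after the improvement window closes.
    Deterministic given (kind, seed); the seed is recorded in the label
    so derived outputs stay traceable.
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
    env = _ENVIRONMENTS[kind]
    mu_min, window, horizon = env["mu_min"], env["window"], env["horizon"]
    mu_max_by_class = list(_CLASS_MU_MAX)
    if kind == "si_limited":
        mu_max_by_class[-1] = _SI_LIMITED_LARGE_MU_MAX

    times = np.arange(0.0, horizon + 0.5 * _SERIES_STEP, _SERIES_STEP)
    tri = np.maximum(0.0, np.minimum(times, 2.0 * window - times))
    classes, series = [], []
    for label, d, a, mu_max in zip(
        _CLASS_LABELS, _CLASS_DIAMETERS, _CLASS_ACCEL, mu_max_by_class
    ):
        mu_t = np.clip(mu_min + a * tri, mu_min, mu_max)
        classes.append(
            LaggedClass(
                label=label,
                diameter=d,
                j=default_lag(d),
                mu_min=mu_min,
                mu_max=mu_max,
                acceleration=a,
            )
        )
        series.append(DivisionRateSeries(times=times.copy(), mu_values=mu_t))
    return BloomScenario(
        classes=classes,
        series=series,
        P0=np.ones(len(classes)),
        dt=0.05,
        label=f"{kind} (seed={seed})",
    )
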