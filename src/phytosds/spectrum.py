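"""Abundance size spectra and the size-distribution slope (SDS).

The SDS is the ordinary least-squares slope of log10 cell-number
concentration per unit length (cells·ml⁻¹·µm⁻¹) against log10 cell
diameter (µm).  Stable, nutrient-poor waters show a remarkably conserved
SDS near −4; the equilibrium model reproduces it exactly when each size
bin holds equal biomass on proportional (geometric) bins, because
abundance density then scales as d⁻³ (biomass per cell) times d⁻¹ (bin
width ∝ diameter).

All logarithms are base 10 and the regression is unweighted; for exact
power-law spectra both choices are immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, NormalizationError
from .size_grid import SizeBinning, cell_biomass

__all__ = [
    "SizeSpectrum",
    "SDSFit",
    "BiomassSpectrum",
    "biomass_to_spectrum",
    "fit_sds",
    "normalize_to_reference",
    "wholesale_tilt",
    "to_biomass_spectrum",
    "UNIFORM_LIMIT_SDS",
    "PROPORTIONAL_SDS",
]

logger = logging.getLogger(__name__)

#: SDS of equal biomass per uniform-width bin (wholesale-grazer limit).
UNIFORM_LIMIT_SDS = -3.0
#: SDS of equal biomass per proportional bin (the fundamental slope).
PROPORTIONAL_SDS = -4.0

#: Defaults of the reference-bin normalization: 10^4 cells ml⁻¹ in the
#: bin containing 0.5 µm.
REF_DIAMETER_UM = 0.5
REF_CELLS_PER_ML = 1e4


@dataclass
class SizeSpectrum:
    """Abundance density (cells·ml⁻¹·µm⁻¹) per bin of a :class:`SizeBinning`."""

    binning: SizeBinning
    density: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.binning.n_bins,):
            raise ValueError("need exactly one density value per bin")
        if np.any(self.density < 0):
            raise ValueError("abundance density must be non-negative")

    @property
    def concentrations(self) -> np.ndarray:
        """Cell concentration per bin (cells·ml⁻¹): density × width."""
        return self.density * self.binning.widths


@dataclass(frozen=True)
class SDSFit:
    """OLS fit of log10(density) on log10(diameter)."""

    slope: float
    intercept: float
    stderr: float
    r_squared: float
    n_bins_used: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "stderr": self.stderr,
            "r_squared": self.r_squared,
            "n_bins_used": self.n_bins_used,
        }


@dataclass
class BiomassSpectrum:
    """Biomass (units·ml⁻¹) integrated over logarithmically spaced volume bins."""

    volume_edges: np.ndarray  # µm³, strictly increasing, log-spaced
    biomass: np.ndarray

    def __post_init__(self) -> None:
        self.volume_edges = np.asarray(self.volume_edges, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if np.any(np.diff(self.volume_edges) <= 0):
            raise ValueError("volume edges must be strictly increasing")
        if self.biomass.size != self.volume_edges.size - 1:
            raise ValueError("need one biomass value per volume bin")
        if np.any(self.biomass < 0):
            raise ValueError("biomass must be non-negative")

    @property
    def total(self) -> float:
        return float(self.biomass.sum())


def biomass_to_spectrum(
    P: np.ndarray,
    binning: SizeBinning,
    carbon_density: float = 1.0,
    label: str = "",
) -> SizeSpectrum:
    """Convert per-bin biomass to abundance density.

    density_i = (P_i / biomass-per-cell(center_i)) / width_i, i.e. cell
    counts from biomass over spherical cells, spread over the bin's
    diameter span.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (binning.n_bins,):
        raise ValueError("need one biomass value per bin")
    cells_per_ml = P / cell_biomass(binning.centers, carbon_density)
    return SizeSpectrum(binning=binning, density=cells_per_ml / binning.widths, label=label)


def fit_sds(spectrum: SizeSpectrum) -> SDSFit:
    """Fit the size-distribution slope by OLS on log10 axes.

    Bins with zero density are excluded (their logarithm is undefined)
    with a logged warning; at least 3 positive bins are required.
    """
    positive = spectrum.density > 0
    n_used = int(positive.sum())
    if n_used < spectrum.binning.n_bins:
        logger.warning(
            "fit_sds: dropping %d zero-density bin(s) out of %d",
            spectrum.binning.n_bins - n_used,
            spectrum.binning.n_bins,
        )
    if n_used < 3:
        raise InsufficientDataError(
            f"need >= 3 bins with positive density, got {n_used}"
        )
    x = np.log10(spectrum.binning.centers[positive])
    y = np.log10(spectrum.density[positive])
    res = stats.linregress(x, y)
    return SDSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_bins_used=n_used,
    )


def normalize_to_reference(
    spectrum: SizeSpectrum,
    ref_diameter: float = REF_DIAMETER_UM,
    ref_value: float = REF_CELLS_PER_ML,
) -> SizeSpectrum:
    """Rescale so the bin containing ``ref_diameter`` holds ``ref_value`` cells·ml⁻¹.

    One scalar multiplies the whole spectrum, so the fitted slope is
    unchanged.  Bin membership is half-open [lo, hi).
    """
    if ref_value <= 0:
        raise ValueError("ref_value must be > 0")
    try:
        idx = spectrum.binning.bin_index(ref_diameter)
    except ValueError as exc:
        raise NormalizationError(str(exc)) from exc
    conc = spectrum.density[idx] * spectrum.binning.widths[idx]
    if conc <= 0:
        raise NormalizationError(
            f"reference bin {idx} (containing {ref_diameter} µm) has zero density"
        )
    scale = ref_value / conc
    return SizeSpectrum(
        binning=spectrum.binning, density=spectrum.density * scale, label=spectrum.label
    )


def wholesale_tilt(
    base_sds: float,
    wholesale_fraction: float,
    uniform_limit: float = UNIFORM_LIMIT_SDS,
) -> float:
    """SDS after adding grazers that feed wholesale across the size domain.

    Wholesale feeders (e.g. mucous-web tunicates) take prey irrespective
    of size, pulling the community toward equal biomass per uniform bin
    (SDS −3).  The tilt is modelled as a linear interpolation in their
    fraction of total loss: f = 0 leaves the proportional-grazing slope,
    f = 1 reaches the uniform limit.
    """
    if not 0 <= wholesale_fraction <= 1:
        raise ValueError(f"wholesale_fraction must lie in [0, 1], got {wholesale_fraction}")
    return base_sds + wholesale_fraction * (uniform_limit - base_sds)


def to_biomass_spectrum(
    spectrum: SizeSpectrum,
    carbon_density: float = 1.0,
    n_log_bins: int = 10,
) -> BiomassSpectrum:
    """Re-express an abundance spectrum as biomass per log-volume bin.

    Cell diameter is converted to spherical volume and abundance to
    biomass at constant density; each diameter bin's biomass
    (density·width·biomass-per-cell) is assigned to the logarithmically
    spaced volume bin containing its center volume, so total biomass is
    conserved exactly.
    """
    from .size_grid import cell_volume

    if n_log_bins < 2:
        raise ValueError("need n_log_bins >= 2")
    positive = spectrum.density > 0
    if not np.any(positive):
        raise InsufficientDataError("spectrum has no positive-density bins")
    v_edges = np.geomspace(
        cell_volume(spectrum.binning.edges[0]),
        cell_volume(spectrum.binning.edges[-1]),
        n_log_bins + 1,
    )
    v_centers = cell_volume(spectrum.binning.centers)
    per_bin_biomass = spectrum.concentrations * cell_biomass(
        spectrum.binning.centers, carbon_density
    )
    idx = np.clip(np.searchsorted(v_edges, v_centers, side="right") - 1, 0, n_log_bins - 1)
    biomass = np.zeros(n_log_bins)
    np.add.at(biomass, idx, per_bin_biomass)
    return BiomassSpectrum(volume_edges=v_edges, biomass=biomass)
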