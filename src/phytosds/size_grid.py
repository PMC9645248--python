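"""Diameter grids and per-cell size conversions.

A size spectrum lives on an ordered partition of the cell-diameter axis.
Two partitions matter for phytoplankton size structuring:

* ``uniform`` bins — equal absolute diameter span per bin, the coordinate
  system in which equal biomass per bin maps to an abundance-density slope
  of −3;
* ``proportional`` bins — geometric spacing, so each bin's diameter span
  scales with its center.  This emulates herbivores whose absolute prey
  size range is proportional to their mean prey size, and is the partition
  in which equal biomass per bin yields the observed −4 slope.

Bin centers are geometric means of the edges in both modes, which makes
power laws exactly linear on log10 axes regardless of bin placement.
Cells are treated as spheres of constant carbon density, so biomass per
cell is proportional to diameter cubed; every headline slope result is
invariant to the density constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SizeBinning",
    "make_uniform_bins",
    "make_proportional_bins",
    "cell_volume",
    "cell_biomass",
    "DEFAULT_D_MIN",
    "DEFAULT_D_MAX",
    "DEFAULT_N_BINS",
]

#: Default diameter range (µm) spanning pico- to micro-phytoplankton.
DEFAULT_D_MIN = 0.5
DEFAULT_D_MAX = 100.0
#: Default number of proportional bins over the default range.
DEFAULT_N_BINS = 24

_REL_TOL = 1e-9


@dataclass(frozen=True)
class SizeBinning:
    """An ordered partition of the diameter axis into contiguous bins.

    Parameters
    ----------
    edges
        Strictly increasing bin edges in µm; ``n_bins + 1`` values.
    mode
        ``"uniform"`` (equal absolute widths) or ``"proportional"``
        (constant edge ratio).  Validated against the edges on
        construction.
    """

    edges: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 3:
            raise ValueError("edges must be a 1-D array with at least 3 values (2 bins)")
        if edges[0] <= 0:
            raise ValueError("diameters must be strictly positive")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("edges must be strictly increasing")
        if self.mode == "uniform":
            if np.max(np.abs(widths - widths[0])) > _REL_TOL * widths[0]:
                raise ValueError("uniform mode requires equal bin widths")
        elif self.mode == "proportional":
            ratios = edges[1:] / edges[:-1]
            if np.max(np.abs(ratios - ratios[0])) > _REL_TOL * ratios[0]:
                raise ValueError("proportional mode requires a constant edge ratio")
        else:
            raise ValueError(f"unknown binning mode: {self.mode!r}")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        """Geometric-mean bin centers, √(lo·hi)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        """Absolute diameter span per bin (µm)."""
        return np.diff(self.edges)

    def bin_index(self, d: float) -> int:
        """Index of the bin containing diameter ``d`` (half-open [lo, hi))."""
        edges = self.edges
        if d < edges[0] or d >= edges[-1]:
            raise ValueError(f"diameter {d} µm outside binning range [{edges[0]}, {edges[-1]})")
        return int(np.searchsorted(edges, d, side="right") - 1)

    def to_json(self) -> str:
        return json.dumps({"edges": self.edges.tolist(), "mode": self.mode})

    @classmethod
    def from_json(cls, text: str) -> "SizeBinning":
        obj = json.loads(text)
        return cls(edges=np.asarray(obj["edges"], dtype=float), mode=obj["mode"])


def _check_range(d_min: float, d_max: float, n_bins: int) -> None:
    if not (0 < d_min < d_max):
        raise ValueError(f"require 0 < d_min < d_max, got ({d_min}, {d_max})")
    if n_bins < 2:
        raise ValueError(f"require n_bins >= 2, got {n_bins}")


def make_uniform_bins(d_min: float, d_max: float, n_bins: int) -> SizeBinning:
    """Partition [d_min, d_max] into ``n_bins`` bins of equal absolute width."""
    _check_range(d_min, d_max, n_bins)
    return SizeBinning(edges=np.linspace(d_min, d_max, n_bins + 1), mode="uniform")


def make_proportional_bins(d_min: float, d_max: float, n_bins: int) -> SizeBinning:
    """Partition [d_min, d_max] into ``n_bins`` geometrically spaced bins.

    The edge ratio is ``(d_max/d_min)**(1/n_bins)``; each bin's width is
    the same fixed fraction of its (geometric-mean) center, the hallmark
    of proportional grazing size ranges.
    """
    _check_range(d_min, d_max, n_bins)
    return SizeBinning(edges=np.geomspace(d_min, d_max, n_bins + 1), mode="proportional")


def cell_volume(d):
    """Volume (µm³) of a spherical cell of diameter ``d`` µm: (π/6)·d³."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("cell diameter must be strictly positive")
    out = (np.pi / 6.0) * d**3
    return float(out) if out.ndim == 0 else out


def cell_biomass(d, carbon_density: float = 1.0):
    """Biomass per cell at constant carbon density (biomass units per cell).

    ``carbon_density`` is mass per µm³; the default of 1 puts biomass in
    arbitrary units, which is sufficient because all slope results are
    invariant to the constant.
    """
    if carbon_density <= 0:
        raise ValueError("carbon_density must be strictly positive")
    return carbon_density * cell_volume(d)
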