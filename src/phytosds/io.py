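"""CSV/JSON/YAML interchange for spectra, fits, and scenarios.

Every CSV written by the package carries '#'-prefixed comment headers
recording the package version, a hash of the generating configuration,
and the seed (when randomness was involved), so outputs are
self-describing and byte-reproducible under a fixed seed.

Spectrum CSV schema (UTF-8, header row required):
    d_lo_um, d_hi_um, d_center_um, n_per_ml_per_um
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lagged import BloomScenario, BloomTrajectory
from .size_grid import SizeBinning
from .spectrum import SDSFit, SizeSpectrum

__all__ = [
    "config_hash",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_sds_json",
    "write_scenario_yaml",
    "read_scenario_yaml",
    "write_trajectory_csv",
]

SPECTRUM_COLUMNS = ["d_lo_um", "d_hi_um", "d_center_um", "n_per_ml_per_um"]


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def _header(meta: Mapping[str, Any]) -> str:
    lines = [f"# phytosds {__version__}"]
    for key, value in meta.items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_spectrum_csv(
    spectrum: SizeSpectrum,
    path: str | Path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> None:
    binning = spectrum.binning
    df = pd.DataFrame(
        {
            "d_lo_um": binning.edges[:-1],
            "d_hi_um": binning.edges[1:],
            "d_center_um": binning.centers,
            "n_per_ml_per_um": spectrum.density,
        }
    )
    meta: dict[str, Any] = {"mode": binning.mode}
    if spectrum.label:
        meta["label"] = spectrum.label
    if config is not None:
        meta["config"] = config_hash(config)
    if seed is not None:
        meta["seed"] = seed
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_spectrum_csv(path: str | Path) -> SizeSpectrum:
    mode, label = None, ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("mode:"):
                mode = body.split(":", 1)[1].strip()
            elif body.startswith("label:"):
                label = body.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(SPECTRUM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectrum CSV missing columns: {sorted(missing)}")
    edges = np.append(df["d_lo_um"].to_numpy(), df["d_hi_um"].iloc[-1])
    if not np.allclose(edges[1:-1], df["d_hi_um"].to_numpy()[:-1], rtol=1e-12):
        raise ValueError("spectrum CSV bins are not contiguous")
    if mode is None:
        mode = _infer_mode(edges)
    binning = SizeBinning(edges=edges, mode=mode)
    return SizeSpectrum(binning=binning, density=df["n_per_ml_per_um"].to_numpy(), label=label)


def _infer_mode(edges: np.ndarray) -> str:
    widths = np.diff(edges)
    if np.allclose(widths, widths[0], rtol=1e-9):
        return "uniform"
    ratios = edges[1:] / edges[:-1]
    if np.allclose(ratios, ratios[0], rtol=1e-9):
        return "proportional"
    raise ValueError("cannot infer binning mode: bins neither uniform nor proportional")


def write_sds_json(fit: SDSFit, path: str | Path | None = None) -> str:
    text = json.dumps(fit.to_dict(), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def write_scenario_yaml(scenario: BloomScenario, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(scenario.to_dict(), sort_keys=False), encoding="utf-8"
    )


def read_scenario_yaml(path: str | Path) -> BloomScenario:
    obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(obj, dict) or "classes" not in obj:
        raise ValueError(f"{path}: not a scenario file (missing 'classes')")
    return BloomScenario.from_dict(obj)


def write_trajectory_csv(
    trajectory: BloomTrajectory,
    path: str | Path,
    sds: np.ndarray | None = None,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    data: dict[str, Any] = {"t_days": trajectory.times}
    for k, label in enumerate(trajectory.labels):
        data[f"P_{label}"] = trajectory.P[:, k]
    for k, label in enumerate(trajectory.labels):
        data[f"r_{label}"] = trajectory.r[:, k]
    if sds is not None:
        data["sds"] = sds
    meta: dict[str, Any] = {}
    if config is not None:
        meta["config"] = config_hash(config)
    if seed is not None:
        meta["seed"] = seed
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header(meta))
        pd.DataFrame(data).to_csv(fh, index=False, float_format="%.17g")
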