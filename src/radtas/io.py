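"""Matrix and configuration I/O.

Transient-absorption matrices travel as UTF-8 CSV: the header row is
``wavelength_nm`` followed by the delay values in ps; each subsequent row is
one wavelength; detector-blocked rows are written as ``NA`` cells. A YAML
sidecar (``<file>.meta.yaml``) carries concentration, dose, seed, mode and
the kinetic-scheme parameters.
"""
from __future__ import annotations

import os

import numpy as np
import yaml

from .matrix import GridError, TAMatrix

__all__ = [
    "read_ta_matrix",
    "write_ta_matrix",
    "RaggedRowsError",
    "HeaderUnitsError",
    "NonMonotoneGridError",
    "UnknownConfigKeyError",
    "load_config",
    "DEFAULT_CONFIG",
]


class RaggedRowsError(ValueError):
    """A CSV row has a different number of cells than the header."""


class HeaderUnitsError(ValueError):
    """The CSV header does not declare the wavelength_nm unit column."""


class NonMonotoneGridError(GridError):
    """A wavelength or delay grid in a file is not strictly ascending."""


class UnknownConfigKeyError(KeyError):
    """A configuration section contains a key the schema does not define."""


def _sidecar_path(path: str) -> str:
    return path + ".meta.yaml"


def write_ta_matrix(matrix: TAMatrix, path: str) -> None:
    """Write a matrix as CSV plus its YAML metadata sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        header = ["wavelength_nm"] + [f"{d:.6g}" for d in matrix.delays]
        fh.write(",".join(header) + "\n")
        for i, wl in enumerate(matrix.wavelengths):
            if matrix.mask[i]:
                cells = ["NA"] * matrix.n_delays
            else:
                cells = [f"{v:.8g}" for v in matrix.absorbance[i]]
            fh.write(",".join([f"{wl:.6g}"] + cells) + "\n")
    meta = {
        "concentration": float(matrix.concentration),
        "dose": float(matrix.dose),
        "seed": None if matrix.seed is None else int(matrix.seed),
    }
    meta.update(matrix.meta)
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_ta_matrix(path: str) -> TAMatrix:
    """Read a matrix CSV (and its sidecar, if present)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GridError(f"{path} is empty")
    header = lines[0].split(",")
    if header[0].strip() != "wavelength_nm":
        raise HeaderUnitsError(
            f"first header cell must be 'wavelength_nm', got {header[0]!r}"
        )
    try:
        delays = np.array([float(x) for x in header[1:]])
    except ValueError as exc:
        raise HeaderUnitsError(f"non-numeric delay header in {path}") from exc
    n_cols = len(header)

    wavelengths, rows, mask = [], [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != n_cols:
            raise RaggedRowsError(
                f"{path}:{ln_no}: expected {n_cols} cells, found {len(cells)}"
            )
        wavelengths.append(float(cells[0]))
        values = cells[1:]
        if all(v.strip() == "NA" for v in values):
            rows.append([np.nan] * (n_cols - 1))
            mask.append(True)
        else:
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise RaggedRowsError(
                    f"{path}:{ln_no}: mixed NA/numeric or bad cell"
                ) from exc
            mask.append(False)

    wavelengths = np.asarray(wavelengths)
    if np.any(np.diff(wavelengths) <= 0):
        raise NonMonotoneGridError(f"{path}: wavelength grid not strictly ascending")
    if delays.size and np.any(np.diff(delays) <= 0):
        raise NonMonotoneGridError(f"{path}: delay grid not strictly ascending")

    meta: dict = {}
    concentration, dose, seed = 0.0, 25.3, None
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
        concentration = float(meta.pop("concentration", 0.0))
        dose = float(meta.pop("dose", 25.3))
        seed = meta.pop("seed", None)
        if seed is not None:
            seed = int(seed)
    return TAMatrix(
        wavelengths=wavelengths,
        delays=delays,
        absorbance=np.asarray(rows),
        mask=np.asarray(mask, dtype=bool),
        concentration=concentration,
        dose=dose,
        seed=seed,
        meta=meta,
    )


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "generator": {
        "tau1": 45.0,
        "tau2": 80.0,
        "tau_tni": 350.0,
        "tau_esol": 5.0,
        "k_esol_attach": 5.0e8,
        "lambda_initial": 750.0,
        "lambda_final": 630.0,
        "c37": 0.37,
        "noise_sd": 5.0e-4,
        "irf_fwhm": 7.0,
        "dose": 25.3,
        "concentrations": [0.0, 0.05, 0.1, 0.2, 0.3, 0.5],
        "solution_concentration": 0.3,
    },
    "analysis": {
        "n_components": 2,
        "rank": 4,
        "ir_window": [900.0, 1000.0],
        "peak_window": [550.0, 900.0],
        "uv_vis_window": [370.0, 600.0],
        "lifetime_window_ps": [20.0, 500.0],
        "esol_window_us": [0.5, 15.0],
        "mcr_max_iter": 500,
        "mcr_tol": 1.0e-3,
    },
    "output": {
        "write_matrices": False,
    },
}


def _validate_section(name: str, given: dict, schema: dict) -> dict:
    merged = dict(schema)
    for key, value in given.items():
        if key not in schema:
            raise UnknownConfigKeyError(f"unknown key {key!r} in section {name!r}")
        merged[key] = value
    return merged


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Load and validate a pipeline configuration.

    Unknown sections or keys are rejected with :class:`UnknownConfigKeyError`;
    missing entries take the documented defaults. ``overrides`` (same nested
    layout) are applied after the file.
    """
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    config = {}
    for section, schema in DEFAULT_CONFIG.items():
        given = raw.pop(section, {}) or {}
        if not isinstance(given, dict):
            raise UnknownConfigKeyError(f"section {section!r} must be a mapping")
        config[section] = _validate_section(section, given, schema)
    if raw:
        raise UnknownConfigKeyError(f"unknown config sections: {sorted(raw)}")
    if overrides:
        for section, vals in overrides.items():
            if section not in config:
                raise UnknownConfigKeyError(f"unknown config section {section!r}")
            config[section] = _validate_section(section, vals, config[section])
    return config
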