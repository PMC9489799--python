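"""File formats, configuration, and the localization-table currency.

The pipeline's central data structure is the *localization table*: one row
per single-molecule localization, held as a :class:`pandas.DataFrame` with
the canonical columns

====================  =========================================================
column                meaning
====================  =========================================================
``frame``             acquisition frame index (integer, >= 0)
``x``, ``y``          position in nm (continuous; origin at the lower-left
                      corner of the field of view, x rightward, y upward)
``intensity``         fitted signal (photons or camera ADU)
``precision``         localization uncertainty sigma in nm (> 0)
``source_id``         ground-truth provenance: aggregate id for simulated
                      data, -1 for background/unknown, -2 for fiducial beads
====================  =========================================================

On disk the table is a UTF-8 CSV with the de-facto SMLM header
``frame,x [nm],y [nm],intensity [photon],uncertainty [nm],source_id`` so
tables exported by common reconstruction software drop in directly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "COLUMNS",
    "CSV_HEADER",
    "AnalysisConfig",
    "ConfigError",
    "FormatError",
    "PRESETS",
    "load_config",
    "make_localizations",
    "read_localizations",
    "read_stack",
    "validate_localizations",
    "write_localizations",
    "write_stack",
]

#: internal column names, in canonical order
COLUMNS = ("frame", "x", "y", "intensity", "precision", "source_id")

#: on-disk header names, matched 1:1 to :data:`COLUMNS`
CSV_HEADER = (
    "frame",
    "x [nm]",
    "y [nm]",
    "intensity [photon]",
    "uncertainty [nm]",
    "source_id",
)

_FLOAT_FORMAT = "%.4f"  # nm written to 0.1 pm; round-trip tolerance 1e-4


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class ConfigError(ValueError):
    """A configuration value violates an invariant."""


# ---------------------------------------------------------------------------
# configuration


#: named parameter presets for the two transient-binding imaging modes:
#: "thx" for thioflavin-X imaging, "paint" for aptamer-PAINT.
PRESETS: dict[str, dict[str, float | int]] = {
    "thx": {"eps": 75.0, "min_pts": 9, "min_signal": 100.0, "max_precision": 20.0},
    "paint": {"eps": 200.0, "min_pts": 10, "min_signal": 60.0, "max_precision": 40.0},
}


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis chain.

    Defaults follow the thioflavin-X super-resolution configuration:
    98.8 nm camera pixels, 8000 frames at 50 ms exposure, DBSCAN with
    eps 75 nm / minPts 9, and localization filtering at signal >= 100
    photons and precision <= 20 nm.  The ``paint`` preset switches to the
    aptamer-PAINT settings (eps 200 nm, minPts 10, signal >= 60,
    precision <= 40 nm).
    """

    fov_size: float = 20000.0        # field of view edge, nm
    pixel_size_sr: float = 98.8      # super-resolution camera pixel, nm
    pixel_size_dl: float = 237.0     # diffraction-limited camera pixel, nm
    n_frames: int = 8000
    exposure_ms: float = 50.0
    eps: float = 75.0                # DBSCAN detection radius, nm
    min_pts: int = 9                 # DBSCAN minimum localization threshold
    min_signal: float = 100.0        # filter: minimum intensity
    max_precision: float = 20.0      # filter: maximum uncertainty, nm
    hist_bin_width: float = 10.0     # length histogram bin, nm
    render_blur: float = 20.0        # rendering Gaussian blur sigma, nm
    seed: int = 0

    def __post_init__(self) -> None:
        for key in (
            "fov_size",
            "pixel_size_sr",
            "pixel_size_dl",
            "eps",
            "max_precision",
            "hist_bin_width",
            "render_blur",
        ):
            if not getattr(self, key) > 0:
                raise ConfigError(f"config key '{key}' must be > 0")
        if self.n_frames < 1:
            raise ConfigError("config key 'n_frames' must be >= 1")
        if self.min_pts < 1:
            raise ConfigError("config key 'min_pts' must be >= 1")
        if self.min_signal < 0:
            raise ConfigError("config key 'min_signal' must be >= 0")
        if self.exposure_ms <= 0:
            raise ConfigError("config key 'exposure_ms' must be > 0")

    def with_preset(self, name: str) -> "AnalysisConfig":
        """Return a copy with one of the named imaging presets applied."""
        if name not in PRESETS:
            raise ConfigError(
                f"unknown preset '{name}'; available: {sorted(PRESETS)}"
            )
        return dataclasses.replace(self, **PRESETS[name])


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON file.

    Absent keys are filled with the documented defaults.  A ``preset`` key
    ("thx" or "paint") applies the corresponding parameter block before any
    explicitly given key overrides it.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise FormatError(f"config file {path} must contain a mapping")
    data = dict(data)
    preset = data.pop("preset", None)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    merged: dict = dict(PRESETS[preset]) if preset in PRESETS else {}
    if preset is not None and preset not in PRESETS:
        raise ConfigError(f"unknown preset '{preset}'; available: {sorted(PRESETS)}")
    merged.update(data)
    return AnalysisConfig(**merged)


# ---------------------------------------------------------------------------
# localization tables


def make_localizations(
    frame: Iterable[int],
    x: Iterable[float],
    y: Iterable[float],
    intensity: Iterable[float] | None = None,
    precision: Iterable[float] | None = None,
    source_id: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Assemble a validated localization table from column arrays."""
    frame = np.asarray(frame, dtype=np.int64)
    n = frame.size
    table = pd.DataFrame(
        {
            "frame": frame,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "intensity": (
                np.zeros(n) if intensity is None else np.asarray(intensity, float)
            ),
            "precision": (
                np.ones(n) if precision is None else np.asarray(precision, float)
            ),
            "source_id": (
                np.full(n, -1, dtype=np.int64)
                if source_id is None
                else np.asarray(source_id, dtype=np.int64)
            ),
        }
    )
    validate_localizations(table)
    return table


def validate_localizations(table: pd.DataFrame, n_frames: int | None = None) -> None:
    """Check localization-table invariants; raise :class:`FormatError` if violated."""
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"localization table lacks column(s): {missing}")
    if len(table) == 0:
        return
    if not np.all(np.isfinite(table[["x", "y"]].to_numpy())):
        raise FormatError("localization table has non-finite coordinates")
    if not np.all(table["precision"].to_numpy() > 0):
        raise FormatError("localization precision must be > 0 for every row")
    frames = table["frame"].to_numpy()
    if frames.min() < 0:
        raise FormatError("frame indices must be >= 0")
    if n_frames is not None and frames.max() >= n_frames:
        raise FormatError(f"frame index beyond n_frames={n_frames}")


def read_localizations(
    path: str | Path,
    dialect: str = "nm",
    pixel_size: float | None = None,
    permissive: bool = False,
    max_precision: float | None = None,
) -> pd.DataFrame:
    """Read a localization table from CSV.

    Parameters
    ----------
    dialect:
        ``"nm"`` (default) for coordinates already in nm, ``"pixel"`` for
        tables storing pixel coordinates; the latter requires ``pixel_size``
        and multiplies x/y (and uncertainty) into nm.
    permissive:
        Missing ``intensity``/``uncertainty`` columns are rejected by
        default because silently defaulted values corrupt filtering.  With
        ``permissive=True`` a missing uncertainty column is substituted by
        ``max_precision`` and a missing intensity column by 0, and the
        substitution is recorded in ``df.attrs["filled_columns"]``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    rename = {h: c for h, c in zip(CSV_HEADER, COLUMNS)}
    raw = raw.rename(columns=rename)
    for mandatory in ("frame", "x", "y"):
        if mandatory not in raw.columns:
            raise FormatError(f"{path} lacks mandatory column '{mandatory}'")
    filled = []
    n = len(raw)
    if "intensity" not in raw.columns:
        if not permissive:
            raise FormatError(f"{path} lacks column 'intensity [photon]'")
        raw["intensity"] = np.zeros(n)
        filled.append("intensity")
    if "precision" not in raw.columns:
        if not permissive:
            raise FormatError(f"{path} lacks column 'uncertainty [nm]'")
        if max_precision is None or not max_precision > 0:
            raise FormatError(
                "permissive read of a table without uncertainties requires max_precision"
            )
        raw["precision"] = np.full(n, float(max_precision))
        filled.append("precision")
    if "source_id" not in raw.columns:
        raw["source_id"] = np.full(n, -1, dtype=np.int64)
    for col in COLUMNS:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = np.nonzero(values.isna().to_numpy() & raw[col].notna().to_numpy())[0]
        if bad.size:
            raise FormatError(f"{path}: non-numeric value in '{col}' at data row {bad[0]}")
        if values.isna().any():
            raise FormatError(f"{path}: missing value in '{col}'")
        raw[col] = values
    if dialect == "pixel":
        if pixel_size is None or not pixel_size > 0:
            raise FormatError("dialect 'pixel' requires a positive pixel_size")
        raw[["x", "y", "precision"]] *= float(pixel_size)
    elif dialect != "nm":
        raise FormatError(f"unknown dialect '{dialect}'")
    table = raw[list(COLUMNS)].astype(
        {"frame": np.int64, "source_id": np.int64}
    )
    validate_localizations(table)
    table.attrs["filled_columns"] = filled
    return table


def write_localizations(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a localization table as CSV in the documented dialect.

    Output is deterministic (fixed column order and float format) so a
    fixed table always produces byte-identical files.
    """
    validate_localizations(table)
    path = Path(path)
    out = table[list(COLUMNS)].copy()
    out.columns = list(CSV_HEADER)
    out.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# image stacks


def write_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a (n_frames, ny, nx) stack as multi-page 16-bit grayscale TIFF."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError("image stack must be 2D or 3D")
    clipped = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(Path(path), clipped, photometric="minisblack")
    return Path(path)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF into a (n_frames, ny, nx) float array."""
    data = tifffile.imread(Path(path))
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path} is not a single-channel 2D stack")
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path} contains non-finite pixels")
    return data


def dump_json(obj, path: str | Path) -> Path:
    """Serialize a report deterministically (sorted keys, fixed separators)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path = Path(path)
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n",
        encoding="utf-8",
    )
    return path
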