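"""Readers and writers for on-disk artifacts.

Formats:

* E-nose traces — long-form CSV with columns ``sample_id, t, f0..f9``
  (one row per second, 75 rows per sample), matching the simplest dialect
  of PEN3 exports.
* Hyperspectral cubes — ENVI header/binary pairs (the de facto container
  for line-scan NIR cameras). Only the metadata the pipeline needs is
  parsed: dimensions, interleave, data type, byte order and the
  wavelength list.
* Feature tables — wide CSV with ``sample_id``, named feature columns and
  an optional ``TP_percent`` target column, round-trip safe at 12
  significant digits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ENoseRecord,
    FeatureTable,
    N_TIMEPOINTS,
    SENSOR_KEYS,
    SpectralCube,
    TARGET_COLUMN,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# E-nose CSV
# ---------------------------------------------------------------------------

@dataclass
class ENoseCsvDialect:
    """Column layout of the long-form E-nose CSV."""

    sample_id_column: str = "sample_id"
    time_column: str = "t"
    sensor_columns: tuple[str, ...] = SENSOR_KEYS

    def __post_init__(self) -> None:
        if len(self.sensor_columns) != 10:
            raise ValueError("dialect must name exactly 10 sensor columns")


def read_enose_csv(
    path: str | Path, dialect: ENoseCsvDialect | None = None
) -> list[ENoseRecord]:
    """Read one record per distinct sample id from a long-form CSV.

    Rejects (with the sample id named) any sample whose trace length is
    not 75 or whose time axis is not 1-s increasing.
    """
    dialect = dialect or ENoseCsvDialect()
    df = pd.read_csv(path)
    needed = [dialect.sample_id_column, dialect.time_column, *dialect.sensor_columns]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in (dialect.time_column, *dialect.sensor_columns):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric values in column {col!r}")

    records: list[ENoseRecord] = []
    for sid, grp in df.groupby(dialect.sample_id_column, sort=False):
        grp = grp.sort_values(dialect.time_column)
        if len(grp) != N_TIMEPOINTS:
            raise ValueError(
                f"sample {sid!r}: expected {N_TIMEPOINTS} rows, got {len(grp)}"
            )
        t = grp[dialect.time_column].to_numpy(dtype=float)
        if not np.allclose(np.diff(t), 1.0):
            raise ValueError(f"sample {sid!r}: time axis is not a 1-s grid")
        records.append(
            ENoseRecord(str(sid), grp[list(dialect.sensor_columns)].to_numpy(float))
        )
    log.info("read %d e-nose records from %s", len(records), path)
    return records


def write_enose_csv(
    records: list[ENoseRecord],
    path: str | Path,
    dialect: ENoseCsvDialect | None = None,
) -> None:
    dialect = dialect or ENoseCsvDialect()
    frames = []
    for rec in records:
        f = pd.DataFrame(rec.traces, columns=list(dialect.sensor_columns))
        f.insert(0, dialect.time_column, np.arange(1, rec.n_times + 1, dtype=float))
        f.insert(0, dialect.sample_id_column, rec.sample_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# ENVI cubes
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    # join {...} blocks onto one line, then split key = value
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(header_path: str | Path) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    Requires a wavelength list in the header; supports BSQ/BIL/BIP
    interleaves and little/big byte order.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"{header_path}: missing ENVI field {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError(f"{header_path}: no wavelength metadata")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(x) for x in wl_text.replace(",", " ").split()], dtype=float
    )
    if len(wavelengths) != bands:
        raise ValueError(
            f"{header_path}: {len(wavelengths)} wavelengths for {bands} bands"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"{header_path}: unsupported data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")

    img_path = header_path.with_suffix(".img")
    if not img_path.exists():
        raise FileNotFoundError(f"{img_path}: ENVI binary not found")
    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(img_path, dtype=dtype, offset=offset)
    if raw.size != lines * samples * bands:
        raise ValueError(
            f"{img_path}: expected {lines * samples * bands} values, got {raw.size}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"{header_path}: unknown interleave {interleave!r}")
    return SpectralCube(np.ascontiguousarray(data), wavelengths)


def write_envi_cube(
    cube: SpectralCube, base_path: str | Path, interleave: str = "bsq"
) -> Path:
    """Write ``<base>.hdr`` and ``<base>.img``; returns the header path."""
    base_path = Path(base_path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    data = cube.data
    if data.dtype not in _ENVI_CODES:
        data = data.astype(np.float32)
    lines, samples, bands = data.shape
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    img_path = base_path.with_suffix(".img")
    hdr_path = base_path.with_suffix(".hdr")
    np.ascontiguousarray(out).tofile(img_path)
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    hdr_path.write_text(
        "ENVI\n"
        "description = {teafuse synthetic reflectance cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return hdr_path


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a wide CSV of features (and optional ``TP_percent`` target)."""
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    seen: set[str] = set()
    for col in header:
        if col in seen:  # pandas would silently mangle these to col.1
            raise ValueError(f"{path}: duplicate column {col!r}")
        seen.add(col)
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    target = None
    if TARGET_COLUMN in df.columns:
        target = df.pop(TARGET_COLUMN).astype(float)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns")
    return FeatureTable(df.astype(float), target)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.features.copy()
    if table.target is not None:
        df[TARGET_COLUMN] = table.target
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.12g")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved run parameters (TOML-loadable).

    ``selection_fractions`` follows the study design: the top 30% of
    sensors per time-domain family, the top 25% of image features by
    absolute Pearson correlation.
    """

    seed: int = 0
    n_samples: int = 110
    roi_size: int = 50
    crop_range_nm: tuple[float, float] = (944.0, 1688.0)
    steady_state_t0_s: int = 55
    selection_fractions: dict[str, float] = field(
        default_factory=lambda: {"enose_sensor_top": 0.30, "hsi_top": 0.25}
    )
    model_name: str = "xgboost"
    cwt_wavelet: str = "mexh"
    dwt_wavelet: str = "db4"

    def __post_init__(self) -> None:
        for key, frac in self.selection_fractions.items():
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"selection fraction {key}={frac} not in (0, 1]")
        low, high = self.crop_range_nm
        if not low < high:
            raise ValueError("crop_range_nm must be (low, high) with low < high")
        if self.model_name not in ("gridsvr", "rf", "xgboost"):
            raise ValueError(f"unknown model {self.model_name!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "crop_range_nm" in data:
            data["crop_range_nm"] = tuple(data["crop_range_nm"])
        return cls(**data)
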