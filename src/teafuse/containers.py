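"""Core in-memory containers shared across the pipeline stages.

The lingua franca between stages is :class:`FeatureTable` — a named feature
matrix (samples x features) with an optional polyphenol target vector.
Raw inputs are :class:`ENoseRecord` (ten gas-sensor response-ratio traces)
and :class:`SpectralCube` (an H x W x B near-infrared reflectance cube).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: PEN3 sensor names in array order f0..f9.
SENSOR_NAMES: tuple[str, ...] = (
    "W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S",
)

#: Column labels f0..f9 used on disk and in feature names.
SENSOR_KEYS: tuple[str, ...] = tuple(f"f{i}" for i in range(10))

#: Number of time points per trace (75 s at 1 Hz).
N_TIMEPOINTS: int = 75

#: Name of the target column in feature tables.
TARGET_COLUMN: str = "TP_percent"


@dataclass
class ENoseRecord:
    """One sample's electronic-nose measurement.

    Parameters
    ----------
    sample_id
        Unique sample identifier.
    traces
        Array of shape ``(n_times, 10)`` of response ratios G/G0, one
        column per sensor in f0..f9 order.
    dt
        Sampling interval in seconds (1 s for the PEN3 protocol).
    """

    sample_id: str
    traces: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2 or self.traces.shape[1] != len(SENSOR_KEYS):
            raise ValueError(
                f"sample {self.sample_id!r}: traces must be (n_times, 10), "
                f"got {self.traces.shape}"
            )
        if not np.all(np.isfinite(self.traces)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite trace values")

    @property
    def n_times(self) -> int:
        return self.traces.shape[0]

    def trace(self, sensor: str) -> np.ndarray:
        """Return one sensor's trace by f-key ('f3') or name ('W6S')."""
        if sensor in SENSOR_KEYS:
            j = SENSOR_KEYS.index(sensor)
        elif sensor in SENSOR_NAMES:
            j = SENSOR_NAMES.index(sensor)
        else:
            raise KeyError(f"unknown sensor {sensor!r}")
        return self.traces[:, j]


@dataclass
class SpectralCube:
    """Hyperspectral reflectance cube with a wavelength axis.

    ``data`` has shape ``(lines, samples, bands)``; ``wavelengths`` is a
    strictly increasing vector of band-center wavelengths in nm.
    """

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest ``wavelength_nm`` (ties -> lower band)."""
        d = np.abs(self.wavelengths - wavelength_nm)
        return int(np.argmin(d))  # argmin takes the first (lower) on ties


@dataclass
class FeatureTable:
    """Named feature matrix plus optional polyphenol target.

    ``features`` is a DataFrame indexed by sample id with one float column
    per feature; ``target`` (if present) is aligned on the same index.
    """

    features: pd.DataFrame
    target: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.features.shape[1] == 0:
            raise ValueError("feature table has no feature columns")
        if self.features.columns.duplicated().any():
            dup = self.features.columns[self.features.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name {dup!r}")
        if self.features.index.duplicated().any():
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.target is not None:
            self.target = self.target.reindex(self.features.index)
            if self.target.isna().any():
                missing = self.target.index[self.target.isna()][0]
                raise ValueError(f"target missing for sample {missing!r}")
            self.target.name = TARGET_COLUMN

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.features.loc[:, names].copy(), self.target)

    def subset_samples(self, ids: list[str]) -> "FeatureTable":
        missing = [i for i in ids if i not in self.features.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        tgt = self.target.loc[ids] if self.target is not None else None
        return FeatureTable(self.features.loc[ids].copy(), tgt)

    def hstack(self, other: "FeatureTable") -> "FeatureTable":
        """Column-wise fusion; indexes must match, names must not collide."""
        if not self.features.index.equals(other.features.index):
            raise ValueError("sample ids differ between tables")
        clash = set(self.features.columns) & set(other.features.columns)
        if clash:
            raise ValueError(f"feature name collision: {sorted(clash)}")
        tgt = self.target if self.target is not None else other.target
        return FeatureTable(
            pd.concat([self.features, other.features], axis=1), tgt
        )


@dataclass
class SelectionResult:
    """Outcome of one feature-selection rule."""

    method: str  # "importance" or "correlation"
    scores: dict[str, float]
    retained: list[str]
    fraction: float

    def __post_init__(self) -> None:
        unknown = [n for n in self.retained if n not in self.scores]
        if unknown:
            raise ValueError(f"retained names not scored: {unknown}")
        if len(set(self.retained)) != len(self.retained):
            raise ValueError("duplicate retained names")


@dataclass
class SetMetrics:
    """R2 / adjusted R2 / RMSE for one evaluation set."""

    r2: float
    adjusted_r2: float
    rmse: float
    n: int
    p: int


@dataclass
class EvaluationReport:
    """Calibration and validation metrics of one trained model."""

    model_name: str
    feature_set: str
    n_variables: int
    calibration: SetMetrics
    validation: SetMetrics
    best_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _set(m: SetMetrics) -> dict:
            return {
                "R2": m.r2,
                "adjusted_R2": m.adjusted_r2,
                "RMSE": m.rmse,
                "n": m.n,
                "p": m.p,
            }

        return {
            "model": self.model_name,
            "features": self.feature_set,
            "variables": self.n_variables,
            "calibration": _set(self.calibration),
            "validation": _set(self.validation),
            "best_params": self.best_params,
        }
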