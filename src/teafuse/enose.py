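"""Time- and frequency-domain features of electronic-nose traces.

Six time-domain statistics per sensor (variance, integral value,
relative steady-state average, average differential, kurtosis, skewness)
give a 60-feature vector per sample; a continuous wavelet transform at
dyadic scales 2^1..2^10 summarizes each trace's frequency content, and
the per-sensor coefficient-energy sums are condensed into two scalars:
WM (maximum over sensors) and WA (mean over sensors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .containers import ENoseRecord, SENSOR_KEYS

#: Feature families in canonical order (family-major naming).
FAMILIES: tuple[str, ...] = ("VAR", "INV", "RSAV", "ADV", "KURT", "SKEW")

#: Default steady-state onset (seconds / index into the 1-Hz trace).
DEFAULT_T0: int = 55

#: Dyadic CWT scales 2^1 .. 2^10.
CWT_SCALES: np.ndarray = 2.0 ** np.arange(1, 11)


def time_domain_feature_names() -> list[str]:
    """The 60 names ``<FAMILY>_<fkey>``, family-major, sensor-minor."""
    return [f"{fam}_{key}" for fam in FAMILIES for key in SENSOR_KEYS]


def _as_trace(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("trace must be a nonempty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    return x


def variance(values: np.ndarray) -> float:
    """Population variance (divisor N)."""
    x = _as_trace(values)
    return float(np.mean((x - x.mean()) ** 2))


def integral_value(values: np.ndarray, dt: float = 1.0) -> float:
    """Rectangle-rule integral: sum(c_i) * dt — the total response."""
    x = _as_trace(values)
    return float(np.sum(x) * dt)


def steady_state_average(values: np.ndarray, t0: int = DEFAULT_T0) -> float:
    """Mean response over the steady-state tail (indices >= t0)."""
    x = _as_trace(values)
    if not 0 < t0 < x.size:
        raise ValueError(f"t0={t0} must lie strictly inside the trace (N={x.size})")
    return float(np.mean(x[t0:]))


def average_differential(values: np.ndarray, dt: float = 1.0) -> float:
    """Mean forward difference per second, (1/(N-1)) * sum((c_{i+1}-c_i)/dt).

    Telescopes to (c_N - c_1) / ((N-1) dt).
    """
    x = _as_trace(values)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    return float(np.mean(np.diff(x)) / dt)


def kurtosis(values: np.ndarray) -> float:
    """Excess kurtosis m4/m2^2 - 3 with population moments."""
    x = _as_trace(values)
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("degenerate trace: zero variance")
    return float(np.mean(d**4) / m2**2 - 3.0)


def skewness(values: np.ndarray) -> float:
    """Adjusted Fisher-Pearson skewness sqrt(N(N-1))/(N-2) * m3/m2^1.5."""
    x = _as_trace(values)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("degenerate trace: zero variance")
    g1 = np.mean(d**3) / m2**1.5
    return float(np.sqrt(n * (n - 1)) / (n - 2) * g1)


def extract_time_domain(
    record: ENoseRecord,
    t0: int = DEFAULT_T0,
    degenerate: str = "error",
) -> dict[str, float]:
    """All 60 time-domain features of one record, name-keyed.

    ``degenerate`` controls zero-variance traces, which break KURT/SKEW:
    ``"error"`` raises (naming the sensor), ``"zero"`` emits 0.0.
    """
    if degenerate not in ("error", "zero"):
        raise ValueError("degenerate must be 'error' or 'zero'")
    out: dict[str, float] = {}
    for fam in FAMILIES:
        for j, key in enumerate(SENSOR_KEYS):
            x = record.traces[:, j]
            try:
                if fam == "VAR":
                    v = variance(x)
                elif fam == "INV":
                    v = integral_value(x, record.dt)
                elif fam == "RSAV":
                    v = steady_state_average(x, t0)
                elif fam == "ADV":
                    v = average_differential(x, record.dt)
                elif fam == "KURT":
                    v = kurtosis(x)
                else:
                    v = skewness(x)
            except ValueError as exc:
                if degenerate == "zero" and "degenerate" in str(exc):
                    v = 0.0
                else:
                    raise ValueError(
                        f"sample {record.sample_id!r}, sensor {key}: {exc}"
                    ) from exc
            out[f"{fam}_{key}"] = v
    return out


@dataclass(frozen=True)
class CwtSummary:
    """Per-sensor CWT energy sums and their max (WM) / mean (WA)."""

    S: np.ndarray  # energy sum per sensor, length 10
    WM: float
    WA: float
    wavelet: str


def cwt_energy(values: np.ndarray, wavelet: str = "mexh") -> float:
    """Sum of squared CWT coefficients over dyadic scales 2^1..2^10.

    The full scale x time plane is summed; scales exceeding the trace
    length rely on pywt's zero-padded convolution at the boundaries.
    """
    x = _as_trace(values)
    coeffs, _ = pywt.cwt(x, CWT_SCALES, wavelet)
    return float(np.sum(coeffs**2))


def extract_cwt_summary(record: ENoseRecord, wavelet: str = "mexh") -> CwtSummary:
    """Condense a record's frequency content into WM and WA."""
    if wavelet not in pywt.wavelist(kind="continuous"):
        raise ValueError(f"unknown continuous wavelet {wavelet!r}")
    S = np.array(
        [cwt_energy(record.traces[:, j], wavelet) for j in range(len(SENSOR_KEYS))]
    )
    return CwtSummary(S=S, WM=float(S.max()), WA=float(S.mean()), wavelet=wavelet)


def extract_enose_features(
    record: ENoseRecord,
    t0: int = DEFAULT_T0,
    wavelet: str = "mexh",
    degenerate: str = "error",
) -> dict[str, float]:
    """62 features: the 60 time-domain statistics plus WM and WA."""
    out = extract_time_domain(record, t0=t0, degenerate=degenerate)
    summary = extract_cwt_summary(record, wavelet=wavelet)
    out["WM"] = summary.WM
    out["WA"] = summary.WA
    return out
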