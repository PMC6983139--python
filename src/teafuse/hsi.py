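"""Hyperspectral features: ROI spectra, spectral cropping, SPA wavelength
selection, and two-level 2-D wavelet energy/entropy of band images.

Per sample the pipeline extracts the mean spectrum of the centered
50 x 50-pixel region of interest, crops the noisy band edges to
944-1688 nm, selects two informative wavelengths with the successive
projections algorithm (SPA), and characterizes the ROI image at each
selected band by the energy (WE) and normalized Shannon entropy (WEN) of
its detail sub-bands (LH, HL, HH) at decomposition levels 1 and 2 —
2 bands x 3 orientations x 2 levels x 2 measures = 24 features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .containers import SpectralCube

log = logging.getLogger(__name__)

SUBBANDS: tuple[str, ...] = ("LH", "HL", "HH")
DEFAULT_DWT_WAVELET = "db4"
#: Boundary mode for the 2-D DWT; periodization keeps the transform
#: orthonormal so sub-band energies satisfy Parseval exactly.
DWT_MODE = "periodization"


@dataclass(frozen=True)
class RoiSpectrum:
    """Mean ROI reflectance per band."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance lengths differ")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("non-finite reflectance")


def roi_bounds(height: int, width: int, roi_size: int) -> tuple[int, int]:
    """Top-left corner of the centered ROI: (floor((H-r)/2), floor((W-r)/2))."""
    if roi_size > height or roi_size > width:
        raise ValueError(f"ROI size {roi_size} exceeds image {height}x{width}")
    return (height - roi_size) // 2, (width - roi_size) // 2


def extract_roi(cube: SpectralCube, roi_size: int = 50) -> np.ndarray:
    """The centered roi_size x roi_size x B sub-cube."""
    h, w, _ = cube.shape
    r0, c0 = roi_bounds(h, w, roi_size)
    return cube.data[r0 : r0 + roi_size, c0 : c0 + roi_size, :]


def extract_roi_spectrum(cube: SpectralCube, roi_size: int = 50) -> RoiSpectrum:
    """Per-band mean reflectance over the centered ROI."""
    roi = extract_roi(cube, roi_size)
    return RoiSpectrum(cube.wavelengths.copy(), roi.mean(axis=(0, 1)).astype(float))


def crop_spectrum(spec: RoiSpectrum, low: float, high: float) -> RoiSpectrum:
    """Retain bands with low <= lambda <= high (closed interval)."""
    if low >= high:
        raise ValueError("crop requires low < high")
    mask = (spec.wavelengths >= low) & (spec.wavelengths <= high)
    if not mask.any():
        raise ValueError(f"crop [{low}, {high}] nm retains no bands")
    return RoiSpectrum(spec.wavelengths[mask], spec.reflectance[mask])


# ---------------------------------------------------------------------------
# Successive projections algorithm
# ---------------------------------------------------------------------------

def spa_chain(X: np.ndarray, start: int, k: int) -> list[int]:
    """Build one SPA projection chain of length k from a start column.

    At each step the column with the largest norm of its component
    orthogonal to the span of the already-selected columns is added;
    ties break toward the lowest band index.
    """
    X = np.asarray(X, dtype=float)
    n_bands = X.shape[1]
    if not 0 <= start < n_bands:
        raise IndexError("start column out of range")
    if k > n_bands:
        raise ValueError("k exceeds band count")
    selected = [start]
    resid = X.copy()
    for _ in range(k - 1):
        v = resid[:, selected[-1]]
        nv = v @ v
        if nv > 0:
            resid = resid - np.outer(v, (v @ resid) / nv)
        norms = np.einsum("ij,ij->j", resid, resid)
        norms[selected] = -1.0
        # highest residual norm; argmax takes the lowest index on ties
        best = int(np.argmax(norms))
        selected.append(best)
    return selected


def _mlr_rmse(
    Xtr: np.ndarray, ytr: np.ndarray, Xva: np.ndarray, yva: np.ndarray
) -> float:
    A = np.column_stack([np.ones(len(Xtr)), Xtr])
    coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    pred = np.column_stack([np.ones(len(Xva)), Xva]) @ coef
    return float(np.sqrt(np.mean((yva - pred) ** 2)))


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    k: int = 2,
) -> np.ndarray:
    """Select k wavelengths by SPA.

    For every candidate start column a projection chain of length k is
    built; each chain is scored by the RMSE of a multilinear regression
    on the chain's columns, fit on a deterministic internal split (every
    4th sample held out), and the chain with minimal RMSE wins (ties ->
    lexicographically smallest sorted band-index tuple).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    n_samples, n_bands = X.shape
    if k > n_bands:
        raise ValueError(f"k={k} exceeds band count {n_bands}")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    val = np.zeros(n_samples, dtype=bool)
    val[3::4] = True
    if not val.any() or val.all():
        raise ValueError("too few samples for the internal split")

    best_key: tuple | None = None
    best_bands: list[int] | None = None
    for start in range(n_bands):
        chain = spa_chain(X, start, k)
        rmse = _mlr_rmse(X[~val][:, chain], y[~val], X[val][:, chain], y[val])
        key = (rmse, tuple(sorted(chain)))
        if best_key is None or key < best_key:
            best_key, best_bands = key, chain
    assert best_bands is not None
    chosen = wavelengths[sorted(best_bands)]
    log.info("SPA selected wavelengths %s nm", np.round(chosen, 1))
    return chosen


# ---------------------------------------------------------------------------
# 2-D wavelet sub-band features
# ---------------------------------------------------------------------------

def wavelet_subband_features(
    img: np.ndarray,
    wavelet: str = DEFAULT_DWT_WAVELET,
    levels: int = 2,
) -> dict[str, float]:
    """WE and WEN of each detail sub-band of a 2-level DWT.

    WE = mean squared coefficient of the sub-band (size M x N).
    WEN = -(1/MN) * sum p*log2(p) with p = coeff^2 / sub-band energy and
    0*log2(0) := 0; an all-zero sub-band has WEN = 0.

    Returns keys ``"<LH|HL|HH><level>_<WE|WEN>"``, e.g. ``"HL1_WE"``.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2**levels:
        raise ValueError(f"image {img.shape} too small for {levels} levels")
    coeffs = pywt.wavedec2(img, wavelet, mode=DWT_MODE, level=levels)
    # coeffs = [cA_L, (cH_L, cV_L, cD_L), ..., (cH_1, cV_1, cD_1)]
    # sub-bands holding only floating-point dust (e.g. from a constant
    # image) count as empty, otherwise the normalized entropy would
    # amplify rounding noise
    energy_floor = 1e-24 * max(float(np.sum(img**2)), 1.0)
    out: dict[str, float] = {}
    for pos, details in enumerate(coeffs[1:]):
        level = levels - pos
        for name, c in zip(SUBBANDS, details):
            c = np.asarray(c)
            mn = c.size
            energy = float(np.sum(c**2))
            out[f"{name}{level}_WE"] = energy / mn
            if energy <= energy_floor:
                out[f"{name}{level}_WEN"] = 0.0
            else:
                p = (c.ravel() ** 2) / energy
                nz = p[p > 0]
                out[f"{name}{level}_WEN"] = float(-np.sum(nz * np.log2(nz)) / mn)
    return out


def hsi_feature_names() -> list[str]:
    """The 24 names ``B{b}_{subband}{level}_{WE|WEN}``."""
    return [
        f"B{b}_{sb}{lvl}_{measure}"
        for b in (1, 2)
        for lvl in (1, 2)
        for sb in SUBBANDS
        for measure in ("WE", "WEN")
    ]


def extract_hsi_features(
    cube: SpectralCube,
    feature_wavelengths: tuple[float, float],
    roi_size: int = 50,
    wavelet: str = DEFAULT_DWT_WAVELET,
    crop_range: tuple[float, float] | None = (944.0, 1688.0),
) -> dict[str, float]:
    """24 wavelet features of the ROI images at two feature wavelengths.

    Wavelengths are snapped to the nearest band on the (cropped) axis;
    requesting one outside the cropped range is an error.
    """
    if len(feature_wavelengths) != 2:
        raise ValueError("exactly two feature wavelengths required")
    if crop_range is not None:
        low, high = crop_range
        for w in feature_wavelengths:
            if not (low <= w <= high):
                raise ValueError(
                    f"wavelength {w} nm outside cropped range [{low}, {high}]"
                )
    roi = extract_roi(cube, roi_size)
    out: dict[str, float] = {}
    for b, target in enumerate(feature_wavelengths, start=1):
        idx = cube.band_index(target)
        actual = cube.wavelengths[idx]
        if abs(actual - target) > 1e-9:
            log.info("band snap: %.1f nm -> %.1f nm (band %d)", target, actual, idx + 1)
        sub = wavelet_subband_features(roi[:, :, idx], wavelet=wavelet)
        for key, val in sub.items():
            out[f"B{b}_{key}"] = val
    return out
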