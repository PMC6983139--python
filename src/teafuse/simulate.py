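"""Synthetic paired E-nose / hyperspectral datasets with known polyphenol truth.

The study design this emulates: 110 tea samples drawn from 10 varieties in
three categories (black, green, yellow), each variety with its own
polyphenol mean, SD and range. Per sample the generator produces

* an electronic-nose record — ten response-ratio traces that rise from 1
  with sensor-specific sign and amplitude and stabilize before 55 s, the
  amplitude an affine-plus-noise function of polyphenol content with
  variety-level offsets;
* a near-infrared reflectance cube (908–1700 nm at 2 nm) — a smooth
  baseline with Gaussian absorption features at 1106 and 1375 nm whose
  depths grow with polyphenol content, modulated by a random spatial
  texture whose high-frequency amplitude also grows with content, plus
  heteroscedastic pixel noise inflated outside 944–1688 nm.

Also houses the permanganate-titration conversion to polyphenol content.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .containers import ENoseRecord, N_TIMEPOINTS, SENSOR_KEYS, SpectralCube

#: Constant of the permanganate titration conversion (mL-to-mass factor
#: over the permanganate equivalence factor, as printed on the instrument
#: protocol); kept symbolic and uninterpreted.
TITRATION_FACTOR: float = 0.00582 / 0.318


@dataclass(frozen=True)
class VarietySpec:
    """One tea variety's sampling plan and polyphenol statistics (%)."""

    name: str
    category: str
    n: int
    tp_mean: float
    tp_sd: float
    tp_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.category not in ("black", "green", "yellow"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.n <= 0 or self.tp_sd <= 0:
            raise ValueError("n and tp_sd must be positive")
        low, high = self.tp_range
        if not (low <= self.tp_mean <= high):
            raise ValueError(f"{self.name}: mean outside range")


def default_variety_table() -> list[VarietySpec]:
    """The study's 10 varieties (110 samples across three categories)."""
    return [
        VarietySpec("Zhengshan Xiaozhong (Fujian)", "black", 10, 11.832, 0.850, (10.65, 13.21)),
        VarietySpec("Qimen Black Tea (Anhui Huangshan)", "black", 10, 15.196, 0.810, (13.66, 16.54)),
        VarietySpec("Qimen Black Tea (Anhui Qimen)", "black", 10, 18.789, 1.567, (16.51, 22.85)),
        VarietySpec("JinJunMei (Fujian)", "black", 10, 16.99, 1.788, (12.62, 19.16)),
        VarietySpec("Huangshan Maofeng (Anhui)", "green", 15, 26.485, 1.195, (25.32, 29.41)),
        VarietySpec("Liuan Guapian (Anhui)", "green", 15, 28.535, 0.632, (27.42, 29.65)),
        VarietySpec("Junshan Yinzhen (Hunan)", "yellow", 10, 16.34, 1.863, (14.55, 19.6)),
        VarietySpec("Huoshan Huangya Tea (Anhui)", "yellow", 10, 13.862, 1.367, (11.88, 16.65)),
        VarietySpec("Mengding Huangya Tea (Sichuan)", "yellow", 10, 14.334, 1.738, (11.36, 16.35)),
        VarietySpec("Pingyang Huangtang Tea (Zhejiang)", "yellow", 10, 16.735, 2.231, (13.34, 19.36)),
    ]


def draw_tp(spec: VarietySpec, rng: np.random.Generator) -> float:
    """Draw one polyphenol content ~ Normal(mean, sd) truncated to range."""
    if spec.tp_sd == 0:
        return spec.tp_mean
    a = (spec.tp_range[0] - spec.tp_mean) / spec.tp_sd
    b = (spec.tp_range[1] - spec.tp_mean) / spec.tp_sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    return float(spec.tp_mean + spec.tp_sd * stats.norm.ppf(u))


# ---------------------------------------------------------------------------
# Titration conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationMeasurement:
    """Raw permanganate-titration readings for one sample.

    A, B: mL permanganate consumed by the sample and by the blank;
    omega: permanganate concentration (%); m: sample mass (g);
    V1, V2: test-solution volume and measured-aliquot volume (mL).
    """

    A: float
    B: float
    omega: float
    m: float
    V1: float
    V2: float


def titration_to_tp(meas: TitrationMeasurement) -> float:
    """Polyphenol content (%) from a titration measurement.

    X = ((A - B) * omega * 0.00582/0.318) / m * (V1/V2).
    """
    if meas.m <= 0 or meas.V2 <= 0 or meas.V1 <= 0:
        raise ValueError("mass and volumes must be positive")
    return (meas.A - meas.B) * meas.omega * TITRATION_FACTOR / meas.m * (meas.V1 / meas.V2)


# ---------------------------------------------------------------------------
# E-nose response simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnoseSimConfig:
    """Kinetics and noise of the simulated sensor array.

    Each sensor's trace is ``1 + a_j * (1 - exp(-t/tau_j)) * (1 + eps)``
    with plateau amplitude ``a_j = sign_j * (base_j + slope_j * tp)``
    scaled by a fixed variety-level offset and a per-sample lognormal-ish
    amplitude perturbation. Signs follow the observed deviation pattern:
    W5S, W1S, W1W, W2S, W2W above 1 (W1W largest); W1C, W3C, W5C slightly
    below 1; W6S, W3S near 1. All tau_j satisfy 1-exp(-55/tau) >= 0.98 so
    traces are within 2% of their plateau at the 55-s steady-state onset.
    """

    base: tuple[float, ...] = (
        -0.05, 0.30, -0.04, 0.010, -0.06, 0.20, 0.50, 0.15, 0.20, 0.020)
    slope: tuple[float, ...] = (
        -0.004, 0.050, -0.003, 0.0008, -0.005, 0.040, 0.090, 0.030, 0.035, 0.0010)
    tau: tuple[float, ...] = (10.0, 12.0, 9.0, 11.0, 10.0, 13.0, 12.0, 11.0, 13.0, 9.0)
    trace_noise_sd: float = 0.01
    amplitude_noise_rel: float = 0.12
    variety_offset_rel: float = 0.10


def _variety_offsets(variety: str, rel_sd: float, n_sensors: int = 10) -> np.ndarray:
    """Deterministic per-(variety, sensor) amplitude factors near 1."""
    seed = zlib.crc32(variety.encode("utf8")) & 0x7FFFFFFF
    rng = np.random.Generator(np.random.PCG64(seed))
    return 1.0 + rel_sd * rng.standard_normal(n_sensors)


def simulate_enose(
    tp: float,
    variety: VarietySpec | str,
    rng: np.random.Generator,
    sample_id: str = "sample",
    config: EnoseSimConfig | None = None,
) -> ENoseRecord:
    """Simulate one PEN3 record (75 points at 1 Hz per sensor) for ``tp`` %."""
    if tp <= 0:
        raise ValueError("tp must be positive")
    cfg = config or EnoseSimConfig()
    vname = variety.name if isinstance(variety, VarietySpec) else variety
    offsets = _variety_offsets(vname, cfg.variety_offset_rel)
    t = np.arange(1, N_TIMEPOINTS + 1, dtype=float)
    traces = np.empty((N_TIMEPOINTS, len(SENSOR_KEYS)))
    for j in range(len(SENSOR_KEYS)):
        a = (cfg.base[j] + cfg.slope[j] * tp) * offsets[j]
        a *= 1.0 + cfg.amplitude_noise_rel * rng.standard_normal()
        rise = 1.0 - np.exp(-t / cfg.tau[j])
        eps = cfg.trace_noise_sd * rng.standard_normal(N_TIMEPOINTS)
        traces[:, j] = 1.0 + a * rise * (1.0 + eps)
    return ENoseRecord(sample_id, traces)


# ---------------------------------------------------------------------------
# Hyperspectral cube simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CubeSimConfig:
    """Optics and noise of the simulated NIR cube.

    Reflectance = (baseline(lambda) - absorptions) * texture(x, y) + noise.
    Absorption features sit at 1106 and 1375 nm with depths affine in tp;
    the multiplicative texture field's high-frequency amplitude is also
    affine in tp, so detail sub-band energies of band images carry signal.
    Noise SD is inflated fivefold outside 944–1688 nm, motivating the
    spectral crop.
    """

    height: int = 64
    width: int = 64
    wl_start: float = 908.0
    wl_step: float = 2.0
    n_bands: int = 397
    absorption_centers: tuple[float, float] = (1106.0, 1375.0)
    absorption_widths: tuple[float, float] = (12.0, 18.0)
    depth_base: tuple[float, float] = (0.05, 0.04)
    depth_slope: tuple[float, float] = (0.004, 0.003)
    depth_noise_rel: float = 0.12
    texture_base: float = 0.010
    texture_slope: float = 0.0020
    texture_noise_rel: float = 0.16
    texture_smooth_sigma: float = 1.5
    noise_sd: float = 0.004
    noise_outside_factor: float = 5.0
    clean_range_nm: tuple[float, float] = (944.0, 1688.0)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.wl_start + self.wl_step * np.arange(self.n_bands)


def _baseline_reflectance(wl: np.ndarray) -> np.ndarray:
    return 0.55 + 0.08 * np.cos((wl - 1300.0) / 250.0)


def simulate_cube(
    tp: float,
    variety: VarietySpec | str,
    rng: np.random.Generator,
    config: CubeSimConfig | None = None,
    texture: bool = True,
    noise: bool = True,
) -> SpectralCube:
    """Simulate one reflectance cube for a sample with polyphenol ``tp`` %."""
    if tp <= 0:
        raise ValueError("tp must be positive")
    cfg = config or CubeSimConfig()
    wl = cfg.wavelengths
    spectrum = _baseline_reflectance(wl)
    for c, w, b, s in zip(
        cfg.absorption_centers, cfg.absorption_widths, cfg.depth_base, cfg.depth_slope
    ):
        depth = (b + s * tp) * (1.0 + cfg.depth_noise_rel * rng.standard_normal())
        spectrum = spectrum - depth * np.exp(-0.5 * ((wl - c) / w) ** 2)

    if texture:
        amp = (cfg.texture_base + cfg.texture_slope * tp) * (
            1.0 + cfg.texture_noise_rel * rng.standard_normal()
        )
        white = rng.standard_normal((cfg.height, cfg.width))
        fieldxy = ndimage.gaussian_filter(white, cfg.texture_smooth_sigma, mode="wrap")
        fieldxy = (fieldxy - fieldxy.mean()) / fieldxy.std()
        tex = 1.0 + amp * fieldxy
    else:
        tex = np.ones((cfg.height, cfg.width))

    data = tex[:, :, None].astype(np.float32) * spectrum.astype(np.float32)[None, None, :]
    if noise:
        low, high = cfg.clean_range_nm
        sd = np.where(
            (wl < low) | (wl > high),
            cfg.noise_sd * cfg.noise_outside_factor,
            cfg.noise_sd,
        ).astype(np.float32)
        data = data + sd[None, None, :] * rng.standard_normal(
            data.shape, dtype=np.float32
        )
    np.clip(data, 0.0, 1.0, out=data)
    return SpectralCube(data, wl)


# ---------------------------------------------------------------------------
# Whole-dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSample:
    """One paired synthetic observation (truth + both sensor modalities).

    ``cube_seed`` allows the (large) cube to be regenerated on demand
    instead of being held in memory.
    """

    sample_id: str
    variety: str
    tp_true: float
    enose: ENoseRecord
    cube_seed: np.random.SeedSequence
    cube_config: CubeSimConfig = field(default_factory=CubeSimConfig)

    def cube(self) -> SpectralCube:
        rng = np.random.Generator(np.random.PCG64(self.cube_seed))
        return simulate_cube(self.tp_true, self.variety, rng, self.cube_config)


def simulate_dataset(
    seed: int,
    varieties: list[VarietySpec] | None = None,
    enose_config: EnoseSimConfig | None = None,
    cube_config: CubeSimConfig | None = None,
) -> list[SyntheticSample]:
    """Generate the full paired dataset (default: the 110-sample design).

    Deterministic: the same seed yields a byte-identical dataset. Sample
    ids are ``<variety index>-<replicate index>``, e.g. ``v04-07``.
    """
    varieties = varieties if varieties is not None else default_variety_table()
    cube_config = cube_config or CubeSimConfig()
    root = np.random.SeedSequence(seed)
    samples: list[SyntheticSample] = []
    for vi, spec in enumerate(varieties):
        for k in range(spec.n):
            child = root.spawn(1)[0]
            tp_seq, enose_seq, cube_seq = child.spawn(3)
            tp = draw_tp(spec, np.random.Generator(np.random.PCG64(tp_seq)))
            sid = f"v{vi:02d}-{k:02d}"
            enose = simulate_enose(
                tp, spec, np.random.Generator(np.random.PCG64(enose_seq)),
                sample_id=sid, config=enose_config,
            )
            samples.append(
                SyntheticSample(sid, spec.name, tp, enose, cube_seq, cube_config)
            )
    return samples
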