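"""End-to-end orchestration: dataset -> features -> selection -> models.

This is the programmatic equivalent of running the CLI stages in order
and is what the acceptance script and recovery tests drive. Cubes are
regenerated lazily from per-sample seeds, so only one 50 x 50 ROI crop
is held per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable, TARGET_COLUMN
from .enose import extract_enose_features
from .hsi import (
    crop_spectrum,
    extract_roi,
    extract_roi_spectrum,
    spa_select,
    wavelet_subband_features,
)
from .model import (
    ModelConfig,
    SplitPlan,
    evaluate,
    fast_grid,
    minmax_fit_apply,
    stratified_split,
    train_model,
)
from .select import correlation_select_hsi, fuse, importance_select_enose
from .simulate import SyntheticSample, simulate_dataset

log = logging.getLogger(__name__)


def enose_feature_table(samples: list[SyntheticSample], t0: int = 55) -> FeatureTable:
    """62-column E-nose feature table (60 time-domain + WM + WA)."""
    rows = {s.sample_id: extract_enose_features(s.enose, t0=t0) for s in samples}
    df = pd.DataFrame.from_dict(rows, orient="index")
    target = pd.Series({s.sample_id: s.tp_true for s in samples}, name=TARGET_COLUMN)
    return FeatureTable(df, target)


def hsi_feature_table(
    samples: list[SyntheticSample],
    roi_size: int = 50,
    crop_range: tuple[float, float] = (944.0, 1688.0),
    wavelengths: tuple[float, float] | None = None,
    spa_ids: list[str] | None = None,
) -> tuple[FeatureTable, tuple[float, float]]:
    """24-column HSI feature table, plus the feature wavelengths used.

    If ``wavelengths`` is None they are derived by SPA on the cropped ROI
    spectra (restricted to ``spa_ids`` samples if given, e.g. the
    calibration set, to avoid leakage).
    """
    spectra, rois = [], []
    for s in samples:
        cube = s.cube()
        crop_mask = (cube.wavelengths >= crop_range[0]) & (
            cube.wavelengths <= crop_range[1]
        )
        spectra.append(crop_spectrum(extract_roi_spectrum(cube, roi_size), *crop_range))
        rois.append(extract_roi(cube, roi_size)[:, :, crop_mask])
    wl_axis = spectra[0].wavelengths
    tp = np.array([s.tp_true for s in samples])

    if wavelengths is None:
        if spa_ids is not None:
            idx = [i for i, s in enumerate(samples) if s.sample_id in set(spa_ids)]
        else:
            idx = list(range(len(samples)))
        X = np.vstack([spectra[i].reflectance for i in idx])
        chosen = spa_select(X, tp[idx], wl_axis, k=2)
        wavelengths = (float(chosen[0]), float(chosen[1]))

    band_idx = [int(np.argmin(np.abs(wl_axis - w))) for w in wavelengths]
    rows = {}
    for s, roi in zip(samples, rois):
        feats = {}
        for b, bi in enumerate(band_idx, start=1):
            for key, val in wavelet_subband_features(roi[:, :, bi]).items():
                feats[f"B{b}_{key}"] = val
        rows[s.sample_id] = feats
    df = pd.DataFrame.from_dict(rows, orient="index")
    target = pd.Series({s.sample_id: s.tp_true for s in samples}, name=TARGET_COLUMN)
    return FeatureTable(df, target), wavelengths


@dataclass
class PipelineResult:
    """Everything one end-to-end run produces."""

    split: SplitPlan
    enose_table: FeatureTable
    hsi_table: FeatureTable
    feature_wavelengths: tuple[float, float]
    enose_selected: list[str]
    hsi_selected: list[str]
    fused: list[str]
    reports: dict[tuple[str, str], object] = field(default_factory=dict)
    # keyed (algorithm, feature_set) -> EvaluationReport


def run_pipeline(
    seed: int,
    algorithms: tuple[str, ...] = ("gridsvr", "rf", "xgboost"),
    feature_sets: tuple[str, ...] = ("enose", "hsi", "fusion"),
    samples: list[SyntheticSample] | None = None,
    grids: str = "fast",
    t0: int = 55,
) -> PipelineResult:
    """Simulate (or take) a dataset and run the full evaluation.

    ``grids``: "fast" uses the coarsened search ladders, "default" the
    full ones. Selection and normalization statistics are fit on the
    calibration set only.
    """
    if samples is None:
        samples = simulate_dataset(seed)
    enose_tbl = enose_feature_table(samples, t0=t0)
    split = stratified_split(
        [s.sample_id for s in samples], [s.variety for s in samples], seed
    )
    cal_ids, val_ids = list(split.calibration_ids), list(split.validation_ids)
    hsi_tbl, wavelengths = hsi_feature_table(samples, spa_ids=cal_ids)

    time_domain = enose_tbl.subset_features(
        [n for n in enose_tbl.feature_names if n not in ("WM", "WA")]
    )
    enose_sel = importance_select_enose(time_domain.subset_samples(cal_ids), seed=seed)
    hsi_sel = correlation_select_hsi(hsi_tbl.subset_samples(cal_ids))
    fused_names = fuse(enose_sel, hsi_sel)
    enose_names = list(enose_sel.retained) + ["WM", "WA"]

    full = enose_tbl.hstack(
        FeatureTable(hsi_tbl.features, None)
    )
    full = FeatureTable(full.features, enose_tbl.target)
    tables = {
        "enose": enose_names,
        "hsi": list(hsi_sel.retained),
        "fusion": fused_names,
    }

    result = PipelineResult(
        split=split,
        enose_table=enose_tbl,
        hsi_table=hsi_tbl,
        feature_wavelengths=wavelengths,
        enose_selected=enose_sel.retained,
        hsi_selected=list(hsi_sel.retained),
        fused=fused_names,
    )
    grid_fn = fast_grid if grids == "fast" else (lambda _: {})
    for fset in feature_sets:
        sub = full.subset_features(tables[fset])
        cal = sub.subset_samples(cal_ids)
        val = sub.subset_samples(val_ids)
        cal_n, val_n, _ = minmax_fit_apply(cal, val)
        for algo in algorithms:
            cfg = ModelConfig(algorithm=algo, grid=grid_fn(algo), seed=seed)
            model = train_model(cfg, cal_n)
            result.reports[(algo, fset)] = evaluate(model, cal_n, val_n, fset)
            rep = result.reports[(algo, fset)]
            log.info(
                "%s/%s: cal R2=%.3f val R2=%.3f RMSE=%.3f",
                algo, fset, rep.calibration.r2, rep.validation.r2,
                rep.validation.rmse,
            )
    return result


def fusion_recovery(
    seeds: list[int] | tuple[int, ...],
    algorithms: tuple[str, ...] = ("gridsvr", "rf", "xgboost"),
) -> pd.DataFrame:
    """Validation R^2 of fused vs HSI-only features over seeded datasets.

    One row per (seed, algorithm) with columns ``r2_hsi``, ``r2_fusion``
    and ``fusion_wins``; used to check that multisensor fusion improves
    the estimate under the default generator conditions.
    """
    rows = []
    for seed in seeds:
        res = run_pipeline(seed, algorithms=algorithms, feature_sets=("hsi", "fusion"))
        for algo in algorithms:
            r_h = res.reports[(algo, "hsi")].validation.r2
            r_f = res.reports[(algo, "fusion")].validation.r2
            rows.append(
                {"seed": seed, "algorithm": algo, "r2_hsi": r_h,
                 "r2_fusion": r_f, "fusion_wins": r_f > r_h}
            )
    return pd.DataFrame(rows)
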