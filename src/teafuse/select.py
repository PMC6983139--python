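"""Feature selection and fusion.

Two selection rules, matching the study design:

* E-nose time-domain features — per feature family (VAR, INV, RSAV, ADV,
  KURT, SKEW) a gradient-boosted-tree regressor is fit on that family's
  ten sensor features and each feature is scored by its split-occurrence
  count (F-score); the top 30% of sensors per family (ceil(0.3*10) = 3)
  are retained, 18 features in all. The two CWT summaries WM and WA
  bypass selection and are always appended, giving 20 E-nose variables.
* HSI wavelet features — Pearson correlation of each of the 24 features
  with polyphenol content; the top 25% by |r| (round(0.25*24) = 6) are
  retained.

Fusion is the ordered concatenation E-nose(20) then HSI(6) -> 26.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from xgboost import XGBRegressor

from .containers import FeatureTable, SENSOR_KEYS, SelectionResult
from .enose import FAMILIES

log = logging.getLogger(__name__)

CWT_SUMMARY_NAMES: tuple[str, str] = ("WM", "WA")


def _family_importance(
    X: np.ndarray, y: np.ndarray, names: list[str], seed: int
) -> dict[str, float]:
    """Split-count importance of each feature from one boosted ensemble."""
    model = XGBRegressor(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.3,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
    )
    model.fit(X, y)
    raw = model.get_booster().get_score(importance_type="weight")
    return {name: float(raw.get(f"f{j}", 0.0)) for j, name in enumerate(names)}


def importance_select_enose(
    table: FeatureTable, fraction: float = 0.30, seed: int = 0
) -> SelectionResult:
    """Retain the top-fraction sensors per time-domain family by F-score.

    With the default 30% this keeps ceil(0.3*10) = 3 sensors per family,
    18 features in total. Ties break by sensor order f0..f9.
    """
    if table.target is None:
        raise ValueError("importance selection needs the polyphenol target")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    y = table.target.to_numpy(dtype=float)
    n_keep = math.ceil(fraction * len(SENSOR_KEYS))
    scores: dict[str, float] = {}
    retained: list[str] = []
    for fam in FAMILIES:
        names = [f"{fam}_{key}" for key in SENSOR_KEYS]
        missing = [n for n in names if n not in table.features.columns]
        if missing:
            raise ValueError(f"family {fam}: missing columns {missing}")
        X = table.features.loc[:, names].to_numpy(dtype=float)
        fam_scores = _family_importance(X, y, names, seed)
        scores.update(fam_scores)
        order = sorted(names, key=lambda n: (-fam_scores[n], names.index(n)))
        retained.extend(order[:n_keep])
    return SelectionResult("importance", scores, retained, fraction)


def correlation_select_hsi(
    table: FeatureTable, fraction: float = 0.25
) -> SelectionResult:
    """Retain the top-fraction features by |Pearson r| with the target.

    Zero-variance features get score 0 with a warning. Retention count is
    round-half-even(fraction * pool size); ties break by name order.
    """
    if table.target is None:
        raise ValueError("correlation selection needs the polyphenol target")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    y = table.target.to_numpy(dtype=float)
    names = table.feature_names
    scores: dict[str, float] = {}
    for name in names:
        x = table.features[name].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"feature {name!r} has zero variance; correlation set to 0")
            scores[name] = 0.0
        else:
            scores[name] = float(np.corrcoef(x, y)[0, 1])
    n_keep = round(fraction * len(names))
    order = sorted(names, key=lambda n: (-abs(scores[n]), names.index(n)))
    return SelectionResult("correlation", scores, order[:n_keep], fraction)


def fuse(
    enose_sel: SelectionResult,
    hsi_sel: SelectionResult,
    cwt_names: tuple[str, str] = CWT_SUMMARY_NAMES,
) -> list[str]:
    """Fused feature order: selected E-nose + WM/WA, then selected HSI."""
    enose_names = list(enose_sel.retained) + list(cwt_names)
    fused = enose_names + list(hsi_sel.retained)
    if len(set(fused)) != len(fused):
        clash = [n for n in fused if fused.count(n) > 1]
        raise ValueError(f"feature name collision in fusion: {sorted(set(clash))}")
    if not hsi_sel.retained:
        warnings.warn("HSI selection is empty; fusion contains E-nose features only")
    return fused
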