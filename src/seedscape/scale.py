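"""Scale-of-effect selection by leave-two-out cross-validated regression.

For one biological response (a diversity metric over patches) and one
landscape metric, a simple linear model is fitted at each of the 13 buffer
radii and scored with the leave-two-out cross-validated coefficient of
determination::

    R2_CV = 1 - SS_cv / [ (1/n) * sum_i (y_i - ybar)^2 ]

where every one of the C(n, 2) patch pairs is held out in turn, the model is
refitted on the remaining n - 2 patches, and SS_cv is the mean squared
prediction error over all held-out observations (2·C(n, 2) of them; the
per-split-sum alternative is available via ``normalization="split"``).
R2_CV is at most 1 (perfect out-of-sample prediction) and unbounded below
(negative = worse than predicting the mean). The radius with the highest
R2_CV is the scale of effect; uncertainty around it is quantified by
resampling patches with replacement and re-selecting.

The C(n, 2) refits use closed-form downdates of the simple-regression
sufficient statistics, vectorized over all pairs, so bootstrap resampling
(B = 1000) over 13 radii stays cheap.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from itertools import combinations

import numpy as np
import pandas as pd

from .types import (
    BootstrapScaleResult,
    ConfigError,
    DegeneratePredictorError,
    DEFAULT_RADII,
    ScaleProfile,
    UndefinedR2Error,
)

__all__ = [
    "fit_simple_lm",
    "r2_cv_leave_two_out",
    "scale_profile",
    "bootstrap_scale",
    "sweep_profiles",
]

_MIN_COMPLETE = 4  # fewer complete pairs than this and a radius is unusable


def fit_simple_lm(
    y: Sequence[float], x: Sequence[float]
) -> tuple[float, float, np.ndarray]:
    """Ordinary least squares of y on a single predictor.

    Returns (intercept, slope, residuals).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ConfigError("y and x must be 1-D and aligned")
    n = len(y)
    if n < 3:
        raise ConfigError("need at least 3 observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        raise DegeneratePredictorError("constant predictor")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    residuals = y - (intercept + slope * x)
    return intercept, slope, residuals


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def r2_cv_leave_two_out(
    y: Sequence[float],
    x: Sequence[float],
    normalization: str = "observation",
) -> float:
    """Leave-two-out cross-validated R^2 of the simple linear model.

    ``normalization="observation"`` (default) divides the accumulated
    squared prediction error by the number of held-out predictions
    (2·C(n,2)), making it commensurate with the (1/n)Σ(y−ȳ)² denominator;
    ``"split"`` divides the per-split error *sums* by C(n,2).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ConfigError("y and x must be 1-D and aligned")
    n = len(y)
    if n < _MIN_COMPLETE:
        raise ConfigError(f"need at least {_MIN_COMPLETE} observations")
    if normalization not in ("observation", "split"):
        raise ConfigError(f"unknown normalization {normalization!r}")
    denom = np.sum((y - y.mean()) ** 2) / n
    if denom <= 0:
        raise UndefinedR2Error("response has zero variance")

    iu, ju = _pair_indices(n)
    m = n - 2
    sx = x.sum() - x[iu] - x[ju]
    sy = y.sum() - y[iu] - y[ju]
    sxx = (x * x).sum() - x[iu] ** 2 - x[ju] ** 2
    sxy = (x * y).sum() - x[iu] * y[iu] - x[ju] * y[ju]
    det = m * sxx - sx * sx
    if np.any(det <= 1e-12 * np.maximum(m * sxx, 1e-300)):
        raise DegeneratePredictorError("constant predictor on a calibration split")
    slope = (m * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / m
    err = (y[iu] - intercept - slope * x[iu]) ** 2
    err += (y[ju] - intercept - slope * x[ju]) ** 2
    n_splits = len(iu)
    if normalization == "observation":
        ss_cv = err.sum() / (2 * n_splits)
    else:
        ss_cv = err.sum() / n_splits
    return float(1.0 - ss_cv / denom)


def _r2cv_column(y: np.ndarray, x: np.ndarray, normalization: str) -> float:
    """r2_cv on one column, mapping degeneracies to NaN (radius invalid)."""
    try:
        return r2_cv_leave_two_out(y, x, normalization)
    except (DegeneratePredictorError, UndefinedR2Error, ConfigError):
        return float("nan")


def _select_radius(r2cv: Mapping[float, float]) -> float:
    """Argmax radius; ties broken toward the smallest radius."""
    valid = [(r, v) for r, v in r2cv.items() if np.isfinite(v)]
    if not valid:
        raise UndefinedR2Error("no radius yielded a valid R2_CV")
    best = max(v for _, v in valid)
    return min(r for r, v in valid if v == best)


def _predictor_matrix(
    metric_table: pd.DataFrame, predictor: str, radii: Sequence[float]
) -> pd.DataFrame:
    """Patch x radius matrix of one metric, NaN where missing."""
    sub = metric_table[metric_table["metric"] == predictor]
    if sub.empty:
        raise ConfigError(f"metric table has no rows for predictor {predictor!r}")
    wide = sub.pivot_table(
        index="patch_id", columns="radius_m", values="value", aggfunc="first",
        dropna=False,
    )
    missing = [r for r in radii if r not in wide.columns]
    if missing:
        raise ConfigError(f"predictor {predictor!r} lacks radii {missing}")
    return wide.loc[:, list(radii)]


def scale_profile(
    response_values: pd.Series,
    metric_table: pd.DataFrame,
    predictor: str,
    response_name: str | None = None,
    radii: Sequence[float] = DEFAULT_RADII,
    normalization: str = "observation",
) -> ScaleProfile:
    """R2_CV of one response against one metric at every radius.

    ``response_values`` is indexed by patch_id; ``metric_table`` is the long
    table (patch_id, radius_m, metric, value). Patches with a missing
    predictor value at a radius (e.g. PI in a single-patch buffer) are
    dropped at that radius only; a radius with fewer than four complete
    pairs is marked NaN and excluded from the argmax.
    """
    wide = _predictor_matrix(metric_table, predictor, radii)
    common = [p for p in wide.index if p in response_values.index]
    if len(common) < _MIN_COMPLETE:
        raise ConfigError("fewer than 4 patches shared by response and metrics")
    y_all = response_values.loc[common].to_numpy(dtype=float)
    X = wide.loc[common].to_numpy(dtype=float)
    r2cv: dict[float, float] = {}
    n_eff: dict[float, int] = {}
    for j, radius in enumerate(radii):
        xj = X[:, j]
        ok = np.isfinite(xj) & np.isfinite(y_all)
        n_eff[float(radius)] = int(ok.sum())
        if ok.sum() < _MIN_COMPLETE:
            r2cv[float(radius)] = float("nan")
            continue
        r2cv[float(radius)] = _r2cv_column(y_all[ok], xj[ok], normalization)
    selected = _select_radius(r2cv)
    return ScaleProfile(
        response=response_name or getattr(response_values, "name", "") or "response",
        predictor=predictor,
        r2cv=r2cv,
        n_effective=n_eff,
        selected_radius=selected,
        n=len(common),
    )


def bootstrap_scale(
    response_values: pd.Series,
    metric_table: pd.DataFrame,
    predictor: str,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    radii: Sequence[float] = DEFAULT_RADII,
    normalization: str = "observation",
    response_name: str | None = None,
) -> BootstrapScaleResult:
    """Bootstrap distribution of the selected scale of effect.

    Patches are resampled with replacement B times; the scale of effect is
    re-selected on each resample and tallied per radius. Resamples on which
    no radius yields a valid R2_CV (e.g. a constant response) are redrawn so
    the counts always sum to B.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    rng = np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    wide = _predictor_matrix(metric_table, predictor, radii)
    common = [p for p in wide.index if p in response_values.index]
    y_all = response_values.loc[common].to_numpy(dtype=float)
    X = wide.loc[common].to_numpy(dtype=float)
    n = len(common)
    radii_f = [float(r) for r in radii]
    counts = {r: 0 for r in radii_f}
    selections = np.empty(B)
    b = 0
    guard = 0
    while b < B:
        guard += 1
        if guard > 100 * B:
            raise UndefinedR2Error("bootstrap cannot find valid resamples")
        idx = rng.integers(0, n, size=n)
        yb, Xb = y_all[idx], X[idx]
        r2cv = {}
        for j, radius in enumerate(radii_f):
            xj = Xb[:, j]
            ok = np.isfinite(xj) & np.isfinite(yb)
            if ok.sum() < _MIN_COMPLETE:
                r2cv[radius] = float("nan")
                continue
            r2cv[radius] = _r2cv_column(yb[ok], xj[ok], normalization)
        try:
            sel = _select_radius(r2cv)
        except UndefinedR2Error:
            continue  # redraw
        counts[sel] += 1
        selections[b] = sel
        b += 1
    return BootstrapScaleResult(
        response=response_name or getattr(response_values, "name", "") or "response",
        predictor=predictor,
        counts=counts,
        B=B,
        mean_radius=float(selections.mean()),
        sd_radius=float(selections.std(ddof=1)) if B > 1 else 0.0,
        seed=int(seed_val),
    )


def sweep_profiles(
    responses: Mapping[str, pd.Series],
    metric_table: pd.DataFrame,
    predictors: Iterable[str],
    radii: Sequence[float] = DEFAULT_RADII,
    normalization: str = "observation",
) -> list[ScaleProfile]:
    """Scale profiles for every response x predictor combination.

    The full study sweep (6 diversity responses x 6 landscape metrics x 13
    radii) fits 468 single-predictor models.
    """
    profiles = []
    for rname, series in responses.items():
        for predictor in predictors:
            profiles.append(
                scale_profile(
                    series,
                    metric_table,
                    predictor,
                    response_name=rname,
                    radii=radii,
                    normalization=normalization,
                )
            )
    return profiles
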