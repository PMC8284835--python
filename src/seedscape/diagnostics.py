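"""Spatial and distributional screening diagnostics.

These mirror the screens a multi-scale landscape study runs before trusting
its regressions: a Clark–Evans test that the sampling sites are not
spatially clustered, Mantel-style tests that neither the responses nor the
model residuals are spatially autocorrelated with inter-site distance, and
Shapiro–Wilk normality checks on the variables. They are reports, not
gates: nothing downstream transforms data because a screen failed.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy import stats

from .types import ConfigError, SeedscapeError

__all__ = ["clark_evans", "distance_screen", "shapiro_screen", "pairwise_distances"]


class DegenerateSampleError(SeedscapeError):
    """A constant sample where variation is required."""


def pairwise_distances(points: Sequence[tuple[float, float]]) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def clark_evans(
    centres: Sequence[tuple[float, float]], study_area: float
) -> tuple[float, float]:
    """Clark–Evans aggregation statistic R with a normal-approximation p.

    R = mean observed nearest-neighbour distance over its expectation under
    complete spatial randomness (0.5/sqrt(density)). R < 1 indicates
    clustering, R > 1 overdispersion; the p-value is two-sided using the
    classical standard error ``0.26136 / sqrt(n * density)``.
    """
    pts = np.asarray(centres, dtype=float)
    n = len(pts)
    if n < 2:
        raise ConfigError("need at least 2 points")
    if study_area <= 0:
        raise ConfigError("study area must be positive")
    d = pairwise_distances(pts)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    lam = n / study_area
    expected = 0.5 / np.sqrt(lam)
    r = float(nn.mean() / expected)
    se = 0.26136 / np.sqrt(n * lam)
    z = (nn.mean() - expected) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return r, p


def distance_screen(
    site_distances: np.ndarray,
    values: Sequence[float],
    permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel-style spatial-autocorrelation screen.

    Pearson correlation between the inter-site distance matrix and the
    pairwise absolute-difference matrix of ``values`` (off-diagonal upper
    triangle), with a permutation p-value obtained by shuffling site labels.
    """
    d = np.asarray(site_distances, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ConfigError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ConfigError("distance matrix must be symmetric")
    if len(v) != d.shape[0]:
        raise ConfigError("values must align with the distance matrix")
    if np.allclose(v, v[0]):
        raise DegenerateSampleError("constant values: correlation undefined")
    if permutations < 1:
        raise ConfigError("need at least 1 permutation")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(len(v), k=1)
    dv = np.abs(v[:, None] - v[None, :])
    r_obs = float(stats.pearsonr(d[iu], dv[iu])[0])
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(len(v))
        dv_p = dv[np.ix_(perm, perm)]
        r_p = stats.pearsonr(d[iu], dv_p[iu])[0]
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (permutations + 1)
    return r_obs, float(p)


def shapiro_screen(values: Sequence[float]) -> tuple[float, float, bool]:
    """Shapiro–Wilk normality test; returns (W, p, pass at alpha = 0.05)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise ConfigError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.allclose(v, v[0]):
        raise DegenerateSampleError("constant sample")
    w, p = stats.shapiro(v)
    return float(w), float(p), bool(p >= 0.05)
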