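"""Hill-number diversity decomposition and sample coverage.

Diversity is expressed in effective numbers of species (Hill numbers ``qD``)
and decomposed multiplicatively per patch: gamma (patch level) over alpha
(plot level) gives beta, the effective number of completely distinct plot
assemblages.

Conventions
-----------
* ``p_ij`` is the relative abundance of species *i* within plot *j* (each
  plot's counts normalized by that plot's own total), and plots receive equal
  weight; ``p̄_i`` is the arithmetic mean of ``p_ij`` over the N plots.
* gamma of order q is ``(Σ_i p̄_i^q)^{1/(1-q)}``, with the q → 1 limit
  ``exp(−Σ p̄_i ln p̄_i)``.
* alpha of order q is ``[(1/N) Σ_j Σ_i p_ij^q]^{1/(1-q)}``, with the q → 1
  limit ``exp{−(1/N) Σ_j Σ_i p_ij ln p_ij}``.
* beta = gamma / alpha, bounded by [1, N]: 1 when all plot assemblages are
  identical, N when the N plots share no species.
* ``0·ln 0 ≡ 0`` throughout; q is restricted to {0, 1, 2} at the block level
  (richness, exponential Shannon, inverse Simpson).

Orders 0/1/2 are read ecologically as diversity of *all*, *typical* and
*dominant* species respectively: q = 0 ignores abundances entirely while
q = 2 is dominated by the most abundant species.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence

import numpy as np

from .types import (
    CommunityBlock,
    CoverageRecord,
    DiversityRecord,
    EmptyCommunityError,
    EmptyPlotError,
    UnsupportedOrderError,
)

__all__ = [
    "filter_animal_dispersed",
    "effective_number",
    "hill_gamma",
    "hill_alpha",
    "hill_beta",
    "sample_coverage",
    "diversity_table",
    "coverage_table",
]

_SUPPORTED_ORDERS = (0, 1, 2)


def filter_animal_dispersed(block: CommunityBlock) -> CommunityBlock:
    """Restrict a community block to its animal-dispersed species columns.

    The plot count is unchanged. Raises :class:`EmptyCommunityError` when no
    species is flagged animal-dispersed (analyses are based on animal-dispersed
    species only, so an all-abiotic block has nothing to contribute).
    """
    keep = np.asarray(block.dispersal, dtype=bool)
    if not keep.any():
        raise EmptyCommunityError(
            f"patch {block.patch_id}: no animal-dispersed species"
        )
    sub = block.abundance[:, keep]
    if sub.sum() == 0:
        raise EmptyCommunityError(
            f"patch {block.patch_id}: animal-dispersed species have no individuals"
        )
    labels = tuple(s for s, k in zip(block.species_labels, keep) if k)
    return CommunityBlock(
        patch_id=block.patch_id,
        abundance=sub,
        species_labels=labels,
        dispersal=np.ones(sub.shape[1], dtype=bool),
        centre=block.centre,
    )


def effective_number(weights: Sequence[float] | np.ndarray, q: float) -> float:
    """Hill number of arbitrary real order from a relative-abundance vector.

    ``weights`` need not be normalized; zeros are ignored (0·ln 0 ≡ 0). The
    general formula ``(Σ p_i^q)^{1/(1−q)}`` is used for q ≠ 1 and the Shannon
    limit for q = 1. Exposed with real ``q`` so the continuity of the family
    at q = 1 can be checked; block-level functions restrict q to {0, 1, 2}.
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise EmptyCommunityError("no positive abundances")
    p = w / w.sum()
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _plot_relative_abundances(block: CommunityBlock) -> np.ndarray:
    ab = block.abundance.astype(float)
    totals = ab.sum(axis=1)
    if (totals == 0).any():
        empty = int(np.flatnonzero(totals == 0)[0])
        raise EmptyPlotError(
            f"patch {block.patch_id}: plot {empty} has no individuals; "
            "relative abundances are undefined"
        )
    return ab / totals[:, None]


def _check_order(q: int) -> None:
    if q not in _SUPPORTED_ORDERS:
        raise UnsupportedOrderError(f"q must be one of {_SUPPORTED_ORDERS}, got {q}")


def hill_gamma(block: CommunityBlock, q: int) -> float:
    """Patch-level (gamma) Hill number of order q ∈ {0, 1, 2}.

    Uses the mean over plots of within-plot relative abundances (p̄_i), i.e.
    plots are weighted equally regardless of how many individuals they hold.
    """
    _check_order(q)
    p = _plot_relative_abundances(block)
    p_bar = p.mean(axis=0)
    return effective_number(p_bar, q)


def hill_alpha(block: CommunityBlock, q: int) -> float:
    """Plot-level (alpha) Hill number of order q ∈ {0, 1, 2}."""
    _check_order(q)
    p = _plot_relative_abundances(block)
    n = p.shape[0]
    if q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return float(np.exp(-plogp.sum() / n))
    if q == 0:
        # mean plot richness (0^0 must count as 0, not 1)
        return float(np.sum(p > 0) / n)
    # q = 2: inverse of the mean over plots of Simpson concentration.
    return float((np.sum(p**q) / n) ** (1.0 / (1.0 - q)))


def hill_beta(block: CommunityBlock, q: int) -> float:
    """Multiplicative beta diversity gamma/alpha, in [1, N]."""
    return hill_gamma(block, q) / hill_alpha(block, q)


def sample_coverage(pooled_counts: Iterable[int], patch_id: str = "") -> CoverageRecord:
    """Chao–Shen sample-coverage estimate from pooled per-species counts.

    ``Ĉ = 1 − (f1/n)·[(n−1)f1 / ((n−1)f1 + 2f2)]`` where f1 and f2 are the
    singleton and doubleton species counts and n the pooled individuals.
    With no singletons the sample is treated as complete (Ĉ = 1).
    """
    counts = np.asarray(list(pooled_counts), dtype=np.int64)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if n == 0:
        raise EmptyCommunityError(f"patch {patch_id}: all-zero pooled counts")
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f1 == 0:
        coverage = 1.0
    else:
        coverage = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))
    return CoverageRecord(patch_id=patch_id, coverage=coverage, n=n, f1=f1, f2=f2)


def diversity_table(
    blocks: Iterable[CommunityBlock], orders: Sequence[int] = _SUPPORTED_ORDERS
) -> list[DiversityRecord]:
    """One (gamma, alpha, beta) record per patch and per order."""
    blocks = list(blocks)
    if not blocks:
        raise EmptyCommunityError("no community blocks")
    records = []
    for block in blocks:
        for q in orders:
            gamma = hill_gamma(block, q)
            alpha = hill_alpha(block, q)
            records.append(
                DiversityRecord(
                    patch_id=block.patch_id,
                    q=q,
                    gamma=gamma,
                    alpha=alpha,
                    beta=gamma / alpha,
                    n_plots=block.n_plots,
                )
            )
    return records


def coverage_table(blocks: Iterable[CommunityBlock]) -> list[CoverageRecord]:
    """Sample coverage of each patch's pooled (10-plot) sample."""
    return [
        sample_coverage(b.pooled_counts(), patch_id=b.patch_id) for b in blocks
    ]
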