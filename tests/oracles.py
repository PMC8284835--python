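"""Independent oracles used by the test suite.

Each oracle re-derives a quantity from first principles by a different
route than the implementation: arbitrary-precision symbolic evaluation of
the diversity formulas (sympy), brute-force Python enumeration of grid
components/adjacencies/distances, and exhaustive leave-two-out splits
fitted with numpy.polyfit. They are deliberately slow and simple.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import sympy as sp


# ---------------------------------------------------------------- diversity


def hill_oracle(abundance: np.ndarray, q: int) -> tuple[float, float, float]:
    """(gamma, alpha, beta) by exact rational + high-precision evaluation.

    abundance: N plots x S species integer matrix, every plot non-empty.
    """
    ab = [[sp.Integer(int(v)) for v in row] for row in abundance]
    n = len(ab)
    s = len(ab[0])
    totals = [sum(row) for row in ab]
    p = [[ab[j][i] / totals[j] for i in range(s)] for j in range(n)]  # p_ij
    p_bar = [sum(p[j][i] for j in range(n)) / n for i in range(s)]

    if q == 1:
        gamma_expr = sp.exp(
            -sum(pi * sp.log(pi) for pi in p_bar if pi != 0)
        )
        alpha_expr = sp.exp(
            -sp.Rational(1, n)
            * sum(p[j][i] * sp.log(p[j][i]) for j in range(n) for i in range(s) if p[j][i] != 0)
        )
    elif q == 0:
        gamma_expr = sp.Integer(sum(1 for pi in p_bar if pi != 0))
        alpha_expr = sp.Rational(
            sum(1 for j in range(n) for i in range(s) if p[j][i] != 0), n
        )
    else:
        gamma_expr = sum(pi**q for pi in p_bar) ** sp.Rational(1, 1 - q)
        alpha_expr = (
            sp.Rational(1, n) * sum(p[j][i] ** q for j in range(n) for i in range(s))
        ) ** sp.Rational(1, 1 - q)
    gamma = float(sp.N(gamma_expr, 30))
    alpha = float(sp.N(alpha_expr, 30))
    return gamma, alpha, gamma / alpha


# ---------------------------------------------------------------- landscape


def _components(cells: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """8-connected components by flood fill."""
    remaining = set(cells)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in remaining:
                        remaining.remove(nb)
                        comp.add(nb)
                        frontier.append(nb)
        comps.append(comp)
    return comps


def landscape_oracle(
    classes: np.ndarray,
    mask: np.ndarray,
    cell_size: float,
    class_code: int,
    ranking: dict[int, int],
) -> dict[str, float]:
    """PD, AI, PI, EC of one class by exhaustive enumeration."""
    nrows, ncols = classes.shape
    member = {
        (r, c) for r in range(nrows) for c in range(ncols) if mask[r, c]
    }
    focal = {rc for rc in member if classes[rc] == class_code}
    area_ha = len(member) * cell_size**2 / 1e4
    comps = _components(focal)
    out: dict[str, float] = {}
    out["PD"] = len(comps) / area_ha

    # AI: like-adjacencies (rook, single count) / analytic maximum
    g = 0
    for (r, c) in focal:
        for nb in ((r, c + 1), (r + 1, c)):
            if nb in focal:
                g += 1
    a = len(focal)
    if a == 0:
        out["AI"] = float("nan")
    else:
        n_side = int(np.floor(np.sqrt(a)))
        m = a - n_side**2
        if m == 0:
            gmax = 2 * n_side * (n_side - 1)
        elif m <= n_side:
            gmax = 2 * n_side * (n_side - 1) + 2 * m - 1
        else:
            gmax = 2 * n_side * (n_side - 1) + 2 * m - 2
        out["AI"] = 100.0 * g / gmax if gmax > 0 else 0.0

    # PI: mean over components of nearest cell-centre distance to another
    if len(comps) < 2:
        out["PI"] = float("nan")
    else:
        nns = []
        for k, comp in enumerate(comps):
            best = np.inf
            for other_i, other in enumerate(comps):
                if other_i == k:
                    continue
                for (r1, c1) in comp:
                    for (r2, c2) in other:
                        d = cell_size * np.hypot(r1 - r2, c1 - c2)
                        best = min(best, d)
            nns.append(best)
        out["PI"] = float(np.mean(nns))

    # EC: per component, mean rank-gap weight over boundary edges in view
    if not comps:
        out["EC"] = float("nan")
    else:
        span = max(ranking.values()) - min(ranking.values())
        num = 0.0
        den = 0.0
        for comp in comps:
            e_sum, e_cnt = 0.0, 0
            for (r, c) in comp:
                for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if nb in member and nb not in focal:
                        d = abs(ranking[class_code] - ranking[int(classes[nb])]) / span
                        e_sum += d
                        e_cnt += 1
            ec_k = 100.0 * e_sum / e_cnt if e_cnt else 0.0
            num += ec_k * len(comp)
            den += len(comp)
        out["EC"] = num / den
    return out


# -------------------------------------------------------------------- r2cv


def r2cv_oracle(y: np.ndarray, x: np.ndarray, normalization: str = "observation") -> float:
    """Leave-two-out R^2_CV by explicit enumeration + polyfit refits."""
    n = len(y)
    errors = []
    for i, j in combinations(range(n), 2):
        keep = [k for k in range(n) if k not in (i, j)]
        slope, intercept = np.polyfit(x[keep], y[keep], 1)
        errors.append((y[i] - (intercept + slope * x[i])) ** 2)
        errors.append((y[j] - (intercept + slope * x[j])) ** 2)
    n_splits = n * (n - 1) // 2
    if normalization == "observation":
        ss_cv = sum(errors) / (2 * n_splits)
    else:
        ss_cv = sum(errors) / n_splits
    denom = np.sum((y - y.mean()) ** 2) / n
    return 1.0 - ss_cv / denom
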