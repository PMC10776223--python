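"""Independent brute-force reference implementations used only by tests.

Deliberately naive and structured differently from the package: flood-fill
components, full-grid ring scans, dense likelihood grids, exhaustive rank
enumeration. They trade speed for obviousness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- designation

def _cell_centroid(grid, cell):
    r, c = cell
    return (
        grid.origin_x + (c + 0.5) * grid.cell_size,
        grid.origin_y + (r + 0.5) * grid.cell_size,
    )


def _counts(usage, cell):
    u = usage.get(cell)
    return u.n_species, u.n_individuals, u.n_obs


def _better(usage, a, b):
    """True if cell a outranks cell b (species, individuals, obs, lex)."""
    sa, ia, oa = _counts(usage, a)
    sb, ib, ob = _counts(usage, b)
    if (sa, ia, oa) != (sb, ib, ob):
        return (sa, ia, oa) > (sb, ib, ob)
    return a < b


def brute_force_designate(usage, mask, crit):
    """Reference designation: returns (pairs, unpaired) as plain tuples.

    pairs: list of (hotspot_cell, control_cell, azimuth_deg);
    unpaired: list of hotspot cells whose ring was exhausted.
    """
    grid = usage.grid

    # 1. qualification
    cand = set()
    for cell, u in usage.usage.items():
        if (
            u.n_individuals >= crit.min_individuals
            and u.n_species >= crit.min_species
            and mask.eligible[cell]
            and not mask.perch_flag[cell]
        ):
            cand.add(cell)

    # 2. connected components by flood fill
    if crit.connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    reps = []
    for start in sorted(cand):
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for dr, dc in nbrs:
                nb = (cur[0] + dr, cur[1] + dc)
                if nb in cand and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        best = comp[0]
        for cell in comp[1:]:
            if _better(usage, cell, best):
                best = cell
        reps.append(best)

    # 3. rank and greedy spacing
    ranked = []
    remaining = list(reps)
    while remaining:
        best = remaining[0]
        for cell in remaining[1:]:
            if _better(usage, cell, best):
                best = cell
        ranked.append(best)
        remaining.remove(best)
    hotspots = []
    for cell in ranked:
        x, y = _cell_centroid(grid, cell)
        ok = True
        for other in hotspots:
            ox, oy = _cell_centroid(grid, other)
            if math.hypot(x - ox, y - oy) < crit.min_hotspot_spacing:
                ok = False
                break
        if ok:
            hotspots.append(cell)

    # 4. controls: full-grid ring scan, clockwise from north
    taken = list(hotspots)
    pairs = []
    unpaired = []
    for hs in hotspots:
        hx, hy = _cell_centroid(grid, hs)
        ring = []
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                x0 = grid.origin_x + c * grid.cell_size
                y0 = grid.origin_y + r * grid.cell_size
                x1, y1 = x0 + grid.cell_size, y0 + grid.cell_size
                nearest = math.hypot(
                    max(x0 - hx, 0, hx - x1), max(y0 - hy, 0, hy - y1)
                )
                corners = max(
                    math.hypot(hx - cx_, hy - cy_)
                    for cx_ in (x0, x1) for cy_ in (y0, y1)
                )
                if nearest <= crit.control_radius <= corners:
                    mx, my = _cell_centroid(grid, (r, c))
                    az = math.atan2(mx - hx, my - hy) % (2 * math.pi)
                    ring.append((az, math.hypot(mx - hx, my - hy), (r, c)))
        ring.sort()
        chosen = None
        for az, _, cell in ring:
            if not mask.farmland[cell] or mask.perch_flag[cell]:
                continue
            if usage.get(cell).n_obs > crit.max_control_obs:
                continue
            mx, my = _cell_centroid(grid, cell)
            conflict = False
            for other in taken:
                if other == hs:
                    continue
                ox, oy = _cell_centroid(grid, other)
                if math.hypot(mx - ox, my - oy) < crit.min_control_spacing:
                    conflict = True
                    break
            if not conflict:
                chosen = (cell, math.degrees(az))
                break
        if chosen is None:
            unpaired.append(hs)
        else:
            pairs.append((hs, chosen[0], chosen[1]))
            taken.append(chosen[0])
    return pairs, unpaired


# ------------------------------------------------------------------- logistic

def grid_search_logistic(x, y, span=12.0, rounds=6, points=61):
    """Maximum-likelihood logistic fit by iterated dense grid refinement.

    Returns (b0, b1, loglik). Final resolution span/points**?: each round
    shrinks the span to 4 grid steps, reaching well below 1e-5.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def nll(b0, b1):
        eta = b0[..., None] + b1[..., None] * x
        return -(y * eta - np.log1p(np.exp(eta))).sum(axis=-1)

    c0, c1, half = 0.0, 0.0, span
    for _ in range(rounds):
        g0 = np.linspace(c0 - half, c0 + half, points)
        g1 = np.linspace(c1 - half, c1 + half, points)
        B0, B1 = np.meshgrid(g0, g1, indexing="ij")
        vals = nll(B0.ravel(), B1.ravel()).reshape(B0.shape)
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        c0, c1 = g0[i], g1[j]
        half = 4 * (g0[1] - g0[0])
    return c0, c1, -nll(np.array([c0]), np.array([c1]))[0]


def null_loglik(y):
    """Intercept-only binomial log-likelihood in closed form."""
    y = np.asarray(y, float)
    p = y.mean()
    n1 = y.sum()
    n0 = len(y) - n1
    return n1 * math.log(p) + n0 * math.log(1 - p)


# ------------------------------------------------------------------- wilcoxon

def exact_rank_sum(x, y):
    """Exhaustive two-sided rank-sum test (midranks; all assignments).

    Returns (W, p). p = P(|W' - E[W]| >= |W - E[W]|) over all C(n+m, n)
    assignments of the pooled midranks to the x group.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    # midranks
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        ranks[pooled[i]] = mid
        i = j
    all_ranks = [ranks[v] for v in pooled]
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    e_w = n * (len(pooled) + 1) / 2.0
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        w = sum(all_ranks[k] for k in comb)
        total += 1
        if abs(w - e_w) >= abs(w_obs - e_w) - 1e-9:
            extreme += 1
    return w_obs, extreme / total
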