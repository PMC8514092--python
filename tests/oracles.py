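"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the volume oracle is
Monte-Carlo point sampling (no grid), the Pareto oracle is the O(n²)
pairwise dominance definition (no sweep).
"""

import numpy as np


def monte_carlo_buried(structure, center_index, grid, n_points=1_000_000, seed=12345):
    """Monte-Carlo percent-buried estimate; returns (percent, sigma)."""
    rng = np.random.default_rng(seed)
    center = structure.coords[center_index]
    dirs = rng.normal(size=(n_points, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = grid.sphere_radius * rng.uniform(size=n_points) ** (1.0 / 3.0)
    pts = center + dirs * radii[:, None]
    hit = np.zeros(n_points, dtype=bool)
    for i, (sym, pos) in enumerate(zip(structure.symbols, structure.coords)):
        if i == center_index and not grid.include_center_atom:
            continue
        if sym == "H" and not grid.include_hydrogens:
            continue
        r = grid.radii[sym]
        hit |= np.einsum("ij,ij->i", pts - pos, pts - pos) <= r * r
    p = hit.mean()
    sigma = 100.0 * np.sqrt(p * (1.0 - p) / n_points)
    return 100.0 * p, sigma


def brute_force_front(records):
    """Set of record positions that are non-dominated, by direct definition."""
    v = np.array([r.percent_buried for r in records])
    s = np.array([r.max_fraction for r in records])
    keep = []
    for i in range(len(records)):
        dominated = np.any(
            (v >= v[i]) & (s <= s[i]) & ((v > v[i]) | (s < s[i]))
        )
        if not dominated:
            keep.append(i)
    return set(keep)
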