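"""Environment maps with controlled spatial autocorrelation.

Landscapes are square grids of phenotypic optima on [0, 1], one value per
deme.  Surfaces are generated with the midpoint-displacement (diamond-square)
algorithm, whose roughness parameter ``h`` controls how quickly displacement
amplitudes decay across scales and hence the spatial autocorrelation of the
result.  Because ``h`` does not map analytically onto Moran's I, maps with a
prescribed autocorrelation are obtained by calibrating ``h`` with bisection
and then rejection-sampling surfaces until the achieved Moran's I falls
within tolerance of the target and the landscape mean lies in (0.4, 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandscapeMap",
    "SpatialWeights",
    "rook_weights",
    "morans_i",
    "midpoint_displacement",
    "generate_map",
    "series_targets",
    "make_map_series",
]


@dataclass(frozen=True)
class SpatialWeights:
    """Binary spatial weights as an explicit list of ordered cell pairs.

    ``pairs`` holds ordered index pairs (i, j) over flattened (row-major)
    grid cells with weight 1; all other pairs have weight 0.  Symmetric by
    construction, with no self-pairs.
    """

    n_cells: int
    pairs: np.ndarray  # (n_pairs, 2) int array of ordered (i, j)

    @property
    def total_weight(self) -> float:
        return float(len(self.pairs))


def rook_weights(n_rows: int, n_cols: int) -> SpatialWeights:
    """Binary rook-adjacency weights (4 cardinal neighbours) for a grid.

    Corner cells have 2 neighbours, non-corner edge cells 3, interior
    cells 4.  Weights are *not* row-standardized.
    """
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    pairs = []
    for (a, b) in [(idx[:, :-1], idx[:, 1:]), (idx[:-1, :], idx[1:, :])]:
        a, b = a.ravel(), b.ravel()
        pairs.append(np.column_stack([a, b]))
        pairs.append(np.column_stack([b, a]))
    return SpatialWeights(n_rows * n_cols, np.concatenate(pairs))


def morans_i(values: np.ndarray, weights: SpatialWeights | None = None) -> float:
    """Moran's I for a grid of values under binary spatial weights.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with W the sum of all weights.  Defaults to rook adjacency on the grid
    shape of ``values``.

    Raises
    ------
    ValueError
        If the values are all identical (zero variance) or the grid has
        fewer than two cells.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("Moran's I requires at least 2 cells")
    if weights is None:
        if values.ndim != 2:
            raise ValueError("grid must be 2-D when weights are not given")
        weights = rook_weights(*values.shape)
    x = values.ravel()
    if weights.n_cells != x.size:
        raise ValueError("weights do not match grid size")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("zero variance, Moran's I undefined")
    i, j = weights.pairs[:, 0], weights.pairs[:, 1]
    num = float(np.sum(z[i] * z[j]))
    return (x.size / weights.total_weight) * num / denom


@dataclass(frozen=True)
class LandscapeMap:
    """A grid of deme phenotypic optima with known spatial autocorrelation."""

    values: np.ndarray  # (n_rows, n_cols), floats in [0, 1]
    target_moran_i: float
    achieved_moran_i: float
    seed: int
    map_id: int = field(default=0)

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def _next_pow2_plus1(n: int) -> int:
    k = 1
    while k + 1 < n:
        k *= 2
    return k + 1


def midpoint_displacement(size: int, h: float, rng: np.random.Generator) -> np.ndarray:
    """One midpoint-displacement (diamond-square) surface, rescaled to [0, 1].

    A (2**k + 1)-sided lattice is built by recursive diamond and square
    steps; random displacements at level ``l`` have amplitude ``2**(-l * h)``.
    Large ``h`` damps fine-scale noise (smooth, high autocorrelation);
    ``h <= 0`` lets fine-scale noise dominate (rough, autocorrelation near
    zero).  The lattice is cropped to ``size`` and min-max rescaled.
    """
    n = _next_pow2_plus1(size)
    grid = np.full((n, n), np.nan)
    grid[0, 0], grid[0, -1], grid[-1, 0], grid[-1, -1] = rng.normal(size=4)
    step = n - 1
    level = 0
    while step > 1:
        half = step // 2
        amp = 2.0 ** (-level * h)
        # diamond step: centres of squares
        rows = np.arange(half, n, step)
        cc, rr = np.meshgrid(rows, rows)
        grid[rr, cc] = 0.25 * (
            grid[rr - half, cc - half]
            + grid[rr - half, cc + half]
            + grid[rr + half, cc - half]
            + grid[rr + half, cc + half]
        ) + amp * rng.normal(size=rr.shape)
        # square step: edge midpoints, averaging existing neighbours
        for r in range(0, n, half):
            c0 = half if (r // half) % 2 == 0 else 0
            for c in range(c0, n, step):
                if not np.isnan(grid[r, c]):
                    continue
                acc, cnt = 0.0, 0
                for dr, dc in ((-half, 0), (half, 0), (0, -half), (0, half)):
                    rr2, cc2 = r + dr, c + dc
                    if 0 <= rr2 < n and 0 <= cc2 < n:
                        acc += grid[rr2, cc2]
                        cnt += 1
                grid[r, c] = acc / cnt + amp * rng.normal()
        step = half
        level += 1
    surf = grid[:size, :size]
    lo, hi = surf.min(), surf.max()
    if hi == lo:  # degenerate draw; caller will reject on Moran's I
        return np.full((size, size), 0.5)
    return (surf - lo) / (hi - lo)


_H_LO, _H_HI = -2.0, 4.0


def _median_achieved_i(
    h: float, size: int, rng: np.random.Generator, k: int, weights: SpatialWeights
) -> float:
    vals = []
    for _ in range(k):
        surf = midpoint_displacement(size, h, rng)
        try:
            vals.append(morans_i(surf, weights))
        except ValueError:
            vals.append(0.0)
    return float(np.median(vals))


def calibrate_roughness(
    target_i: float,
    size: int,
    rng: np.random.Generator,
    n_probe: int = 5,
    n_iter: int = 18,
) -> float:
    """Bisection on the roughness parameter for a target Moran's I.

    The median achieved I over ``n_probe`` probe surfaces is used as the
    (noisy, monotone-increasing in h) objective.
    """
    weights = rook_weights(size, size)
    lo, hi = _H_LO, _H_HI
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if _median_achieved_i(mid, size, rng, n_probe, weights) < target_i:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_map(
    target_i: float,
    size: int = 14,
    seed: int = 0,
    tol: float = 0.02,
    max_tries: int = 1000,
    map_id: int = 0,
) -> LandscapeMap:
    """Generate one landscape with Moran's I within ``tol`` of ``target_i``.

    Roughness is first calibrated by bisection, then surfaces are drawn and
    rejected until both |I - target| <= tol and 0.4 < mean < 0.6 hold.

    Raises
    ------
    RuntimeError
        If no acceptable surface is found within ``max_tries`` attempts.
    """
    if size < 4:
        raise ValueError("size must be >= 4")
    rng = np.random.default_rng(seed)
    weights = rook_weights(size, size)
    h = calibrate_roughness(target_i, size, rng)
    for _ in range(max_tries):
        surf = midpoint_displacement(size, h, rng)
        if not (0.4 < surf.mean() < 0.6):
            continue
        try:
            achieved = morans_i(surf, weights)
        except ValueError:
            continue
        if abs(achieved - target_i) <= tol:
            return LandscapeMap(surf, float(target_i), achieved, seed, map_id)
    raise RuntimeError(
        f"could not reach Moran's I target {target_i} within tol={tol} "
        f"after {max_tries} attempts"
    )


def series_targets(n_maps: int, i_min: float, i_max: float) -> np.ndarray:
    """Evenly spaced Moran's I targets with spacing (i_max - i_min) / n_maps."""
    if n_maps < 2:
        raise ValueError("n_maps must be >= 2")
    if not i_min < i_max:
        raise ValueError("need i_min < i_max")
    spacing = (i_max - i_min) / n_maps
    return i_min + spacing * np.arange(n_maps)


def make_map_series(
    n_maps: int,
    i_min: float = 0.05,
    i_max: float = 0.95,
    size: int = 14,
    seed: int = 0,
    tol: float = 0.02,
) -> list[LandscapeMap]:
    """A series of maps spanning Moran's I targets from ``i_min`` to ``i_max``.

    Per-map seeds are spawned from the master seed so that any single map can
    be regenerated independently.
    """
    targets = series_targets(n_maps, i_min, i_max)
    children = np.random.SeedSequence(seed).spawn(n_maps)
    maps = []
    for k, (t, ss) in enumerate(zip(targets, children)):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        maps.append(generate_map(float(t), size, sub_seed, tol, map_id=k))
    return maps
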