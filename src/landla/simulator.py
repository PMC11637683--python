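"""Forward-in-time simulation of spatially varying stabilizing selection.

The model is a diploid Wright–Fisher metapopulation on a square
stepping-stone grid.  Each deme holds ``deme_size`` individuals; migration
moves individuals between rook-adjacent demes; reproduction within each deme
is fitness-weighted with non-overlapping generations.  Fitness is Gaussian
stabilizing selection toward a deme-specific phenotypic optimum: with one
trait

    W = exp[-(alpha - theta)^2 / (2 V_s)]

and with two traits the exponents are averaged, so fitness equals the mean of
the marginal one-trait fitnesses on the log scale.  Trait mutations arise
under the infinite-sites model on a continuous genome of length ``L`` with
per-bp rates ``mut_rate`` (mutation) and ``recomb_rate`` (crossover); effects
are drawn from a normal distribution (independent across traits) and act
additively (semidominant).

Genotypes are stored as a dense haplotype-by-polymorphism 0/1 matrix;
mutations lost from the metapopulation are dropped and fixed mutations are
folded into a global phenotype baseline, which keeps the matrix small while
leaving all fitness differences unchanged.

A separate neutral engine (`run_neutral`) propagates per-deme allele
frequencies of unlinked biallelic loci by deterministic migration mixing
followed by binomial resampling; it is used to calibrate neutral F_ST
against the migration rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from numba import njit

from landla.landscape import LandscapeMap

__all__ = [
    "SimParams",
    "SimSnapshot",
    "gaussian_fitness",
    "fitness_matrix",
    "grid_neighbors",
    "step_generation",
    "run_simulation",
    "run_neutral",
    "neutral_fst",
]


@dataclass(frozen=True)
class SimParams:
    """Demographic and genetic constants of one simulation.

    ``m`` is the per-neighbour-pair migration rate: with the default
    ``migration_mode="per_edge"`` an individual emigrates across each of
    its deme's edges independently with probability ``m`` (total
    ``m * n_neighbours``), the convention used when deme-pair migration
    rates are specified in Wright–Fisher metapopulation software.  This
    semantics reproduces the neutral F_ST calibration (F_ST of about 0.02,
    0.05 and 0.10 at m = 0.07, 0.035 and 0.0175 on the default grid).
    With ``migration_mode="total"``, ``m`` is instead the total emigration
    probability, split uniformly among the deme's existing neighbours.
    """

    grid_size: int = 14
    deme_size: int = 100
    m: float = 0.07
    v_s: float = 12.5
    genome_length: float = 10_000_000.0
    recomb_rate: float = 1e-7
    mut_rate: float = 1e-10
    effect_sd: float = 1.0
    n_traits: int = 1
    burn_in: int = 400
    main_gens: int = 100_000
    seed: int = 0
    migration_mode: str = "per_edge"

    def __post_init__(self) -> None:
        if self.grid_size < 1 or self.deme_size < 1:
            raise ValueError("grid_size and deme_size must be positive")
        if self.v_s <= 0:
            raise ValueError("v_s must be positive")
        if self.n_traits not in (1, 2):
            raise ValueError("n_traits must be 1 or 2")
        if not 0 <= self.m <= 1:
            raise ValueError("m must be in [0, 1]")
        if self.migration_mode not in ("total", "per_edge"):
            raise ValueError("migration_mode must be 'total' or 'per_edge'")

    @property
    def n_demes(self) -> int:
        return self.grid_size**2

    @property
    def n_total(self) -> int:
        """Total metapopulation census size."""
        return self.n_demes * self.deme_size

    @property
    def mutational_variance(self) -> float:
        """Per-gamete mutational variance L * mu * E[gamma^2]."""
        return self.genome_length * self.mut_rate * self.effect_sd**2

    @classmethod
    def from_json(cls, path: str | Path) -> "SimParams":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def gaussian_fitness(phenotype, optimum, v_s: float) -> float:
    """Gaussian stabilizing-selection fitness of one individual.

    One trait: ``exp[-(alpha - theta)^2 / (2 v_s)]``.  With ``k`` traits the
    squared deviations are summed and the exponent divided by ``k`` (the
    fitness is the average of the marginal log-fitnesses), so for two traits
    ``W = exp[-((d1^2 + d2^2) / (2 v_s)) / 2]``.
    """
    if v_s <= 0:
        raise ValueError("v_s must be positive")
    a = np.atleast_1d(np.asarray(phenotype, dtype=float))
    t = np.atleast_1d(np.asarray(optimum, dtype=float))
    if a.shape != t.shape:
        raise ValueError("phenotype and optimum must have the same length")
    dev2 = float(np.sum((a - t) ** 2))
    return float(np.exp(-dev2 / (2.0 * v_s) / a.size))


def fitness_matrix(phenotypes: np.ndarray, optima: np.ndarray, v_s: float) -> np.ndarray:
    """Fitness of every individual at every optimum.

    Parameters are arrays of shape (n_ind, n_traits) and (n_demes,
    n_traits); returns (n_ind, n_demes).
    """
    if v_s <= 0:
        raise ValueError("v_s must be positive")
    phenotypes = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    optima = np.atleast_2d(np.asarray(optima, dtype=float))
    k = phenotypes.shape[1]
    d2 = ((phenotypes[:, None, :] - optima[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * v_s) / k)


def grid_neighbors(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Rook neighbour table for a square grid of demes.

    Returns ``(neighbors, counts)`` where ``neighbors`` is (n_demes, 4) with
    -1 padding and ``counts`` the number of neighbours of each deme (2 at
    corners, 3 on edges, 4 in the interior).
    """
    g = grid_size
    nbrs = np.full((g * g, 4), -1, dtype=np.int64)
    counts = np.zeros(g * g, dtype=np.int64)
    for r in range(g):
        for c in range(g):
            d = r * g + c
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < g and 0 <= cc < g:
                    nbrs[d, counts[d]] = rr * g + cc
                    counts[d] += 1
    return nbrs, counts


@dataclass
class SimSnapshot:
    """Mutable state of a metapopulation at one generation.

    Haplotypes are rows of ``geno`` (individual ``i`` owns rows ``2i`` and
    ``2i + 1``); columns are segregating trait polymorphisms sorted by
    genomic position.  ``baseline`` accumulates the phenotypic contribution
    (two copies each) of mutations that fixed metapopulation-wide.
    """

    params: SimParams
    optima: np.ndarray  # (n_demes, n_traits)
    generation: int
    deme: np.ndarray  # (n_total,) deme index of each individual
    geno: np.ndarray  # (2 * n_total, n_mut) uint8
    pos: np.ndarray  # (n_mut,) positions, sorted
    eff: np.ndarray  # (n_mut, n_traits) effects
    origin: np.ndarray  # (n_mut,) origin generation
    baseline: np.ndarray  # (n_traits,)
    landscape: LandscapeMap | None = None
    la_trajectory: list = field(default_factory=list)  # (generation, mean LA)

    @classmethod
    def initial(cls, params: SimParams, optima: np.ndarray | None = None) -> "SimSnapshot":
        n, t = params.n_total, params.n_traits
        if optima is None:
            optima = np.zeros((params.n_demes, t))
        return cls(
            params=params,
            optima=np.asarray(optima, dtype=float).reshape(params.n_demes, t),
            generation=0,
            deme=np.repeat(np.arange(params.n_demes), params.deme_size),
            geno=np.zeros((2 * n, 0), dtype=np.uint8),
            pos=np.empty(0),
            eff=np.empty((0, t)),
            origin=np.empty(0, dtype=np.int64),
            baseline=np.zeros(t),
        )

    @property
    def n_mut(self) -> int:
        return self.pos.size

    def phenotypes(self) -> np.ndarray:
        """(n_total, n_traits) additive phenotypes including the baseline."""
        dosage = (self.geno[0::2].astype(np.float64) + self.geno[1::2]).reshape(
            self.params.n_total, self.n_mut
        )
        return self.baseline + dosage @ self.eff

    def fitness(self) -> np.ndarray:
        """Fitness of each individual in its current (home) deme."""
        w = fitness_matrix(self.phenotypes(), self.optima, self.params.v_s)
        return w[np.arange(self.params.n_total), self.deme]

    def deme_frequencies(self) -> np.ndarray:
        """(n_demes, n_mut) allele frequency of each polymorphism per deme."""
        n_dem, n = self.params.n_demes, self.params.deme_size
        hap_deme = np.repeat(self.deme, 2)
        freq = np.zeros((n_dem, self.n_mut))
        np.add.at(freq, hap_deme, self.geno)
        counts = 2 * np.bincount(self.deme, minlength=n_dem).astype(float)
        return freq / counts[:, None]

    def polymorphism_table(self):
        """One row per segregating trait polymorphism, as a DataFrame.

        Columns: id, position, effect_t1[, effect_t2], origin_gen, age, and
        one per-deme frequency column ``freq_d{k}`` in row-major deme order.
        """
        import pandas as pd

        data = {"id": np.arange(self.n_mut), "position": self.pos}
        for t in range(self.params.n_traits):
            data[f"effect_t{t + 1}"] = self.eff[:, t]
        data["origin_gen"] = self.origin
        data["age"] = self.generation - self.origin
        df = pd.DataFrame(data)
        freqs = self.deme_frequencies()
        for d in range(self.params.n_demes):
            df[f"freq_d{d}"] = freqs[d]
        return df

    def copy(self) -> "SimSnapshot":
        return replace(
            self,
            optima=self.optima.copy(),
            deme=self.deme.copy(),
            geno=self.geno.copy(),
            pos=self.pos.copy(),
            eff=self.eff.copy(),
            origin=self.origin.copy(),
            baseline=self.baseline.copy(),
            la_trajectory=list(self.la_trajectory),
        )


@njit(cache=True)
def _transmit(geno, parents, start_hap, bp_flat, bp_off, pos, out):  # pragma: no cover
    """Copy one recombinant haplotype per gamete into ``out``.

    For gamete ``g`` of parent ``parents[g]``, walk the (sorted) mutation
    positions and toggle between the parent's two haplotypes at each
    crossover breakpoint.
    """
    n_gam, n_mut = out.shape
    for g in range(n_gam):
        h = start_hap[g]
        row = 2 * parents[g]
        k = bp_off[g]
        k_end = bp_off[g + 1]
        for j in range(n_mut):
            while k < k_end and bp_flat[k] < pos[j]:
                h ^= 1
                k += 1
            out[g, j] = geno[row + h, j]


def _migrate(state: SimSnapshot, rng: np.random.Generator, nbrs, counts) -> None:
    p = state.params
    if p.m == 0 or p.n_demes == 1:
        return
    k_here = counts[state.deme]
    if p.migration_mode == "total":
        move = rng.random(p.n_total) < p.m
    else:  # per_edge: emigrate with probability m across each edge
        move = rng.random(p.n_total) < p.m * k_here
    idx = np.where(move)[0]
    if idx.size == 0:
        return
    choice = rng.integers(0, counts[state.deme[idx]])
    state.deme[idx] = nbrs[state.deme[idx], choice]


def step_generation(state: SimSnapshot, rng: np.random.Generator) -> SimSnapshot:
    """Advance the metapopulation by one Wright–Fisher generation (in place).

    Event order: migration, then fitness-weighted reproduction refilling
    every deme to ``deme_size`` offspring, each offspring receiving one
    recombinant, possibly mutated gamete from each of two parents drawn with
    replacement from the deme's post-migration pool.
    """
    p = state.params
    n_dem, n_size, n_tot = p.n_demes, p.deme_size, p.n_total
    nbrs, counts = grid_neighbors(p.grid_size)

    _migrate(state, rng, nbrs, counts)

    # fitness of every individual where it now stands
    phen = state.phenotypes()
    w_home = fitness_matrix(phen, state.optima, p.v_s)[np.arange(n_tot), state.deme]

    order = np.argsort(state.deme, kind="stable")
    sizes = np.bincount(state.deme, minlength=n_dem)
    if (sizes == 0).any():
        raise AssertionError("empty post-migration deme pool")
    starts = np.concatenate([[0], np.cumsum(sizes)])

    parents = np.empty(2 * n_tot, dtype=np.int64)
    for d in range(n_dem):
        pool = order[starts[d] : starts[d + 1]]
        cw = np.cumsum(w_home[pool])
        u = rng.random(2 * n_size) * cw[-1]
        parents[2 * n_size * d : 2 * n_size * (d + 1)] = pool[np.searchsorted(cw, u)]

    n_gam = 2 * n_tot
    n_cross = rng.poisson(p.recomb_rate * p.genome_length, n_gam)
    bp = rng.uniform(0.0, p.genome_length, int(n_cross.sum()))
    gid = np.repeat(np.arange(n_gam), n_cross)
    srt = np.lexsort((bp, gid))
    bp_flat = np.ascontiguousarray(bp[srt])
    bp_off = np.concatenate([[0], np.cumsum(n_cross)]).astype(np.int64)
    start_hap = rng.integers(0, 2, n_gam).astype(np.uint8)

    child = np.empty((n_gam, state.n_mut), dtype=np.uint8)
    _transmit(
        np.ascontiguousarray(state.geno), parents, start_hap, bp_flat, bp_off,
        state.pos, child,
    )

    # new mutations: Poisson(mu * L) per gamete, fresh effects
    n_new = rng.poisson(p.mut_rate * p.genome_length * n_gam)
    pos, eff, origin = state.pos, state.eff, state.origin
    if n_new > 0:
        tgt = rng.integers(0, n_gam, n_new)
        new_pos = rng.uniform(0.0, p.genome_length, n_new)
        new_eff = rng.normal(0.0, p.effect_sd, (n_new, p.n_traits))
        cols = np.zeros((n_gam, n_new), dtype=np.uint8)
        cols[tgt, np.arange(n_new)] = 1
        child = np.hstack([child, cols])
        pos = np.concatenate([pos, new_pos])
        eff = np.vstack([eff, new_eff])
        origin = np.concatenate([origin, np.full(n_new, state.generation + 1)])
        srt2 = np.argsort(pos, kind="stable")
        pos, eff, origin = pos[srt2], eff[srt2], origin[srt2]
        child = np.ascontiguousarray(child[:, srt2])

    # purge lost mutations; fold fixed ones into the baseline phenotype
    tot = child.sum(axis=0, dtype=np.int64)
    fixed = tot == n_gam
    if fixed.any():
        state.baseline = state.baseline + 2.0 * eff[fixed].sum(axis=0)
    keep = (tot > 0) & ~fixed
    if not keep.all():
        child = np.ascontiguousarray(child[:, keep])
        pos, eff, origin = pos[keep], eff[keep], origin[keep]

    state.geno = child
    state.pos, state.eff, state.origin = pos, eff, origin
    state.deme = np.repeat(np.arange(n_dem), n_size)
    state.generation += 1
    return state


def run_simulation(
    params: SimParams,
    landscape: LandscapeMap | np.ndarray,
    la_log_interval: int | None = None,
) -> SimSnapshot:
    """Burn in at a uniform optimum of 0, then evolve on the landscape.

    The metapopulation first evolves for ``burn_in`` generations with
    theta = 0 in every deme, after which the optima switch to the landscape
    values and evolution continues for ``main_gens`` generations.  The mean
    home-vs-away local adaptation is logged every ``la_log_interval``
    generations of the main phase (default: 50 evenly spaced points).

    With two traits the same map supplies the optima of both traits.
    """
    from landla.la_stats import home_away_la  # local import; avoids a cycle

    if isinstance(landscape, LandscapeMap):
        values = landscape.values
        lmap = landscape
    else:
        values = np.asarray(landscape, dtype=float)
        lmap = None
    if values.shape[0] != params.grid_size or values.shape[1] != params.grid_size:
        raise ValueError("landscape size does not match params.grid_size")

    rng = np.random.default_rng(params.seed)
    state = SimSnapshot.initial(params)
    state.landscape = lmap
    for _ in range(params.burn_in):
        step_generation(state, rng)

    theta = np.repeat(values.ravel()[:, None], params.n_traits, axis=1)
    state.optima = theta
    if la_log_interval is None:
        la_log_interval = max(1, params.main_gens // 50)
    for g in range(1, params.main_gens + 1):
        step_generation(state, rng)
        if g % la_log_interval == 0 or g == params.main_gens:
            state.la_trajectory.append(
                (state.generation, home_away_la(state).mean_la)
            )
    return state


# ---------------------------------------------------------------------------
# neutral engine


def _mixing_matrix(params: SimParams) -> np.ndarray:
    """Expected post-migration composition of each deme's pool.

    Entry (d, j) is the proportion of deme d's post-migration pool drawn
    from pre-migration deme j, under the same migration semantics as the
    individual-based engine.
    """
    nbrs, counts = grid_neighbors(params.grid_size)
    n = params.n_demes
    a = np.zeros((n, n))
    for d in range(n):
        if params.migration_mode == "total":
            a[d, d] = 1.0 - params.m
            for j in nbrs[d, : counts[d]]:
                a[d, j] = params.m / counts[j]
        else:
            a[d, d] = 1.0 - params.m * counts[d]
            for j in nbrs[d, : counts[d]]:
                a[d, j] = params.m
    return a / a.sum(axis=1, keepdims=True)


def run_neutral(
    params: SimParams,
    n_loci: int = 200,
    rng: np.random.Generator | int | None = None,
    locus_mut_rate: float = 1e-6,
    window: int = 1000,
    plateau_tol: float = 0.01,
    max_gens: int = 200_000,
    init_freq: float = 0.5,
    return_trajectory: bool = False,
):
    """Neutral allele-frequency simulation of unlinked biallelic loci.

    Each generation the per-deme frequencies are mixed deterministically by
    the migration matrix, perturbed by symmetric per-allele mutation at
    ``locus_mut_rate`` (which keeps loci segregating), and resampled
    binomially with 2N draws per deme.  The run ends when the multi-locus
    Weir–Cockerham F_ST changes by less than ``plateau_tol`` (relative)
    between successive ``window``-generation windows.

    Returns the final (n_demes, n_loci) frequency matrix, or
    ``(freqs, trajectory)`` with ``trajectory`` a list of (generation, F_ST)
    checkpoints when ``return_trajectory`` is set.

    Raises
    ------
    ValueError
        For a single-deme grid, where F_ST is undefined.
    """
    from landla.la_stats import wc_fst

    if params.n_demes < 2:
        raise ValueError("F_ST undefined for a single-deme grid")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(params.seed if rng is None else rng)

    two_n = 2 * params.deme_size
    mix = _mixing_matrix(params)
    p = np.full((params.n_demes, n_loci), init_freq)
    sizes = np.full(params.n_demes, two_n)
    traj = []
    prev_fst = None
    gen = 0
    while gen < max_gens:
        for _ in range(window):
            p = mix @ p
            p = p * (1.0 - locus_mut_rate) + (1.0 - p) * locus_mut_rate
            p = rng.binomial(two_n, p) / two_n
        gen += window
        fst = wc_fst(np.round(p * two_n).astype(np.int64), sizes)
        traj.append((gen, fst))
        if prev_fst is not None and abs(fst - prev_fst) <= plateau_tol * abs(prev_fst):
            break
        prev_fst = fst
    return (p, traj) if return_trajectory else p


def neutral_fst(
    params: SimParams,
    n_loci: int = 200,
    n_reps: int = 3,
    seed: int | None = None,
    **kwargs,
) -> float:
    """Equilibrium multi-locus Weir–Cockerham F_ST, averaged over replicates."""
    from landla.la_stats import wc_fst

    base = params.seed if seed is None else seed
    two_n = 2 * params.deme_size
    sizes = np.full(params.n_demes, two_n)
    out = []
    for child in np.random.SeedSequence(base).spawn(n_reps):
        rng = np.random.default_rng(child)
        p = run_neutral(params, n_loci, rng, **kwargs)
        out.append(wc_fst(np.round(p * two_n).astype(np.int64), sizes))
    return float(np.mean(out))
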