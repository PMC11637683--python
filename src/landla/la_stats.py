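"""Local-adaptation statistics computed on simulation snapshots.

Implements the home-vs-away measure of local adaptation, the
allele-shuffling contribution of single polymorphisms (LA_rel), cumulative
maladaptation, per-deme additive genetic variance, local environmental
heterogeneity, the multi-locus Weir–Cockerham F_ST estimator and allele-age
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from landla.simulator import SimSnapshot, fitness_matrix

__all__ = [
    "LAResult",
    "home_away_la",
    "la_rel",
    "snp_contributions",
    "cumulative_maladaptation",
    "effect_class_sums",
    "additive_variance_per_deme",
    "local_heterogeneity",
    "wc_fst",
    "allele_age_summary",
    "pool_low_high",
]


@dataclass(frozen=True)
class LAResult:
    """Per-deme and landscape-wide home-vs-away local adaptation.

    ``cv_la`` (sd/mean of the per-deme values) is NaN when ``mean_la`` is
    not positive, where a coefficient of variation is not meaningful.
    """

    per_deme_la: np.ndarray  # (grid_size, grid_size)
    mean_la: float
    cv_la: float


def home_away_la(snapshot: SimSnapshot) -> LAResult:
    """Home-vs-away local adaptation for every deme.

    Each individual's fitness is evaluated at its home deme's optimum and at
    the optima of all other demes.  The individual's home-vs-away score is
    its home fitness minus its mean away fitness, and per-deme local
    adaptation LA_d is the mean score over the deme's residents.
    """
    p = snapshot.params
    if p.n_demes < 2:
        raise ValueError("home-vs-away requires at least 2 demes")
    w = fitness_matrix(snapshot.phenotypes(), snapshot.optima, p.v_s)
    return _la_from_fitness(w, snapshot.deme, p)


def _la_from_fitness(w: np.ndarray, deme: np.ndarray, p) -> LAResult:
    home = w[np.arange(w.shape[0]), deme]
    away = (w.sum(axis=1) - home) / (p.n_demes - 1)
    ha = home - away
    per_deme = np.bincount(deme, weights=ha, minlength=p.n_demes)
    per_deme /= np.bincount(deme, minlength=p.n_demes)
    mean_la = float(per_deme.mean())
    sd = float(per_deme.std(ddof=1))
    cv = sd / mean_la if mean_la > 0 else float("nan")
    if per_deme.size == p.grid_size**2:
        per_deme = per_deme.reshape(p.grid_size, p.grid_size)
    return LAResult(per_deme, mean_la, cv)


def _shuffled_mean_la(
    snapshot: SimSnapshot,
    phen: np.ndarray,
    col: np.ndarray,
    gamma: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Mean LA after one uniform permutation of a presence/absence column."""
    p = snapshot.params
    perm = rng.permutation(col)
    delta = (perm[0::2] + perm[1::2]).astype(float) - (col[0::2] + col[1::2])
    phen_i = phen + delta[:, None] * gamma[None, :]
    w = fitness_matrix(phen_i, snapshot.optima, p.v_s)
    return _la_from_fitness(w, snapshot.deme, p).mean_la


def la_rel(
    snapshot: SimSnapshot,
    mutation_id: int,
    n_shuffles: int = 1,
    rng: np.random.Generator | int | None = None,
    baseline_mean_la: float | None = None,
) -> float:
    """Relative contribution of one polymorphism to mean local adaptation.

    The focal allele's presence/absence vector over all 2N haplotypes is
    permuted uniformly (preserving its global count and hence its
    contribution to range-wide additive variance), all phenotypes are
    recomputed, and mean local adaptation is re-quantified as LA_i.  The
    contribution is ``1 - LA_i / LA``; values may be negative (locally
    maladaptive alleles) and the contributions of different alleles need not
    sum to 1.  With ``n_shuffles > 1`` the mean over independent
    permutations is returned.

    Raises
    ------
    ValueError
        If the baseline mean local adaptation is zero.
    """
    rng = np.random.default_rng(rng)
    if baseline_mean_la is None:
        baseline_mean_la = home_away_la(snapshot).mean_la
    if baseline_mean_la == 0:
        raise ValueError("LA_rel undefined at zero mean local adaptation")
    phen = snapshot.phenotypes()
    col = snapshot.geno[:, mutation_id]
    gamma = snapshot.eff[mutation_id]
    vals = [
        _shuffled_mean_la(snapshot, phen, col, gamma, rng)
        for _ in range(n_shuffles)
    ]
    return float(1.0 - np.mean(vals) / baseline_mean_la)


def snp_contributions(
    snapshot: SimSnapshot,
    n_shuffles: int = 1,
    seed: int | None = 0,
) -> pd.DataFrame:
    """LA_rel and descriptors for every segregating trait polymorphism.

    Returns a DataFrame with columns id, position, effect, effect_sq,
    frequency (unweighted mean per-deme allele frequency), age (generations
    since origin) and la_rel.  Per-mutation permutation streams are derived
    deterministically from ``seed`` so the table is reproducible.
    """
    base_la = home_away_la(snapshot).mean_la
    if base_la == 0:
        raise ValueError("LA_rel undefined at zero mean local adaptation")
    phen = snapshot.phenotypes()
    freqs = snapshot.deme_frequencies().mean(axis=0)
    rows = []
    for l in range(snapshot.n_mut):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed or 0), l]))
        vals = [
            _shuffled_mean_la(
                snapshot, phen, snapshot.geno[:, l], snapshot.eff[l], rng
            )
            for _ in range(n_shuffles)
        ]
        rows.append(1.0 - float(np.mean(vals)) / base_la)
    eff1 = snapshot.eff[:, 0]
    return pd.DataFrame(
        {
            "id": np.arange(snapshot.n_mut),
            "position": snapshot.pos,
            "effect": eff1,
            "effect_sq": eff1**2,
            "frequency": freqs,
            "age": snapshot.generation - snapshot.origin,
            "la_rel": rows,
        }
    )


def cumulative_maladaptation(contributions) -> float:
    """Magnitude of the summed LA_rel of all locally maladaptive alleles.

    Accepts a contribution table (with an ``la_rel`` column) or a plain
    sequence of LA_rel values; returns |sum of negative values|.
    """
    la = _la_rel_values(contributions)
    return float(abs(la[la < 0].sum())) if la.size else 0.0


def _la_rel_values(contributions) -> np.ndarray:
    if isinstance(contributions, pd.DataFrame):
        return contributions["la_rel"].to_numpy(dtype=float)
    return np.asarray(contributions, dtype=float)


_CLASS_EDGES = (0.01, 0.10)


def effect_class_sums(contributions) -> dict[str, float]:
    """Summed LA_rel of locally adaptive alleles by contribution class.

    Alleles with positive LA_rel are split into large (> 0.10), intermediate
    (0.01–0.10) and small (< 0.01) contributors; the three sums partition
    the total positive LA_rel exactly.  ``proportion_*`` entries divide each
    class sum by the total positive sum (NaN when nothing is adaptive).
    """
    la = _la_rel_values(contributions)
    pos = la[la > 0]
    lo, hi = _CLASS_EDGES
    sums = {
        "large": float(pos[pos > hi].sum()),
        "intermediate": float(pos[(pos > lo) & (pos <= hi)].sum()),
        "small": float(pos[pos <= lo].sum()),
    }
    total = pos.sum()
    for k in ("large", "intermediate", "small"):
        sums[f"proportion_{k}"] = sums[k] / total if total > 0 else float("nan")
    sums["total_positive"] = float(total)
    return sums


def additive_variance_per_deme(snapshot: SimSnapshot, trait: int = 0) -> np.ndarray:
    """Per-deme additive genetic variance V_A = sum 2 p (1 - p) gamma^2.

    Summed over all segregating trait polymorphisms using each deme's own
    allele frequencies; returned on the deme grid.
    """
    p = snapshot.deme_frequencies()
    g2 = snapshot.eff[:, trait] ** 2
    va = (2.0 * p * (1.0 - p)) @ g2
    return va.reshape(snapshot.params.grid_size, snapshot.params.grid_size)


def local_heterogeneity(landscape, deme: tuple[int, int]) -> float:
    """Mean squared optimum difference between a deme and its 4 neighbours.

    Defined only for interior demes (those with all four cardinal
    neighbours on the grid).
    """
    values = landscape.values if hasattr(landscape, "values") else np.asarray(landscape)
    r, c = deme
    n_rows, n_cols = values.shape
    if not (0 < r < n_rows - 1 and 0 < c < n_cols - 1):
        raise ValueError("local heterogeneity defined for interior demes only")
    focal = values[r, c]
    nb = np.array([values[r - 1, c], values[r + 1, c], values[r, c - 1], values[r, c + 1]])
    return float(np.mean((focal - nb) ** 2))


def wc_fst(allele_counts: np.ndarray, sample_sizes) -> float:
    """Multi-locus Weir–Cockerham F_ST from per-deme allele counts.

    ``allele_counts`` is (n_demes, n_loci) counts of the focal allele;
    ``sample_sizes`` the total number of alleles sampled per deme (scalar or
    per-deme).  Per locus the among-deme (MSP) and within-deme (MSG) mean
    squares give variance components a = (MSP - MSG) / n_c and b = MSG; loci
    are combined as the ratio of summed components ("ratio of averages"):

        theta = sum_l (MSP_l - MSG_l) / sum_l (MSP_l + (n_c - 1) MSG_l)

    Raises
    ------
    ValueError
        With fewer than two demes or no polymorphic locus.
    """
    counts = np.asarray(allele_counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    r = counts.shape[0]
    if r < 2:
        raise ValueError("F_ST requires at least 2 demes")
    n_i = np.broadcast_to(np.asarray(sample_sizes, dtype=float), (r,))
    if (n_i < 1).any():
        raise ValueError("sample sizes must be positive")
    p = counts / n_i[:, None]
    sum_n = n_i.sum()
    nc = (sum_n - (n_i**2).sum() / sum_n) / (r - 1)
    pbar = (n_i[:, None] * p).sum(axis=0) / sum_n
    msp = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (n_i[:, None] * p * (1.0 - p)).sum(axis=0) / (sum_n - r)
    num = msp - msg
    den = msp + (nc - 1.0) * msg
    poly = den > 0
    if not poly.any():
        raise ValueError("all loci monomorphic, F_ST undefined")
    return float(num[poly].sum() / den[poly].sum())


def allele_age_summary(contributions, weighted: bool = False) -> float:
    """Mean age of segregating trait polymorphisms, in generations.

    ``weighted`` uses |effect| weights, emphasising large-effect alleles:
    sum(age * |gamma|) / sum(|gamma|).
    """
    if isinstance(contributions, pd.DataFrame):
        ages = contributions["age"].to_numpy(dtype=float)
        eff = contributions["effect"].to_numpy(dtype=float)
    else:
        ages, eff = (np.asarray(x, dtype=float) for x in contributions)
    if ages.size == 0:
        raise ValueError("no segregating polymorphisms, allele age undefined")
    if not weighted:
        return float(ages.mean())
    w = np.abs(eff)
    if w.sum() == 0:
        return float(ages.mean())
    return float((ages * w).sum() / w.sum())


def pool_low_high(
    tables: list[pd.DataFrame], moran_is: list[float], n_pool: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool contribution tables from the lowest- and highest-I landscapes.

    Returns (low_pool, high_pool), concatenating the tables of the
    ``n_pool`` maps with the smallest and the largest Moran's I.
    """
    if n_pool < 1 or 2 * n_pool > len(tables):
        raise ValueError("n_pool must satisfy 1 <= n_pool <= len(tables) / 2")
    order = np.argsort(moran_is)
    low = pd.concat([tables[i] for i in order[:n_pool]], ignore_index=True)
    high = pd.concat([tables[i] for i in order[-n_pool:]], ignore_index=True)
    return low, high
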