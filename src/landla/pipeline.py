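"""Sweep orchestration: map series -> simulations -> statistics -> tables.

`run_sweep` executes every (map, migration rate, V_s, replicate) cell of a
configured parameter grid, computes the full statistic set on the final
snapshot of each simulation, and returns one tidy row per cell.  Binned
means over Moran's I (with bootstrap confidence intervals) stand in for
scatter-plot smoothing when summarising sweeps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from landla.landscape import LandscapeMap, make_map_series
from landla.simulator import SimParams, neutral_fst, run_simulation
from landla.la_stats import (
    allele_age_summary,
    cumulative_maladaptation,
    effect_class_sums,
    home_away_la,
    snp_contributions,
)

__all__ = ["SweepConfig", "run_sweep", "binned_means", "cell_seed"]


@dataclass(frozen=True)
class SweepConfig:
    """Parameter grid and scale of one sweep.

    The ``full`` preset mirrors the reference study conditions (14x14 grid,
    100 diploids per deme, 200 maps, 100,000 post-burn-in generations); the
    ``desk`` preset is a scaled-down grid for interactive use and testing,
    with the genome shortened by a factor k and the per-bp mutation and
    recombination rates multiplied by k so that genome-wide totals (the
    mutational variance L*mu*E[gamma^2] and the map length r*L) are
    preserved.
    """

    n_maps: int = 200
    i_min: float = 0.05
    i_max: float = 0.95
    grid_size: int = 14
    deme_size: int = 100
    m_values: tuple[float, ...] = (0.07,)
    v_s_values: tuple[float, ...] = (12.5,)
    n_traits: int = 1
    genome_length: float = 10_000_000.0
    recomb_rate: float = 1e-7
    mut_rate: float = 1e-10
    burn_in: int = 400
    main_gens: int = 100_000
    n_seeds: int = 1
    master_seed: int = 0
    map_tol: float = 0.02
    n_shuffles: int = 1
    neutral_loci: int = 200
    compute_fst: bool = False
    keep_contributions: bool = False
    out_dir: str | None = None

    @classmethod
    def desk(cls, **overrides) -> "SweepConfig":
        """Scaled-down preset: 7x7 grid, N = 50, 20 maps, 5,000 generations."""
        base = dict(
            n_maps=20,
            i_max=0.85,  # ~ the 7x7 ceiling: even a perfect gradient has I = 0.833
            grid_size=7,
            deme_size=50,
            v_s_values=(2.5,),  # strong selection: resolvable above drift at N = 50
            genome_length=100_000.0,
            recomb_rate=1e-5,
            mut_rate=1e-8,
            burn_in=200,
            main_gens=5_000,
            n_seeds=3,
        )
        base.update(overrides)
        return cls(**base)


def cell_seed(master_seed: int, map_id: int, m: float, v_s: float, replicate: int) -> int:
    """Deterministic, order-independent seed for one sweep cell."""
    m_bits = int(np.float64(m).view(np.uint64))
    vs_bits = int(np.float64(v_s).view(np.uint64))
    ss = np.random.SeedSequence([master_seed, map_id, m_bits, vs_bits, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(
    config: SweepConfig,
    lmap: LandscapeMap,
    m: float,
    v_s: float,
    replicate: int,
    return_contributions: bool = False,
):
    """Run one simulation cell and compute its summary row."""
    seed = cell_seed(config.master_seed, lmap.map_id, m, v_s, replicate)
    params = SimParams(
        grid_size=config.grid_size,
        deme_size=config.deme_size,
        m=m,
        v_s=v_s,
        genome_length=config.genome_length,
        recomb_rate=config.recomb_rate,
        mut_rate=config.mut_rate,
        n_traits=config.n_traits,
        burn_in=config.burn_in,
        main_gens=config.main_gens,
        seed=seed,
    )
    snap = run_simulation(params, lmap)
    la = home_away_la(snap)
    row = {
        "map_id": lmap.map_id,
        "target_i": lmap.target_moran_i,
        "achieved_i": lmap.achieved_moran_i,
        "m": m,
        "v_s": v_s,
        "replicate": replicate,
        "seed": seed,
        "n_poly": snap.n_mut,
        "mean_la": la.mean_la,
        "cv_la": la.cv_la,
    }
    contrib = None
    if snap.n_mut > 0 and la.mean_la != 0:
        contrib = snp_contributions(snap, config.n_shuffles, seed)
        row["maladaptation"] = cumulative_maladaptation(contrib)
        row["mean_age"] = allele_age_summary(contrib)
        row["weighted_age"] = allele_age_summary(contrib, weighted=True)
        for k, v in effect_class_sums(contrib).items():
            row[f"la_rel_{k}"] = v
    else:
        row["maladaptation"] = 0.0
        row["mean_age"] = np.nan
        row["weighted_age"] = np.nan
    return (row, contrib) if return_contributions else row


def run_sweep(
    config: SweepConfig, maps: list[LandscapeMap] | None = None
) -> pd.DataFrame:
    """Execute every (map, m, V_s, replicate) cell of the sweep.

    Cell failures are recorded (``df.attrs["failures"]``) and the sweep
    continues.  Results are independent of execution order because every
    cell derives its own seed from the master seed.  When ``out_dir`` is
    set, writes ``results.tsv``, binned summaries and per-cell logs there.
    """
    if maps is None:
        maps = make_map_series(
            config.n_maps,
            config.i_min,
            config.i_max,
            config.grid_size,
            config.master_seed,
            config.map_tol,
        )
    rows, failures, contribs = [], [], []
    for lmap in maps:
        for m in config.m_values:
            for v_s in config.v_s_values:
                for rep in range(config.n_seeds):
                    try:
                        row, contrib = run_cell(config, lmap, m, v_s, rep, True)
                        rows.append(row)
                        if config.keep_contributions:
                            contribs.append(contrib)
                    except Exception as exc:  # log-and-continue policy
                        failures.append(
                            {"map_id": lmap.map_id, "m": m, "v_s": v_s,
                             "replicate": rep, "error": repr(exc)}
                        )
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    if config.keep_contributions:
        df.attrs["contributions"] = contribs

    if config.compute_fst and not df.empty:
        fst_by_m = {
            m: neutral_fst(
                SimParams(grid_size=config.grid_size, deme_size=config.deme_size, m=m),
                n_loci=config.neutral_loci,
                seed=config.master_seed,
            )
            for m in config.m_values
        }
        df["fst_neutral"] = df["m"].map(fst_by_m)

    if config.out_dir is not None:
        _write_outputs(config, df, failures)
    return df


def _write_outputs(config: SweepConfig, df: pd.DataFrame, failures: list) -> None:
    out = Path(config.out_dir)
    (out / "summaries").mkdir(parents=True, exist_ok=True)
    (out / "logs").mkdir(exist_ok=True)
    df.to_csv(out / "results.tsv", sep="\t", index=False)
    with open(out / "logs" / "cells.json", "w") as fh:
        json.dump(
            {"config": asdict(config), "failures": failures,
             "seeds": df["seed"].tolist() if not df.empty else []},
            fh, indent=1,
        )
    if not df.empty:
        for y in ("mean_la", "cv_la", "maladaptation", "weighted_age"):
            if y in df:
                binned_means(df, y=y).to_csv(
                    out / "summaries" / f"{y}_vs_moran_i.tsv", sep="\t", index=False
                )


def binned_means(
    df: pd.DataFrame,
    y: str,
    x: str = "achieved_i",
    n_bins: int = 10,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Equal-width binned means of ``y`` against ``x`` with bootstrap CIs."""
    rng = np.random.default_rng(seed)
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    edges = np.linspace(xv.min(), xv.max() + 1e-12, n_bins + 1)
    rows = []
    for b in range(n_bins):
        sel = (xv >= edges[b]) & (xv < edges[b + 1])
        if not sel.any():
            continue
        vals = yv[sel]
        boots = rng.choice(vals, (n_boot, vals.size)).mean(axis=1)
        rows.append(
            {
                "bin_mid": 0.5 * (edges[b] + edges[b + 1]),
                "n": int(sel.sum()),
                "mean": float(vals.mean()),
                "ci_lo": float(np.quantile(boots, 0.025)),
                "ci_hi": float(np.quantile(boots, 0.975)),
            }
        )
    return pd.DataFrame(rows)
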