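"""Plain-text file formats: landscape maps, snapshot tables, configs.

Maps are stored as a headerless CSV grid plus a JSON sidecar of metadata;
snapshot exports are TSV tables (polymorphisms and individuals).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from landla.landscape import LandscapeMap
from landla.simulator import SimSnapshot

__all__ = [
    "save_map",
    "load_map",
    "export_snapshot",
    "load_polymorphisms",
    "load_individuals",
]


def save_map(lmap: LandscapeMap, path: str | Path) -> None:
    """Write a map as ``<path>.csv`` (grid) and ``<path>.json`` (metadata)."""
    path = Path(path)
    np.savetxt(path.with_suffix(".csv"), lmap.values, delimiter=",", fmt="%.10g")
    meta = {
        "target_moran_i": lmap.target_moran_i,
        "achieved_moran_i": lmap.achieved_moran_i,
        "mean": lmap.mean,
        "seed": lmap.seed,
        "size": lmap.size,
        "map_id": lmap.map_id,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_map(path: str | Path) -> LandscapeMap:
    """Read a map written by `save_map` (pass either file or the stem)."""
    path = Path(path)
    values = np.loadtxt(path.with_suffix(".csv"), delimiter=",")
    meta_file = path.with_suffix(".json")
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
    else:
        from landla.landscape import morans_i

        meta = {"target_moran_i": float("nan"), "achieved_moran_i": morans_i(values),
                "seed": -1, "map_id": 0}
    return LandscapeMap(
        values,
        meta["target_moran_i"],
        meta["achieved_moran_i"],
        meta["seed"],
        meta.get("map_id", 0),
    )


def export_snapshot(snapshot: SimSnapshot, out_dir: str | Path) -> None:
    """Write ``polymorphisms.tsv`` and ``individuals.tsv`` for a snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot.polymorphism_table().to_csv(out / "polymorphisms.tsv", sep="\t", index=False)

    p = snapshot.params
    phen = snapshot.phenotypes()
    data = {
        "id": np.arange(p.n_total),
        "deme_row": snapshot.deme // p.grid_size,
        "deme_col": snapshot.deme % p.grid_size,
    }
    for t in range(p.n_traits):
        data[f"phenotype_t{t + 1}"] = phen[:, t]
    data["fitness"] = snapshot.fitness()
    pd.DataFrame(data).to_csv(out / "individuals.tsv", sep="\t", index=False)


def load_polymorphisms(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def load_individuals(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
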