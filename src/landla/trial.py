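"""Provenance trials on simulated metapopulations.

A provenance trial evaluates the mean fitness of individuals from sampled
source demes ("provenances") at the phenotypic optima of sampled target
demes ("planting sites"), and regresses that fitness on the environmental
distance between provenance and site.  A negative fixed slope of the
transfer function indicates local adaptation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from landla.simulator import SimSnapshot, fitness_matrix

__all__ = ["TrialDesign", "TransferFit", "simulate_provenance_trial", "fit_transfer_function"]


@dataclass(frozen=True)
class TrialDesign:
    """Sampled sites and provenances with the fitness and distance matrices."""

    planting_sites: np.ndarray  # deme ids, (n_sites,)
    provenances: np.ndarray  # deme ids, (n_prov,)
    fitness: np.ndarray  # (n_prov, n_sites) mean relative fitness
    env_distance: np.ndarray  # (n_prov, n_sites) |theta_prov - theta_site|

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: provenance, site, env_distance, fitness."""
        n_prov, n_sites = self.fitness.shape
        return pd.DataFrame(
            {
                "provenance": np.repeat(self.provenances, n_sites),
                "site": np.tile(self.planting_sites, n_prov),
                "env_distance": self.env_distance.ravel(),
                "fitness": self.fitness.ravel(),
            }
        )


@dataclass(frozen=True)
class TransferFit:
    """Fixed and provenance-level estimates of the transfer function."""

    fixed_slope: float
    fixed_intercept: float
    random_effects: pd.DataFrame  # per-provenance intercept/slope deviations
    method: str  # "mixed" or "two_stage"


def simulate_provenance_trial(
    snapshot: SimSnapshot,
    n_sites: int = 50,
    n_prov: int = 100,
    rng: np.random.Generator | int | None = None,
) -> TrialDesign:
    """Sample a provenance trial from a snapshot.

    Sites and provenances are sampled uniformly without replacement within
    each set (a deme may appear in both sets).  The fitness of a provenance
    at a site is the mean Gaussian fitness of the provenance deme's
    individuals evaluated at the site's optimum; environmental distance is
    the Euclidean distance between the two demes' optima (the absolute
    difference for a single trait).
    """
    p = snapshot.params
    if n_sites > p.n_demes or n_prov > p.n_demes:
        raise ValueError("cannot sample more demes than exist on the grid")
    rng = np.random.default_rng(rng)
    sites = np.sort(rng.choice(p.n_demes, n_sites, replace=False))
    provs = np.sort(rng.choice(p.n_demes, n_prov, replace=False))

    w = fitness_matrix(snapshot.phenotypes(), snapshot.optima[sites], p.v_s)
    fit = np.empty((n_prov, n_sites))
    for k, d in enumerate(provs):
        fit[k] = w[snapshot.deme == d].mean(axis=0)
    dist = np.sqrt(
        ((snapshot.optima[provs][:, None, :] - snapshot.optima[sites][None, :, :]) ** 2).sum(
            axis=2
        )
    )
    return TrialDesign(sites, provs, fit, dist)


def _two_stage_fit(df: pd.DataFrame) -> TransferFit:
    """Per-provenance OLS, then unweighted averaging of the coefficients."""
    rows = []
    for prov, grp in df.groupby("provenance"):
        x, y = grp["env_distance"].to_numpy(), grp["fitness"].to_numpy()
        if np.ptp(x) > 0:
            slope, intercept = np.polyfit(x, y, 1)
        else:
            slope, intercept = np.nan, y.mean()
        rows.append((prov, intercept, slope))
    re = pd.DataFrame(rows, columns=["provenance", "intercept", "slope"]).set_index(
        "provenance"
    )
    b0, b1 = re["intercept"].mean(), re["slope"].mean(skipna=True)
    re = re.assign(intercept=re["intercept"] - b0, slope=re["slope"] - b1)
    return TransferFit(float(b1), float(b0), re, "two_stage")


def fit_transfer_function(design: TrialDesign | pd.DataFrame) -> TransferFit:
    """Mixed-model fit of fitness on environmental distance.

    Fits ``fitness ~ env_distance`` with provenance-level random intercepts
    and slopes (REML).  Falls back to a two-stage per-provenance OLS fit if
    the mixed model fails to converge; the two estimators agree in sign on
    well-posed designs.

    Raises
    ------
    ValueError
        If the environmental distances have zero variance, where the slope
        is not identifiable.
    """
    df = design.to_frame() if isinstance(design, TrialDesign) else design
    if np.ptp(df["env_distance"].to_numpy()) == 0:
        raise ValueError("degenerate design: environmental distance has zero variance")
    try:
        import statsmodels.formula.api as smf

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "fitness ~ env_distance",
                df,
                groups=df["provenance"],
                re_formula="~env_distance",
            )
            res = model.fit(reml=True)
        if not np.isfinite(res.params["env_distance"]):
            raise RuntimeError("non-finite fixed slope")
        re = pd.DataFrame(res.random_effects).T
        re.columns = ["intercept", "slope"]
        re.index.name = "provenance"
        return TransferFit(
            float(res.params["env_distance"]),
            float(res.params["Intercept"]),
            re,
            "mixed",
        )
    except (ImportError, RuntimeError, np.linalg.LinAlgError, ValueError):
        return _two_stage_fit(df)
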