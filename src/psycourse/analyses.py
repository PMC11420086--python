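"""Canned end-to-end analyses: registry bundle in, published-style estimate out.

Each function reruns the full phenotyping path — trajectories, progression
groups, burden/usage metrics — on a bundle and fits the corresponding model,
so the same code serves the pipeline, preset verification and acceptance
checks. All genetic models use the standard covariates (sex, birth year, ten
PCs) and in-sample standardized polygenic scores.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .association import (
    FitResult,
    build_covariates,
    fit_binary_endpoint,
    fit_burden_model,
    fit_progression_cox,
    standardized_pgs_frame,
)
from .burden import cohort_burden, int_transform, window_episode_lengths
from .hierarchy import progression_cohort, summarize_trajectories
from .mediation import MediationResult, fit_path_model, sud_exclusion_analysis
from .registry import MajorClass, RegistryBundle


def _frames(bundle: RegistryBundle):
    traj = summarize_trajectories(bundle)
    covs = build_covariates(bundle.persons)
    pgs = standardized_pgs_frame(bundle.persons)
    return traj, covs, pgs


def progression_logistic_fit(bundle: RegistryBundle, trait: str = "sz") -> FitResult:
    """OR per SD of a PGS for progression to schizophrenia vs remaining at a
    lower-ranked diagnosis."""
    traj, covs, pgs = _frames(bundle)
    labelled, _ = progression_cohort(traj)
    labelled = labelled.set_index("person_id")
    sub = labelled.loc[labelled["progression_group"] != "direct_sz"]
    endpoint = (sub["progression_group"] == "progressed_to_sz").astype(float)
    return fit_binary_endpoint(
        endpoint, pgs[trait].reindex(sub.index), covs.reindex(sub.index),
        term=f"{trait}_pgs",
    )


def progression_sex_fit(bundle: RegistryBundle) -> FitResult:
    """OR for female sex predicting progressed-to-schizophrenia membership vs
    receiving schizophrenia as the first major diagnosis."""
    traj, covs, _ = _frames(bundle)
    labelled, _ = progression_cohort(traj)
    labelled = labelled.set_index("person_id")
    sub = labelled.loc[labelled["progression_group"].isin(["direct_sz", "progressed_to_sz"])]
    endpoint = (sub["progression_group"] == "progressed_to_sz").astype(float)
    sex = covs["sex_female"].reindex(sub.index)
    return fit_binary_endpoint(
        endpoint, sex, covs[["birth_year"]].reindex(sub.index), term="female",
    )


def progression_cox_fit(
    bundle: RegistryBundle, trait: str = "sz", time_origin: str = "first_major"
) -> FitResult:
    """HR per SD of a PGS for time from first lower-ranked major diagnosis to
    the first schizophrenia diagnosis (administrative censoring)."""
    traj, covs, pgs = _frames(bundle)
    traj = traj.set_index("person_id")
    sub = traj.loc[
        (traj["first_major"] != MajorClass.NONE.value)
        & (traj["first_major"] != MajorClass.SZ.value)
    ]
    durations = sub["time_at_risk_years"].clip(lower=1 / 365.25)
    events = sub["progressed_to_sz"].astype(bool)
    return fit_progression_cox(
        durations, events, pgs[trait].reindex(sub.index), covs.reindex(sub.index),
        term=f"{trait}_pgs",
    )


#: Default inclusion floor for burden regressions: persons observed for fewer
#: aligned years contribute fractions too coarse to be informative.
MIN_OBSERVED_YEARS = 3


def _transformed_burden(
    bundle: RegistryBundle,
    traj: pd.DataFrame,
    ids: pd.Index,
    min_observed_years: int = MIN_OBSERVED_YEARS,
) -> pd.Series:
    bt = cohort_burden(bundle, traj).set_index("person_id")
    bt = bt.loc[bt["observed_years"] >= min_observed_years]
    frac = bt["burden_fraction"].reindex(ids).dropna()
    return pd.Series(int_transform(frac.to_numpy()), index=frac.index)


def burden_hierarchy_fit(bundle: RegistryBundle) -> FitResult:
    """β (SD units of rank-INT burden) for main-lifetime schizophrenia vs the
    lower-ranked diagnoses."""
    traj, covs, _ = _frames(bundle)
    tj = traj.set_index("person_id")
    ids = tj.index[tj["main_lifetime"] != MajorClass.NONE.value]
    y = _transformed_burden(bundle, traj, ids)
    indicator = (tj["main_lifetime"] == MajorClass.SZ.value).astype(float).reindex(y.index)
    return fit_burden_model(y, indicator, covs.reindex(y.index), term="main_lifetime_sz")


def burden_pgs_fit(bundle: RegistryBundle, trait: str = "sz") -> FitResult:
    """β per SD of a PGS on rank-INT burden among schizophrenia individuals."""
    traj, covs, pgs = _frames(bundle)
    tj = traj.set_index("person_id")
    ids = tj.index[tj["main_lifetime"] == MajorClass.SZ.value]
    y = _transformed_burden(bundle, traj, ids)
    return fit_burden_model(
        y, pgs[trait].reindex(y.index), covs.reindex(y.index), term=f"{trait}_pgs"
    )


def sud_logistic_fit(bundle: RegistryBundle, trait: str = "ea") -> FitResult:
    """OR per SD of a PGS for the SUD endpoint among schizophrenia individuals."""
    traj, covs, pgs = _frames(bundle)
    tj = traj.set_index("person_id")
    ids = tj.index[tj["main_lifetime"] == MajorClass.SZ.value]
    endpoint = tj["sud"].astype(float).reindex(ids)
    return fit_binary_endpoint(
        endpoint, pgs[trait].reindex(ids), covs.reindex(ids), term=f"{trait}_pgs"
    )


def burden_on_sud_fit(bundle: RegistryBundle) -> FitResult:
    """β (SD units) for the binary SUD endpoint on rank-INT burden among
    schizophrenia individuals."""
    traj, covs, _ = _frames(bundle)
    tj = traj.set_index("person_id")
    ids = tj.index[tj["main_lifetime"] == MajorClass.SZ.value]
    y = _transformed_burden(bundle, traj, ids)
    sud = tj["sud"].astype(float).reindex(y.index)
    return fit_burden_model(y, sud, covs.reindex(y.index), term="sud")


def mediation_fit(
    bundle: RegistryBundle, bootstrap_reps: int = 1000, seed: int | None = None
) -> MediationResult:
    """SUD-mediation path model for the EA-PGS burden effect (SZ persons)."""
    traj, covs, pgs = _frames(bundle)
    tj = traj.set_index("person_id")
    ids = tj.index[tj["main_lifetime"] == MajorClass.SZ.value]
    bt = cohort_burden(bundle, traj).set_index("person_id")
    bt = bt.loc[bt["observed_years"] >= MIN_OBSERVED_YEARS]
    frac = bt["burden_fraction"].reindex(ids).dropna()
    return fit_path_model(
        frac, pgs["ea"].reindex(frac.index), tj["sud"].astype(float).reindex(frac.index),
        covs.reindex(frac.index), bootstrap_reps=bootstrap_reps, seed=seed,
    )


def sud_exclusion_fit(bundle: RegistryBundle) -> FitResult:
    """EA-PGS burden association restricted to SUD-free schizophrenia persons."""
    traj, covs, pgs = _frames(bundle)
    tj = traj.set_index("person_id")
    ids = tj.index[tj["main_lifetime"] == MajorClass.SZ.value]
    bt = cohort_burden(bundle, traj).set_index("person_id")
    bt = bt.loc[bt["observed_years"] >= MIN_OBSERVED_YEARS]
    frac = bt["burden_fraction"].reindex(ids).dropna()
    return sud_exclusion_analysis(
        frac, pgs["ea"].reindex(frac.index), tj["sud"].astype(bool).reindex(frac.index),
        covs.reindex(frac.index),
    )


def median_los_sud(bundle: RegistryBundle) -> float:
    """Pooled median per-episode length of stay (days) among SUD persons,
    episodes clipped to the 15-year onset-aligned window."""
    traj, _, _ = _frames(bundle)
    tj = traj.set_index("person_id")
    lengths = window_episode_lengths(bundle, traj)
    sud_ids = set(tj.index[tj["sud"].astype(bool)])
    los = lengths.loc[lengths["person_id"].isin(sud_ids), "los"]
    if not len(los):
        raise ValueError("no in-window episodes among SUD persons")
    return float(np.median(los))


# Mapping preset name → scalar-producing analysis (for verification/recovery).
_PRESET_ANALYSES = {
    "progression-logistic": lambda b: progression_logistic_fit(b).effect,
    "progression-logistic-sex": lambda b: progression_sex_fit(b).effect,
    "progression-cox": lambda b: progression_cox_fit(b).effect,
    "burden-hierarchy": lambda b: burden_hierarchy_fit(b).estimate,
    "burden-pgs": lambda b: burden_pgs_fit(b).estimate,
    "sud-logistic": lambda b: sud_logistic_fit(b).effect,
    "mediation": lambda b: mediation_fit(b, bootstrap_reps=0).indirect,
    "usage-profiles": median_los_sud,
}


def analysis_for_preset(name: str):
    """The downstream analysis whose estimand a named preset sets."""
    try:
        return _PRESET_ANALYSES[name]
    except KeyError:
        raise ValueError(f"no matching analysis for preset {name!r}") from None
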