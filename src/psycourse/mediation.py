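"""Path-model mediation of the EA-PGS effect on hospitalization burden via SUD.

The question: how much of the (negative) association between the educational-
attainment PGS and psychiatric hospitalization burden flows through the
substance-use-disorder endpoint? A two-equation product-of-coefficients path
model makes the decomposition explicit:

    (i)  mediator ~ EA-PGS + covariates     (linear probability for SUD)
    (ii) burden   ~ EA-PGS + mediator(s) + covariates

with ``a`` the EA-PGS coefficient in (i), ``b`` the mediator coefficient in
(ii), indirect effect ``a·b``, direct effect the EA-PGS coefficient in (ii),
and total ``direct + indirect``. The mediator enters (i) on the linear-
probability scale so that ``a·b`` keeps an additive SD-scale interpretation
on the rank-INT burden outcome. Uncertainty comes from a nonparametric
person-level bootstrap with percentile intervals.

Education (an ordered attainment level treated as numeric) can enter as a
second mediator; its paths are reported separately and never summed into the
SUD indirect effect.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .association import FitResult, fit_burden_model
from .burden import int_transform

_PATHS = ("a", "b", "direct", "indirect", "total")


@dataclasses.dataclass(frozen=True)
class MediationResult:
    a: float                       # EA-PGS → mediator (probability per SD)
    b: float                       # mediator → burden (SD units)
    direct: float                  # EA-PGS → burden adjusting mediator(s)
    indirect: float                # a·b
    total: float                   # direct + indirect
    bootstrap_ci: dict[str, tuple[float, float]]
    n: int
    reps: int
    seed: int | None
    education_paths: dict[str, float] | None = None


def _path_coefficients(
    y: np.ndarray, ea: np.ndarray, med: np.ndarray, covs: np.ndarray,
    edu: np.ndarray | None,
) -> tuple[float, float, float, dict[str, float] | None]:
    """(a, b, direct) by two least-squares fits; edu paths reported on the side."""
    ones = np.ones((len(ea), 1))
    X1 = np.column_stack([ones, ea[:, None], covs])
    beta1, *_ = np.linalg.lstsq(X1, med, rcond=None)
    a = float(beta1[1])

    cols = [ones, ea[:, None], med[:, None]]
    if edu is not None:
        cols.append(edu[:, None])
    cols.append(covs)
    X2 = np.column_stack(cols)
    beta2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    direct = float(beta2[1])
    b = float(beta2[2])

    edu_paths = None
    if edu is not None:
        Xe = np.column_stack([ones, ea[:, None], covs])
        betae, *_ = np.linalg.lstsq(Xe, edu, rcond=None)
        a_edu = float(betae[1])
        b_edu = float(beta2[3])
        edu_paths = {"a": a_edu, "b": b_edu, "indirect": a_edu * b_edu}
    return a, b, direct, edu_paths


def fit_path_model(
    burden: pd.Series,
    ea_pgs: pd.Series,
    sud: pd.Series,
    covariates: pd.DataFrame | None = None,
    education: pd.Series | None = None,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    transform_burden: bool = True,
) -> MediationResult:
    """Estimate the SUD-mediation decomposition of the EA-PGS burden effect.

    Parameters
    ----------
    burden:
        Raw burden fractions (rank-INT applied here when ``transform_burden``)
        or an already SD-scale outcome (set ``transform_burden=False``).
    bootstrap_reps:
        0 skips the bootstrap (point estimates only); values below 100 warn.
    """
    frames = [burden, ea_pgs, sud] + ([education] if education is not None else []) \
        + ([covariates] if covariates is not None else [])
    idx = burden.index
    mask = pd.Series(True, index=idx)
    for f in frames:
        mask &= ~pd.DataFrame(f).reindex(idx).isna().any(axis=1)
    idx = idx[mask]
    n = len(idx)

    med = sud.loc[idx].astype(float).to_numpy()
    if np.all(med == med[0]):
        raise ValueError("mediator is constant in the analyzed sample")
    if 0 < bootstrap_reps < 100:
        warnings.warn(f"bootstrap_reps={bootstrap_reps} < 100: intervals will be unstable")

    y_raw = burden.loc[idx].astype(float).to_numpy()
    y = int_transform(y_raw) if transform_burden else y_raw
    ea = ea_pgs.loc[idx].astype(float).to_numpy()
    covs = (
        covariates.loc[idx].to_numpy(dtype=float)
        if covariates is not None
        else np.empty((n, 0))
    )
    edu = education.loc[idx].astype(float).to_numpy() if education is not None else None

    a, b, direct, edu_paths = _path_coefficients(y, ea, med, covs, edu)
    indirect = a * b
    total = direct + indirect

    cis: dict[str, tuple[float, float]] = {}
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        draws = {p: np.empty(bootstrap_reps) for p in _PATHS}
        for r in range(bootstrap_reps):
            take = rng.integers(0, n, size=n)
            # re-transform within the resample so the outcome stays SD-scale
            yb = int_transform(y_raw[take]) if transform_burden else y[take]
            ab, bb, db, _ = _path_coefficients(
                yb, ea[take], med[take], covs[take], edu[take] if edu is not None else None
            )
            draws["a"][r] = ab
            draws["b"][r] = bb
            draws["direct"][r] = db
            draws["indirect"][r] = ab * bb
            draws["total"][r] = db + ab * bb
        for p in _PATHS:
            lo, hi = np.percentile(draws[p], [2.5, 97.5])
            cis[p] = (float(lo), float(hi))

    return MediationResult(
        a=a, b=b, direct=direct, indirect=indirect, total=total,
        bootstrap_ci=cis, n=n, reps=bootstrap_reps, seed=seed,
        education_paths=edu_paths,
    )


def sud_exclusion_analysis(
    burden: pd.Series,
    ea_pgs: pd.Series,
    sud: pd.Series,
    covariates: pd.DataFrame | None = None,
    transform_burden: bool = True,
) -> FitResult:
    """EA-PGS burden association after dropping every SUD-endpoint person.

    The burden outcome is re-transformed within the SUD-free subsample so the
    coefficient stays in SD units of that subsample.
    """
    keep = ~sud.astype(bool)
    idx = sud.index[keep]
    if not len(idx):
        raise ValueError("no SUD-free persons: exclusion analysis undefined")
    y = burden.reindex(idx).dropna()
    idx = y.index
    outcome = pd.Series(
        int_transform(y.to_numpy()) if transform_burden else y.to_numpy(), index=idx
    )
    return fit_burden_model(
        outcome,
        ea_pgs.reindex(idx),
        covariates.reindex(idx) if covariates is not None else None,
        term="ea_pgs_sud_excluded",
    )


def mediator_timing_rates(
    sud_dates: pd.Series, onset_dates: pd.Series
) -> dict[str, float]:
    """Descriptive rates of SUD-before-onset ordering among SUD persons.

    A purely descriptive check of temporal plausibility (no causal search):
    the fraction of SUD-endpoint persons whose first SUD diagnosis precedes,
    ties with, or follows psychotic illness onset.
    """
    sud_d = pd.to_datetime(sud_dates).dropna()
    onset = pd.to_datetime(onset_dates).reindex(sud_d.index)
    both = sud_d.notna() & onset.notna()
    if not both.any():
        return {"before": np.nan, "same_day": np.nan, "after": np.nan, "n": 0}
    d, o = sud_d[both], onset[both]
    n = int(both.sum())
    return {
        "before": float((d < o).mean()),
        "same_day": float((d == o).mean()),
        "after": float((d > o).mean()),
        "n": n,
    }
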