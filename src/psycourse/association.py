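"""Polygenic-score standardization, strata and the study's regression family.

Every genetic association model uses the same covariate set: sex (female = 1),
year of birth, and the first ten ancestry principal components. Predictors are
standardized in-sample, so linear coefficients are per SD of the predictor,
logistic coefficients exponentiate to odds ratios per SD, and proportional-
hazards coefficients to hazard ratios per SD.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.stats import rankdata

from .registry import N_PCS, PGS_TRAITS

COVARIATE_COLUMNS = ["sex_female", "birth_year"] + [f"pc{i}" for i in range(1, N_PCS + 1)]


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit — the MLE does not exist."""


@dataclasses.dataclass(frozen=True)
class FitResult:
    term: str
    model: str                      # linear | logistic | cox
    estimate: float                 # beta / log-OR / log-HR
    effect: float | None            # exp(estimate) for logistic/cox, None for linear
    ci95: tuple[float, float]       # on the estimate (not exponentiated) scale
    p: float
    n: int

    @property
    def effect_ci95(self) -> tuple[float, float] | None:
        if self.effect is None:
            return None
        return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))

    def as_row(self, analysis_id: str = "") -> dict:
        lo, hi = self.ci95
        return {
            "analysis_id": analysis_id, "term": self.term, "model": self.model,
            "estimate": self.estimate, "effect": self.effect,
            "ci_low": lo, "ci_high": hi, "p": self.p, "n": self.n,
        }


# ---------------------------------------------------------------------------
# Standardization and strata
# ---------------------------------------------------------------------------

def standardize_pgs(values: pd.Series | np.ndarray) -> np.ndarray:
    """Z-scores with the population-SD convention (divide by √(Σ(x−x̄)²/n))."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two scores to standardize")
    if not np.isfinite(x).all():
        raise ValueError("non-finite scores")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return (x - x.mean()) / sd


def pgs_strata(zscores: pd.Series | np.ndarray) -> np.ndarray:
    """Percentile strata: [0,20) → low, [20,80) → middle, [80,100] → high."""
    z = np.asarray(zscores, dtype=float)
    pct = 100.0 * (rankdata(z, method="average") - 0.5) / z.size
    return np.select([pct < 20.0, pct < 80.0], ["low", "middle"], default="high")


def build_covariates(persons: pd.DataFrame) -> pd.DataFrame:
    """Standard covariate frame indexed by person_id."""
    out = pd.DataFrame(index=persons["person_id"])
    out["sex_female"] = (persons["sex"].to_numpy() == "female").astype(float)
    out["birth_year"] = pd.to_datetime(persons["birth_date"]).dt.year.to_numpy().astype(float)
    for i in range(1, N_PCS + 1):
        out[f"pc{i}"] = persons[f"pc{i}"].to_numpy()
    return out


def standardized_pgs_frame(persons: pd.DataFrame) -> pd.DataFrame:
    """In-sample standardized PGS columns (one per trait), indexed by person_id."""
    out = pd.DataFrame(index=persons["person_id"])
    for t in PGS_TRAITS:
        out[t] = standardize_pgs(persons[f"pgs_{t}"])
    return out


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _design(predictor: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({"predictor": predictor})
    if covariates is not None:
        X = X.join(covariates)
    return X


def _complete_cases(*frames: pd.Series | pd.DataFrame) -> pd.Index:
    idx = frames[0].index
    mask = pd.Series(True, index=idx)
    for f in frames:
        f = f.reindex(idx)
        mask &= ~pd.DataFrame(f).isna().any(axis=1)
    return idx[mask]


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = np.ones((len(X), 1))
        for col in X.columns:
            cand = np.column_stack([cur, X[col].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(col)
            else:
                cur = cand
        raise ValueError(f"rank-deficient design; offending columns: {bad}")


def fit_burden_model(
    outcome: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    term: str = "predictor",
) -> FitResult:
    """OLS of an SD-scale outcome (rank-INT burden or usage statistic) on a predictor."""
    idx = _complete_cases(outcome, predictor, *( [covariates] if covariates is not None else [] ))
    y = outcome.loc[idx].astype(float)
    X = _design(predictor.loc[idx], covariates.loc[idx] if covariates is not None else None)
    _check_rank(X)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    ci = res.conf_int().loc["predictor"]
    return FitResult(
        term=term, model="linear",
        estimate=float(res.params["predictor"]), effect=None,
        ci95=(float(ci[0]), float(ci[1])), p=float(res.pvalues["predictor"]), n=int(res.nobs),
    )


def fit_binary_endpoint(
    endpoint: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    term: str = "predictor",
) -> FitResult:
    """Logistic regression; returns the odds ratio per SD with a Wald 95% CI."""
    idx = _complete_cases(endpoint, predictor, *( [covariates] if covariates is not None else [] ))
    y = endpoint.loc[idx].astype(float)
    if y.nunique() < 2:
        raise ValueError("endpoint has a single class")
    X = _design(predictor.loc[idx], covariates.loc[idx] if covariates is not None else None)
    _check_rank(X)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation detected: {exc}") from exc
    if not np.isfinite(res.bse["predictor"]) or res.bse["predictor"] > 1e3:
        raise SeparationError("quasi-separation: unbounded coefficient for predictor")
    ci = res.conf_int().loc["predictor"]
    est = float(res.params["predictor"])
    return FitResult(
        term=term, model="logistic", estimate=est, effect=float(np.exp(est)),
        ci95=(float(ci[0]), float(ci[1])), p=float(res.pvalues["predictor"]), n=int(res.nobs),
    )


def fit_progression_cox(
    durations: pd.Series,
    events: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    term: str = "predictor",
) -> FitResult:
    """Proportional-hazards fit (Efron tie handling); hazard ratio per SD.

    ``durations`` are years from the configured time origin (first lower-ranked
    major diagnosis by default) to the first schizophrenia diagnosis or
    administrative censoring; ``events`` flags observed progressions.
    """
    if not events.astype(bool).any():
        raise ValueError("no progression events: Cox model undefined")
    idx = _complete_cases(durations, events, predictor, *( [covariates] if covariates is not None else [] ))
    df = _design(predictor.loc[idx], covariates.loc[idx] if covariates is not None else None)
    _check_rank(df)
    df = df.copy()
    df["T"] = durations.loc[idx].astype(float)
    df["E"] = events.loc[idx].astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")  # lifelines uses Efron ties
    row = cph.summary.loc["predictor"]
    est = float(row["coef"])
    return FitResult(
        term=term, model="cox", estimate=est, effect=float(np.exp(est)),
        ci95=(float(row["coef lower 95%"]), float(row["coef upper 95%"])),
        p=float(row["p"]), n=int(len(df)),
    )


def compare_group_pgs(
    group_a_ids: pd.Index,
    group_b_ids: pd.Index,
    zscores: pd.Series,
    covariates: pd.DataFrame | None = None,
    term: str = "group_b_vs_a",
) -> FitResult:
    """Covariate-adjusted mean PGS difference (group B − group A) in SD units."""
    overlap = set(group_a_ids) & set(group_b_ids)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    ids = list(group_a_ids) + list(group_b_ids)
    indicator = pd.Series(
        [0.0] * len(group_a_ids) + [1.0] * len(group_b_ids), index=ids, name="predictor"
    )
    y = zscores.reindex(ids)
    res = fit_burden_model(
        y, indicator, covariates.reindex(ids) if covariates is not None else None, term=term
    )
    return res
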