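"""Synthetic psychiatric-registry generator with named presets.

Real individual-level registry data of this kind cannot be redistributed, so
every analysis in this package is exercised against synthetic cohorts whose
*generating* parameters are set to the published effect sizes. Each named
preset is single-mechanism: exactly one effect family is non-zero, so the
downstream estimator that targets it can be checked for parameter recovery in
isolation. A ``full`` preset combines all mechanisms for integration tests.

What is emulated: birth years 1927–2000; log-normal psychotic-onset ages with
class-specific medians and IQR-derived spreads; the four-tier diagnostic
hierarchy with unidirectional progression to schizophrenia (logistic or
proportional-hazards mechanism); a latent-score hospitalization-burden process
over the 15-year onset-aligned window; SUD endpoints (linear-probability or
logistic in the EA-PGS); and log-normal hospital-episode durations with
SUD-specific medians plus a Poisson revolving-door episode-count option.

Randomness: every per-person quantity is drawn from its own Philox stream
keyed by ``(seed, quantity-name)`` with the person index as array position,
so cohorts are reproducible, order-independent, and growing ``n`` only
appends persons.
"""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import logging
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field
from scipy.special import expit, logit as sp_logit
from scipy.stats import norm

from .registry import (
    DEFAULT_STUDY_END,
    N_PCS,
    PGS_TRAITS,
    REGISTRY_START,
    MajorClass,
    RegistryBundle,
)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
WINDOW_YEARS = 15
_WINDOW_DAYS = int(np.ceil(WINDOW_YEARS * DAYS_PER_YEAR))  # 5479

#: Representative ICD-10 code emitted for each major class.
CLASS_CODES = {
    MajorClass.SZ: "F20.0",
    MajorClass.SAD: "F25.0",
    MajorClass.BD: "F31.0",
    MajorClass.PMDD: "F32.3",
}
SUD_CODE = "F10.2"

#: Onset-age log-normal parameters per first-major class: median and the
#: log-scale sigma implied by the published interquartile ranges.
ONSET_MEDIANS = {"SZ": 24.4, "SAD": 26.9, "BD": 34.0, "pMDD": 35.9, "progressed": 24.3}
ONSET_SIGMAS = {"SZ": 0.286, "SAD": 0.338, "BD": 0.414, "pMDD": 0.532, "progressed": 0.34}

#: Cohort composition constants (counts-derived).
LOWER_CLASS_MIXTURE = {"SAD": 0.328, "BD": 0.435, "pMDD": 0.237}
HIERARCHY_MIXTURE = {"SZ": 0.655, "SAD": 0.105, "BD": 0.179, "pMDD": 0.061}
PROGRESSION_BASE_RATE = 0.244        # progressed / (progressed + remained)
PROGRESSED_VS_DIRECT_RATE = 0.169    # progressed / all eventual schizophrenia
SUD_BASE_RATE = 0.32                 # SUD among schizophrenia


class ProgressionLogistic(BaseModel):
    kind: Literal["logistic"] = "logistic"
    or_per_sd_szpgs: float = 1.0
    base_rate: float = PROGRESSION_BASE_RATE
    sex_or: float = 1.0              # used by the eventual-schizophrenia design
    delay_median_years: float = 5.6
    delay_sigma_log: float = 0.6


class ProgressionCox(BaseModel):
    kind: Literal["cox"] = "cox"
    hr_per_sd_szpgs: float = 1.0
    baseline_hazard: float = 0.012   # progressions per person-year at PGS = 0


class BurdenMechanism(BaseModel):
    """Latent-score burden process: z = Σβ·x + ε with Var(z) ≈ 1, mapped
    monotonically to an expected hospitalized-year fraction in [p_min, p_max]."""

    beta_group_sz: float = 0.0       # main-lifetime SZ vs lower-ranked
    beta_szpgs: float = 0.0
    beta_eapgs: float = 0.0
    beta_sud: float = 0.0            # SUD-endpoint indicator
    realization: Literal["deterministic", "stochastic"] = "deterministic"
    p_min: float = 0.02
    p_max: float = 0.95


class SudMechanism(BaseModel):
    kind: Literal["linear", "logistic"] = "linear"
    base_rate: float = SUD_BASE_RATE
    slope_per_sd_eapgs: float = 0.0  # linear-probability slope
    or_per_sd_eapgs: float = 1.0     # logistic slope


class EpisodeModel(BaseModel):
    median_los_days_sud: float = 28.0
    median_los_days_non_sud: float = 28.0
    sigma_log_los: float = 0.8
    max_los_days: int = 300
    # episodes per hospitalized year = 1 + Poisson(extra); >0 gives the
    # revolving-door pattern of multiple short admissions per year
    poisson_extra_sud: float = 0.0
    poisson_extra_non_sud: float = 0.0
    max_episodes_per_year: int = 4


class GeneratorPreset(BaseModel):
    """Complete, serializable description of one synthetic study condition."""

    name: str
    design: Literal["lower_start", "sz_enders", "hierarchy_mix", "sz_only"]
    n_persons: int = 10_000
    seed: int = 0
    version: int = 1
    birth_year_range: tuple[int, int] = (1927, 2000)
    study_end: datetime.date = DEFAULT_STUDY_END
    lower_class_mixture: dict[str, float] = Field(default_factory=lambda: dict(LOWER_CLASS_MIXTURE))
    hierarchy_mixture: dict[str, float] = Field(default_factory=lambda: dict(HIERARCHY_MIXTURE))
    onset_medians: dict[str, float] = Field(default_factory=lambda: dict(ONSET_MEDIANS))
    onset_sigmas: dict[str, float] = Field(default_factory=lambda: dict(ONSET_SIGMAS))
    progression: Optional[ProgressionLogistic | ProgressionCox] = None
    burden: Optional[BurdenMechanism] = None
    sud: SudMechanism = Field(default_factory=SudMechanism)
    episodes: EpisodeModel = Field(default_factory=EpisodeModel)
    ensure_full_window: bool = False   # force ≥15 observed years after onset
    progressed_pgs_shift: float = 0.0  # SZ-PGS shift of the progressed group
    max_clip_rate: float = 0.20

    def to_yaml(self) -> str:
        data = self.model_dump(mode="json")
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorPreset":
        return cls.model_validate(yaml.safe_load(text))


@dataclasses.dataclass
class TruthRecord:
    """Per-person latent values and labels, sufficient to recompute every
    expected estimate, plus the preset that generated them."""

    frame: pd.DataFrame
    preset: GeneratorPreset
    clip_rates: dict[str, float]


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "progression-logistic", "progression-logistic-sex", "progression-cox",
    "burden-hierarchy", "burden-pgs", "sud-logistic", "mediation",
    "usage-profiles", "full",
)


def preset_paper_defaults(name: str, n_persons: int = 10_000, seed: int = 0) -> GeneratorPreset:
    """Named preset whose true parameters are the published effect sizes.

    Each preset activates a single mechanism (all other effects zero) so the
    matching estimator can be validated in isolation; ``full`` combines them.
    """
    kw = dict(name=name, n_persons=n_persons, seed=seed)
    if name == "progression-logistic":
        return GeneratorPreset(
            design="lower_start", ensure_full_window=True,
            progression=ProgressionLogistic(or_per_sd_szpgs=1.32), **kw,
        )
    if name == "progression-logistic-sex":
        return GeneratorPreset(
            design="sz_enders", ensure_full_window=True,
            progression=ProgressionLogistic(sex_or=1.72, base_rate=PROGRESSED_VS_DIRECT_RATE),
            **kw,
        )
    if name == "progression-cox":
        return GeneratorPreset(
            design="lower_start",
            progression=ProgressionCox(hr_per_sd_szpgs=1.23), **kw,
        )
    if name == "burden-hierarchy":
        return GeneratorPreset(
            design="hierarchy_mix", ensure_full_window=True,
            burden=BurdenMechanism(beta_group_sz=0.65), **kw,
        )
    if name == "burden-pgs":
        return GeneratorPreset(
            design="sz_only", ensure_full_window=True,
            burden=BurdenMechanism(beta_szpgs=0.054), **kw,
        )
    if name == "sud-logistic":
        return GeneratorPreset(
            design="sz_only", ensure_full_window=True,
            sud=SudMechanism(kind="logistic", or_per_sd_eapgs=0.68), **kw,
        )
    if name == "mediation":
        return GeneratorPreset(
            design="sz_only", ensure_full_window=True,
            sud=SudMechanism(kind="linear", slope_per_sd_eapgs=-0.080),
            burden=BurdenMechanism(beta_sud=0.50, beta_eapgs=-0.020), **kw,
        )
    if name == "usage-profiles":
        return GeneratorPreset(
            design="sz_only", ensure_full_window=True,
            burden=BurdenMechanism(),  # noise-only hospitalized years
            episodes=EpisodeModel(
                median_los_days_sud=21.0, median_los_days_non_sud=41.0,
                poisson_extra_sud=1.0,
            ),
            **kw,
        )
    if name == "full":
        return GeneratorPreset(
            design="hierarchy_mix", ensure_full_window=True,
            progression=ProgressionLogistic(or_per_sd_szpgs=1.32),
            sud=SudMechanism(kind="linear", slope_per_sd_eapgs=-0.080),
            burden=BurdenMechanism(
                beta_group_sz=0.65, beta_szpgs=0.054, beta_eapgs=-0.020,
                beta_sud=0.50, realization="stochastic",
            ),
            episodes=EpisodeModel(
                median_los_days_sud=21.0, median_los_days_non_sud=41.0,
                poisson_extra_sud=1.0,
            ),
            **kw,
        )
    raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")


def zero_effect(preset: GeneratorPreset) -> GeneratorPreset:
    """Copy of a preset with every effect parameter nulled (for calibration)."""
    upd: dict = {"name": preset.name + "-null"}
    if preset.progression is not None:
        if preset.progression.kind == "logistic":
            upd["progression"] = preset.progression.model_copy(
                update={"or_per_sd_szpgs": 1.0, "sex_or": 1.0}
            )
        else:
            upd["progression"] = preset.progression.model_copy(update={"hr_per_sd_szpgs": 1.0})
    if preset.burden is not None:
        upd["burden"] = preset.burden.model_copy(
            update={"beta_group_sz": 0.0, "beta_szpgs": 0.0, "beta_eapgs": 0.0, "beta_sud": 0.0}
        )
    upd["sud"] = preset.sud.model_copy(update={"slope_per_sd_eapgs": 0.0, "or_per_sd_eapgs": 1.0})
    upd["progressed_pgs_shift"] = 0.0
    return preset.model_copy(update=upd)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _stream(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    key = int.from_bytes(digest[:16], "little")
    return np.random.Generator(np.random.Philox(key=key))


_EPOCH_ORD = datetime.date(1970, 1, 1).toordinal()


def _to_datetime(ordinals: np.ndarray) -> pd.Series:
    return pd.to_datetime(np.asarray(ordinals, dtype="int64") - _EPOCH_ORD, unit="D")


def _mixture_draw(u: np.ndarray, mixture: dict[str, float]) -> np.ndarray:
    labels = list(mixture)
    probs = np.array([mixture[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    edges = np.cumsum(probs)
    return np.array(labels, dtype=object)[np.searchsorted(edges, u, side="right").clip(max=len(labels) - 1)]


def simulate_cohort(preset: GeneratorPreset) -> tuple[RegistryBundle, TruthRecord]:
    """Generate a registry bundle plus its per-person truth record.

    Deterministic given the preset (seed included); the resulting bundle
    always passes :class:`~psycourse.registry.RegistryBundle` validation.
    """
    n, seed = preset.n_persons, preset.seed
    end_ord = preset.study_end.toordinal()
    clip_rates: dict[str, float] = {}

    person_id = np.array([f"S{i:06d}" for i in range(n)], dtype=object)
    female = _stream(seed, "sex").random(n) < 0.5
    y0, y1 = preset.birth_year_range
    byear = _stream(seed, "birth_year").integers(y0, y1 + 1, size=n)
    bday = _stream(seed, "birth_day").integers(0, 365, size=n)
    birth_ord = np.array([datetime.date(int(y), 1, 1).toordinal() for y in byear]) + bday
    pgs = _stream(seed, "pgs").standard_normal((n, len(PGS_TRAITS)))
    pcs = _stream(seed, "pcs").standard_normal((n, N_PCS))
    z_sz = pgs[:, PGS_TRAITS.index("sz")]
    z_ea = pgs[:, PGS_TRAITS.index("ea")]

    # ---- class assignment and progression -------------------------------
    u_class = _stream(seed, "class").random(n)
    u_prog = _stream(seed, "prog").random(n)
    progressed = np.zeros(n, dtype=bool)
    first_major = np.empty(n, dtype=object)

    if preset.design == "lower_start":
        first_major[:] = _mixture_draw(u_class, preset.lower_class_mixture)
        mech = preset.progression
        if mech is None:
            raise ValueError("lower_start design requires a progression mechanism")
        if mech.kind == "logistic":
            eta = sp_logit(mech.base_rate) + np.log(mech.or_per_sd_szpgs) * z_sz \
                + np.log(mech.sex_or) * female
            p_prog = expit(eta)
            progressed = u_prog < p_prog
    elif preset.design == "sz_enders":
        mech = preset.progression
        if mech is None or mech.kind != "logistic":
            raise ValueError("sz_enders design requires a logistic progression mechanism")
        eta = sp_logit(mech.base_rate) + np.log(mech.sex_or) * female \
            + np.log(mech.or_per_sd_szpgs) * z_sz
        progressed = u_prog < expit(eta)
        first_major[:] = MajorClass.SZ.value
        first_major[progressed] = _mixture_draw(u_class[progressed], preset.lower_class_mixture)
        if preset.progressed_pgs_shift:
            z_sz = z_sz + preset.progressed_pgs_shift * progressed
            pgs[:, PGS_TRAITS.index("sz")] = z_sz
    elif preset.design == "hierarchy_mix":
        first_major[:] = _mixture_draw(u_class, preset.hierarchy_mixture)
    elif preset.design == "sz_only":
        first_major[:] = MajorClass.SZ.value

    # ---- onset dates -----------------------------------------------------
    onset_group = first_major.astype(object).copy()
    onset_group[progressed] = "progressed"
    med = np.array([preset.onset_medians[g] for g in onset_group])
    sig = np.array([preset.onset_sigmas[g] for g in onset_group])
    onset_age = np.exp(np.log(med) + sig * _stream(seed, "onset").standard_normal(n))

    # onsets must fall inside the registry era and leave room for the
    # follow-up the preset requires (the 15-year window, plus a year's slack
    # for progression delays); birth years are truncated accordingly
    margin = _WINDOW_DAYS + int(DAYS_PER_YEAR) if preset.ensure_full_window else int(DAYS_PER_YEAR)
    latest = end_ord - margin
    earliest = REGISTRY_START.toordinal()
    min_onset_age_days = int(10 * DAYS_PER_YEAR)
    birth_ord = np.minimum(birth_ord, latest - min_onset_age_days)
    onset_ord = birth_ord + np.round(onset_age * DAYS_PER_YEAR).astype(int)
    clipped = (onset_ord > latest) | (onset_ord < earliest)
    clip_rates["onset_date"] = float(clipped.mean())
    onset_ord = np.clip(onset_ord, earliest, latest)
    onset_ord = np.maximum(onset_ord, birth_ord + min_onset_age_days)  # no infant onsets
    onset_age = (onset_ord - birth_ord) / DAYS_PER_YEAR
    byear = (pd.to_datetime(_to_datetime(birth_ord))).year.to_numpy()
    follow_days = end_ord - onset_ord

    # ---- schizophrenia progression dates ---------------------------------
    sz_ord = np.full(n, -1, dtype=int)
    mech = preset.progression
    if mech is not None and preset.design in ("lower_start", "sz_enders") and mech.kind == "logistic":
        delay = np.exp(
            np.log(mech.delay_median_years)
            + mech.delay_sigma_log * _stream(seed, "delay").standard_normal(n)
        )
        delay_days = np.round(delay * DAYS_PER_YEAR).astype(int)
        # keep the schizophrenia diagnosis inside the observed window so the
        # progression indicator is recoverable from events
        delay_days = np.minimum(delay_days, np.maximum((0.95 * follow_days).astype(int), 30))
        sz_ord[progressed] = onset_ord[progressed] + delay_days[progressed]
    elif mech is not None and mech.kind == "cox":
        rate = mech.baseline_hazard * np.exp(np.log(mech.hr_per_sd_szpgs) * z_sz)
        t_years = _stream(seed, "cox_t").exponential(1.0, size=n) / rate
        t_days = np.round(t_years * DAYS_PER_YEAR).astype(int).clip(min=1)
        event = onset_ord + t_days <= end_ord
        progressed = event
        sz_ord[event] = onset_ord[event] + t_days[event]
    if preset.design == "sz_enders":
        direct = ~progressed
        sz_ord[direct] = onset_ord[direct]

    # ---- SUD endpoint ----------------------------------------------------
    sm = preset.sud
    if sm.kind == "linear":
        p_sud_raw = sm.base_rate + sm.slope_per_sd_eapgs * z_ea
    else:
        p_sud_raw = expit(sp_logit(sm.base_rate) + np.log(sm.or_per_sd_eapgs) * z_ea)
    p_sud = np.clip(p_sud_raw, 0.01, 0.99)
    clip_rates["sud_probability"] = float((p_sud != p_sud_raw).mean())
    sud = _stream(seed, "sud").random(n) < p_sud
    sud_offset = (_stream(seed, "sud_date").random(n) * np.minimum(follow_days, 10 * DAYS_PER_YEAR)).astype(int)
    sud_ord = onset_ord + sud_offset

    # ---- burden process --------------------------------------------------
    bm = preset.burden
    latent_z = np.full(n, np.nan)
    p_frac = np.full(n, np.nan)
    hospitalized = np.zeros((n, WINDOW_YEARS), dtype=bool)
    observed_years = np.minimum(WINDOW_YEARS, np.ceil(follow_days / DAYS_PER_YEAR)).astype(int)
    main_is_sz = (first_major == MajorClass.SZ.value) | progressed
    if bm is not None:
        q_g = float(main_is_sz.mean())
        struct = (
            bm.beta_group_sz * (main_is_sz - q_g)
            + bm.beta_szpgs * z_sz
            + bm.beta_eapgs * z_ea
            + bm.beta_sud * (sud - sud.mean())
        )
        var_struct = float(np.var(struct))
        if var_struct >= 0.95:
            raise ValueError(f"infeasible burden mechanism: structural variance {var_struct:.2f}")
        eps = _stream(seed, "burden_eps").standard_normal(n) * np.sqrt(1.0 - var_struct)
        latent_z = struct + eps
        p_raw = bm.p_min + (bm.p_max - bm.p_min) * norm.cdf(latent_z)
        p_frac = np.clip(p_raw, 0.01, 0.99)
        clip_rates["burden_probability"] = float((p_frac != p_raw).mean())
        if bm.realization == "deterministic":
            k_years = np.floor(WINDOW_YEARS * p_frac + 0.5).astype(int)
            order = np.argsort(_stream(seed, "yearpick").random((n, WINDOW_YEARS)), axis=1)
            hospitalized = order < k_years[:, None]
        else:
            hospitalized = _stream(seed, "yearflip").random((n, WINDOW_YEARS)) < p_frac[:, None]
        hospitalized &= np.arange(WINDOW_YEARS)[None, :] < observed_years[:, None]

    # feasibility is judged on probability clipping; onset-date truncation at
    # the registry edges is expected (left truncation at 1969) and only logged
    prob_clip = max(
        (v for k, v in clip_rates.items() if k.endswith("probability")), default=0.0
    )
    if prob_clip > preset.max_clip_rate:
        raise ValueError(
            f"infeasible preset: probability clip rate {prob_clip:.2f} exceeds {preset.max_clip_rate}"
        )
    if any(v > 0 for v in clip_rates.values()):
        logger.info("simulate_cohort[%s]: clip rates %s", preset.name, clip_rates)

    # ---- hospital episodes ----------------------------------------------
    ep_person: list[np.ndarray] = []
    ep_admit: list[np.ndarray] = []
    ep_disch: list[np.ndarray] = []
    if bm is not None and hospitalized.any():
        em = preset.episodes
        extra = np.where(sud, em.poisson_extra_sud, em.poisson_extra_non_sud)
        counts = 1 + _stream(seed, "ep_count").poisson(extra[:, None], size=(n, WINDOW_YEARS))
        counts = np.minimum(counts, em.max_episodes_per_year)
        counts *= hospitalized
        m = em.max_episodes_per_year
        mu = np.where(sud, np.log(em.median_los_days_sud), np.log(em.median_los_days_non_sud))
        los = np.exp(
            mu[:, None, None]
            + em.sigma_log_los * _stream(seed, "ep_los").standard_normal((n, WINDOW_YEARS, m))
        )
        los = np.clip(np.round(los), 1, em.max_los_days).astype(int)
        u_off = _stream(seed, "ep_offset").random((n, WINDOW_YEARS, m))
        year_start = onset_ord[:, None] + np.ceil(np.arange(WINDOW_YEARS) * DAYS_PER_YEAR).astype(int)[None, :]
        year_len = 365  # episodes are placed fully inside their aligned year
        start = year_start[:, :, None] + (u_off * np.maximum(year_len - los, 1)).astype(int)
        active = np.arange(m)[None, None, :] < counts[:, :, None]
        pidx, yidx, eidx = np.nonzero(active)
        ep_person.append(pidx)
        s = start[pidx, yidx, eidx]
        ep_admit.append(s)
        ep_disch.append(np.minimum(s + los[pidx, yidx, eidx] - 1, end_ord))

    # ---- assemble tables -------------------------------------------------
    persons = pd.DataFrame({"person_id": person_id})
    persons["sex"] = np.where(female, "female", "male")
    persons["birth_date"] = _to_datetime(birth_ord)
    for j, t in enumerate(PGS_TRAITS):
        persons[f"pgs_{t}"] = pgs[:, j]
    for i in range(N_PCS):
        persons[f"pc{i+1}"] = pcs[:, i]

    dx_person = [person_id]
    dx_ord = [onset_ord]
    dx_code = [np.array([CLASS_CODES[MajorClass(c)] for c in first_major], dtype=object)]
    has_sz_event = sz_ord >= 0
    if preset.design == "sz_enders":
        has_sz_event &= progressed  # direct persons' onset event is already SZ
    dx_person.append(person_id[has_sz_event])
    dx_ord.append(sz_ord[has_sz_event])
    dx_code.append(np.full(int(has_sz_event.sum()), CLASS_CODES[MajorClass.SZ], dtype=object))
    dx_person.append(person_id[sud])
    dx_ord.append(sud_ord[sud])
    dx_code.append(np.full(int(sud.sum()), SUD_CODE, dtype=object))
    diagnoses = pd.DataFrame(
        {
            "person_id": np.concatenate(dx_person),
            "date": _to_datetime(np.concatenate(dx_ord)),
            "icd_version": 10,
            "code": np.concatenate(dx_code),
        }
    ).sort_values(["person_id", "date"], kind="mergesort").reset_index(drop=True)

    if ep_person:
        pall = np.concatenate(ep_person)
        class_codes = np.array([CLASS_CODES[MajorClass(c)] for c in first_major], dtype=object)
        episodes = pd.DataFrame(
            {
                "person_id": person_id[pall],
                "admit_date": _to_datetime(np.concatenate(ep_admit)),
                "discharge_date": _to_datetime(np.concatenate(ep_disch)),
                "primary_code": class_codes[pall],
            }
        ).sort_values(["person_id", "admit_date"], kind="mergesort").reset_index(drop=True)
    else:
        episodes = pd.DataFrame(columns=["person_id", "admit_date", "discharge_date", "primary_code"])

    bundle = RegistryBundle(
        persons=persons, diagnoses=diagnoses, episodes=episodes, study_end=preset.study_end
    )
    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "female": female,
            "birth_year": byear,
            "onset_age": onset_age,
            "first_major": first_major.astype(str),
            "progressed": progressed,
            "main_is_sz": main_is_sz,
            "sud": sud,
            "p_sud": p_sud,
            "latent_z": latent_z,
            "p_fraction": p_frac,
            "hospitalized_years": hospitalized.sum(axis=1),
            "observed_years": observed_years,
        }
    )
    return bundle, TruthRecord(frame=truth, preset=preset, clip_rates=clip_rates)


# ---------------------------------------------------------------------------
# Preset verification (simulation oracle)
# ---------------------------------------------------------------------------

def replicate_seeds(base_seed: int, reps: int) -> list[int]:
    """Independent replicate-cohort seeds derived from one base seed.

    Uses numpy's SeedSequence entropy spreading so replicates are
    well-separated regardless of the arithmetic structure of ``base_seed``.
    """
    state = np.random.SeedSequence(base_seed).generate_state(reps, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def preset_truth(preset: GeneratorPreset) -> float:
    """The generating-side true value the preset's matching analysis targets."""
    name = preset.name.removesuffix("-null")
    if name == "progression-logistic":
        return preset.progression.or_per_sd_szpgs
    if name == "progression-logistic-sex":
        return preset.progression.sex_or
    if name == "progression-cox":
        return preset.progression.hr_per_sd_szpgs
    if name == "burden-hierarchy":
        return preset.burden.beta_group_sz
    if name == "burden-pgs":
        return preset.burden.beta_szpgs
    if name == "sud-logistic":
        return preset.sud.or_per_sd_eapgs
    if name == "mediation":
        return preset.sud.slope_per_sd_eapgs * preset.burden.beta_sud
    if name == "usage-profiles":
        return preset.episodes.median_los_days_sud
    raise ValueError(f"no scalar truth defined for preset {preset.name!r}")


def verify_preset(
    preset: GeneratorPreset, reps: int = 5, n: int | None = None
) -> dict:
    """Parameter-recovery check: rerun the matching analysis on fresh cohorts.

    Reports the per-replicate estimates, their mean, the Monte-Carlo standard
    error of the mean, and a pass flag at the looser of 3 MC SE and 5%
    relative error around the preset's true value.
    """
    from .analyses import analysis_for_preset

    if reps < 3:
        raise ValueError("verify_preset needs reps >= 3")
    fn = analysis_for_preset(preset.name.removesuffix("-null"))
    estimates = []
    for r, s in enumerate(replicate_seeds(preset.seed, reps)):
        p = preset.model_copy(update={"seed": s})
        if n is not None:
            p = p.model_copy(update={"n_persons": n})
        bundle, _ = simulate_cohort(p)
        estimates.append(float(fn(bundle)))
    est = np.asarray(estimates)
    mean = float(est.mean())
    mc_se = float(est.std(ddof=1) / np.sqrt(reps))
    truth = preset_truth(preset)
    tol = max(3 * mc_se, 0.05 * abs(truth))
    return {
        "preset": preset.name,
        "truth": truth,
        "estimates": estimates,
        "mean": mean,
        "mc_se": mc_se,
        "tolerance": tol,
        "pass": bool(abs(mean - truth) <= tol),
    }
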