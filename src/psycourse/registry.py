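"""Registry data model, ICD-10 code classification and delimited-table I/O.

The unit of analysis is a :class:`RegistryBundle`: a persons table (sex, birth
date, seven standardized polygenic scores, ten ancestry principal components),
a diagnosis-event table (dated ICD codes) and a hospital-episode table
(admission/discharge dates with a primary discharge code), together with an
administrative study-end date. All downstream stages — trajectory phenotyping,
hospitalization-burden metrics, association models — consume bundles only.
"""
from __future__ import annotations

import dataclasses
import datetime
import enum
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: Traits for which standardized polygenic scores are expected, in column order.
PGS_TRAITS: tuple[str, ...] = ("sz", "bd", "mdd", "ea", "iq", "cud", "alc")

#: Number of ancestry principal components carried as covariates.
N_PCS = 10

#: First date covered by the hospital discharge registry.
REGISTRY_START = datetime.date(1969, 1, 1)

#: Default administrative censoring date.
DEFAULT_STUDY_END = datetime.date(2018, 12, 31)

PERSON_COLUMNS = (
    ["person_id", "sex", "birth_date"]
    + [f"pgs_{t}" for t in PGS_TRAITS]
    + [f"pc{i}" for i in range(1, N_PCS + 1)]
)
DIAGNOSIS_COLUMNS = ["person_id", "date", "icd_version", "code"]
EPISODE_COLUMNS = ["person_id", "admit_date", "discharge_date", "primary_code"]


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class MajorClass(str, enum.Enum):
    """The four ranked major psychotic diagnoses (plus ``none``)."""

    SZ = "SZ"      # schizophrenia
    SAD = "SAD"    # schizoaffective disorder
    BD = "BD"      # bipolar disorder
    PMDD = "pMDD"  # major depressive disorder with psychotic features
    NONE = "none"


# ---------------------------------------------------------------------------
# ICD-10 code classification
# ---------------------------------------------------------------------------

#: Code sets defining the four major classes (ICD-10, prefix semantics below).
MAJOR_CLASS_PREFIXES: dict[MajorClass, tuple[str, ...]] = {
    MajorClass.SZ: ("F20",),
    MajorClass.SAD: ("F25",),
    MajorClass.BD: ("F30.2", "F31"),
    MajorClass.PMDD: ("F32.3", "F33.3"),
}

#: Any psychotic illness: F20–F29 plus the bipolar/psychotic-depression codes.
PSYCHOSIS_PREFIXES: tuple[str, ...] = tuple(
    [f"F2{i}" for i in range(10)] + ["F30.2", "F31", "F32.3", "F33.3"]
)

#: Substance use disorder: F10–F16 and F18–F19 (nicotine dependence F17 excluded).
SUD_PREFIXES: tuple[str, ...] = tuple(f"F1{i}" for i in (0, 1, 2, 3, 4, 5, 6, 8, 9))

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$")


class UnsupportedICDVersionError(ValueError):
    """Raised when a non-ICD-10 code arrives without a user-supplied mapping."""


@dataclasses.dataclass(frozen=True)
class CodeClassification:
    is_psychosis: bool
    major_class: MajorClass
    is_sud: bool
    is_psychiatric_primary: bool


def _matches(code: str, prefix: str) -> bool:
    # Dotted dialect: a bare category "F20" matches "F20" or "F20.x"; a dotted
    # prefix "F32.3" matches itself or deeper subdivisions ("F32.30").
    if "." in prefix:
        return code == prefix or code.startswith(prefix)
    return code == prefix or code.startswith(prefix + ".")


def _matches_any(code: str, prefixes: Iterable[str]) -> bool:
    return any(_matches(code, p) for p in prefixes)


def classify_code(
    code: str,
    icd_version: int = 10,
    mapping: Mapping[str, str] | None = None,
) -> CodeClassification:
    """Classify a single diagnosis code against the study's endpoint sets.

    Parameters
    ----------
    code:
        Diagnosis code in dotted form, e.g. ``"F20.0"`` or ``"F31"``. Undotted
        concatenations such as ``"F200"`` are rejected as ambiguous.
    icd_version:
        Only ICD-10 is supported natively. For versions 8 and 9 a
        ``mapping`` from historical codes to ICD-10 codes must be supplied;
        no historical equivalence list is invented here.
    mapping:
        Optional code→ICD-10-code table applied before classification when
        ``icd_version`` is 8 or 9.
    """
    if not code:
        raise ValueError("empty diagnosis code")
    if icd_version in (8, 9):
        if mapping is None:
            raise UnsupportedICDVersionError(
                f"ICD-{icd_version} code {code!r}: supply a code mapping to "
                "ICD-10; historical equivalents are not built in"
            )
        try:
            code = mapping[code]
        except KeyError:
            raise UnsupportedICDVersionError(
                f"ICD-{icd_version} code {code!r} missing from supplied mapping"
            ) from None
    elif icd_version != 10:
        raise UnsupportedICDVersionError(f"unsupported ICD version {icd_version!r}")

    code = code.strip().upper()
    if not _CODE_RE.match(code):
        raise ValueError(
            f"malformed code {code!r}: expected dotted ICD-10 form like 'F20' or 'F20.0'"
        )

    major = MajorClass.NONE
    for cls, prefixes in MAJOR_CLASS_PREFIXES.items():
        if _matches_any(code, prefixes):
            major = cls
            break
    is_psychosis = _matches_any(code, PSYCHOSIS_PREFIXES)
    is_sud = _matches_any(code, SUD_PREFIXES)
    is_psychiatric = code.startswith("F")
    return CodeClassification(
        is_psychosis=is_psychosis,
        major_class=major,
        is_sud=is_sud,
        is_psychiatric_primary=is_psychiatric,
    )


def classify_codes(codes: pd.Series, icd_versions: pd.Series | int = 10) -> pd.DataFrame:
    """Vectorized :func:`classify_code` over a code column.

    Returns a DataFrame aligned with ``codes`` holding the four classification
    flags. Unique (code, version) pairs are classified once and broadcast.
    """
    if isinstance(icd_versions, pd.Series):
        versions = icd_versions.astype(int)
    else:
        versions = pd.Series(int(icd_versions), index=codes.index)
    keys = codes.astype(str) + "|" + versions.astype(str)
    rows: dict[str, tuple] = {}
    for key in keys.unique():
        c, v = key.rsplit("|", 1)
        cl = classify_code(c, int(v))
        rows[key] = (cl.is_psychosis, cl.major_class.value, cl.is_sud, cl.is_psychiatric_primary)
    mapped = keys.map(rows)
    return pd.DataFrame(
        mapped.tolist(),
        columns=["is_psychosis", "major_class", "is_sud", "is_psychiatric_primary"],
        index=codes.index,
    )


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Person:
    person_id: str
    sex: Sex
    birth_date: datetime.date
    pgs: Mapping[str, float]
    pcs: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.pcs) != N_PCS:
            raise ValueError(f"person {self.person_id}: expected {N_PCS} PCs")
        for trait, value in self.pgs.items():
            if not np.isfinite(value):
                raise ValueError(f"person {self.person_id}: non-finite PGS for {trait}")


@dataclasses.dataclass(frozen=True)
class DiagnosisEvent:
    person_id: str
    date: datetime.date
    icd_version: int
    code: str


@dataclasses.dataclass(frozen=True)
class HospitalEpisode:
    person_id: str
    admit_date: datetime.date
    discharge_date: datetime.date
    primary_code: str

    @property
    def length_of_stay_days(self) -> int:
        # Inclusive of both admission and discharge day, so same-day stays count 1.
        return (self.discharge_date - self.admit_date).days + 1


class BundleValidationError(ValueError):
    """Raised when a bundle violates schema or referential integrity."""


@dataclasses.dataclass
class RegistryBundle:
    """Validated persons + diagnoses + episodes tables.

    The three frames use the canonical column sets
    (:data:`PERSON_COLUMNS` etc.); dates are ``datetime64[ns]``.
    """

    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    episodes: pd.DataFrame
    study_end: datetime.date = DEFAULT_STUDY_END

    def __post_init__(self) -> None:
        self.persons = self.persons.reset_index(drop=True)
        self.diagnoses = self.diagnoses.reset_index(drop=True)
        self.episodes = self.episodes.reset_index(drop=True)
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        for frame, cols, name in (
            (self.persons, PERSON_COLUMNS, "persons"),
            (self.diagnoses, DIAGNOSIS_COLUMNS, "diagnoses"),
            (self.episodes, EPISODE_COLUMNS, "episodes"),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                problems.append(f"{name}: missing columns {missing}")
        if problems:
            raise BundleValidationError("; ".join(problems))

        if self.persons["person_id"].duplicated().any():
            dupes = self.persons.loc[self.persons["person_id"].duplicated(), "person_id"]
            problems.append(f"duplicate person_id values: {sorted(set(dupes))[:5]}")
        bad_sex = ~self.persons["sex"].isin([s.value for s in Sex])
        if bad_sex.any():
            problems.append(f"invalid sex values in rows {list(self.persons.index[bad_sex])[:5]}")
        pgs_cols = [f"pgs_{t}" for t in PGS_TRAITS]
        if not np.isfinite(self.persons[pgs_cols].to_numpy(dtype=float)).all():
            problems.append("non-finite PGS values in persons table")

        ids = set(self.persons["person_id"])
        end = pd.Timestamp(self.study_end)
        for frame, name, datecols in (
            (self.diagnoses, "diagnoses", ["date"]),
            (self.episodes, "episodes", ["admit_date", "discharge_date"]),
        ):
            orphan = ~frame["person_id"].isin(ids)
            if orphan.any():
                problems.append(f"{name}: orphan person_id rows {list(frame.index[orphan])[:5]}")
            for col in datecols:
                dates = pd.to_datetime(frame[col])
                late = dates > end
                if late.any():
                    problems.append(
                        f"{name}.{col}: {int(late.sum())} event(s) after study_end "
                        f"(rows {list(frame.index[late])[:5]})"
                    )
        if len(self.episodes):
            neg = pd.to_datetime(self.episodes["discharge_date"]) < pd.to_datetime(
                self.episodes["admit_date"]
            )
            if neg.any():
                problems.append(f"episodes: discharge before admission rows {list(self.episodes.index[neg])[:5]}")
        if len(self.diagnoses):
            empty = self.diagnoses["code"].astype(str).str.len() == 0
            if empty.any():
                problems.append("diagnoses: empty codes")
        if problems:
            raise BundleValidationError("; ".join(problems))

    # -- conversions -------------------------------------------------------
    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def iter_persons(self) -> Iterable[Person]:
        for row in self.persons.itertuples(index=False):
            yield Person(
                person_id=row.person_id,
                sex=Sex(row.sex),
                birth_date=pd.Timestamp(row.birth_date).date(),
                pgs={t: getattr(row, f"pgs_{t}") for t in PGS_TRAITS},
                pcs=[getattr(row, f"pc{i}") for i in range(1, N_PCS + 1)],
            )

    def equals(self, other: "RegistryBundle") -> bool:
        def norm(df: pd.DataFrame, datecols: list[str]) -> pd.DataFrame:
            df = df.reset_index(drop=True).copy()
            for c in datecols:
                df[c] = pd.to_datetime(df[c])
            return df

        return (
            self.study_end == other.study_end
            and norm(self.persons, ["birth_date"]).round(12).equals(
                norm(other.persons, ["birth_date"]).round(12)
            )
            and norm(self.diagnoses, ["date"]).equals(norm(other.diagnoses, ["date"]))
            and norm(self.episodes, ["admit_date", "discharge_date"]).equals(
                norm(other.episodes, ["admit_date", "discharge_date"])
            )
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_FILE = "study.json"


def _read_table(
    path: Path,
    columns: Sequence[str],
    date_columns: Sequence[str],
    schema: Mapping[str, str] | None,
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str}, float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise BundleValidationError(f"{path.name}: missing columns {missing}")
    df = df[list(columns)]
    for col in date_columns:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise BundleValidationError(
                f"{path.name}.{col}: unparseable ISO dates in rows {list(df.index[bad])[:5]}"
            )
        df[col] = parsed
    return df


def read_bundle(
    directory: str | Path,
    study_end: datetime.date | None = None,
    schema: Mapping[str, Mapping[str, str]] | None = None,
) -> RegistryBundle:
    """Read ``persons.csv``, ``diagnoses.csv`` and ``episodes.csv``.

    ``schema`` may remap column names per table, e.g.
    ``{"persons": {"id": "person_id"}}``. ``study_end`` defaults to the value
    stored in ``study.json`` (written by :func:`write_bundle`) or 2018-12-31.
    """
    directory = Path(directory)
    schema = schema or {}
    if study_end is None:
        meta = directory / _META_FILE
        if meta.exists():
            study_end = datetime.date.fromisoformat(json.loads(meta.read_text())["study_end"])
        else:
            study_end = DEFAULT_STUDY_END
    persons = _read_table(directory / "persons.csv", PERSON_COLUMNS, ["birth_date"], schema.get("persons"))
    diagnoses = _read_table(directory / "diagnoses.csv", DIAGNOSIS_COLUMNS, ["date"], schema.get("diagnoses"))
    episodes = _read_table(
        directory / "episodes.csv", EPISODE_COLUMNS, ["admit_date", "discharge_date"], schema.get("episodes")
    )
    return RegistryBundle(persons=persons, diagnoses=diagnoses, episodes=episodes, study_end=study_end)


def write_bundle(bundle: RegistryBundle, directory: str | Path) -> dict[str, Path]:
    """Write the three canonical tables plus ``study.json``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def dump(df: pd.DataFrame, name: str, datecols: list[str]) -> None:
        out = df.copy()
        for c in datecols:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path

    dump(bundle.persons[PERSON_COLUMNS], "persons", ["birth_date"])
    dump(bundle.diagnoses[DIAGNOSIS_COLUMNS], "diagnoses", ["date"])
    dump(bundle.episodes[EPISODE_COLUMNS], "episodes", ["admit_date", "discharge_date"])
    meta = directory / _META_FILE
    meta.write_text(json.dumps({"study_end": bundle.study_end.isoformat()}) + "\n")
    paths["meta"] = meta
    return paths
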