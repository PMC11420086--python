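import datetime

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psycourse.registry import (
    MAJOR_CLASS_PREFIXES,
    PSYCHOSIS_PREFIXES,
    BundleValidationError,
    MajorClass,
    UnsupportedICDVersionError,
    classify_code,
    read_bundle,
    write_bundle,
)

from conftest import make_bundle, person_row


@pytest.mark.parametrize(
    "code,major,psychosis,sud,psych_primary",
    [
        ("F20.0", MajorClass.SZ, True, False, True),      # schizophrenia
        ("F20", MajorClass.SZ, True, False, True),
        ("F25.1", MajorClass.SAD, True, False, True),     # schizoaffective
        ("F31", MajorClass.BD, True, False, True),        # bipolar
        ("F30.2", MajorClass.BD, True, False, True),      # manic w/ psychosis
        ("F32.3", MajorClass.PMDD, True, False, True),    # psychotic MDD
        ("F33.3", MajorClass.PMDD, True, False, True),
        ("F23", MajorClass.NONE, True, False, True),      # unranked psychosis
        ("F29", MajorClass.NONE, True, False, True),
        ("F12.1", MajorClass.NONE, False, True, True),    # cannabis SUD
        ("F10.2", MajorClass.NONE, False, True, True),    # alcohol SUD
        ("F17.2", MajorClass.NONE, False, False, True),   # nicotine excluded
        ("F32.2", MajorClass.NONE, False, False, True),   # non-psychotic MDD
        ("F30.1", MajorClass.NONE, False, False, True),   # mania, no psychosis
        ("J45.9", MajorClass.NONE, False, False, False),  # non-psychiatric
    ],
)
def test_icd10_endpoint_sets(code, major, psychosis, sud, psych_primary):
    cl = classify_code(code, 10)
    assert cl.major_class is major
    assert cl.is_psychosis is psychosis
    assert cl.is_sud is sud
    assert cl.is_psychiatric_primary is psych_primary


def test_undotted_concatenation_rejected():
    with pytest.raises(ValueError, match="dotted"):
        classify_code("F200", 10)
    with pytest.raises(ValueError):
        classify_code("", 10)


def test_historical_versions_need_mapping():
    with pytest.raises(UnsupportedICDVersionError):
        classify_code("295.00", 9)
    cl = classify_code("295.00", 9, mapping={"295.00": "F20.0"})
    assert cl.major_class is MajorClass.SZ
    with pytest.raises(UnsupportedICDVersionError):
        classify_code("295.99", 9, mapping={"295.00": "F20.0"})
    with pytest.raises(UnsupportedICDVersionError):
        classify_code("F20", 7)


@given(
    st.integers(0, 99),
    st.one_of(st.none(), st.integers(0, 9)),
)
def test_major_classes_are_psychotic_and_disjoint(num, sub):
    """Every ranked code is in the psychosis set; class sets never overlap,
    and classification is a pure function of the code."""
    code = f"F{num:02d}" + (f".{sub}" if sub is not None else "")
    cl = classify_code(code, 10)
    assert cl == classify_code(code, 10)
    if cl.major_class is not MajorClass.NONE:
        assert cl.is_psychosis
    hits = [
        cls
        for cls, prefixes in MAJOR_CLASS_PREFIXES.items()
        if any(code == p or code.startswith(p + ".") or ("." in p and code.startswith(p)) for p in prefixes)
    ]
    assert len(hits) <= 1


def test_class_prefixes_subset_of_psychosis_prefixes():
    for prefixes in MAJOR_CLASS_PREFIXES.values():
        for p in prefixes:
            assert any(p == q or p.startswith(q + ".") or p == q for q in PSYCHOSIS_PREFIXES)


class TestBundleIO:
    def test_round_trip_identity(self, tmp_path, small_full_bundle):
        bundle, _ = small_full_bundle
        write_bundle(bundle, tmp_path)
        again = read_bundle(tmp_path)
        assert bundle.equals(again)
        # second write is byte-identical (deterministic column order/headers)
        write_bundle(again, tmp_path / "b")
        a = (tmp_path / "persons.csv").read_text()
        b = (tmp_path / "b" / "persons.csv").read_text()
        assert a == b
        assert a.splitlines()[0].startswith("person_id,sex,birth_date,pgs_sz")

    def test_empty_tables(self, tmp_path):
        bundle = make_bundle([person_row("a"), person_row("b")])
        assert len(bundle.episodes) == 0
        write_bundle(bundle, tmp_path)
        again = read_bundle(tmp_path)
        assert again.n_persons == 2 and len(again.episodes) == 0

    def test_zero_person_bundle_headers_only(self, tmp_path):
        template = make_bundle([person_row("x")])
        empty = template.__class__(
            persons=template.persons.iloc[:0],
            diagnoses=template.diagnoses.iloc[:0],
            episodes=template.episodes.iloc[:0],
            study_end=template.study_end,
        )
        paths = write_bundle(empty, tmp_path)
        text = paths["persons"].read_text().strip()
        assert "\n" not in text and text.startswith("person_id,")

    def test_event_after_study_end_rejected(self):
        with pytest.raises(BundleValidationError, match="study_end"):
            make_bundle(
                [person_row("a")],
                diagnoses=[("a", "2019-06-01", "F20")],
                study_end=datetime.date(2018, 12, 31),
            )

    def test_orphan_event_rejected(self):
        with pytest.raises(BundleValidationError, match="orphan"):
            make_bundle([person_row("a")], diagnoses=[("ghost", "2000-01-01", "F20")])

    def test_discharge_before_admission_rejected(self):
        with pytest.raises(BundleValidationError, match="discharge"):
            make_bundle(
                [person_row("a")],
                episodes=[("a", "2001-05-10", "2001-05-01", "F20")],
            )

    def test_missing_column_and_bad_date(self, tmp_path, small_full_bundle):
        bundle, _ = small_full_bundle
        write_bundle(bundle, tmp_path)
        persons = pd.read_csv(tmp_path / "persons.csv")
        persons.drop(columns=["pgs_ea"]).to_csv(tmp_path / "persons.csv", index=False)
        with pytest.raises(BundleValidationError, match="pgs_ea"):
            read_bundle(tmp_path)
        write_bundle(bundle, tmp_path)
        dx = pd.read_csv(tmp_path / "diagnoses.csv")
        dx.loc[0, "date"] = "01/02/2000"
        dx.to_csv(tmp_path / "diagnoses.csv", index=False)
        with pytest.raises(BundleValidationError, match="date"):
            read_bundle(tmp_path)

    def test_schema_remap(self, tmp_path):
        bundle = make_bundle([person_row("a")], diagnoses=[("a", "2000-01-01", "F20")])
        write_bundle(bundle, tmp_path)
        dx = pd.read_csv(tmp_path / "diagnoses.csv").rename(columns={"code": "dg_code"})
        dx.to_csv(tmp_path / "diagnoses.csv", index=False)
        again = read_bundle(tmp_path, schema={"diagnoses": {"dg_code": "code"}})
        assert again.diagnoses.loc[0, "code"] == "F20"
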