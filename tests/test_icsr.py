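"""Line-listing I/O and domain-type invariants."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from pvsignal import (
    AgeGroup,
    CohortCriteria,
    ICSRecord,
    LineListingDialect,
    LineListingFormatError,
    MedDRAMap,
    Region,
    ReporterQualification,
    SeriousCriterion,
    Seriousness,
    Sex,
    read_line_listing,
    write_line_listing,
)

HEADER = (
    "local_report_id,receipt_date,origin_region,seriousness,serious_criteria,"
    "outcome_death,reporter_qualification,sex,age_group,suspect_drugs,reactions"
)


def make_record(**overrides) -> ICSRecord:
    base = dict(
        local_report_id="R-1",
        receipt_date=dt.date(2020, 6, 1),
        origin_region=Region.EEA,
        seriousness=Seriousness.SERIOUS,
        serious_criteria=frozenset({SeriousCriterion.HOSPITALIZATION}),
        outcome_death=False,
        reporter_qualification=ReporterQualification.HEALTHCARE_PROFESSIONAL,
        sex=Sex.FEMALE,
        age_group=AgeGroup.Y18_64,
        suspect_drugs=frozenset({"esketamine"}),
        reactions=("Anxiety",),
    )
    base.update(overrides)
    return ICSRecord(**base)


class TestICSRecordInvariants:
    def test_reactions_must_be_nonempty(self):
        with pytest.raises(ValueError, match="reactions"):
            make_record(reactions=())

    def test_duplicate_pt_rejected_after_normalization(self):
        with pytest.raises(ValueError, match="duplicate PT"):
            make_record(reactions=("Anxiety", "anxiety "))

    def test_fatal_outcome_requires_serious_with_death_criterion(self):
        with pytest.raises(ValueError, match="death criterion"):
            make_record(outcome_death=True)
        ok = make_record(
            outcome_death=True, serious_criteria=frozenset({SeriousCriterion.DEATH})
        )
        assert ok.outcome_death

    def test_empty_report_id_rejected(self):
        with pytest.raises(ValueError, match="local_report_id"):
            make_record(local_report_id="")


class TestMedDRAMap:
    def test_merge_is_idempotent_and_canonical_terms_are_mapped(self):
        m = MedDRAMap(
            pt_to_soc={"Dissociation/dissociative disorder": "Psychiatric disorders"},
            synonym_merge={
                "Dissociation": "Dissociation/dissociative disorder",
                "Dissociative disorder": "Dissociation/dissociative disorder",
            },
        )
        once = m.merge_term("Dissociation")
        assert m.merge_term(once) == once
        assert m.soc_of("Dissociative disorder") == "Psychiatric disorders"

    def test_canonical_term_without_soc_entry_rejected(self):
        with pytest.raises(ValueError, match="no SOC entry"):
            MedDRAMap(pt_to_soc={}, synonym_merge={"Dissociation": "Merged term"})

    def test_unmapped_terms_pass_through(self):
        m = MedDRAMap()
        assert m.merge_term("Vertigo") == "Vertigo"
        assert m.soc_of("Vertigo") is None

    def test_csv_round_trip(self, tmp_path):
        m = MedDRAMap(
            pt_to_soc={"Anxiety": "Psychiatric disorders", "Nausea": "Gastrointestinal disorders"},
            synonym_merge={"Anxiousness": "Anxiety"},
        )
        m.to_csv(tmp_path / "soc.csv", tmp_path / "syn.csv")
        back = MedDRAMap.from_csv(tmp_path / "soc.csv", tmp_path / "syn.csv")
        assert back.soc_of("Anxiousness") == "Psychiatric disorders"


class TestCohortCriteria:
    def test_inverted_date_window_rejected(self):
        with pytest.raises(ValueError, match="after end"):
            CohortCriteria(date_window=(dt.date(2024, 1, 1), dt.date(2019, 1, 1)))

    def test_first_failed_criterion_is_named(self):
        crit = CohortCriteria(require_serious=True, require_hcp_reporter=True)
        rec = make_record(seriousness=Seriousness.NON_SERIOUS, serious_criteria=frozenset())
        assert crit.failed_criterion(rec) == "seriousness"
        assert crit.failed_criterion(make_record()) is None


class TestLineListingIO:
    def test_three_row_fixture_preserves_order_and_multiple_pts(self, tmp_path):
        path = tmp_path / "l.csv"
        path.write_text(
            HEADER + "\n"
            'A,2020-01-02,EEA,SERIOUS,hospitalization,false,HEALTHCARE_PROFESSIONAL,'
            'Female,18-64 years,esketamine,"Anxiety;Dizziness"\n'
            "B,2020-01-03,EEA,NON_SERIOUS,,false,HEALTHCARE_PROFESSIONAL,"
            "Male,65-85 years,esketamine,Nausea\n"
            "C,2020-01-04,UK,SERIOUS,death,true,HEALTHCARE_PROFESSIONAL,"
            "Male,18-64 years,esketamine,Completed suicide\n"
        )
        records = read_line_listing(path)
        assert [r.local_report_id for r in records] == ["A", "B", "C"]
        assert records[0].reactions == ("Anxiety", "Dizziness")
        assert records[2].outcome_death

    def test_unparseable_sex_and_age_map_to_unknown(self, tmp_path):
        path = tmp_path / "l.csv"
        path.write_text(
            HEADER + "\n"
            "A,2020-01-02,EEA,SERIOUS,hospitalization,false,HEALTHCARE_PROFESSIONAL,"
            "Not Specified,Adolescent?,esketamine,Anxiety\n"
        )
        (rec,) = read_line_listing(path)
        assert rec.sex is Sex.UNKNOWN
        assert rec.age_group is AgeGroup.UNKNOWN

    def test_missing_mandatory_column_is_named(self, tmp_path):
        path = tmp_path / "l.csv"
        path.write_text(HEADER.replace("reactions", "rxns") + "\n")
        with pytest.raises(LineListingFormatError, match="reactions"):
            read_line_listing(path)

    def test_empty_file_yields_empty_collection(self, tmp_path):
        path = tmp_path / "l.csv"
        path.write_text("")
        assert read_line_listing(path) == []

    def test_write_empty_collection_gives_header_only(self, tmp_path):
        path = tmp_path / "out.csv"
        write_line_listing([], path)
        assert path.read_text().strip() == HEADER

    def test_reaction_cell_is_subdelimited(self, tmp_path):
        path = tmp_path / "out.csv"
        write_line_listing([make_record(reactions=("A pt", "B pt", "C pt"))], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert "A pt;B pt;C pt" in lines[1]

    def test_custom_dialect_column_mapping(self, tmp_path):
        dialect = LineListingDialect(
            delimiter="\t", sub_delimiter="|", column_map={"EV Local Number": "local_report_id"}
        )
        path = tmp_path / "l.tsv"
        header = HEADER.replace(",", "\t").replace("local_report_id", "EV Local Number")
        path.write_text(
            header + "\n"
            "A\t2020-01-02\tEEA\tSERIOUS\thospitalization\tfalse\t"
            "HEALTHCARE_PROFESSIONAL\tFemale\t18-64 years\tesketamine\tAnxiety|Nausea\n"
        )
        (rec,) = read_line_listing(path, dialect)
        assert rec.local_report_id == "A"
        assert rec.reactions == ("Anxiety", "Nausea")

    def test_round_trip_on_reference_listing(self, tmp_path, study):
        path = tmp_path / "esk.csv"
        original = study.raw_records["esketamine"]
        write_line_listing(original, path)
        assert read_line_listing(path) == original


_pt = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ ",
    min_size=1,
    max_size=20,
).map(lambda s: " ".join(s.split())).filter(bool)


@st.composite
def icsr_records(draw):
    death = draw(st.booleans())
    reactions = draw(
        st.lists(_pt, min_size=1, max_size=4, unique_by=lambda t: t.casefold())
    )
    criteria = set(draw(st.sets(st.sampled_from(list(SeriousCriterion)), max_size=3)))
    if death:
        criteria.add(SeriousCriterion.DEATH)
    return make_record(
        local_report_id=draw(st.uuids()).hex,
        receipt_date=draw(st.dates(dt.date(2019, 1, 1), dt.date(2024, 12, 31))),
        origin_region=draw(st.sampled_from(list(Region))),
        seriousness=Seriousness.SERIOUS if death else draw(st.sampled_from(list(Seriousness))),
        serious_criteria=frozenset(criteria),
        outcome_death=death,
        sex=draw(st.sampled_from(list(Sex))),
        age_group=draw(st.sampled_from(list(AgeGroup))),
        suspect_drugs=frozenset(
            draw(st.lists(_pt.map(str.casefold), min_size=1, max_size=3, unique=True))
        ),
        reactions=tuple(reactions),
    )


@given(st.lists(icsr_records(), max_size=25))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_round_trip_is_lossless_for_arbitrary_records(tmp_path_factory, records):
    """write ∘ read is the identity on any valid record collection."""
    path = tmp_path_factory.mktemp("rt") / "listing.csv"
    write_line_listing(records, path)
    assert read_line_listing(path) == records
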