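"""Pedigree I/O round-trips, validation, ancestor traversal, and the
eligibility filters of cohort construction."""

import io

import numpy as np
import pandas as pd
import pytest

from lineage_load.pedigree import (
    IndividualRecord,
    Pedigree,
    PedigreeError,
    age_at_fathering,
    build_cohort,
    collect_male_ancestors,
    read_pedigree,
    write_pedigree,
)
from lineage_load.synthetic_data import SimulationConfig, simulate_population
from lineage_load.wmama import compute_wmama


def ped_from_text(text: str) -> Pedigree:
    return read_pedigree(io.StringIO(text))


TOY = """id\tsex\tfather_id\tmother_id\tbirth_year
c\tmale\tf\tm\t1850
f\tmale\tNA\tNA\t1820
m\tfemale\tNA\tNA\t1822
"""


class TestReadWrite:
    def test_toy_file_resolves_parents(self):
        ped = ped_from_text(TOY)
        assert len(ped) == 3
        assert ped.father_of("c").id == "f"
        assert ped.mother_of("c").sex == "female"

    def test_comma_dialect_and_column_mapping(self):
        text = "ind,gender,pa,ma,born\nc,male,NA,NA,1850\n"
        ped = read_pedigree(
            io.StringIO(text),
            dialect={"id": "ind", "sex": "gender", "father_id": "pa", "mother_id": "ma", "birth_year": "born"},
        )
        assert ped["c"].birth_year == 1850

    def test_self_parent_rejected(self):
        bad = "id\tsex\tfather_id\tmother_id\tbirth_year\nc\tmale\tc\tNA\t1850\n"
        with pytest.raises(PedigreeError, match="own parent"):
            ped_from_text(bad)

    def test_ancestry_cycle_rejected(self):
        records = {
            "a": IndividualRecord(id="a", sex="male", father_id="b"),
            "b": IndividualRecord(id="b", sex="male", father_id="a"),
        }
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree(records=records)

    def test_duplicate_id_rejected(self):
        dup = TOY + "c\tmale\tNA\tNA\t1851\n"
        with pytest.raises(PedigreeError, match="duplicate"):
            ped_from_text(dup)

    def test_missing_column_named(self):
        with pytest.raises(PedigreeError, match="birth_year"):
            ped_from_text("id\tsex\tfather_id\tmother_id\nc\tmale\tNA\tNA\n")

    def test_wrong_parent_sex_rejected(self):
        bad = (
            "id\tsex\tfather_id\tmother_id\tbirth_year\n"
            "c\tmale\tf\tNA\t1850\n"
            "f\tfemale\tNA\tNA\t1820\n"
        )
        with pytest.raises(PedigreeError, match="sex"):
            ped_from_text(bad)

    def test_empty_pedigree_roundtrip(self):
        buf = io.StringIO()
        write_pedigree(Pedigree(records={}), buf)
        assert len(ped_from_text(buf.getvalue())) == 0

    def test_roundtrip_identity(self, fixture_pedigree):
        buf = io.StringIO()
        write_pedigree(fixture_pedigree, buf)
        again = ped_from_text(buf.getvalue())
        assert again.records.keys() == fixture_pedigree.records.keys()
        for pid, rec in fixture_pedigree.records.items():
            assert again[pid] == rec

    def test_fixture_loads_clean(self, fixture_pedigree):
        assert len(fixture_pedigree) == 15


class TestAgeAtFathering:
    def test_integer_years(self):
        f = IndividualRecord(id="f", sex="male", birth_year=1820)
        c = IndividualRecord(id="c", sex="male", birth_year=1850)
        assert age_at_fathering(f, c) == 30

    def test_fractional_years(self):
        f = IndividualRecord(id="f", sex="male", birth_year=1820.5)
        c = IndividualRecord(id="c", sex="male", birth_year=1850.25)
        assert age_at_fathering(f, c) == pytest.approx(29.75)

    def test_impossible_ordering_raises(self):
        f = IndividualRecord(id="f", sex="male", birth_year=1850)
        c = IndividualRecord(id="c", sex="male", birth_year=1840)
        with pytest.raises(PedigreeError):
            age_at_fathering(f, c)

    def test_argument_swap_raises_never_negative(self):
        f = IndividualRecord(id="f", sex="male", birth_year=1820)
        c = IndividualRecord(id="c", sex="male", birth_year=1850)
        assert age_at_fathering(f, c) == 30
        with pytest.raises(PedigreeError):
            age_at_fathering(c, f)

    def test_extreme_age_warns_but_returns(self):
        f = IndividualRecord(id="f", sex="male", birth_year=1820)
        c = IndividualRecord(id="c", sex="male", birth_year=1910)
        with pytest.warns(UserWarning, match="outside"):
            assert age_at_fathering(f, c) == 90


class TestCollectMaleAncestors:
    def test_full_lattice(self, fixture_pedigree):
        aset = collect_male_ancestors(fixture_pedigree, "P1")
        assert len(aset.entries) == 7
        by_gen = {g: sorted(e.age for e in aset.at_generation(g)) for g in (1, 2, 3)}
        assert by_gen == {1: [25.0], 2: [30.0, 35.0], 3: [40.0, 40.0, 40.0, 40.0]}
        weights = sorted(e.relatedness for e in aset.entries)
        assert weights == [0.125] * 4 + [0.25] * 2 + [0.5]
        assert sum(weights) == pytest.approx(1.5)
        assert aset.missing_by_generation == {1: 0, 2: 0, 3: 0}
        assert compute_wmama(aset).m == pytest.approx(32.5)
        assert compute_wmama(aset, "exclude_father").m == pytest.approx(36.25)

    def test_grandfathers_only_weight_sum(self, fixture_pedigree):
        aset = collect_male_ancestors(fixture_pedigree, "F")
        # F has father and both grandfathers known, no great-grandfathers
        assert len(aset.entries) == 3
        assert sum(e.relatedness for e in aset.entries) == pytest.approx(1.0)
        assert aset.missing_by_generation[3] == 4

    def test_no_father(self, fixture_pedigree):
        aset = collect_male_ancestors(fixture_pedigree, "FFF")
        assert aset.entries == []
        assert aset.missing_by_generation[1] == 1

    def test_absent_proband(self, fixture_pedigree):
        with pytest.raises(KeyError):
            collect_male_ancestors(fixture_pedigree, "nobody")


class TestBuildCohort:
    def test_unknown_outcome(self, fixture_pedigree):
        with pytest.raises(ValueError, match="outcome"):
            build_cohort(fixture_pedigree, "fecundity")

    def test_emigrant_exclusion_matches_truth(self, small_cohort):
        result = build_cohort(small_cohort.pedigree, "survival15")
        truth = small_cohort.truth.set_index("id")
        # recompute, from the generative truth, how many probands eligible at
        # that point in the filter chain emigrated before 15
        eligible = []
        for pid, rec in small_cohort.pedigree.records.items():
            aset = collect_male_ancestors(small_cohort.pedigree, pid)
            if rec.birth_year is not None and rec.birth_year < 1900 and aset.has_baseline():
                father = small_cohort.pedigree.father_of(pid)
                if father is not None and father.social_class is not None:
                    eligible.append(pid)
        emi = truth.loc[eligible, "emigration_year"] - truth.loc[eligible, "birth_year"]
        expected = int((emi < 15).sum())
        assert result.attrition["emigrated_before_15"] == expected

    def test_attrition_sums_to_candidates_minus_rows(self, small_cohort):
        for outcome in ("survival15", "longevity", "marriage", "lbs"):
            result = build_cohort(small_cohort.pedigree, outcome)
            assert sum(result.attrition.values()) == result.n_candidates - len(result.table)
            assert result.table["outcome"].notna().all()

    def test_filters_are_monotone(self, small_cohort):
        result = build_cohort(small_cohort.pedigree, "marriage")
        assert all(v >= 0 for v in result.attrition.values())

    def test_partial_grandfather_knowledge_excludes(self):
        # proband with only one grandfather's birth year known
        rows = [
            "id\tsex\tfather_id\tmother_id\tbirth_year\tdeath_year\tparish\tsocial_class",
            "p\tmale\tf\tm\t1850\t1920\tx\tpoor",
            "f\tmale\tff\tNA\t1820\t1880\tx\tpoor",
            "m\tfemale\tmf\tNA\t1822\t1884\tx\tpoor",
            "ff\tmale\tNA\tNA\t1790\t1860\tx\tpoor",
            "mf\tmale\tNA\tNA\tNA\t1858\tx\tpoor",  # birth year unknown
        ]
        ped = ped_from_text("\n".join(rows) + "\n")
        result = build_cohort(ped, "survival15")
        assert len(result.table) == 0
        assert result.attrition["father_or_grandfather_age_unknown"] >= 1

    def test_early_death_excluded_from_marriage(self):
        rows = [
            "id\tsex\tfather_id\tmother_id\tbirth_year\tdeath_year\tparish\tsocial_class\tmarried\tmaternal_age_at_birth",
            "p\tfemale\tf\tm\t1850\t1890\tx\tpoor\t0\t28",  # died at 40, never married
            "q\tfemale\tf\tm\t1852\t1902\tx\tpoor\t1\t30",  # followed past 45
            "f\tmale\tff\tmf2\t1820\t1880\tx\tpoor\t1\t25",
            "m\tfemale\tmf\tNA\t1822\t1884\tx\tpoor\t1\t26",
            "ff\tmale\tNA\tNA\t1790\t1860\tx\tpoor\t1\tNA",
            "mf\tmale\tNA\tNA\t1795\t1858\tx\tpoor\t1\tNA",
            "mf2\tfemale\tNA\tNA\t1794\t1860\tx\tpoor\t1\tNA",
        ]
        ped = ped_from_text("\n".join(rows) + "\n")
        result = build_cohort(ped, "marriage")
        assert list(result.table["proband_id"]) == ["q"]
        assert result.attrition["died_or_emigrated_before_repro_completion"] == 1
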