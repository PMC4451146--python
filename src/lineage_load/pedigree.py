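"""Pedigree data model, delimited-text I/O, and cohort construction.

One row per individual; parent links by id.  The file dialect is a
header-bearing tab- (or comma-) delimited table with ``NA`` as the missing
marker, columns named as in :class:`IndividualRecord`.  A column-mapping
dict supports files with other header names.

Cohort construction applies the eligibility rules used throughout the
analyses: probands born before 1900 whose father's and both grandfathers'
ages at fathering the lineage are known, with known social class, plus
outcome-specific restrictions (see :func:`build_cohort`).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import IO, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .wmama import AncestorAge, AncestorAgeSet, compute_wmama

__all__ = [
    "IndividualRecord",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "age_at_fathering",
    "collect_male_ancestors",
    "build_cohort",
    "CohortResult",
    "PEDIGREE_COLUMNS",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or record set."""


#: Canonical file columns, in write order.
PEDIGREE_COLUMNS = [
    "id",
    "sex",
    "father_id",
    "mother_id",
    "birth_year",
    "death_year",
    "emigration_year",
    "parish",
    "social_class",
    "twin",
    "first_born",
    "married",
    "marriage_year",
    "n_children",
    "maternal_age_at_birth",
]

REQUIRED_COLUMNS = ["id", "sex", "father_id", "mother_id", "birth_year"]

SOCIAL_CLASSES = ("rich", "middle", "poor")

#: Plausible age-at-fathering window; values outside it trigger a warning
#: but are still returned (historical records contain outliers).
FATHERING_AGE_RANGE = (13.0, 80.0)


@dataclass
class IndividualRecord:
    """One person: identifiers, vital dates, covariates, fitness outcomes."""

    id: str
    sex: Literal["male", "female"]
    father_id: str | None = None
    mother_id: str | None = None
    birth_year: float | None = None
    death_year: float | None = None
    emigration_year: float | None = None
    parish: str | None = None
    social_class: str | None = None
    twin: bool = False
    first_born: bool = False
    married: bool | None = None
    marriage_year: float | None = None
    n_children: int | None = None
    maternal_age_at_birth: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise PedigreeError(f"record {self.id!r}: sex must be 'male' or 'female', got {self.sex!r}")
        if self.father_id == self.id or self.mother_id == self.id:
            raise PedigreeError(f"record {self.id!r} lists itself as its own parent")
        if self.birth_year is not None:
            if self.death_year is not None and self.death_year < self.birth_year:
                raise PedigreeError(f"record {self.id!r}: death_year precedes birth_year")
            if self.marriage_year is not None and self.marriage_year < self.birth_year:
                raise PedigreeError(f"record {self.id!r}: marriage_year precedes birth_year")
        if self.social_class is not None and self.social_class not in SOCIAL_CLASSES:
            raise PedigreeError(f"record {self.id!r}: social_class must be one of {SOCIAL_CLASSES}, got {self.social_class!r}")
        if self.n_children is not None and self.n_children < 0:
            raise PedigreeError(f"record {self.id!r}: n_children must be non-negative")


@dataclass
class Pedigree:
    """Mapping id -> IndividualRecord with validated parent links."""

    records: dict[str, IndividualRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.records

    def __getitem__(self, individual_id: str) -> IndividualRecord:
        try:
            return self.records[individual_id]
        except KeyError:
            raise KeyError(f"no individual {individual_id!r} in pedigree") from None

    def add(self, record: IndividualRecord) -> None:
        if record.id in self.records:
            raise PedigreeError(f"duplicate id {record.id!r}")
        self.records[record.id] = record

    def father_of(self, individual_id: str) -> IndividualRecord | None:
        fid = self[individual_id].father_id
        return self.records.get(fid) if fid is not None else None

    def mother_of(self, individual_id: str) -> IndividualRecord | None:
        mid = self[individual_id].mother_id
        return self.records.get(mid) if mid is not None else None

    def validate(self) -> None:
        """Check parent sexes and acyclicity of the parent graph.

        Parent ids that do not resolve within the pedigree are treated as
        external (founder parents outside the record set), not as errors.
        """
        g = nx.DiGraph()
        for rec in self.records.values():
            g.add_node(rec.id)
            for pid, want_sex in ((rec.father_id, "male"), (rec.mother_id, "female")):
                if pid is None:
                    continue
                parent = self.records.get(pid)
                if parent is not None:
                    if parent.sex != want_sex:
                        role = "father" if want_sex == "male" else "mother"
                        raise PedigreeError(f"record {rec.id!r}: {role} {pid!r} has sex {parent.sex!r}")
                    g.add_edge(rec.id, pid)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(a) for a, _ in cycle)
            raise PedigreeError(f"pedigree contains an ancestry cycle: {path}")


def _coerce_records(df: pd.DataFrame, source_name: str) -> dict[str, IndividualRecord]:
    records: dict[str, IndividualRecord] = {}
    problems: list[str] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        d = dict(zip(df.columns, row))
        try:
            rec = IndividualRecord(
                id=str(d["id"]),
                sex=str(d["sex"]),
                father_id=None if pd.isna(d.get("father_id")) else str(d["father_id"]),
                mother_id=None if pd.isna(d.get("mother_id")) else str(d["mother_id"]),
                birth_year=None if pd.isna(d.get("birth_year")) else float(d["birth_year"]),
                death_year=None if pd.isna(d.get("death_year")) else float(d["death_year"]),
                emigration_year=None if pd.isna(d.get("emigration_year")) else float(d["emigration_year"]),
                parish=None if pd.isna(d.get("parish")) else str(d["parish"]),
                social_class=None if pd.isna(d.get("social_class")) else str(d["social_class"]),
                twin=bool(int(d.get("twin", 0))) if not pd.isna(d.get("twin")) else False,
                first_born=bool(int(d.get("first_born", 0))) if not pd.isna(d.get("first_born")) else False,
                married=None if pd.isna(d.get("married")) else bool(int(d["married"])),
                marriage_year=None if pd.isna(d.get("marriage_year")) else float(d["marriage_year"]),
                n_children=None if pd.isna(d.get("n_children")) else int(d["n_children"]),
                maternal_age_at_birth=None if pd.isna(d.get("maternal_age_at_birth")) else float(d["maternal_age_at_birth"]),
            )
        except (PedigreeError, ValueError, TypeError) as exc:
            problems.append(f"{source_name} line {lineno}: {exc}")
            continue
        if rec.id in records:
            raise PedigreeError(f"{source_name} line {lineno}: duplicate id {rec.id!r}")
        records[rec.id] = rec
    if problems:
        raise PedigreeError("unparseable rows:\n" + "\n".join(problems))
    return records


def read_pedigree(
    source: str | Path | IO[str],
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> Pedigree:
    """Read a delimited pedigree file into a validated :class:`Pedigree`.

    Parameters
    ----------
    source
        Path or open text stream; tab- or comma-delimited with a header row
        and ``NA`` for missing values.
    dialect
        Optional mapping from canonical column names to the file's header
        names, for files that use a different vocabulary.
    sep
        Field separator; sniffed from the header line when omitted.
    """
    name = getattr(source, "name", None) or str(source)
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    if sep is None:
        header = text.split("\n", 1)[0]
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, na_values=["NA"], keep_default_na=False, dtype={"id": str, "father_id": str, "mother_id": str})
    if dialect:
        reverse = {v: k for k, v in dialect.items()}
        df = df.rename(columns=reverse)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"{name}: missing required column(s): {', '.join(missing)}")
    return Pedigree(records=_coerce_records(df, name))


def write_pedigree(pedigree: Pedigree, sink: str | Path | IO[str], sep: str = "\t") -> None:
    """Write a pedigree as delimited text; round-trips through :func:`read_pedigree`."""

    def cell(value: object) -> str:
        if value is None:
            return "NA"
        if isinstance(value, bool):
            return str(int(value))
        if isinstance(value, float) and value.is_integer():
            return str(int(value))
        return str(value)

    rows = []
    for rec in pedigree.records.values():
        rows.append({f.name: cell(getattr(rec, f.name)) for f in dataclass_fields(rec)})
    df = pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)
    out = df.to_csv(sep=sep, index=False, lineterminator="\n")
    if hasattr(sink, "write"):
        sink.write(out)
    else:
        Path(sink).write_text(out)


def age_at_fathering(father: IndividualRecord, child: IndividualRecord) -> float:
    """Father's age at the child's birth, from birth years.

    Fractional years propagate if the input years are fractional; with
    integer calendar years the value is quantised to +/- 1 year.
    """
    if father.birth_year is None or child.birth_year is None:
        raise PedigreeError(f"birth year missing for {father.id!r} or {child.id!r}")
    age = child.birth_year - father.birth_year
    if age <= 0:
        raise PedigreeError(f"father {father.id!r} (born {father.birth_year}) not older than child {child.id!r} (born {child.birth_year})")
    lo, hi = FATHERING_AGE_RANGE
    if not lo <= age <= hi:
        warnings.warn(f"age at fathering {age:.1f} for {father.id!r} -> {child.id!r} outside [{lo:.0f}, {hi:.0f}]", stacklevel=2)
    return age


def collect_male_ancestors(pedigree: Pedigree, proband_id: str, max_generations: int = 3) -> AncestorAgeSet:
    """Male ancestors of a proband with ages at fathering the lineage.

    Walks the full ancestor lattice: at generation g the male ancestors are
    the fathers of the (male and female) generation g-1 ancestors, and each
    contributes his age at fathering the next individual down the proband's
    lineage.  Ancestors that cannot be resolved, or whose birth year (or the
    child's) is unknown, are omitted and tallied in
    ``missing_by_generation``.
    """
    if proband_id not in pedigree:
        raise KeyError(f"no individual {proband_id!r} in pedigree")
    if max_generations not in (1, 2, 3):
        raise ValueError(f"max_generations must be 1, 2 or 3, got {max_generations}")

    entries: list[AncestorAge] = []
    missing: dict[int, int] = {g: 0 for g in range(1, max_generations + 1)}
    # frontier: individuals at generation g-1 whose fathers are the
    # generation-g male ancestors; None marks an untraceable branch
    frontier: list[IndividualRecord | None] = [pedigree[proband_id]]
    for g in range(1, max_generations + 1):
        next_frontier: list[IndividualRecord | None] = []
        for child in frontier:
            if child is None:
                missing[g] += 1
                next_frontier.extend([None, None])
                continue
            father = pedigree.father_of(child.id)
            mother = pedigree.mother_of(child.id)
            if father is None or father.birth_year is None or child.birth_year is None:
                missing[g] += 1
            else:
                entries.append(AncestorAge(ancestor_id=father.id, generation=g, age=age_at_fathering(father, child)))
            next_frontier.extend([father, mother])
        frontier = next_frontier
    return AncestorAgeSet(proband_id=proband_id, entries=entries, missing_by_generation=missing)


OUTCOMES = ("survival15", "longevity", "marriage", "lbs")

#: Censoring/completion age thresholds for marriage and breeding analyses:
#: 99% of reproduction is complete by 45 in females and 50 in males.
REPRO_COMPLETE_AGE = {"female": 45.0, "male": 50.0}


@dataclass
class CohortResult:
    """Filtered analysis table plus per-filter attrition counts."""

    table: pd.DataFrame
    attrition: dict[str, int]
    n_candidates: int


def _survived_to_15(rec: IndividualRecord) -> bool | None:
    if rec.birth_year is None:
        return None
    if rec.death_year is not None:
        return rec.death_year - rec.birth_year >= 15.0
    return True  # no recorded death before 15


def build_cohort(
    pedigree: Pedigree,
    outcome: str,
    wmama_values: Mapping[str, Mapping[str, float]] | None = None,
) -> CohortResult:
    """Build the analysis cohort for one fitness outcome.

    Filters applied in order, with attrition counted at each step:

    1. born before 1900;
    2. father's and both grandfathers' ages at fathering known (the WMAMA
       eligibility baseline; great-grandfathers optional);
    3. social class known — from the father's record for survival15,
       longevity and marriage (children carried their father's class), from
       the proband's own record for lifetime breeding success;
    4. outcome-specific:

       * ``survival15`` — exclude probands who emigrated before 15 and, when
         a ``birth_parish`` attribute distinguishes it from ``parish``,
         probands born outside the focal parish;
       * ``longevity`` — survived to 15, death year known, non-emigrant;
       * ``marriage`` — survived to 15, marital status known, and not dead
         or emigrated before age 45 (female) / 50 (male);
       * ``lbs`` — as marriage, plus ever married and child count known.

    ``wmama_values`` optionally overrides the WMAMA columns; by default they
    are computed from the pedigree for each candidate.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")

    candidates = list(pedigree.records.values())
    n_candidates = len(candidates)
    attrition: dict[str, int] = {}

    def apply(label: str, keep) -> None:
        nonlocal candidates
        before = len(candidates)
        candidates = [r for r in candidates if keep(r)]
        attrition[label] = before - len(candidates)

    apply("born_1900_or_later_or_unknown", lambda r: r.birth_year is not None and r.birth_year < 1900)

    ancestor_sets: dict[str, AncestorAgeSet] = {}

    def has_baseline(rec: IndividualRecord) -> bool:
        aset = collect_male_ancestors(pedigree, rec.id)
        ancestor_sets[rec.id] = aset
        return aset.has_baseline()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # out-of-range fathering ages already vetted upstream
        apply("father_or_grandfather_age_unknown", has_baseline)

    def class_of(rec: IndividualRecord) -> str | None:
        if outcome == "lbs":
            return rec.social_class
        father = pedigree.father_of(rec.id)
        return father.social_class if father is not None else None

    apply("social_class_unknown", lambda r: class_of(r) is not None)

    def age_or_none(year: float | None, rec: IndividualRecord) -> float | None:
        return None if year is None or rec.birth_year is None else year - rec.birth_year

    if outcome == "survival15":
        apply("emigrated_before_15", lambda r: not (
            r.emigration_year is not None and age_or_none(r.emigration_year, r) < 15.0
        ))
        apply("born_outside_focal_parish", lambda r: getattr(r, "birth_parish", r.parish) == r.parish)
        apply("survival_unknown", lambda r: _survived_to_15(r) is not None and r.parish is not None)
    elif outcome == "longevity":
        apply("died_before_15_or_unknown", lambda r: _survived_to_15(r) is True)
        apply("death_year_unknown", lambda r: r.death_year is not None)
        apply("emigrant", lambda r: r.emigration_year is None or r.emigration_year >= r.death_year)
    elif outcome in ("marriage", "lbs"):
        apply("died_before_15_or_unknown", lambda r: _survived_to_15(r) is True)

        def followed_to_completion(r: IndividualRecord) -> bool:
            threshold = REPRO_COMPLETE_AGE[r.sex]
            death_age = age_or_none(r.death_year, r)
            emi_age = age_or_none(r.emigration_year, r)
            if emi_age is not None and emi_age < threshold:
                return False
            return death_age is not None and death_age >= threshold

        apply("died_or_emigrated_before_repro_completion", followed_to_completion)
        apply("marital_status_unknown", lambda r: r.married is not None)
        if outcome == "lbs":
            apply("never_married", lambda r: r.married is True)
            apply("n_children_unknown", lambda r: r.n_children is not None)

    rows = []
    for rec in candidates:
        aset = ancestor_sets[rec.id]
        if wmama_values is not None and rec.id in wmama_values:
            w = wmama_values[rec.id]
            wm, wm_nf = w["wmama"], w["wmama_excl_father"]
        else:
            wm = compute_wmama(aset, "full").m
            wm_nf = compute_wmama(aset, "exclude_father").m
        father = pedigree.father_of(rec.id)
        maternal_age = rec.maternal_age_at_birth
        if maternal_age is None:
            mother = pedigree.mother_of(rec.id)
            if mother is not None and mother.birth_year is not None and rec.birth_year is not None:
                maternal_age = rec.birth_year - mother.birth_year
        if outcome == "survival15":
            y: float | int | None = int(_survived_to_15(rec))
        elif outcome == "longevity":
            y = int(rec.death_year - rec.birth_year - 15.0)  # whole years lived past 15
        elif outcome == "marriage":
            y = int(rec.married)
        else:
            y = int(rec.n_children)
        rows.append(
            {
                "proband_id": rec.id,
                "outcome": y,
                "wmama": wm,
                "wmama_excl_father": wm_nf,
                "father_age": aset.father.age,
                "maternal_age": maternal_age,
                "parish": rec.parish,
                "social_class": class_of(rec),
                "twin": int(rec.twin),
                "first_born": int(rec.first_born),
                "sex": rec.sex,
                "birth_year": rec.birth_year,
                "mother_id": rec.mother_id if rec.mother_id is not None else f"solo:{rec.id}",
                # death age (NaN if unknown) feeds the person-year hazard model
                "death_age": (rec.death_year - rec.birth_year) if rec.death_year is not None else np.nan,
            }
        )
    columns = [
        "proband_id", "outcome", "wmama", "wmama_excl_father", "father_age",
        "maternal_age", "parish", "social_class", "twin", "first_born",
        "sex", "birth_year", "mother_id", "death_age",
    ]
    table = pd.DataFrame(rows, columns=columns)
    # maternal age is a required analysis covariate
    before = len(table)
    table = table[table["maternal_age"].notna() & table["parish"].notna()].reset_index(drop=True)
    attrition["maternal_age_or_parish_unknown"] = before - len(table)
    return CohortResult(table=table, attrition=attrition, n_candidates=n_candidates)
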