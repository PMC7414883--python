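"""Study records for biallelic case-control SNP data: parsing, validation,
classification, and the bundled 15-study rs1805087 prostate-cancer dataset.

The central container is :class:`StudyRecord` -- genotype counts for the case
and control arms of one study plus the stratification metadata a meta-analysis
needs (ethnicity, control source, Newcastle-Ottawa quality score, genotyping
method).  Genotypes are encoded relative to the *minor* allele G: ``gg`` is
the minor-allele homozygote, ``ga`` the heterozygote, ``aa`` the major-allele
(wild-type) homozygote.

Studies are exchanged as UTF-8 delimited text with the canonical header::

    study_id,author,year,ethnicity,source,nos,method,
    case_gg,case_ga,case_aa,ctrl_gg,ctrl_ga,ctrl_aa

Lines starting with ``#`` are comments.  A column map lets differently named
exports load without editing.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from .exceptions import (
    DegenerateStudyError,
    StudyValidationError,
    VocabularyError,
)

__all__ = [
    "ETHNICITIES",
    "SOURCES",
    "CANONICAL_COLUMNS",
    "GenotypeCounts",
    "StudyRecord",
    "StudyStrata",
    "parse_studies",
    "write_studies",
    "builtin_fixture",
    "classify",
    "BUILTIN_DATASETS",
]

#: Closed vocabulary of ethnicity labels.
ETHNICITIES = ("European", "Asian", "African", "SouthAmerican")

#: Closed vocabulary of control-source labels: hospital- or population-based.
SOURCES = ("HB", "PB")

#: Canonical CSV header, in file order.
CANONICAL_COLUMNS = (
    "study_id", "author", "year", "ethnicity", "source", "nos", "method",
    "case_gg", "case_ga", "case_aa", "ctrl_gg", "ctrl_ga", "ctrl_aa",
)

#: Total sample size (cases + controls) at or above which a study counts as
#: "large" in the sample-size stratification.
LARGE_STUDY_THRESHOLD = 1000

#: NOS stars at or above which a study counts as "high quality".
HIGH_QUALITY_NOS = 7


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one study arm of a biallelic SNP.

    ``gg``: minor-allele homozygotes; ``ga``: heterozygotes; ``aa``:
    major-allele homozygotes.  All counts are non-negative integers and the
    arm must contain at least one individual.
    """

    gg: int
    ga: int
    aa: int

    def __post_init__(self) -> None:
        for name in ("gg", "ga", "aa"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise StudyValidationError(f"genotype count {name} must be an integer, got {v!r}")
            if v < 0:
                raise StudyValidationError(f"genotype count {name} must be >= 0, got {v}")
        if self.n == 0:
            raise DegenerateStudyError("study arm has zero individuals")

    @property
    def n(self) -> int:
        """Number of individuals in the arm."""
        return self.gg + self.ga + self.aa

    @property
    def minor_allele_count(self) -> int:
        """Copies of the minor (G) allele in the arm."""
        return 2 * self.gg + self.ga

    @property
    def maf(self) -> float:
        """Minor-allele frequency estimate, (2*gg + ga) / 2n."""
        return self.minor_allele_count / (2 * self.n)


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study: genotype counts for both arms plus metadata."""

    study_id: str
    first_author: str
    year: int
    ethnicity: str
    source: str
    nos_score: int
    cases: GenotypeCounts
    controls: GenotypeCounts
    method: str = ""

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise VocabularyError(
                f"unknown ethnicity {self.ethnicity!r}; expected one of {ETHNICITIES}"
            )
        if self.source not in SOURCES:
            raise VocabularyError(
                f"unknown control source {self.source!r}; expected one of {SOURCES}"
            )
        if not 0 <= self.nos_score <= 9:
            raise StudyValidationError(
                f"NOS score must be in [0, 9], got {self.nos_score}"
            )

    @property
    def n_total(self) -> int:
        return self.cases.n + self.controls.n


@dataclass(frozen=True)
class StudyStrata:
    """Deterministic subgroup labels for one study.

    ``quality_group`` is ``"high"`` iff the NOS score is >= 7 stars;
    ``size_group`` is ``"large"`` iff cases + controls >= 1000.
    """

    race_group: str
    source_group: str
    size_group: str
    quality_group: str


def classify(study: StudyRecord) -> StudyStrata:
    """Assign a study to its race / source / size / quality subgroups."""
    return StudyStrata(
        race_group=study.ethnicity,
        source_group=study.source,
        size_group="large" if study.n_total >= LARGE_STUDY_THRESHOLD else "small",
        quality_group="high" if study.nos_score >= HIGH_QUALITY_NOS else "low",
    )


def _open(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def _parse_count(raw: str, row: int, column: str) -> int:
    try:
        value = int(str(raw).strip().replace(",", ""))
    except (TypeError, ValueError):
        raise StudyValidationError(
            f"genotype count {raw!r} is not an integer", row=row, column=column
        ) from None
    if value < 0:
        raise StudyValidationError(
            f"genotype count must be >= 0, got {value}", row=row, column=column
        )
    return value


def parse_studies(
    source: str | Path | TextIO,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[StudyRecord]:
    """Read study records from delimited text.

    Parameters
    ----------
    source:
        Path or open text handle.  A header row is required; lines starting
        with ``#`` are skipped.
    columns:
        Optional map from canonical column names (:data:`CANONICAL_COLUMNS`)
        to the names actually present, so TSV/CSV exports with different
        headers load without editing.
    delimiter:
        Field separator, ``","`` by default (use ``"\\t"`` for TSV).

    Returns
    -------
    list of StudyRecord, in file order.  Every record passes the
    :class:`StudyRecord` invariants; violations raise
    :class:`~snpmeta.exceptions.StudyValidationError` naming the row and
    column.
    """
    colmap = dict(zip(CANONICAL_COLUMNS, CANONICAL_COLUMNS))
    if columns:
        colmap.update(columns)

    handle, own = _open(source)
    try:
        lines = [ln for ln in handle if not ln.lstrip().startswith("#")]
    finally:
        if own:
            handle.close()
    reader = csv.DictReader(lines, delimiter=delimiter)
    if reader.fieldnames is None:
        raise StudyValidationError("input has no header row")
    missing = [colmap[c] for c in CANONICAL_COLUMNS if colmap[c] not in reader.fieldnames]
    if missing:
        raise StudyValidationError(f"missing columns: {missing}")

    records: list[StudyRecord] = []
    for i, row in enumerate(reader, start=2):  # row 1 is the header
        def get(canonical: str) -> str:
            value = row.get(colmap[canonical])
            if value is None or str(value).strip() == "":
                raise StudyValidationError("missing value", row=i, column=colmap[canonical])
            return str(value).strip()

        counts = {
            c: _parse_count(get(c), i, colmap[c])
            for c in ("case_gg", "case_ga", "case_aa", "ctrl_gg", "ctrl_ga", "ctrl_aa")
        }
        try:
            cases = GenotypeCounts(counts["case_gg"], counts["case_ga"], counts["case_aa"])
            controls = GenotypeCounts(counts["ctrl_gg"], counts["ctrl_ga"], counts["ctrl_aa"])
            record = StudyRecord(
                study_id=get("study_id"),
                first_author=get("author"),
                year=int(get("year")),
                ethnicity=get("ethnicity"),
                source=get("source"),
                nos_score=int(get("nos")),
                cases=cases,
                controls=controls,
                method=str(row.get(colmap["method"], "") or "").strip(),
            )
        except StudyValidationError as err:
            if err.row is None:
                raise type(err)(str(err), row=i) from None
            raise
        records.append(record)
    return records


def write_studies(studies: Iterable[StudyRecord], dest: str | Path | TextIO,
                  delimiter: str = ",") -> None:
    """Write study records as delimited text with the canonical header."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_studies(studies, fh, delimiter=delimiter)
        return
    writer = csv.writer(dest, delimiter=delimiter, lineterminator="\n")
    writer.writerow(CANONICAL_COLUMNS)
    for s in studies:
        writer.writerow([
            s.study_id, s.first_author, s.year, s.ethnicity, s.source,
            s.nos_score, s.method,
            s.cases.gg, s.cases.ga, s.cases.aa,
            s.controls.gg, s.controls.ga, s.controls.aa,
        ])


#: Names accepted by ``builtin_fixture`` / the CLI's ``--input builtin:<name>``.
BUILTIN_DATASETS = {"zhang2020": "zhang2020_rs1805087.csv"}


def builtin_fixture(name: str = "zhang2020") -> list[StudyRecord]:
    """Return a bundled dataset; by default the 15 rs1805087 A/G
    prostate-cancer case-control studies (10,666 cases / 40,750 controls).
    """
    try:
        filename = BUILTIN_DATASETS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin dataset {name!r}; available: {sorted(BUILTIN_DATASETS)}"
        ) from None
    text = resources.files("snpmeta.data").joinpath(filename).read_text(encoding="utf-8")
    return parse_studies(io.StringIO(text))
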