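"""Genetic-model contrasts: fold genotype counts into 2x2 tables.

Five standard contrasts of a biallelic SNP are supported, always oriented so
that the minor-allele-bearing category is the "exposure" (an odds ratio above
1 therefore means risk with the G allele):

========== ======================= =========================================
model      exposed vs unexposed    counting unit
========== ======================= =========================================
ALLELIC    G allele vs A allele    alleles (2 per individual)
HOMOZYGOTE GG vs AA                individuals; heterozygotes dropped
HETEROZYGOTE GA vs AA              individuals; GG homozygotes dropped
DOMINANT   GG+GA vs AA             individuals
RECESSIVE  GG vs GA+AA             individuals
========== ======================= =========================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .exceptions import UndefinedOddsError
from .studies import GenotypeCounts

__all__ = ["GeneticModel", "TwoByTwo", "build_table", "continuity_correct"]


class GeneticModel(Enum):
    """The five contrasts, with their conventional CLI short names."""

    ALLELIC = "allelic"
    HOMOZYGOTE = "hom"
    HETEROZYGOTE = "het"
    DOMINANT = "dom"
    RECESSIVE = "rec"

    @classmethod
    def from_name(cls, name: str) -> "GeneticModel":
        """Accept either the enum name or the short alias, case-insensitively."""
        token = name.strip().lower()
        for member in cls:
            if token in (member.value, member.name.lower()):
                return member
        raise ValueError(f"unknown genetic model {name!r}")

    @property
    def label(self) -> str:
        """Human-readable contrast, e.g. ``"GG+GA vs AA"``."""
        return {
            GeneticModel.ALLELIC: "G vs A",
            GeneticModel.HOMOZYGOTE: "GG vs AA",
            GeneticModel.HETEROZYGOTE: "GA vs AA",
            GeneticModel.DOMINANT: "GG+GA vs AA",
            GeneticModel.RECESSIVE: "GG vs GA+AA",
        }[self]


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 exposure-by-disease contingency table.

    ``a``: exposed cases, ``b``: exposed controls, ``c``: unexposed cases,
    ``d``: unexposed controls.  Cells are floats because continuity
    correction adds 0.5; ``corrected`` records whether that happened.
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def build_table(cases: GenotypeCounts, controls: GenotypeCounts,
                model: GeneticModel) -> TwoByTwo:
    """Build the 2x2 table for one study under a genetic-model contrast.

    The allelic model counts alleles (each individual contributes two); all
    other models count individuals.  For the homozygote and heterozygote
    contrasts the excluded genotype is dropped from both arms, so the table
    totals shrink accordingly.  Zero cells are legal here -- apply
    :func:`continuity_correct` before odds-ratio arithmetic.
    """
    if model is GeneticModel.ALLELIC:
        return TwoByTwo(
            a=2 * cases.gg + cases.ga, b=2 * controls.gg + controls.ga,
            c=2 * cases.aa + cases.ga, d=2 * controls.aa + controls.ga,
        )
    if model is GeneticModel.HOMOZYGOTE:
        return TwoByTwo(a=cases.gg, b=controls.gg, c=cases.aa, d=controls.aa)
    if model is GeneticModel.HETEROZYGOTE:
        return TwoByTwo(a=cases.ga, b=controls.ga, c=cases.aa, d=controls.aa)
    if model is GeneticModel.DOMINANT:
        return TwoByTwo(a=cases.gg + cases.ga, b=controls.gg + controls.ga,
                        c=cases.aa, d=controls.aa)
    if model is GeneticModel.RECESSIVE:
        return TwoByTwo(a=cases.gg, b=controls.gg,
                        c=cases.ga + cases.aa, d=controls.ga + controls.aa)
    raise ValueError(f"unknown model {model!r}")


def continuity_correct(table: TwoByTwo) -> TwoByTwo:
    """Haldane-Anscombe correction: if any cell is zero, add 0.5 to all four.

    Tables with no zero cell are returned unchanged.  A table whose exposure
    margin is empty (``a + b == 0`` or ``c + d == 0``) has no defined odds
    ratio even after correction and raises
    :class:`~snpmeta.exceptions.UndefinedOddsError`.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise UndefinedOddsError(
            "table has an empty exposure margin; odds ratio undefined"
        )
    if min(table.cells) > 0:
        return table
    return replace(table, a=table.a + 0.5, b=table.b + 0.5,
                   c=table.c + 0.5, d=table.d + 0.5, corrected=True)
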