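"""Stratified (subgroup) analyses and leave-one-out sensitivity.

``analyze_all`` runs the heterogeneity-gated pooling for all five genetic
models on the full study set and on every level of the four stratification
factors used in case-control SNP meta-analysis: race, source of controls
(hospital- vs population-based), sample size (large vs small) and study
quality (NOS >= 7 vs below).  The gate is re-evaluated inside every stratum
and every leave-one-out subset rather than inherited from the overall
analysis, because heterogeneity is a property of the subset being pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import InsufficientStudiesError
from .meta import PooledResult, select_and_pool
from .models import GeneticModel, build_table
from .studies import StudyRecord, classify

__all__ = [
    "STRATA_FACTORS",
    "StratumResult",
    "StratifiedReport",
    "LeaveOneOutEntry",
    "LeaveOneOutReport",
    "stratify_studies",
    "analyze_all",
    "leave_one_out",
]

#: Stratification factors and the display order of their levels.
STRATA_FACTORS: dict[str, tuple[str, ...]] = {
    "race": ("European", "Asian", "SouthAmerican", "African"),
    "source": ("PB", "HB"),
    "size": ("large", "small"),
    "quality": ("high", "low"),
}


def _stratum_label(study: StudyRecord, factor: str) -> str:
    strata = classify(study)
    return {
        "race": strata.race_group,
        "source": strata.source_group,
        "size": strata.size_group,
        "quality": strata.quality_group,
    }[factor]


def stratify_studies(studies: Sequence[StudyRecord],
                     factor: str) -> dict[str, list[StudyRecord]]:
    """Partition studies by one factor; empty levels are omitted."""
    if factor not in STRATA_FACTORS:
        raise KeyError(f"unknown stratification factor {factor!r}")
    out: dict[str, list[StudyRecord]] = {}
    for level in STRATA_FACTORS[factor]:
        members = [s for s in studies if _stratum_label(s, factor) == level]
        if members:
            out[level] = members
    return out


@dataclass(frozen=True)
class StratumResult:
    """Pooled results for all genetic models within one stratum."""

    factor: str
    level: str
    k: int
    n_cases: int
    n_controls: int
    results: Mapping[GeneticModel, PooledResult]
    study_ids: tuple[str, ...] = ()


@dataclass
class StratifiedReport:
    """The full stratified grid: (factor, level) -> per-model pooled results."""

    rows: dict[tuple[str, str], StratumResult] = field(default_factory=dict)

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Flatten to one row per (stratum, model).

        With ``rounded=True`` numbers are rounded the way such tables are
        conventionally printed: OR and CI bounds to 2 decimals, p-values to
        3, I^2 to 1.
        """
        records = []
        for (factor, level), stratum in self.rows.items():
            for model, res in stratum.results.items():
                rec = {
                    "factor": factor,
                    "level": level,
                    "k": stratum.k,
                    "cases": stratum.n_cases,
                    "controls": stratum.n_controls,
                    "model": model.value,
                    "method": res.method,
                    "or": res.pooled_or,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "p_het": res.p_het,
                    "i2": res.i2,
                    "tau2": res.tau2,
                }
                if rounded:
                    for key in ("or", "ci_low", "ci_high"):
                        rec[key] = round(rec[key], 2)
                    rec["p"] = round(rec["p"], 3)
                    if rec["p_het"] is not None:
                        rec["p_het"] = round(rec["p_het"], 3)
                    if rec["i2"] is not None:
                        rec["i2"] = round(rec["i2"], 1)
                records.append(rec)
        return pd.DataFrame.from_records(records)


def _pool_stratum(studies: Sequence[StudyRecord], factor: str, level: str,
                  models: Sequence[GeneticModel],
                  het_alpha: float) -> StratumResult:
    results = {
        m: select_and_pool(
            [build_table(s.cases, s.controls, m) for s in studies], het_alpha
        )
        for m in models
    }
    return StratumResult(
        factor=factor,
        level=level,
        k=len(studies),
        n_cases=sum(s.cases.n for s in studies),
        n_controls=sum(s.controls.n for s in studies),
        results=results,
        study_ids=tuple(s.study_id for s in studies),
    )


def analyze_all(studies: Sequence[StudyRecord], het_alpha: float = 0.05,
                models: Sequence[GeneticModel] = tuple(GeneticModel),
                factors: Sequence[str] = tuple(STRATA_FACTORS),
                ) -> StratifiedReport:
    """Gated pooling for every model on the total set and every stratum level.

    Single-study strata yield that study's own estimate (Woolf CI, no
    heterogeneity fields); empty strata are omitted, not errored.
    """
    if not studies:
        raise InsufficientStudiesError("no studies to analyze")
    report = StratifiedReport()
    report.rows[("total", "Total")] = _pool_stratum(
        studies, "total", "Total", models, het_alpha
    )
    for factor in factors:
        for level, members in stratify_studies(studies, factor).items():
            report.rows[(factor, level)] = _pool_stratum(
                members, factor, level, models, het_alpha
            )
    return report


@dataclass(frozen=True)
class LeaveOneOutEntry:
    """Pooled result with one study omitted, plus its influence flags."""

    omitted: str
    result: PooledResult
    outside_overall_ci: bool
    significance_flipped: bool


@dataclass(frozen=True)
class LeaveOneOutReport:
    """All k leave-one-out re-poolings plus the all-studies reference."""

    model: GeneticModel
    overall: PooledResult
    entries: tuple[LeaveOneOutEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records([
            {
                "omitted": e.omitted,
                "method": e.result.method,
                "or": e.result.pooled_or,
                "ci_low": e.result.ci_low,
                "ci_high": e.result.ci_high,
                "p": e.result.p,
                "outside_overall_ci": e.outside_overall_ci,
                "significance_flipped": e.significance_flipped,
            }
            for e in self.entries
        ])


def leave_one_out(studies: Sequence[StudyRecord], model: GeneticModel,
                  het_alpha: float = 0.05,
                  alpha: float = 0.05) -> LeaveOneOutReport:
    """Sensitivity analysis by sequential exclusion of each study.

    Each omission re-runs the full gated pooling.  An omission is flagged
    influential if the reduced-set point estimate falls outside the
    all-studies 95% CI, or if the pooled p-value crosses ``alpha`` in
    either direction.
    """
    if len(studies) < 2:
        raise InsufficientStudiesError("leave-one-out needs at least 2 studies")
    tables = [build_table(s.cases, s.controls, model) for s in studies]
    overall = select_and_pool(tables, het_alpha)
    entries = []
    for i, omitted in enumerate(studies):
        subset = tables[:i] + tables[i + 1:]
        res = select_and_pool(subset, het_alpha)
        entries.append(LeaveOneOutEntry(
            omitted=omitted.study_id,
            result=res,
            outside_overall_ci=not (overall.ci_low <= res.pooled_or <= overall.ci_high),
            significance_flipped=(res.p < alpha) != (overall.p < alpha),
        ))
    return LeaveOneOutReport(model=model, overall=overall, entries=tuple(entries))
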