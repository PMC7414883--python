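"""Report assembly: study summary, stratified grid, sensitivity and bias
tables, and the full-precision JSON manifest.

The manifest is the single source of truth: every number in the CSV or
markdown renderings is copied from it, never recomputed, and serialising it
twice from the same input yields identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .bias import begg_test, egger_test
from .hwe import hwe_chisq
from .meta import PooledResult, effects_from_tables
from .models import GeneticModel, build_table
from .stratify import LeaveOneOutReport, StratifiedReport, analyze_all, leave_one_out
from .studies import StudyRecord, classify

__all__ = ["build_manifest", "manifest_json", "study_table", "write_reports"]


def study_table(studies: Sequence[StudyRecord]) -> pd.DataFrame:
    """Per-study summary with recomputed Hardy-Weinberg statistics."""
    rows = []
    for s in studies:
        strata = classify(s)
        hc, hw = hwe_chisq(s.cases), hwe_chisq(s.controls)
        rows.append({
            "study_id": s.study_id,
            "author": s.first_author,
            "year": s.year,
            "ethnicity": s.ethnicity,
            "source": s.source,
            "nos": s.nos_score,
            "quality": strata.quality_group,
            "size": strata.size_group,
            "method": s.method,
            "n_cases": s.cases.n,
            "n_controls": s.controls.n,
            "case_gg": s.cases.gg, "case_ga": s.cases.ga, "case_aa": s.cases.aa,
            "ctrl_gg": s.controls.gg, "ctrl_ga": s.controls.ga, "ctrl_aa": s.controls.aa,
            "case_maf": s.cases.maf,
            "ctrl_maf": s.controls.maf,
            "hwe_p_cases": hc.p,
            "hwe_p_controls": hw.p,
        })
    return pd.DataFrame.from_records(rows)


def _pooled_dict(r: PooledResult) -> dict:
    return {
        "k": r.k,
        "method": r.method,
        "or": r.pooled_or,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "log_or": r.log_or,
        "se": r.se,
        "z": r.z,
        "p": r.p,
        "q": r.q,
        "p_het": r.p_het,
        "i2": r.i2,
        "tau2": r.tau2,
    }


def build_manifest(studies: Sequence[StudyRecord], het_alpha: float = 0.05,
                   loo_model: GeneticModel = GeneticModel.DOMINANT) -> dict:
    """Run the complete analysis and collect every number at full precision.

    Sections: per-study summary (with HWE), the stratified grid for all
    five genetic models, leave-one-out sensitivity for ``loo_model``, and
    Egger/Begg publication-bias statistics per model.
    """
    stratified: StratifiedReport = analyze_all(studies, het_alpha=het_alpha)
    loo: LeaveOneOutReport = leave_one_out(studies, loo_model, het_alpha=het_alpha)

    bias = {}
    for m in GeneticModel:
        effects = effects_from_tables(
            [build_table(s.cases, s.controls, m) for s in studies]
        )
        e = egger_test(effects)
        b = begg_test(effects)
        bias[m.value] = {
            "egger": {"intercept": e.intercept, "se": e.se, "t": e.t,
                      "df": e.df, "p": e.p, "slope": e.slope},
            "begg": {"tau": b.tau, "z": b.z, "p": b.p},
        }

    return {
        "snpmeta_version": __version__,
        "het_alpha": het_alpha,
        "n_studies": len(studies),
        "total_cases": sum(s.cases.n for s in studies),
        "total_controls": sum(s.controls.n for s in studies),
        "studies": study_table(studies).to_dict(orient="records"),
        "stratified": {
            f"{factor}/{level}": {
                "k": stratum.k,
                "cases": stratum.n_cases,
                "controls": stratum.n_controls,
                "study_ids": list(stratum.study_ids),
                "models": {m.value: _pooled_dict(r)
                           for m, r in stratum.results.items()},
            }
            for (factor, level), stratum in stratified.rows.items()
        },
        "leave_one_out": {
            "model": loo.model.value,
            "overall": _pooled_dict(loo.overall),
            "entries": [
                {"omitted": e.omitted, **_pooled_dict(e.result),
                 "outside_overall_ci": e.outside_overall_ci,
                 "significance_flipped": e.significance_flipped}
                for e in loo.entries
            ],
        },
        "publication_bias": bias,
    }


def manifest_json(manifest: dict) -> str:
    """Deterministic JSON serialisation (sorted keys, fixed separators)."""
    return json.dumps(manifest, sort_keys=True, indent=1, allow_nan=False)


def write_reports(manifest: dict, outdir: str | Path,
                  formats: Sequence[str] = ("csv", "json")) -> dict[str, Path]:
    """Write the manifest plus flat CSV/markdown renderings of its tables.

    Returns a name -> path map of everything written.  All table content is
    taken from the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "json" in formats:
        p = outdir / "manifest.json"
        p.write_text(manifest_json(manifest) + "\n", encoding="utf-8")
        written["manifest"] = p

    studies_df = pd.DataFrame.from_records(manifest["studies"])
    grid_rows = []
    for key, stratum in manifest["stratified"].items():
        factor, level = key.split("/", 1)
        for model, r in stratum["models"].items():
            grid_rows.append({
                "factor": factor, "level": level, "k": stratum["k"],
                "cases": stratum["cases"], "controls": stratum["controls"],
                "model": model, **{k: v for k, v in r.items() if k != "k"},
            })
    grid_df = pd.DataFrame.from_records(grid_rows)
    loo_df = pd.DataFrame.from_records(manifest["leave_one_out"]["entries"])
    bias_rows = []
    for model, r in manifest["publication_bias"].items():
        bias_rows.append({"model": model,
                          **{f"egger_{k}": v for k, v in r["egger"].items()},
                          **{f"begg_{k}": v for k, v in r["begg"].items()}})
    bias_df = pd.DataFrame.from_records(bias_rows)

    tables = {"studies": studies_df, "stratified": grid_df,
              "leave_one_out": loo_df, "bias": bias_df}
    if "csv" in formats:
        for name, df in tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written[name] = p
    if "markdown" in formats:
        p = outdir / "report.md"
        parts = [f"# Meta-analysis report (snpmeta {manifest['snpmeta_version']})",
                 f"\n{manifest['n_studies']} studies, "
                 f"{manifest['total_cases']} cases / "
                 f"{manifest['total_controls']} controls.\n"]
        for name, df in tables.items():
            parts.append(f"\n## {name}\n")
            parts.append(df.round(4).to_markdown(index=False))
            parts.append("\n")
        p.write_text("".join(parts), encoding="utf-8")
        written["markdown"] = p
    return written
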