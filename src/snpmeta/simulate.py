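"""Synthetic multi-study case-control genotype data with known truth.

The generator emulates the statistical structure a genotype meta-analysis
assumes: control genotypes are multinomial under Hardy-Weinberg proportions
at a control minor-allele frequency ``q``; case genotypes follow the
genotype-tilted multinomial with per-genotype probabilities proportional to
the Hardy-Weinberg probabilities times ``OR**g`` for ``g`` copies of the
minor allele (retrospective sampling under a log-additive per-allele odds
ratio).  Controls therefore sit exactly in HWE in expectation while cases
may deviate, as real case arms do.

Between-study heterogeneity enters as a normal random effect on the study
log odds ratio with standard deviation ``tau``.  Optional small-study
(publication) bias is injected by resampling any below-median-size study
whose allelic Z falls short of 1, with probability ``bias_strength`` --
the classic mechanism that hollows out the lower-left of a funnel plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .meta import study_effect
from .models import GeneticModel, build_table, continuity_correct
from .studies import GenotypeCounts, StudyRecord, builtin_fixture

__all__ = ["SimulationConfig", "simulate_study", "simulate_meta"]

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic multi-study dataset.

    ``n_cases`` / ``n_controls`` may be a single per-study size, a sequence
    of length ``k_studies``, or ``None`` to resample (case, control) size
    pairs from the bundled 15-study dataset's observed sizes.  ``seed``
    fully determines the output.
    """

    k_studies: int = 15
    n_cases: int | Sequence[int] | None = None
    n_controls: int | Sequence[int] | None = None
    q: float = 0.2
    or_per_allele: float = 1.2
    tau: float = 0.0
    bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        if self.or_per_allele <= 0:
            raise ValueError("or_per_allele must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must be in [0, 1]")


def _genotype_probs(q: float, log_or: float) -> np.ndarray:
    """(GG, GA, AA) probabilities under the tilted-HWE case model."""
    or_ = math.exp(log_or)
    raw = np.array([q * q * or_ * or_, 2 * q * (1 - q) * or_, (1 - q) ** 2])
    return raw / raw.sum()


def _draw_counts(rng: np.random.Generator, n: int, probs: np.ndarray) -> GenotypeCounts:
    gg, ga, aa = rng.multinomial(n, probs)
    return GenotypeCounts(int(gg), int(ga), int(aa))


def simulate_study(config: SimulationConfig, study_log_or: float,
                   rng: np.random.Generator | None = None,
                   n_cases: int | None = None, n_controls: int | None = None,
                   study_id: str = "sim01") -> StudyRecord:
    """Draw one study at a given true log odds ratio.

    Controls are multinomial with exact Hardy-Weinberg probabilities
    ``(q^2, 2q(1-q), (1-q)^2)``; cases use the same probabilities tilted by
    ``exp(study_log_or)`` per minor-allele copy.  Metadata fields carry
    neutral placeholders.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nca = n_cases if n_cases is not None else _resolve_sizes(config, rng)[0][0]
    nco = n_controls if n_controls is not None else _resolve_sizes(config, rng)[0][1]
    control_probs = _genotype_probs(config.q, 0.0)
    case_probs = _genotype_probs(config.q, study_log_or)
    return StudyRecord(
        study_id=study_id,
        first_author="Synthetic",
        year=2020,
        ethnicity="European",
        source="PB",
        nos_score=7,
        cases=_draw_counts(rng, nca, case_probs),
        controls=_draw_counts(rng, nco, control_probs),
        method="simulated",
    )


def _resolve_sizes(config: SimulationConfig,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Per-study (case, control) sizes, resolving the three input forms."""
    k = config.k_studies
    if config.n_cases is None or config.n_controls is None:
        pool = [(s.cases.n, s.controls.n) for s in builtin_fixture()]
        idx = rng.integers(0, len(pool), size=k)
        return [pool[i] for i in idx]

    def expand(spec: int | Sequence[int]) -> list[int]:
        if isinstance(spec, int):
            return [spec] * k
        sizes = list(spec)
        if len(sizes) != k:
            raise ValueError(f"expected {k} per-study sizes, got {len(sizes)}")
        return sizes

    return list(zip(expand(config.n_cases), expand(config.n_controls)))


def _allelic_z(study: StudyRecord) -> float:
    table = continuity_correct(
        build_table(study.cases, study.controls, GeneticModel.ALLELIC)
    )
    eff = study_effect(table)
    return eff.log_or / eff.se


def simulate_meta(config: SimulationConfig) -> list[StudyRecord]:
    """Draw a full k-study dataset from one seeded RNG stream.

    Study-level true log-ORs are Normal(ln(or_per_allele), tau^2).  With
    ``bias_strength > 0``, a drawn study whose total size is below the
    median of the configured sizes and whose allelic Z is below 1 is thrown
    back and redrawn (new effect and new counts) with that probability,
    which censors small null studies the way publication bias does.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _resolve_sizes(config, rng)
    median_n = float(np.median([nca + nco for nca, nco in sizes]))
    mu = math.log(config.or_per_allele)

    studies: list[StudyRecord] = []
    for i, (nca, nco) in enumerate(sizes):
        for _ in range(_MAX_RESAMPLE):
            log_or = rng.normal(mu, config.tau)
            study = simulate_study(
                config, log_or, rng, n_cases=nca, n_controls=nco,
                study_id=f"sim{i + 1:02d}",
            )
            small = nca + nco < median_n
            if (config.bias_strength > 0 and small and _allelic_z(study) < 1.0
                    and rng.random() < config.bias_strength):
                continue
            break
        studies.append(study)
    return studies
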