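"""Validation harness: blinded concordance, group Tm statistics, delta-Tm recovery.

Reproduces a sequencing-anchored HRM validation in silico: build references
from a standardization simulation, genotype a blinded cohort, unblind, and
score the calls against the simulated truth.  Inconclusive calls count as
errors -- a blinded assay that refuses to answer has not identified the
sample.  Group Tm statistics are computed from the CALLED groups, exactly
as a blinded observer would form them, so miscalls contaminate the delta-Tm
estimate; that is the honest replication of the validation procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_caller import (
    INCONCLUSIVE,
    AnalysisConfig,
    CallResult,
    QCPolicy,
    build_references,
    call_cohort,
)
from .melt_model import (
    GENOTYPES,
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    AssayDefinition,
    CohortSpec,
    NoiseModel,
    simulate_cohort,
)

__all__ = [
    "EvaluationReport",
    "concordance",
    "group_tm_stats",
    "default_panel",
    "blinded_validation",
]

CALL_CATEGORIES = GENOTYPES + (INCONCLUSIVE,)


@dataclass
class EvaluationReport:
    """Per-assay concordance, confusion matrix and Tm statistics."""

    assay_id: str
    n_samples: int
    n_correct: int
    accuracy_percent: float
    confusion: pd.DataFrame  # rows: truth genotype; columns: called category
    genotype_tm_stats: dict[str, dict[str, float]]
    delta_tm_hom_c: float | None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "assay_id": self.assay_id,
            "n_samples": self.n_samples,
            "n_correct": self.n_correct,
            "accuracy_percent": self.accuracy_percent,
            "confusion": {
                truth: {call: int(self.confusion.loc[truth, call]) for call in self.confusion.columns}
                for truth in self.confusion.index
            },
            "genotype_tm_stats": self.genotype_tm_stats,
            "delta_tm_hom_c": self.delta_tm_hom_c,
            "seed": self.seed,
        }

    def to_text(self) -> str:
        lines = [
            f"Assay {self.assay_id}: {self.n_correct}/{self.n_samples} correct "
            f"({self.accuracy_percent:.1f} %)",
            "",
            "Confusion (rows: truth, columns: call):",
            self.confusion.to_string(),
            "",
            "Group Tm statistics (called groups):",
        ]
        for genotype, stats in self.genotype_tm_stats.items():
            lines.append(
                f"  {genotype:10s} n={stats['n']:>3.0f}  "
                f"mean {stats['mean_c']:.3f} degC  SD {stats['sd_c']:.4f} degC"
            )
        if self.delta_tm_hom_c is not None:
            lines.append(f"Homozygote delta-Tm estimate: {self.delta_tm_hom_c:.3f} degC")
        else:
            lines.append("Homozygote delta-Tm estimate: not available")
        return "\n".join(lines)


def group_tm_stats(
    calls: Sequence[CallResult], assay: AssayDefinition
) -> tuple[dict[str, dict[str, float]], float | None]:
    """Mean/SD of replicate-mean Tms per called genotype, plus homozygote delta-Tm.

    delta-Tm = mean Tm of the G.C-allele homozygote group minus the other
    homozygote group (positive by construction of the melt model).  Missing
    homozygote classes yield ``None`` rather than zero.
    """
    stats: dict[str, dict[str, float]] = {}
    for genotype in GENOTYPES:
        tms = np.asarray([c.tm_mean_c for c in calls if c.called_genotype == genotype])
        if tms.size == 0:
            continue
        sd = float(np.std(tms, ddof=1)) if tms.size > 1 else 0.0
        stats[genotype] = {"mean_c": float(tms.mean()), "sd_c": sd, "n": float(tms.size)}
    gc_g, at_g = assay.gc_genotype, assay.at_genotype
    delta = None
    if gc_g in stats and at_g in stats:
        delta = stats[gc_g]["mean_c"] - stats[at_g]["mean_c"]
    return stats, delta


def concordance(
    calls: Sequence[CallResult],
    truth: Mapping[str, str],
    assay: AssayDefinition,
) -> EvaluationReport:
    """Score calls against the truth table (inconclusive counts as incorrect)."""
    if len(calls) == 0:
        raise ValueError("no calls to evaluate")
    unknown = sorted({c.sample_id for c in calls} - set(truth))
    if unknown:
        raise KeyError(f"sample id(s) missing from truth table: {', '.join(unknown)}")
    confusion = pd.DataFrame(
        0, index=list(GENOTYPES), columns=list(CALL_CATEGORIES), dtype=int
    )
    n_correct = 0
    for call in calls:
        t = truth[call.sample_id]
        confusion.loc[t, call.called_genotype] += 1
        if call.called_genotype == t:
            n_correct += 1
    stats, delta = group_tm_stats(calls, assay)
    n = len(calls)
    return EvaluationReport(
        assay_id=assay.assay_id,
        n_samples=n,
        n_correct=n_correct,
        accuracy_percent=100.0 * n_correct / n,
        confusion=confusion,
        genotype_tm_stats=stats,
        delta_tm_hom_c=delta,
    )


def default_panel(n_samples: int) -> dict[str, int]:
    """Mixed genotype panel: ~32 % heterozygote, ~16 % minor homozygote.

    For the canonical 25-sample cohort this gives 13/8/4
    (major-hom / het / minor-hom).  The composition is an arbitrary mixed
    panel choice, exposed here so callers can override it.
    """
    if n_samples < 3:
        raise ValueError("a mixed panel needs at least 3 samples")
    het = max(1, round(0.32 * n_samples))
    minor = max(1, round(0.16 * n_samples))
    return {HOM_MAJOR: n_samples - het - minor, HET: het, HOM_MINOR: minor}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def blinded_validation(
    assay: AssayDefinition,
    n_samples: int = 25,
    genotype_counts: Mapping[str, int] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    replicates: int = 3,
    standardization_per_genotype: int = 3,
    qc: QCPolicy | None = None,
    config: AnalysisConfig | None = None,
) -> EvaluationReport:
    """End-to-end blinded validation of one assay.

    A standardization plate (``standardization_per_genotype`` samples per
    genotype, its own seed) builds the reference set; an independent cohort
    is then simulated, its sample ids anonymized by a seeded shuffle, and
    calls are unblinded against the truth.  Deterministic for a fixed seed.
    """
    noise = noise if noise is not None else NoiseModel()
    counts = dict(genotype_counts) if genotype_counts is not None else default_panel(n_samples)
    std_seed, cohort_seed, blind_seed = _spawn_seeds(seed, 3)

    std_counts = {g: standardization_per_genotype for g in GENOTYPES}
    std_curves, std_truth = simulate_cohort(
        CohortSpec(assay, 3 * standardization_per_genotype, std_counts, replicates, noise, std_seed)
    )
    by_genotype: dict[str, list] = {g: [] for g in GENOTYPES}
    for curve in std_curves:
        by_genotype[std_truth[curve.sample_id]].append(curve)
    references = build_references(by_genotype, assay, config)

    curves, truth = simulate_cohort(
        CohortSpec(assay, n_samples, counts, replicates, noise, cohort_seed)
    )
    # Blind: reassign opaque ids by a seeded permutation.
    rng = np.random.default_rng(blind_seed)
    original_ids = sorted(truth)
    shuffled = rng.permutation(len(original_ids))
    alias = {sid: f"B{shuffled[i] + 1:03d}" for i, sid in enumerate(original_ids)}
    blinded_curves = [
        type(c)(alias[c.sample_id], c.replicate, c.temperatures_c, c.fluorescence)
        for c in curves
    ]
    blinded_truth = {alias[sid]: g for sid, g in truth.items()}

    calls = call_cohort(blinded_curves, references, assay, qc, config)
    report = concordance(calls, blinded_truth, assay)
    report.seed = seed
    return report
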