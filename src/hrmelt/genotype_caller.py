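"""Reference-assisted genotype calling from melt curves.

The calling strategy mirrors how HRM genotyping is actually run: a
standardization plate of sequenced samples first characterizes the melt
profile and Tm of each genotype (the reference set); unknown plates are
then auto-grouped by melt transition (average-linkage clustering on the
RMS distance between normalized curves) and each cluster is labelled by
reconciling it with the references -- homozygote clusters by Tm ordering
(the G.C-pairing allele melts higher), heterozygote clusters by their
flatter transition and large difference-plot amplitude against the
major-allele homozygote reference.  Triplicate QC (consistent Tms, one
cluster per sample) turns unreliable wells into "inconclusive" calls
rather than wrong ones.

Clustering and difference amplitudes operate on normalized, unshifted
curves: in the two-state melt model the two homozygote classes differ by a
rigid temperature translation only, so the transition position must remain
part of the distance (temperature shifting would erase it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .curve_analysis import (
    NormalizedCurve,
    auto_windows,
    derivative_curve,
    difference_amplitude,
    difference_curve,
    estimate_tm,
    normalize,
    transition_width,
)
from .melt_model import GENOTYPES, HET, HOM_MAJOR, AssayDefinition, RawMeltCurve

__all__ = [
    "INCONCLUSIVE",
    "AnalysisConfig",
    "QCPolicy",
    "CallResult",
    "ReferenceSet",
    "ClusterCountError",
    "AmbiguousLabelingError",
    "build_references",
    "auto_group",
    "label_clusters",
    "call_sample",
    "call_cohort",
]

INCONCLUSIVE = "inconclusive"


class ClusterCountError(ValueError):
    """More clusters than genotypes; the linkage threshold needs review."""


class AmbiguousLabelingError(ValueError):
    """Two homozygote candidate clusters melt too close to order by Tm."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis defaults shared by the calling pipeline.

    margin_low_c / margin_high_c
        Placement of the automatic baseline windows relative to the coarse
        Tm (degC below / above).
    smoothing_halfwidth_points
        Savitzky-Golay half-width for the derivative (25 points = 0.5 degC
        on the default grid).
    shift_level_percent
        Fluorescence level at which temperature shifting aligns curves.
    width_factor
        Clusters wider than ``width_factor`` times the reference homozygote
        transition width are heterozygote candidates.
    amplitude_threshold_percent
        Minimum difference-plot amplitude (vs the major-allele homozygote
        reference) for a heterozygote call.
    linkage_scale
        Auto-grouping threshold = ``linkage_scale`` x median
        within-triplicate RMS distance.
    min_hom_delta_tm_c
        Two homozygote candidate clusters closer than this in Tm cannot be
        ordered and raise :class:`AmbiguousLabelingError`.
    """

    margin_low_c: float = 5.0
    margin_high_c: float = 3.0
    smoothing_halfwidth_points: int = 25
    shift_level_percent: float = 5.0
    width_factor: float = 1.25
    amplitude_threshold_percent: float = 5.0
    linkage_scale: float = 3.0
    min_hom_delta_tm_c: float = 0.2


@dataclass(frozen=True)
class QCPolicy:
    """Triplicate consistency rules; failures yield inconclusive calls."""

    max_tm_range_c: float = 0.2
    require_same_cluster: bool = True


@dataclass
class CallResult:
    """Per-sample genotype call with the evidence behind it."""

    sample_id: str
    called_genotype: str
    tm_replicates_c: np.ndarray
    tm_mean_c: float
    tm_sd_c: float
    shape_width_c: float
    diff_amplitude_vs_ref: float
    cluster_id: int | None
    qc_pass: bool
    qc_reason: str = ""


@dataclass
class ReferenceSet:
    """Per-genotype mean normalized curves and Tms from a standardization run."""

    assay_id: str
    curves: dict[str, NormalizedCurve]
    tms: dict[str, float]
    delta_tm_hom_c: float
    hom_width_c: float


def _prepare(curve: RawMeltCurve, cfg: AnalysisConfig):
    """Normalize one raw curve and measure its Tm (unshifted) and width."""
    pre, post = auto_windows(curve, cfg.margin_low_c, cfg.margin_high_c)
    norm = normalize(curve, pre, post)
    tm = estimate_tm(derivative_curve(curve, cfg.smoothing_halfwidth_points))
    width = transition_width(norm)
    return norm, tm, width


def _mean_curve(curves: Sequence[NormalizedCurve], label: str) -> NormalizedCurve:
    base = curves[0]
    values = np.mean(
        [np.interp(base.temperatures_c, c.temperatures_c, c.values) for c in curves],
        axis=0,
    )
    return NormalizedCurve(
        sample_id=label,
        replicate=0,
        temperatures_c=base.temperatures_c.copy(),
        values=values,
        pre_window=base.pre_window,
        post_window=base.post_window,
    )


def build_references(
    curves_by_genotype: Mapping[str, Sequence[RawMeltCurve]],
    assay: AssayDefinition,
    config: AnalysisConfig | None = None,
) -> ReferenceSet:
    """Characterize each genotype from labelled standardization curves.

    Returns the per-genotype mean normalized profile and mean Tm, the
    expected homozygote Tm separation, and the reference homozygote
    transition width used by the heterozygote shape rule.
    """
    cfg = config or AnalysisConfig()
    missing = [g for g in GENOTYPES if not curves_by_genotype.get(g)]
    if missing:
        raise ValueError(
            "standardization run is missing genotype class(es): " + ", ".join(missing)
        )
    curves: dict[str, NormalizedCurve] = {}
    tms: dict[str, float] = {}
    for genotype in GENOTYPES:
        prepped = [_prepare(c, cfg) for c in curves_by_genotype[genotype]]
        curves[genotype] = _mean_curve([p[0] for p in prepped], f"ref_{genotype}")
        tms[genotype] = float(np.mean([p[1] for p in prepped]))
    hom_width = float(
        np.mean(
            [transition_width(curves[g]) for g in (assay.gc_genotype, assay.at_genotype)]
        )
    )
    return ReferenceSet(
        assay_id=assay.assay_id,
        curves=curves,
        tms=tms,
        delta_tm_hom_c=tms[assay.gc_genotype] - tms[assay.at_genotype],
        hom_width_c=hom_width,
    )


def _curve_matrix(curves: Sequence[NormalizedCurve]) -> np.ndarray:
    lo = max(c.temperatures_c[0] for c in curves)
    hi = min(c.temperatures_c[-1] for c in curves)
    if hi <= lo:
        raise ValueError("curves do not share a common temperature range")
    base = curves[0].temperatures_c
    grid = base[(base >= lo) & (base <= hi)]
    return np.vstack([np.interp(grid, c.temperatures_c, c.values) for c in curves])


def auto_group(curves: Sequence[NormalizedCurve], linkage_threshold: float) -> np.ndarray:
    """Average-linkage agglomerative clustering on RMS curve distance.

    Returns 0-based cluster ids numbered by first occurrence, so the
    assignment is deterministic given the input order.
    """
    if len(curves) == 0:
        raise ValueError("no curves to group")
    if len(curves) == 1:
        return np.zeros(1, dtype=int)
    x = _curve_matrix(curves)
    dist = pdist(x) / np.sqrt(x.shape[1])  # RMS pointwise distance
    raw = fcluster(linkage(dist, method="average"), t=linkage_threshold, criterion="distance")
    relabel: dict[int, int] = {}
    out = np.empty(raw.size, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel)
        out[i] = relabel[r]
    return out


def triplicate_linkage_threshold(
    sample_index: Sequence[int], curves: Sequence[NormalizedCurve], scale: float = 3.0
) -> float:
    """Adaptive grouping threshold: ``scale`` x median within-sample RMS distance."""
    x = _curve_matrix(curves)
    sample_index = np.asarray(sample_index)
    intra: list[float] = []
    for s in np.unique(sample_index):
        rows = x[sample_index == s]
        if rows.shape[0] < 2:
            continue
        intra.extend(pdist(rows) / np.sqrt(rows.shape[1]))
    if not intra:
        raise ValueError(
            "adaptive linkage threshold needs replicate structure; "
            "pass linkage_threshold explicitly"
        )
    return scale * float(np.median(intra))


def label_clusters(
    curves: Sequence[NormalizedCurve],
    cluster_ids: np.ndarray,
    tms: Sequence[float],
    references: ReferenceSet,
    assay: AssayDefinition,
    config: AnalysisConfig | None = None,
) -> dict[int, str]:
    """Assign a genotype to every cluster by shape and Tm ordering.

    Narrow clusters are homozygote candidates: with two of them the higher
    mean Tm takes the G.C-pairing allele, otherwise each maps to the
    nearest reference homozygote Tm.  Wide clusters with a large
    difference-plot amplitude against the major-allele homozygote
    reference are heterozygotes.
    """
    cfg = config or AnalysisConfig()
    cluster_ids = np.asarray(cluster_ids)
    tms = np.asarray(tms, dtype=float)
    unique = np.unique(cluster_ids)
    if unique.size > 3:
        raise ClusterCountError(
            f"{unique.size} clusters for 3 genotypes; review the linkage threshold"
        )
    ref_major = references.curves[HOM_MAJOR]
    width_threshold = cfg.width_factor * references.hom_width_c

    labels: dict[int, str] = {}
    hom_candidates: list[tuple[int, float]] = []
    for cid in unique:
        members = [c for c, k in zip(curves, cluster_ids) if k == cid]
        mean = _mean_curve(members, f"cluster_{cid}")
        mean_width = float(np.mean([transition_width(c) for c in members]))
        amp = difference_amplitude(difference_curve(mean, ref_major))
        mean_tm = float(np.mean(tms[cluster_ids == cid]))
        if mean_width > width_threshold and abs(amp) > cfg.amplitude_threshold_percent:
            labels[int(cid)] = HET
        else:
            hom_candidates.append((int(cid), mean_tm))

    if len(hom_candidates) == 2:
        (c_lo, tm_lo), (c_hi, tm_hi) = sorted(hom_candidates, key=lambda x: x[1])
        if tm_hi - tm_lo < cfg.min_hom_delta_tm_c:
            raise AmbiguousLabelingError(
                f"homozygote clusters separated by only {tm_hi - tm_lo:.3f} degC"
            )
        labels[c_hi] = assay.gc_genotype
        labels[c_lo] = assay.at_genotype
    else:
        # 0, 1 or 3 homozygote candidates: anchor on the reference Tms.
        for cid, tm in hom_candidates:
            hom_genotypes = (assay.gc_genotype, assay.at_genotype)
            labels[cid] = min(hom_genotypes, key=lambda g: abs(tm - references.tms[g]))
    return labels


def _call_grouped(
    grouped: dict[str, list[RawMeltCurve]],
    references: ReferenceSet,
    assay: AssayDefinition,
    qc: QCPolicy,
    cfg: AnalysisConfig,
    linkage_threshold: float | None,
) -> list[CallResult]:
    sample_ids = sorted(grouped)
    norms: list[NormalizedCurve] = []
    tms: list[float] = []
    widths: list[float] = []
    owner: list[int] = []
    for s, sid in enumerate(sample_ids):
        for curve in grouped[sid]:
            norm, tm, width = _prepare(curve, cfg)
            norms.append(norm)
            tms.append(tm)
            widths.append(width)
            owner.append(s)
    owner_arr = np.asarray(owner)
    if linkage_threshold is None:
        if len(norms) == 1:
            linkage_threshold = 0.0
        else:
            linkage_threshold = triplicate_linkage_threshold(
                owner_arr, norms, cfg.linkage_scale
            )
    clusters = auto_group(norms, linkage_threshold)
    genotype_of = label_clusters(norms, clusters, tms, references, assay, cfg)
    ref_major = references.curves[HOM_MAJOR]

    results: list[CallResult] = []
    for s, sid in enumerate(sample_ids):
        idx = np.nonzero(owner_arr == s)[0]
        rep_tms = np.asarray([tms[i] for i in idx])
        rep_clusters = {int(clusters[i]) for i in idx}
        tm_sd = float(np.std(rep_tms, ddof=1)) if rep_tms.size > 1 else 0.0
        mean = _mean_curve([norms[i] for i in idx], sid)
        amp = difference_amplitude(difference_curve(mean, ref_major))
        reasons: list[str] = []
        tm_range = float(np.ptp(rep_tms))
        if tm_range > qc.max_tm_range_c:
            reasons.append(
                f"replicate Tm range {tm_range:.3f} degC exceeds {qc.max_tm_range_c:.2f} degC"
            )
        if qc.require_same_cluster and len(rep_clusters) > 1:
            reasons.append("replicates split across melt-curve clusters")
        qc_pass = not reasons
        if qc_pass:
            cluster_id: int | None = int(clusters[idx[0]])
            genotype = genotype_of[cluster_id]
        else:
            cluster_id = None
            genotype = INCONCLUSIVE
        results.append(
            CallResult(
                sample_id=sid,
                called_genotype=genotype,
                tm_replicates_c=rep_tms,
                tm_mean_c=float(rep_tms.mean()),
                tm_sd_c=tm_sd,
                shape_width_c=float(np.mean([widths[i] for i in idx])),
                diff_amplitude_vs_ref=amp,
                cluster_id=cluster_id,
                qc_pass=qc_pass,
                qc_reason="; ".join(reasons),
            )
        )
    return results


def call_sample(
    curves: Sequence[RawMeltCurve],
    references: ReferenceSet,
    assay: AssayDefinition,
    qc: QCPolicy | None = None,
    config: AnalysisConfig | None = None,
) -> CallResult:
    """Call one sample from its replicate wells (a cohort of one)."""
    if len(curves) == 0:
        raise ValueError("sample has no curves")
    sample_ids = {c.sample_id for c in curves}
    if len(sample_ids) > 1:
        raise ValueError(f"curves belong to several samples: {sorted(sample_ids)}")
    return _call_grouped(
        {curves[0].sample_id: list(curves)},
        references,
        assay,
        qc or QCPolicy(),
        config or AnalysisConfig(),
        linkage_threshold=None,
    )[0]


def call_cohort(
    curves: Sequence[RawMeltCurve],
    references: ReferenceSet,
    assay: AssayDefinition,
    qc: QCPolicy | None = None,
    config: AnalysisConfig | None = None,
    linkage_threshold: float | None = None,
) -> list[CallResult]:
    """Call every sample on a plate; output ordered by sample id.

    The adaptive linkage threshold is derived from within-triplicate
    distances unless given explicitly.  Calls are invariant to the input
    order of the curves.
    """
    if len(curves) == 0:
        return []
    grouped: dict[str, list[RawMeltCurve]] = {}
    for curve in curves:
        grouped.setdefault(curve.sample_id, []).append(curve)
    for sid, group in grouped.items():
        group.sort(key=lambda c: c.replicate)
        if not group:
            raise ValueError(f"sample {sid} has no curves")
    return _call_grouped(
        grouped,
        references,
        assay,
        qc or QCPolicy(),
        config or AnalysisConfig(),
        linkage_threshold,
    )
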