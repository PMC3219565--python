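"""File formats: curve/truth/call CSV, assay YAML, VCF, FASTA fixtures, reports.

Melt curves travel as long-format CSV (sample_id, replicate, temperature_c,
fluorescence); temperatures are serialized with 3 decimals and fluorescence
with 4, enough to round-trip the default 0.02 degC grid losslessly.  Assay
definitions are YAML (JSON also parses); three assay files transcribed from
the published RET/PAX2/ALDH1A2 SNP panel ship inside the package.  Calls
are emitted as CSV and as a minimal VCF 4.2 (GT only; inconclusive becomes
"./."); synthetic amplicon fixtures as FASTA.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .curve_analysis import DerivativeCurve, DifferenceCurve, NormalizedCurve
from .evaluation import EvaluationReport
from .genotype_caller import CallResult, INCONCLUSIVE
from .melt_model import (
    GENOTYPES,
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    AssayDefinition,
    RawMeltCurve,
)

__all__ = [
    "CURVE_COLUMNS",
    "read_curves",
    "write_curves",
    "read_truth",
    "write_truth",
    "load_assay",
    "packaged_assay",
    "packaged_assay_names",
    "write_calls_csv",
    "write_vcf",
    "write_amplicon_fasta",
    "write_report_json",
    "write_report_text",
    "write_stage_csv",
]

CURVE_COLUMNS = ["sample_id", "replicate", "temperature_c", "fluorescence"]
PACKAGED_ASSAYS = {
    "RET": "ret_rs1800860.yaml",
    "PAX2": "pax2_rs11190688.yaml",
    "ALDH1A2": "aldh1a2_rs7169289.yaml",
}


def write_curves(curves: Sequence[RawMeltCurve], path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "replicate": c.replicate,
                    "temperature_c": [f"{t:.3f}" for t in c.temperatures_c],
                    "fluorescence": [f"{f:.4f}" for f in c.fluorescence],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path) -> list[RawMeltCurve]:
    """Read a long-format curve CSV back into per-well curves.

    Curves are grouped by (sample_id, replicate) and sorted by temperature.
    Missing columns, non-numeric values and duplicate acquisitions raise
    descriptive errors naming the offending column or data rows.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve file {path} is missing column(s): {', '.join(missing)}")
    for col in ("replicate", "temperature_c", "fluorescence"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()].tolist()
        if bad or converted.isna().any():
            rows = bad or df.index[converted.isna()].tolist()
            raise ValueError(
                f"non-numeric or missing values in column {col!r} at data row(s) "
                f"{rows[:10]}"
            )
        df[col] = converted
    dup = df.duplicated(subset=["sample_id", "replicate", "temperature_c"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise ValueError(
            f"duplicate (sample_id, replicate, temperature_c) acquisitions at data "
            f"row(s) {rows[:10]}"
        )
    curves = []
    for (sid, rep), group in df.groupby(["sample_id", "replicate"], sort=True):
        group = group.sort_values("temperature_c")
        curves.append(
            RawMeltCurve(
                str(sid),
                int(rep),
                group["temperature_c"].to_numpy(),
                group["fluorescence"].to_numpy(),
            )
        )
    return curves


def write_truth(truth: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(truth), "genotype": [truth[s] for s in truth]}
    ).sort_values("sample_id").to_csv(path, index=False)


def read_truth(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "genotype"):
        if col not in df.columns:
            raise ValueError(f"truth file {path} is missing column {col!r}")
    bad = sorted(set(df["genotype"]) - set(GENOTYPES))
    if bad:
        raise ValueError(f"unknown genotype token(s) in truth file: {', '.join(bad)}")
    return dict(zip(df["sample_id"], df["genotype"]))


def _assay_from_mapping(data: Mapping) -> AssayDefinition:
    data = dict(data)
    vcf = data.pop("vcf", None)
    if vcf:
        data.setdefault("vcf_chrom", vcf.get("chrom", "UNPLACED"))
        data.setdefault("vcf_pos", vcf.get("pos", 1))
    field_names = {f.name for f in dataclasses.fields(AssayDefinition)}
    unknown = sorted(set(data) - field_names)
    if unknown:
        raise ValueError(f"unknown assay field(s): {', '.join(unknown)}")
    return AssayDefinition(**data)


def load_assay(path) -> AssayDefinition:
    """Load one assay definition from a YAML (or JSON) document."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"assay file {path} does not contain a mapping")
    return _assay_from_mapping(data)


def packaged_assay_names() -> list[str]:
    return list(PACKAGED_ASSAYS)


def packaged_assay(name: str) -> AssayDefinition:
    """Load one of the three packaged SNP assays (RET, PAX2, ALDH1A2)."""
    key = name.upper()
    if key not in PACKAGED_ASSAYS:
        raise KeyError(f"no packaged assay {name!r}; choose from {list(PACKAGED_ASSAYS)}")
    ref = resources.files("hrmelt").joinpath("assays", PACKAGED_ASSAYS[key])
    data = yaml.safe_load(ref.read_text())
    return _assay_from_mapping(data)


def resolve_assay(name_or_path: str) -> AssayDefinition:
    """Accept a packaged assay name or a path to an assay file."""
    if name_or_path.upper() in PACKAGED_ASSAYS:
        return packaged_assay(name_or_path)
    return load_assay(name_or_path)


def write_calls_csv(calls: Sequence[CallResult], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "genotype": [c.called_genotype for c in calls],
            "tm_mean_c": [round(c.tm_mean_c, 4) for c in calls],
            "tm_sd_c": [round(c.tm_sd_c, 5) for c in calls],
            "qc_pass": [c.qc_pass for c in calls],
            "qc_reason": [c.qc_reason for c in calls],
            "cluster_id": [c.cluster_id if c.cluster_id is not None else "" for c in calls],
        }
    ).to_csv(path, index=False)


_GT = {HOM_MAJOR: (0, 0), HET: (0, 1), HOM_MINOR: (1, 1), INCONCLUSIVE: (None, None)}


def write_vcf(calls: Sequence[CallResult], assay: AssayDefinition, path) -> None:
    """Write calls as a minimal VCF 4.2: one site, GT only.

    CHROM/POS come from the assay configuration; the packaged assays carry
    clearly marked placeholders rather than fabricated genomic coordinates.
    """
    header = pysam.VariantHeader()
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.contigs.add(assay.vcf_chrom)
    ordered = sorted(calls, key=lambda c: c.sample_id)
    for call in ordered:
        header.add_sample(call.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        record = out.new_record(
            contig=assay.vcf_chrom,
            start=assay.vcf_pos - 1,
            alleles=(assay.major_allele, assay.minor_allele),
            id=assay.rs_id,
        )
        for call in ordered:
            record.samples[call.sample_id]["GT"] = _GT[call.called_genotype]
        out.write(record)


def write_amplicon_fasta(assay: AssayDefinition, path, seed: int = 0) -> None:
    """Write synthetic amplicon sequences, one record per allele.

    The amplicon has the declared length with the SNP allele at the
    declared 1-based position; the flanking sequence is random under the
    given seed and shared between the two alleles.  These are synthetic
    fixtures, not the published primer products.
    """
    rng = np.random.default_rng(seed)
    flanks = rng.choice(list("ACGT"), size=assay.amplicon_length_bp)
    records = []
    for allele in (assay.major_allele, assay.minor_allele):
        seq = flanks.copy()
        seq[assay.snp_position_bp - 1] = allele
        records.append(
            SeqRecord(
                Seq("".join(seq)),
                id=f"{assay.assay_id}_{assay.rs_id}_{allele}",
                description=(
                    f"synthetic amplicon, {assay.amplicon_length_bp} bp, "
                    f"allele {allele} at position {assay.snp_position_bp}"
                ),
            )
        )
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")


def write_report_json(report: EvaluationReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def write_report_text(report: EvaluationReport, path) -> None:
    Path(path).write_text(report.to_text() + "\n")


def write_stage_csv(stages: Mapping[str, Sequence], path) -> None:
    """Write analysis-stage curves in one long CSV with a ``stage`` column.

    Accepts normalized, derivative and difference curves; each contributes
    rows (sample_id, replicate, stage, temperature_c, value).
    """
    frames = []
    for stage, curves in stages.items():
        for c in curves:
            if isinstance(c, NormalizedCurve):
                sid, rep, t, v = c.sample_id, c.replicate, c.temperatures_c, c.values
            elif isinstance(c, DerivativeCurve):
                sid, rep, t, v = "", 0, c.temperatures_c, c.minus_df_dt
            elif isinstance(c, DifferenceCurve):
                sid, rep, t, v = c.reference_id, 0, c.temperatures_c, c.delta_values
            else:  # (label, replicate, curve) triple for anonymous stages
                sid, rep, curve = c
                t = curve.temperatures_c
                v = next(
                    getattr(curve, attr)
                    for attr in ("values", "minus_df_dt", "delta_values")
                    if hasattr(curve, attr)
                )
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "replicate": rep,
                        "stage": stage,
                        "temperature_c": np.round(t, 3),
                        "value": np.round(v, 4),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
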