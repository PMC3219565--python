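"""Two-state duplex-melting simulator for HRM genotyping assays.

High-resolution melting (HRM) genotyping reads out a biallelic SNP from the
fluorescence of a saturating double-strand DNA dye during a slow temperature
ramp over the PCR amplicon.  This module is the synthetic stand-in for the
instrument and the samples: it produces realistic raw melt curves for any
genotype, replicate structure and noise level.

The physical picture is deliberately minimal.  Each duplex population
(species) melts as a two-state helix/coil transition with a logistic
helicity profile

    theta(T) = 1 / (1 + exp((T - Tm) / w)),

where ``Tm`` is the midpoint (melting temperature) and ``w`` sets the
transition width.  A homozygote contains a single perfectly matched
homoduplex.  A heterozygote, after denaturation and random re-annealing of
two equal sense-strand pools with two equal antisense pools, is a uniform
2x2 mixture: both homoduplexes plus two single-mismatch heteroduplexes at
25 % each.  Heteroduplexes are destabilized (lower Tm, broader transition),
and the G.C-pairing allele always melts above the A.T-pairing allele.

The dye signal is a helicity-weighted blend of two linear baselines (the
double-strand and single-strand fluorescence levels) plus i.i.d. Gaussian
acquisition noise; replicate wells receive a rigid Tm jitter (salt/volume
effects shift every species in the well together) and a small gain factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HOM_MAJOR",
    "HET",
    "HOM_MINOR",
    "GENOTYPES",
    "TemperatureGrid",
    "DuplexSpecies",
    "AssayDefinition",
    "NoiseModel",
    "Baselines",
    "RawMeltCurve",
    "CohortSpec",
    "helicity",
    "species_mixture",
    "simulate_curve",
    "simulate_sample",
    "simulate_cohort",
    "tm_shift_for_length",
]

#: Genotype tokens used throughout the package.
HOM_MAJOR = "hom_major"
HET = "het"
HOM_MINOR = "hom_minor"
GENOTYPES = (HOM_MAJOR, HET, HOM_MINOR)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class TemperatureGrid:
    """Evenly spaced acquisition grid, inclusive of both endpoints.

    The default (65-95 degC at 50 acquisitions per degC) yields 1501 points,
    matching a LightCycler-style high-resolution ramp.
    """

    start_c: float = 65.0
    end_c: float = 95.0
    acquisitions_per_c: int = 50

    def __post_init__(self) -> None:
        if not self.start_c < self.end_c:
            raise ValueError("start_c must be strictly below end_c")
        if self.acquisitions_per_c < 1:
            raise ValueError("acquisitions_per_c must be >= 1")

    @property
    def n_points(self) -> int:
        return int(round((self.end_c - self.start_c) * self.acquisitions_per_c)) + 1

    @property
    def spacing_c(self) -> float:
        return (self.end_c - self.start_c) / (self.n_points - 1)

    def temperatures(self) -> np.ndarray:
        return np.linspace(self.start_c, self.end_c, self.n_points)


@dataclass(frozen=True)
class DuplexSpecies:
    """One duplex population: a label, a midpoint Tm, a width and a weight."""

    label: str
    tm_c: float
    width_c: float
    weight: float

    def __post_init__(self) -> None:
        if self.width_c <= 0:
            raise ValueError("width_c must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass(frozen=True)
class AssayDefinition:
    """One biallelic SNP assay: alleles, duplex Tm parameters, amplicon geometry.

    ``gc_allele`` names the allele whose base pair is G.C; its homoduplex
    melts at ``tm_gc_hom_c`` and the other homoduplex ``delta_tm_hom_c``
    below it.  Heteroduplexes melt ``het_penalty_c`` below the less stable
    homoduplex; ``het_split_c`` optionally separates the two mismatch
    species (default 0: both share one Tm, since single-mismatch stability
    differences are below the resolution this model targets).
    """

    assay_id: str
    rs_id: str
    major_allele: str
    minor_allele: str
    gc_allele: str
    tm_gc_hom_c: float = 85.0
    delta_tm_hom_c: float = 0.50
    het_penalty_c: float = 1.0
    het_split_c: float = 0.0
    width_hom_c: float = 0.35
    width_het_c: float = 0.525
    amplicon_length_bp: int = 100
    snp_position_bp: int = 50
    vcf_chrom: str = "UNPLACED"
    vcf_pos: int = 1

    def __post_init__(self) -> None:
        for name in ("major_allele", "minor_allele", "gc_allele"):
            if getattr(self, name) not in _COMPLEMENT:
                raise ValueError(f"{name} must be one of A/C/G/T")
        if self.major_allele == self.minor_allele:
            raise ValueError("major and minor alleles must differ")
        if self.gc_allele not in (self.major_allele, self.minor_allele):
            raise ValueError("gc_allele must be the major or the minor allele")
        if self.delta_tm_hom_c <= 0:
            raise ValueError("delta_tm_hom_c must be positive")
        if self.het_penalty_c <= 0:
            raise ValueError("het_penalty_c must be positive")
        if self.het_split_c < 0:
            raise ValueError("het_split_c must be non-negative")
        if self.width_hom_c <= 0 or self.width_het_c <= 0:
            raise ValueError("transition widths must be positive")
        if not 1 <= self.snp_position_bp <= self.amplicon_length_bp:
            raise ValueError("snp_position_bp must lie within the amplicon")

    @property
    def gc_genotype(self) -> str:
        """Homozygous genotype carrying the G.C base pair (higher Tm)."""
        return HOM_MAJOR if self.gc_allele == self.major_allele else HOM_MINOR

    @property
    def at_genotype(self) -> str:
        """Homozygous genotype carrying the A.T base pair (lower Tm)."""
        return HOM_MINOR if self.gc_allele == self.major_allele else HOM_MAJOR

    def allele_of(self, genotype: str) -> str:
        if genotype == HOM_MAJOR:
            return self.major_allele
        if genotype == HOM_MINOR:
            return self.minor_allele
        raise ValueError(f"no single allele for genotype {genotype!r}")

    def hom_tm_c(self, genotype: str) -> float:
        """Homoduplex Tm of a homozygous genotype."""
        if self.allele_of(genotype) == self.gc_allele:
            return self.tm_gc_hom_c
        return self.tm_gc_hom_c - self.delta_tm_hom_c


@dataclass(frozen=True)
class NoiseModel:
    """Instrument and well-to-well noise.

    fluor_sd
        Gaussian fluorescence noise per acquisition (signal units).
    tm_jitter_sd_c
        Per-replicate rigid Tm shift (degC) applied to every species in the
        well.  The default keeps replicate-triplicate Tm SDs comfortably
        under the 0.06 degC ceiling observed on real instruments.
    baseline_jitter
        Relative per-well gain variation (fraction).
    """

    fluor_sd: float = 0.25
    tm_jitter_sd_c: float = 0.025
    baseline_jitter: float = 0.02

    def __post_init__(self) -> None:
        if self.fluor_sd < 0 or self.tm_jitter_sd_c < 0 or self.baseline_jitter < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Baselines:
    """Linear double-strand (upper) and single-strand (lower) signal levels."""

    upper_intercept: float = 100.0
    upper_slope_per_c: float = -0.3
    lower_intercept: float = 5.0
    lower_slope_per_c: float = -0.02
    reference_t_c: float = 65.0

    def upper(self, t):
        return self.upper_intercept + self.upper_slope_per_c * (
            np.asarray(t, dtype=float) - self.reference_t_c
        )

    def lower(self, t):
        return self.lower_intercept + self.lower_slope_per_c * (
            np.asarray(t, dtype=float) - self.reference_t_c
        )

    def scaled(self, factor: float) -> "Baselines":
        """Rescale both baselines by a gain factor (per-well variation)."""
        return Baselines(
            self.upper_intercept * factor,
            self.upper_slope_per_c * factor,
            self.lower_intercept * factor,
            self.lower_slope_per_c * factor,
            self.reference_t_c,
        )


@dataclass
class RawMeltCurve:
    """Fluorescence versus temperature for one well (one replicate)."""

    sample_id: str
    replicate: int
    temperatures_c: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures_c = np.asarray(self.temperatures_c, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures_c.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence vectors differ in length")
        if self.temperatures_c.ndim != 1 or self.temperatures_c.size < 2:
            raise ValueError("a melt curve needs at least two acquisitions")
        if not np.all(np.diff(self.temperatures_c) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")


@dataclass(frozen=True)
class CohortSpec:
    """A simulated plate: one assay, a genotype panel, replicates, noise, seed."""

    assay: AssayDefinition
    n_samples: int
    genotype_counts: Mapping[str, int]
    replicates: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for genotype, count in self.genotype_counts.items():
            if genotype not in GENOTYPES:
                raise ValueError(f"unknown genotype {genotype!r}")
            if count < 0:
                raise ValueError("genotype counts must be non-negative")
        if sum(self.genotype_counts.values()) != self.n_samples:
            raise ValueError("genotype_counts must sum to n_samples")


def helicity(t, tm_c: float, width_c: float):
    """Fraction of duplex still helical at temperature ``t``.

    Logistic in temperature: 0.5 at ``tm_c``, approaching 1 far below and
    0 far above; strictly decreasing.
    """
    if width_c <= 0:
        raise ValueError("width_c must be positive")
    arr = np.asarray(t, dtype=float)
    out = 1.0 / (1.0 + np.exp((arr - tm_c) / width_c))
    if np.ndim(t) == 0:
        return float(out)
    return out


def species_mixture(genotype: str, assay: AssayDefinition) -> list[DuplexSpecies]:
    """Duplex populations present in a sample of the given genotype.

    Homozygotes carry a single homoduplex (weight 1).  Heterozygotes carry
    four species at weight 0.25 each: random re-association of two equal
    sense-strand pools with two equal antisense pools forces a uniform 2x2
    mixture of the two homoduplexes and the two mismatch heteroduplexes.
    """
    tm_at = assay.tm_gc_hom_c - assay.delta_tm_hom_c

    def _hom(allele: str, weight: float) -> DuplexSpecies:
        tm = assay.tm_gc_hom_c if allele == assay.gc_allele else tm_at
        label = f"{allele}:{_COMPLEMENT[allele]} homoduplex"
        return DuplexSpecies(label, tm, assay.width_hom_c, weight)

    if genotype in (HOM_MAJOR, HOM_MINOR):
        return [_hom(assay.allele_of(genotype), 1.0)]
    if genotype == HET:
        het_tm = tm_at - assay.het_penalty_c
        maj, mino = assay.major_allele, assay.minor_allele
        return [
            _hom(maj, 0.25),
            _hom(mino, 0.25),
            DuplexSpecies(
                f"{maj}:{_COMPLEMENT[mino]} heteroduplex",
                het_tm,
                assay.width_het_c,
                0.25,
            ),
            DuplexSpecies(
                f"{mino}:{_COMPLEMENT[maj]} heteroduplex",
                het_tm - assay.het_split_c,
                assay.width_het_c,
                0.25,
            ),
        ]
    raise ValueError(f"unknown genotype token {genotype!r}")


def _mixture_helicity(mixture: Sequence[DuplexSpecies], t: np.ndarray) -> np.ndarray:
    total = np.zeros_like(t, dtype=float)
    for sp in mixture:
        total += sp.weight * helicity(t, sp.tm_c, sp.width_c)
    return total


def simulate_curve(
    mixture: Sequence[DuplexSpecies],
    grid: TemperatureGrid | None = None,
    baselines: Baselines | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
    replicate: int = 0,
) -> RawMeltCurve:
    """Simulate one acquisition: F(T) = upper(T)*H(T) + lower(T)*(1-H(T)) + noise.

    ``H`` is the weight-averaged helicity of the mixture, so the curve of a
    mixture equals the weighted sum of its single-species curves (shared
    baselines) -- the model is linear in the species.
    """
    grid = grid or TemperatureGrid()
    baselines = baselines or Baselines()
    noise = noise or NoiseModel.zero()
    if len(mixture) == 0:
        raise ValueError("mixture must contain at least one species")
    total_weight = sum(sp.weight for sp in mixture)
    if abs(total_weight - 1.0) > 1e-9:
        raise ValueError(f"mixture weights sum to {total_weight}, expected 1")
    t = grid.temperatures()
    upper = baselines.upper(t)
    lower = baselines.lower(t)
    if np.any(upper <= lower):
        raise ValueError("upper baseline must exceed lower baseline over the grid")
    h = _mixture_helicity(mixture, t)
    f = upper * h + lower * (1.0 - h)
    if noise.fluor_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        f = f + rng.normal(0.0, noise.fluor_sd, size=t.size)
    return RawMeltCurve(sample_id, replicate, t, f)


def simulate_sample(
    assay: AssayDefinition,
    genotype: str,
    replicates: int = 3,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    grid: TemperatureGrid | None = None,
    baselines: Baselines | None = None,
    sample_id: str = "S1",
    return_jitter: bool = False,
):
    """Simulate one sample assayed in ``replicates`` wells.

    Each replicate receives a single rigid Tm jitter (every species in the
    well shifts together, modelling well-to-well salt/volume effects) and a
    per-well gain factor, then acquisition noise per point.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    noise = noise if noise is not None else NoiseModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    baselines = baselines or Baselines()
    mixture = species_mixture(genotype, assay)
    curves: list[RawMeltCurve] = []
    jitters: list[float] = []
    for rep in range(1, replicates + 1):
        delta = rng.normal(0.0, noise.tm_jitter_sd_c) if noise.tm_jitter_sd_c > 0 else 0.0
        gain = 1.0 + (rng.normal(0.0, noise.baseline_jitter) if noise.baseline_jitter > 0 else 0.0)
        shifted = [replace(sp, tm_c=sp.tm_c + delta) for sp in mixture]
        curves.append(
            simulate_curve(
                shifted,
                grid=grid,
                baselines=baselines.scaled(gain),
                noise=noise,
                rng=rng,
                sample_id=sample_id,
                replicate=rep,
            )
        )
        jitters.append(delta)
    if return_jitter:
        return curves, np.asarray(jitters)
    return curves


def simulate_cohort(spec: CohortSpec):
    """Simulate a whole plate and return ``(curves, truth)``.

    Genotypes are assigned to opaque sample IDs by a seeded permutation, so
    the curve list carries no positional genotype signal (blinding
    supported); the truth table is returned separately.  Fixed seed implies
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(3, len(str(spec.n_samples)))
    sample_ids = [f"S{i:0{width}d}" for i in range(1, spec.n_samples + 1)]
    pool: list[str] = []
    for genotype in GENOTYPES:
        pool.extend([genotype] * spec.genotype_counts.get(genotype, 0))
    order = rng.permutation(spec.n_samples)
    truth = {sid: pool[order[i]] for i, sid in enumerate(sample_ids)}
    curves: list[RawMeltCurve] = []
    for sid in sample_ids:
        curves.extend(
            simulate_sample(
                spec.assay,
                truth[sid],
                replicates=spec.replicates,
                noise=spec.noise,
                rng=rng,
                sample_id=sid,
            )
        )
    return curves, truth


def tm_shift_for_length(delta_tm_ref: float, length_ref: int, length_new: int) -> float:
    """Rescale a homozygote Tm separation to a different amplicon length.

    Inverse-length model: the separation contributed by a single base
    substitution is diluted proportionally to amplicon size, so shorter
    amplicons discriminate better.  A design utility only -- measured
    separations also depend strongly on sequence context.
    """
    if length_ref <= 0 or length_new <= 0:
        raise ValueError("amplicon lengths must be positive")
    return delta_tm_ref * length_ref / length_new
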