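"""Minor-contributor (cross-contamination) detection in mixed samples.

Two cell lines usually share alleles at several STR loci, so detection of a
minor contaminating line rests on its *informative alleles*: repeat lengths
present in the minor line's reference profile but absent from the major
line's.  Informative alleles one to two repeats **longer** than the nearest
major allele are the best markers, because PCR stutter is predominantly one
repeat *shorter* than its parent: an informative allele sitting exactly one
repeat below a major allele is indistinguishable from the major's stutter
and is excluded from pooled estimation by default.

The minor genome fraction is estimated from read fractions of informative
alleles in the mixed sample's raw (unclassified) spectra — sub-threshold
lengths must stay visible — corrected for allele dose: a heterozygous minor
carries each informative allele on one of two chromosomes, so its reads
represent half the minor's genome fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.stats import binomtest

from .locus_config import Panel
from .profiler import LocusProfile, SampleProfile
from .repeats import RepeatLength

DEFAULT_DETECTION_MIN_FRAC = 0.002
DEFAULT_DETECTION_MIN_READS = 10


@dataclass(frozen=True)
class InformativeAllele:
    """A minor-line allele absent from the major line at the same locus."""

    locus: str
    length: RepeatLength
    offset_bp: int            # signed bp offset from the nearest major allele
    offset_repeats: float     # the same offset in repeat units
    stutter_colliding: bool   # sits at -1 repeat of a major allele
    dose: float               # expected fraction of minor reads carrying it


@dataclass(frozen=True)
class DetectionRule:
    """An informative allele supports detection when its read fraction and
    read count both clear these floors."""

    min_frac: float = DEFAULT_DETECTION_MIN_FRAC
    min_reads: int = DEFAULT_DETECTION_MIN_READS


@dataclass
class AlleleObservation:
    allele: InformativeAllele
    reads: int
    locus_total: int

    @property
    def fraction(self) -> float:
        return self.reads / self.locus_total if self.locus_total else 0.0


@dataclass
class MixtureResult:
    """Observed informative-allele fractions and the pooled minor estimate."""

    observations: list[AlleleObservation]
    pooled_reads: int = 0
    pooled_total: int = 0
    pooled_fraction: float = 0.0
    minor_fraction_estimate: Optional[float] = None
    confidence_interval: Optional[tuple[float, float]] = None
    decision: Optional[str] = None  # "detected" | "not-detected"
    rule: Optional[DetectionRule] = None
    supporting: list[InformativeAllele] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def undetermined(self) -> bool:
        return self.minor_fraction_estimate is None


def informative_alleles(
    major: SampleProfile, minor: SampleProfile, panel: Panel
) -> list[InformativeAllele]:
    """Minor alleles absent from the major profile, per shared locus.

    Each is annotated with its bp offset from the nearest major allele
    (ties resolve to the positive side) and flagged ``stutter_colliding``
    when it sits exactly one repeat below a major allele.  Identical
    profiles yield an empty list — the two lines are indistinguishable at
    this panel.
    """
    result: list[InformativeAllele] = []
    for locus in sorted(set(major.genotypes) & set(minor.genotypes)):
        spec = panel[locus]
        major_set = major.allele_set(locus)
        minor_call = minor.genotypes[locus]
        if not major_set or not minor_call.alleles:
            continue
        for length, frac in sorted(minor_call.alleles):
            if length in major_set:
                continue
            bp = length.total_bp(spec.repeat_size)
            offset = min(
                (bp - m.total_bp(spec.repeat_size) for m in major_set),
                key=lambda d: (abs(d), -d),
            )
            result.append(
                InformativeAllele(
                    locus=locus,
                    length=length,
                    offset_bp=offset,
                    offset_repeats=offset / spec.repeat_size,
                    stutter_colliding=offset == -spec.repeat_size,
                    dose=frac,
                )
            )
    return result


def estimate_minor_fraction(
    mixed_profiles: dict[str, LocusProfile],
    informative: Sequence[InformativeAllele],
    *,
    confidence_level: float = 0.95,
) -> MixtureResult:
    """Estimate the minor genome fraction from a mixed sample's raw spectra.

    ``mixed_profiles`` must be *unclassified* tabulated profiles so that
    sub-threshold informative lengths are still visible.  Stutter-colliding
    informative alleles are reported but excluded from pooling.  The pooled
    read fraction over informative alleles is divided by the read-weighted
    mean allele dose to give the genome-fraction estimate; the confidence
    interval is exact binomial on the pooled count, scaled the same way.
    """
    observations: list[AlleleObservation] = []
    for allele in informative:
        profile = mixed_profiles.get(allele.locus)
        if profile is None or profile.is_empty:
            continue
        observations.append(
            AlleleObservation(
                allele=allele,
                reads=profile.spectrum.get(allele.length, 0),
                locus_total=profile.total_calls,
            )
        )
    result = MixtureResult(observations=observations)
    if not observations:
        result.warnings.append("no informative alleles observable; result undetermined")
        return result

    usable = [o for o in observations if not o.allele.stutter_colliding]
    if not usable:
        result.warnings.append(
            "all informative alleles collide with major stutter positions"
        )
        return result
    result.pooled_reads = sum(o.reads for o in usable)
    result.pooled_total = sum(o.locus_total for o in usable)
    result.pooled_fraction = result.pooled_reads / result.pooled_total
    mean_dose = (
        sum(o.allele.dose * o.locus_total for o in usable)
        / sum(o.locus_total for o in usable)
    )
    result.minor_fraction_estimate = result.pooled_fraction / mean_dose
    ci = binomtest(result.pooled_reads, result.pooled_total).proportion_ci(
        confidence_level=confidence_level
    )
    result.confidence_interval = (ci.low / mean_dose, ci.high / mean_dose)
    return result


def detect_contamination(
    result: MixtureResult, rule: DetectionRule = DetectionRule()
) -> str:
    """Apply the detection rule and record the decision on the result.

    Detected iff at least one non-stutter-colliding informative allele has
    read fraction >= ``rule.min_frac`` and read count >= ``rule.min_reads``.
    """
    supporting = [
        o.allele
        for o in result.observations
        if not o.allele.stutter_colliding
        and o.fraction >= rule.min_frac
        and o.reads >= rule.min_reads
    ]
    result.rule = rule
    result.supporting = supporting
    result.decision = "detected" if supporting else "not-detected"
    return result.decision
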