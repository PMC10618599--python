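"""Locus profiles, allele/stutter/noise classification, genotypes, concordance.

The per-read calls at one locus form a *spectrum*: read counts over repeat
lengths.  Classification follows the error taxonomy of amplicon STR
sequencing:

* **allele** — a repeat length carried by the sample, observed as a read
  class at or above the allele threshold (default 10% of locus reads).
  Partial-repeat (microvariant) lengths above threshold are genuine
  alleles, e.g. 13.2.
* **stutter** — a complete-repeat length below threshold: PCR slippage
  products, predominantly one repeat shorter than a parent allele.
* **noise** — a partial-repeat length below threshold: sequencing error or
  off-target amplification (e.g. a stray 11.2 under an integer allele).

Because read counts are proportional to template copy number, the ratio of
allele read counts at a multi-copy locus estimates the per-allele copy
state: a ~2:1 ratio between two alleles suggests three copies of the locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .locus_config import Panel
from .repeat_caller import RepeatCall, RunTally
from .repeats import RepeatLength

ALLELE = "allele"
STUTTER = "stutter"
NOISE = "noise"

#: Candidate integer copy states for two-allele loci, as (a, b) count ratios.
COPY_RATIO_CANDIDATES: tuple[tuple[int, int], ...] = ((1, 1), (3, 2), (2, 1), (3, 1))
COPY_RATIO_TOLERANCE = 0.2

DEFAULT_ALLELE_MIN_FRAC = 0.10
DEFAULT_MIN_READS = 100
MAX_ALLELES = 4


@dataclass
class LocusProfile:
    """Read-count spectrum over repeat lengths at one locus."""

    locus: str
    total_calls: int
    spectrum: dict[RepeatLength, int]
    percentages: dict[RepeatLength, float]
    class_labels: dict[RepeatLength, str] = field(default_factory=dict)
    top_sequences: dict[RepeatLength, tuple[str, int]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.total_calls == 0

    def fraction(self, length: RepeatLength) -> float:
        return self.spectrum.get(length, 0) / self.total_calls if self.total_calls else 0.0

    def lengths_with_label(self, label: str) -> list[RepeatLength]:
        return sorted(l for l, c in self.class_labels.items() if c == label)


def tabulate(locus: str, calls: Iterable[RepeatCall]) -> LocusProfile:
    """Build the (unclassified) spectrum for one locus's calls.

    Zero calls yield an empty profile flagged ``empty``; it is skipped by
    classification and produces a dropout-suspect genotype downstream.
    Percentages are kept at full precision here and rounded only in reports.
    """
    spectrum: Counter[RepeatLength] = Counter()
    seqs: dict[RepeatLength, Counter[str]] = {}
    for call in calls:
        spectrum[call.repeat_length] += 1
        seqs.setdefault(call.repeat_length, Counter())[call.span_sequence] += 1
    total = sum(spectrum.values())
    if total == 0:
        return LocusProfile(locus, 0, {}, {}, flags=["empty"])
    ordered = sorted(spectrum)
    return LocusProfile(
        locus=locus,
        total_calls=total,
        spectrum={l: spectrum[l] for l in ordered},
        percentages={l: 100.0 * spectrum[l] / total for l in ordered},
        top_sequences={l: seqs[l].most_common(1)[0] for l in ordered},
    )


def classify(
    profile: LocusProfile, *, allele_min_frac: float = DEFAULT_ALLELE_MIN_FRAC
) -> LocusProfile:
    """Label every spectrum length as allele, stutter, or noise.

    Lengths at or above ``allele_min_frac`` of locus reads are alleles,
    whether or not they carry a partial repeat (microvariant alleles are
    real).  Below the threshold, complete-repeat lengths are stutter and
    partial-repeat lengths are noise.  A profile in which nothing reaches
    the threshold is flagged ``no allele``.
    """
    if profile.is_empty:
        return profile
    labels: dict[RepeatLength, str] = {}
    for length, count in profile.spectrum.items():
        frac = count / profile.total_calls
        if frac >= allele_min_frac:
            labels[length] = ALLELE
        elif length.is_partial:
            labels[length] = NOISE
        else:
            labels[length] = STUTTER
    flags = list(profile.flags)
    if ALLELE not in labels.values():
        flags.append("no allele")
    return LocusProfile(
        locus=profile.locus,
        total_calls=profile.total_calls,
        spectrum=profile.spectrum,
        percentages=profile.percentages,
        class_labels=labels,
        top_sequences=profile.top_sequences,
        flags=flags,
    )


@dataclass
class GenotypeCall:
    """Called alleles at one locus with fractions and copy-state estimate."""

    locus: str
    alleles: list[tuple[RepeatLength, float]]
    copy_ratio: Optional[tuple[int, int]] = None
    flags: list[str] = field(default_factory=list)

    @property
    def allele_set(self) -> frozenset[RepeatLength]:
        return frozenset(length for length, _ in self.alleles)


def _nearest_copy_ratio(count_ratio: float) -> Optional[tuple[int, int]]:
    best = min(COPY_RATIO_CANDIDATES, key=lambda ab: abs(count_ratio - ab[0] / ab[1]))
    if abs(count_ratio - best[0] / best[1]) <= COPY_RATIO_TOLERANCE:
        return best
    return None


def call_genotype(
    profile: LocusProfile, *, min_reads: int = DEFAULT_MIN_READS
) -> GenotypeCall:
    """Call the genotype from a classified locus profile.

    Allele fractions are renormalized over allele reads only.  With two or
    more alleles, the read-count ratio of the top two is snapped to the
    nearest small-integer copy ratio (1:1, 3:2, 2:1 or 3:1) when within
    tolerance; otherwise the ratio is left undetermined and the genotype
    flagged ``imbalance``.
    """
    if profile.is_empty:
        return GenotypeCall(profile.locus, [], flags=["dropout-suspect"])
    allele_lengths = profile.lengths_with_label(ALLELE)
    flags: list[str] = []
    if profile.total_calls < min_reads:
        flags.append("low-coverage")
    if not allele_lengths:
        return GenotypeCall(profile.locus, [], flags=flags + ["no allele"])

    counts = {l: profile.spectrum[l] for l in allele_lengths}
    # descending count; ties broken by ascending repeat length
    ranked = sorted(allele_lengths, key=lambda l: (-counts[l], l))[:MAX_ALLELES]
    allele_total = sum(counts[l] for l in ranked)
    alleles = [(l, counts[l] / allele_total) for l in ranked]

    copy_ratio = None
    if len(ranked) >= 2:
        ratio = counts[ranked[0]] / counts[ranked[1]]
        copy_ratio = _nearest_copy_ratio(ratio)
        if copy_ratio is None:
            flags.append("imbalance")
    return GenotypeCall(profile.locus, alleles, copy_ratio=copy_ratio, flags=flags)


@dataclass
class SampleProfile:
    """Per-locus genotypes for one sample, plus raw profiles and run tally."""

    name: str
    genotypes: dict[str, GenotypeCall]
    profiles: dict[str, LocusProfile] = field(default_factory=dict)
    tally: Optional[RunTally] = None

    def allele_set(self, locus: str) -> frozenset[RepeatLength]:
        call = self.genotypes.get(locus)
        return call.allele_set if call is not None else frozenset()


def build_sample_profile(
    name: str,
    calls_by_locus: dict[str, list[RepeatCall]],
    panel: Panel,
    *,
    allele_min_frac: float = DEFAULT_ALLELE_MIN_FRAC,
    min_reads: int = DEFAULT_MIN_READS,
    tally: Optional[RunTally] = None,
) -> SampleProfile:
    """Tabulate, classify and genotype every panel locus for one sample."""
    genotypes: dict[str, GenotypeCall] = {}
    profiles: dict[str, LocusProfile] = {}
    for spec in panel:
        profile = classify(
            tabulate(spec.name, calls_by_locus.get(spec.name, [])),
            allele_min_frac=allele_min_frac,
        )
        profiles[spec.name] = profile
        genotypes[spec.name] = call_genotype(profile, min_reads=min_reads)
    return SampleProfile(name=name, genotypes=genotypes, profiles=profiles, tally=tally)


@dataclass
class LocusComparison:
    locus: str
    match: bool
    alleles_a: tuple[RepeatLength, ...]
    alleles_b: tuple[RepeatLength, ...]


@dataclass
class ConcordanceReport:
    """Locus-by-locus allele-set agreement between two sample profiles."""

    sample_a: str
    sample_b: str
    comparisons: list[LocusComparison]
    only_in_a: list[str]
    only_in_b: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def matched(self) -> int:
        return sum(c.match for c in self.comparisons)

    @property
    def total(self) -> int:
        return len(self.comparisons)

    def summary(self) -> str:
        return f"matched at {self.matched} of {self.total} loci"


def compare_profiles(a: SampleProfile, b: SampleProfile) -> ConcordanceReport:
    """Compare two profiles locus by locus; a locus matches iff the called
    allele repeat-length sets are identical."""
    shared = sorted(set(a.genotypes) & set(b.genotypes))
    comparisons = [
        LocusComparison(
            locus=locus,
            match=a.allele_set(locus) == b.allele_set(locus),
            alleles_a=tuple(sorted(a.allele_set(locus))),
            alleles_b=tuple(sorted(b.allele_set(locus))),
        )
        for locus in shared
    ]
    report = ConcordanceReport(
        sample_a=a.name,
        sample_b=b.name,
        comparisons=comparisons,
        only_in_a=sorted(set(a.genotypes) - set(b.genotypes)),
        only_in_b=sorted(set(b.genotypes) - set(a.genotypes)),
    )
    if not shared:
        report.warnings.append("no shared loci between profiles")
    return report
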