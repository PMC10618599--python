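"""Synthetic amplicon-read generation with a parameterized stutter/noise model.

The generator emulates deep amplicon sequencing of STR loci: each read is an
amplicon from one contributing genome ("component"), at one locus, carrying
one of that genome's alleles in proportion to its copy number.  Three error
processes can perturb the emitted repeat tract:

* **stutter** — with probability ``stutter_prob`` the whole-repeat count
  shifts; the shift is -1 with ``minus_one_weight`` (stutter is
  predominantly one repeat shorter) and the remaining mass splits evenly
  over +1 and -2;
* **partial-repeat noise** — with probability ``partial_noise_prob`` a
  random 1..repeat_size-1 bp deletion in the tract leaves a partial repeat
  (the source of "n.r" noise calls);
* **substitutions** — per-base errors at ``substitution_rate`` anywhere in
  the read (these do not change the tract length but can destroy an anchor
  and drop the read from calling).

Every run is reproducible from the :class:`SimSpec` seed, and a truth table
records each read's component, locus, true and emitted repeat length, so
caller output can be reconciled read-for-read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .locus_config import LocusSpec, LocusValidationError, make_synthetic_locus
from .repeats import RepeatLength

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class StutterModel:
    """Probabilities of the per-read error processes (see module docstring)."""

    stutter_prob: float = 0.0
    minus_one_weight: float = 0.8
    partial_noise_prob: float = 0.0
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("stutter_prob", "minus_one_weight", "partial_noise_prob", "substitution_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def shift_kernel(self) -> dict[int, float]:
        """Distribution of whole-repeat shifts, including the no-shift mass."""
        s, w = self.stutter_prob, self.minus_one_weight
        side = s * (1.0 - w) / 2.0
        kernel = {0: 1.0 - s, -1: s * w, +1: side, -2: side}
        return {k: v for k, v in kernel.items() if v > 0.0}


#: genotype: locus name -> sequence of (allele repeat length, copy number)
Genotype = dict[str, Sequence[tuple[RepeatLength, int]]]


@dataclass(frozen=True)
class Component:
    """One contributing genome: a genotype and its mixing weight."""

    name: str
    genotype: Genotype
    weight: float = 1.0


@dataclass(frozen=True)
class SimSpec:
    """Full generative description of one synthetic sample."""

    loci: tuple[LocusSpec, ...]
    components: tuple[Component, ...]
    reads_per_locus: int
    stutter: StutterModel = StutterModel()
    read_length: Optional[int] = None  # None = full amplicon
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.loci or not self.components:
            raise ValueError("SimSpec needs at least one locus and one component")
        total_w = sum(c.weight for c in self.components)
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total_w}")
        for comp in self.components:
            for locus in self.loci:
                alleles = comp.genotype.get(locus.name)
                if not alleles:
                    raise ValueError(f"component {comp.name} lacks genotype at {locus.name}")
                if any(copies < 1 for _, copies in alleles):
                    raise ValueError(f"copy numbers must be >= 1 at {locus.name}")


@dataclass(frozen=True)
class AmpliconParts:
    """A locus's reference decomposed for read assembly.

    ``left`` ends with the start anchor, ``right`` begins with the end
    anchor; ``prefix``/``suffix`` are the fixed non-repeat bases inside the
    measured span (their lengths sum to ``bp_modifier``); ``unit`` is the
    repeat unit as spelled in the reference.
    """

    left: str
    prefix: str
    unit: str
    suffix: str
    right: str


def locus_building_blocks(spec: LocusSpec) -> AmpliconParts:
    """Decompose a locus reference into assembly parts for simulation.

    Requires a reference sequence and a declared reference repeat count; the
    repeat tract is located as the unique window of the declared length
    inside the inter-anchor span that spells a tandem run of the repeat
    unit, with the flanking span bases accounting for ``bp_modifier``.
    """
    ref = spec.reference_sequence
    if not ref:
        raise LocusValidationError(f"{spec.name}: simulation needs a reference sequence")
    if spec.reference_repeat_count is None:
        raise LocusValidationError(f"{spec.name}: simulation needs a reference repeat count")
    i = ref.index(spec.start_anchor)
    j = ref.index(spec.end_anchor)
    span_start = i + len(spec.start_anchor)
    span = ref[span_start:j]
    tract_bp = spec.reference_repeat_count.total_bp(spec.repeat_size)
    if len(span) - tract_bp != spec.bp_modifier:
        raise LocusValidationError(
            f"{spec.name}: span length {len(span)} inconsistent with "
            f"tract {tract_bp} bp + bp_modifier {spec.bp_modifier}"
        )
    if tract_bp < spec.repeat_size:
        raise LocusValidationError(
            f"{spec.name}: reference tract shorter than one repeat unit"
        )
    n_units, rem = divmod(tract_bp, spec.repeat_size)
    for offset in range(len(span) - tract_bp + 1):
        window = span[offset : offset + tract_bp]
        unit = window[: spec.repeat_size]
        if window == unit * n_units + unit[:rem]:
            return AmpliconParts(
                left=ref[: span_start],
                prefix=span[:offset],
                unit=unit,
                suffix=span[offset + tract_bp :],
                right=ref[j:],
            )
    raise LocusValidationError(f"{spec.name}: no tandem repeat tract found in span")


def make_locus(
    name: str,
    motif: str,
    flank_length: int = 60,
    seed: int = 0,
    *,
    reference_repeat_count: Union[int, str, RepeatLength] = 12,
    **kwargs,
) -> LocusSpec:
    """Generate a synthetic locus (flanks, anchors, reference) for simulation.

    Deterministic in ``seed``; the result always passes locus validation and
    its flanks are free of tandem runs of the motif.
    """
    return make_synthetic_locus(
        name,
        motif,
        reference_repeat_count,
        flank_length=flank_length,
        seed=seed,
        **kwargs,
    )


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    component: str
    locus: str
    true_length: RepeatLength
    emitted_length: RepeatLength
    event: str  # clean | stutter | partial | stutter+partial


def _mutate(seq: str, rng: np.random.Generator, n_subs: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    positions = rng.integers(0, len(arr), size=n_subs)
    for pos in positions:
        current = arr[pos]
        choices = _BASES[_BASES != current]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(spec: SimSpec) -> list[SimRead]:
    """Draw all reads for a :class:`SimSpec` (deterministic in its seed)."""
    rng = np.random.default_rng(spec.seed)
    n_loci = len(spec.loci)
    n = spec.reads_per_locus * n_loci
    parts = [locus_building_blocks(locus) for locus in spec.loci]

    weights = np.array([c.weight for c in spec.components])
    comp_idx = rng.choice(len(spec.components), size=n, p=weights)
    locus_idx = rng.integers(0, n_loci, size=n)
    allele_u = rng.random(n)

    # per (component, locus): allele lengths and cumulative copy fractions
    allele_tables: dict[tuple[int, int], tuple[list[RepeatLength], np.ndarray]] = {}
    for ci, comp in enumerate(spec.components):
        for li, locus in enumerate(spec.loci):
            alleles = list(comp.genotype[locus.name])
            lengths = [RepeatLength.coerce(a) for a, _ in alleles]
            copies = np.array([c for _, c in alleles], dtype=float)
            allele_tables[(ci, li)] = (lengths, np.cumsum(copies / copies.sum()))

    model = spec.stutter
    stutter_hit = rng.random(n) < model.stutter_prob
    stutter_u = rng.random(n)
    partial_hit = rng.random(n) < model.partial_noise_prob
    partial_u = rng.random(n)
    w = model.minus_one_weight

    reads: list[SimRead] = []
    for k in range(n):
        ci, li = int(comp_idx[k]), int(locus_idx[k])
        locus = spec.loci[li]
        lengths, cum = allele_tables[(ci, li)]
        true_len = lengths[int(np.searchsorted(cum, allele_u[k], side="right"))]

        emitted = true_len
        event = "clean"
        if stutter_hit[k]:
            u = stutter_u[k]
            if u < w:
                shift = -1
            elif u < w + (1.0 - w) / 2.0:
                shift = +1
            else:
                shift = -2
            if emitted.whole + shift >= 0:
                emitted = emitted.shifted(shift)
                event = "stutter"
        if partial_hit[k]:
            cut = 1 + int(partial_u[k] * (locus.repeat_size - 1))
            bp = emitted.total_bp(locus.repeat_size) - cut
            if bp >= 0:
                emitted = RepeatLength.from_bp(bp, locus.repeat_size)
                event = "partial" if event == "clean" else "stutter+partial"

        p = parts[li]
        tract = p.unit * emitted.whole + p.unit[: emitted.remainder]
        seq = p.left + p.prefix + tract + p.suffix + p.right
        if model.substitution_rate > 0.0:
            n_subs = rng.binomial(len(seq), model.substitution_rate)
            if n_subs:
                seq = _mutate(seq, rng, n_subs)
        if spec.read_length is not None:
            seq = seq[: spec.read_length]
        reads.append(
            SimRead(
                read_id=f"sim:{k}:{spec.components[ci].name}:{locus.name}",
                sequence=seq,
                component=spec.components[ci].name,
                locus=locus.name,
                true_length=true_len,
                emitted_length=emitted,
                event=event,
            )
        )
    return reads


def write_fastq(reads: Sequence[SimRead], path: Union[str, Path]) -> None:
    """Write reads as 4-line FASTQ (gzipped when the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read in reads:
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def write_truth(reads: Sequence[SimRead], path: Union[str, Path]) -> None:
    """Write the per-read truth table as comma-separated text."""
    with open(path, "wt") as out:
        out.write("read_id,component,locus,true_length,emitted_length,event\n")
        for read in reads:
            out.write(
                f"{read.read_id},{read.component},{read.locus},"
                f"{read.true_length},{read.emitted_length},{read.event}\n"
            )


def simulate_sample(
    spec: SimSpec,
    fastq_path: Union[str, Path],
    truth_path: Optional[Union[str, Path]] = None,
) -> list[SimRead]:
    """Simulate a sample to disk: FASTQ reads plus an optional truth table."""
    reads = simulate_reads(spec)
    write_fastq(reads, fastq_path)
    if truth_path is not None:
        write_truth(reads, truth_path)
    return reads


def expected_spectrum(spec: SimSpec, locus_name: str) -> dict[RepeatLength, float]:
    """Analytic distribution of emitted repeat lengths at one locus.

    Mixes component weights and copy fractions, then convolves the stutter
    shift kernel and the partial-deletion kernel, mirroring the generative
    order (and boundary clamping) of :func:`simulate_reads`.  Substitutions
    do not move tract-length mass and are ignored.  Fractions sum to 1.
    """
    locus = next(l for l in spec.loci if l.name == locus_name)
    rs = locus.repeat_size
    mass: dict[RepeatLength, float] = {}
    for comp in spec.components:
        alleles = [(RepeatLength.coerce(a), c) for a, c in comp.genotype[locus.name]]
        total_copies = sum(c for _, c in alleles)
        for allele, copies in alleles:
            mass[allele] = mass.get(allele, 0.0) + comp.weight * copies / total_copies

    kernel = spec.stutter.shift_kernel()
    shifted: dict[RepeatLength, float] = {}
    for length, p in mass.items():
        for shift, q in kernel.items():
            target = length if length.whole + shift < 0 else length.shifted(shift)
            shifted[target] = shifted.get(target, 0.0) + p * q

    pnp = spec.stutter.partial_noise_prob
    if pnp == 0.0 or rs < 2:
        return dict(sorted(shifted.items()))
    final: dict[RepeatLength, float] = {}
    per_cut = pnp / (rs - 1)
    for length, p in shifted.items():
        final[length] = final.get(length, 0.0) + p * (1.0 - pnp)
        for cut in range(1, rs):
            bp = length.total_bp(rs) - cut
            target = RepeatLength.from_bp(bp, rs) if bp >= 0 else length
            final[target] = final.get(target, 0.0) + p * per_cut
    return dict(sorted(final.items()))


# ---------------------------------------------------------------------------
# Scenario helpers


def two_component_mixture(
    locus: LocusSpec,
    major_alleles: Sequence[Union[int, str, RepeatLength]],
    minor_alleles: Sequence[Union[int, str, RepeatLength]],
    dilution: float,
    reads_per_locus: int,
    stutter: StutterModel,
    seed: int,
) -> SimSpec:
    """A major/minor two-genome mixture at one locus.

    ``dilution`` is the x in a minor:major ratio of 1:x — the minor genome
    contributes ``1/(1+x)`` of templates.  Both genomes are diploid
    heterozygotes (one copy of each listed allele).
    """
    minor_w = 1.0 / (1.0 + dilution)
    components = (
        Component(
            "major",
            {locus.name: [(RepeatLength.coerce(a), 1) for a in major_alleles]},
            weight=1.0 - minor_w,
        ),
        Component(
            "minor",
            {locus.name: [(RepeatLength.coerce(a), 1) for a in minor_alleles]},
            weight=minor_w,
        ),
    )
    return SimSpec(
        loci=(locus,),
        components=components,
        reads_per_locus=reads_per_locus,
        stutter=stutter,
        seed=seed,
    )


def single_sample(
    loci: Sequence[LocusSpec],
    genotype: Genotype,
    reads_per_locus: int,
    stutter: StutterModel = StutterModel(),
    seed: int = 0,
) -> SimSpec:
    """A one-genome sample over the given loci."""
    return SimSpec(
        loci=tuple(loci),
        components=(Component("sample", genotype, weight=1.0),),
        reads_per_locus=reads_per_locus,
        stutter=stutter,
        seed=seed,
    )
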