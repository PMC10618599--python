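"""Per-read repeat-length calling by exact anchor matching.

Each read is searched (in both orientations) for a locus's start and end
anchor sequences.  When both are found exactly once, in order, the span
between them is measured in base pairs, the locus's ``bp_modifier`` is
subtracted, the optional SNP rule is applied, and the corrected distance
is divided by the repeat unit size to give a :class:`RepeatLength` —
including a remainder for partial repeats (e.g. a corrected distance of
46 at a 4-bp motif calls as 11.2).

Anchor matching is exact by default, matching the behaviour of distance-
based STR callers; an opt-in single-mismatch mode exists for degraded
anchors but changes stutter/noise statistics and is off by default.
"""

from __future__ import annotations

import enum
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .locus_config import LocusSpec, Panel
from .repeats import RepeatLength, reverse_complement

FORWARD = "forward"
REVERSE = "reverse-complement"


class ScanFailure(enum.Enum):
    """Why a read produced no call at a locus."""

    NO_CALL = "no-call"              # at least one anchor absent
    AMBIGUOUS_ANCHORS = "ambiguous"  # an anchor occurs more than once
    MALFORMED = "malformed"          # corrected distance negative

    def __bool__(self) -> bool:  # failures are falsy; RepeatCall is truthy
        return False


@dataclass(frozen=True)
class RepeatCall:
    """One read's repeat-length measurement at one locus."""

    locus: str
    repeat_length: RepeatLength
    span_sequence: str
    orientation: str
    snp_applied: bool = False


def _locate_once(seq: str, anchor: str, mismatches: int) -> Union[int, None, ScanFailure]:
    """Position of the unique occurrence of anchor, None if absent."""
    if mismatches == 0:
        i = seq.find(anchor)
        if i < 0:
            return None
        if seq.find(anchor, i + 1) >= 0:
            return ScanFailure.AMBIGUOUS_ANCHORS
        return i
    # Tolerant mode: Hamming distance <= mismatches at each offset.
    hits = []
    m = len(anchor)
    for off in range(len(seq) - m + 1):
        window = seq[off : off + m]
        if sum(a != b for a, b in zip(window, anchor)) <= mismatches:
            hits.append(off)
            if len(hits) > 1:
                return ScanFailure.AMBIGUOUS_ANCHORS
    return hits[0] if hits else None


def _scan_oriented(
    seq: str, spec: LocusSpec, orientation: str, mismatches: int
) -> Union[RepeatCall, ScanFailure, None]:
    start = _locate_once(seq, spec.start_anchor, mismatches)
    if isinstance(start, ScanFailure):
        return start
    end = _locate_once(seq, spec.end_anchor, mismatches)
    if isinstance(end, ScanFailure):
        return end
    if start is None or end is None:
        return None  # anchor absent in this orientation
    span_start = start + len(spec.start_anchor)
    if end < span_start:
        return None  # anchors out of order: not a consistent hit
    corrected = (end - span_start) - spec.bp_modifier
    snp_applied = False
    increment = 0
    if spec.snp_rule is not None and spec.snp_rule.trigger_sequence in seq:
        increment = spec.snp_rule.increment
        snp_applied = True
    if corrected < 0:
        return ScanFailure.MALFORMED
    length = RepeatLength.from_bp(corrected, spec.repeat_size)
    if length.whole + increment < 0:
        return ScanFailure.MALFORMED
    if increment:
        length = length.shifted(increment)
    return RepeatCall(
        locus=spec.name,
        repeat_length=length,
        span_sequence=seq[span_start:end],
        orientation=orientation,
        snp_applied=snp_applied,
    )


def scan_read(
    read_sequence: str, spec: LocusSpec, *, max_mismatches: int = 0
) -> Union[RepeatCall, ScanFailure]:
    """Call the repeat length of one read at one locus.

    Returns a :class:`RepeatCall`, or a :class:`ScanFailure` distinguishing
    a plain no-call (anchor absent) from a discarded read (duplicated
    anchors, or a corrected distance below zero).  The read and its reverse
    complement are both tried; the SNP trigger is searched in whichever
    orientation the anchors matched.
    """
    read_sequence = read_sequence.upper()
    result = _scan_oriented(read_sequence, spec, FORWARD, max_mismatches)
    if result is not None:
        return result
    result = _scan_oriented(
        reverse_complement(read_sequence), spec, REVERSE, max_mismatches
    )
    if result is not None:
        return result
    return ScanFailure.NO_CALL


UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"
MALFORMED = "malformed"
ASSIGNED = "assigned"


@dataclass(frozen=True)
class Assignment:
    status: str
    call: Optional[RepeatCall] = None


def assign_read(
    read_sequence: str, panel: Panel, *, max_mismatches: int = 0
) -> Assignment:
    """Assign a (possibly multiplexed) read to the unique locus it calls at.

    Exactly one locus calling -> assigned; none -> unassigned; several ->
    ambiguous.  A read discarded at some locus (duplicated anchors or a
    negative corrected span) with no clean call elsewhere is counted under
    that discard class rather than as a silent no-call.
    """
    calls: list[RepeatCall] = []
    saw_ambiguous = False
    saw_malformed = False
    for spec in panel:
        result = scan_read(read_sequence, spec, max_mismatches=max_mismatches)
        if isinstance(result, RepeatCall):
            calls.append(result)
        elif result is ScanFailure.AMBIGUOUS_ANCHORS:
            saw_ambiguous = True
        elif result is ScanFailure.MALFORMED:
            saw_malformed = True
    if len(calls) == 1:
        return Assignment(ASSIGNED, calls[0])
    if len(calls) > 1 or saw_ambiguous:
        return Assignment(AMBIGUOUS)
    if saw_malformed:
        return Assignment(MALFORMED)
    return Assignment(UNASSIGNED)


@dataclass
class RunTally:
    """Per-run read accounting; classes partition the input records."""

    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    malformed: int = 0

    def add(self, status: str) -> None:
        self.total += 1
        setattr(self, status, getattr(self, status) + 1)


@dataclass
class RunResult:
    calls_by_locus: dict[str, list[RepeatCall]]
    tally: RunTally


def process_records(
    sequences: Iterable[str], panel: Panel, *, max_mismatches: int = 0
) -> RunResult:
    """Assign an iterable of read sequences against a panel and tally them."""
    calls_by_locus: dict[str, list[RepeatCall]] = {spec.name: [] for spec in panel}
    tally = RunTally()
    for seq in sequences:
        assignment = assign_read(seq, panel, max_mismatches=max_mismatches)
        tally.add(assignment.status)
        if assignment.call is not None:
            calls_by_locus[assignment.call.locus].append(assignment.call)
    return RunResult(calls_by_locus=calls_by_locus, tally=tally)


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(
    paths: Union[str, Path, Sequence[Union[str, Path]]],
    *,
    min_mean_quality: Optional[float] = None,
) -> Iterator[str]:
    """Yield read sequences from FASTQ / FASTQ.gz files.

    Paired files are simply concatenated: mates are scanned independently.
    ``min_mean_quality`` optionally drops reads below a mean Phred score
    (off by default; calling itself never uses base qualities).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    for path in paths:
        index = 0
        try:
            with _open_text(path) as handle:
                for _title, seq, qual in FastqGeneralIterator(handle):
                    index += 1
                    if min_mean_quality is not None and qual:
                        mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
                        if mean_q < min_mean_quality:
                            continue
                    yield seq
        except (OSError, ValueError) as exc:
            raise IOError(
                f"error reading FASTQ {path!s} near record {index + 1}: {exc}"
            ) from exc


def process_reads(
    fastq_sources,
    panel: Panel,
    *,
    max_mismatches: int = 0,
    min_mean_quality: Optional[float] = None,
) -> RunResult:
    """Scan FASTQ file(s) against a panel; see :func:`process_records`."""
    reads = iter_fastq(fastq_sources, min_mean_quality=min_mean_quality)
    return process_records(reads, panel, max_mismatches=max_mismatches)
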