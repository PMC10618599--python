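"""STR locus definitions: the nine-column table, validation, bundled panels.

A locus is called from reads by locating two short *anchor* sequences that
flank the repeat tract and measuring the distance between them.  Because
anchors are often placed a few bases away from the tract (to dodge known
SNPs) or because the tract contains fixed interrupting bases, a per-locus
``bp_modifier`` is subtracted from the raw inter-anchor distance before
dividing by the repeat unit size.  A locus may additionally carry a SNP
rule: when a specific variant creates an extra repeat unit at the tract
boundary without changing the inter-anchor distance, finding the variant's
trigger sequence in a read adds a fixed number of repeats to the call.

The on-disk format is a comma-separated table with nine columns:

    name, reference sequence, start target, end target, repeat size,
    bp_modifier, reference repeat count, SNP_modifier, notes

``SNP_modifier`` is encoded as ``TRIGGER:+n`` (e.g. ``TATCAATCATC:+1``);
an empty field means the locus has no SNP rule.  Lines starting with
``#`` are ignored.
"""

from __future__ import annotations

import csv
import functools
import io
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from .repeats import RepeatLength

_DNA = re.compile(r"^[ACGT]+$")

HEADER = (
    "name",
    "reference_sequence",
    "start_target",
    "end_target",
    "repeat_size",
    "bp_modifier",
    "reference_repeat_count",
    "SNP_modifier",
    "notes",
)


class LocusTableError(ValueError):
    """Malformed locus table (wrong shape, unparseable fields)."""


class LocusValidationError(ValueError):
    """A locus definition that violates the calling model's assumptions."""


@dataclass(frozen=True)
class SnpRule:
    """Add ``increment`` repeats when ``trigger_sequence`` occurs in a read."""

    trigger_sequence: str
    increment: int

    def __post_init__(self) -> None:
        if not self.trigger_sequence or not _DNA.match(self.trigger_sequence):
            raise LocusValidationError(
                f"SNP trigger must be a non-empty A/C/G/T string, got {self.trigger_sequence!r}"
            )
        if self.increment == 0:
            raise LocusValidationError("SNP increment must be non-zero")

    def encode(self) -> str:
        return f"{self.trigger_sequence}:{self.increment:+d}"

    @classmethod
    def decode(cls, text: str) -> Optional["SnpRule"]:
        text = text.strip()
        if not text:
            return None
        trigger, sep, inc = text.partition(":")
        if not sep:
            raise LocusTableError(f"SNP_modifier must be 'TRIGGER:+n', got {text!r}")
        try:
            increment = int(inc)
        except ValueError as exc:
            raise LocusTableError(f"SNP_modifier increment not an integer: {text!r}") from exc
        return cls(trigger.strip().upper(), increment)


_CATEGORY_RE = re.compile(r"categories=([0-9]+:[A-Za-z]+(?:,[0-9]+:[A-Za-z]+)*)")


@dataclass(frozen=True)
class LocusSpec:
    """Calling parameters for one STR locus (one row of the nine-column table).

    ``reference_sequence`` may be empty when no reference is available; all
    reference-dependent checks are then skipped.  ``notes`` may embed a
    category map (``categories=0:X,1:Y``) used by sex loci such as
    Amelogenin, where the "repeat count" is really an amplicon-length class.
    """

    name: str
    reference_sequence: str
    start_anchor: str
    end_anchor: str
    repeat_size: int
    bp_modifier: int
    reference_repeat_count: Optional[RepeatLength] = None
    snp_rule: Optional[SnpRule] = None
    notes: str = ""
    panel: str = "custom"

    def __post_init__(self) -> None:
        if not self.name:
            raise LocusValidationError("locus name must be non-empty")
        if not (2 <= self.repeat_size <= 6):
            raise LocusValidationError(
                f"{self.name}: repeat size must be in [2, 6], got {self.repeat_size}"
            )
        if self.bp_modifier < 0:
            raise LocusValidationError(f"{self.name}: bp_modifier must be >= 0")
        for label, anchor in (("start", self.start_anchor), ("end", self.end_anchor)):
            if not anchor or not _DNA.match(anchor):
                raise LocusValidationError(
                    f"{self.name}: {label} anchor must be a non-empty A/C/G/T string"
                )
        if self.start_anchor == self.end_anchor:
            raise LocusValidationError(f"{self.name}: start and end anchors must differ")
        if self.reference_sequence and not _DNA.match(self.reference_sequence):
            raise LocusValidationError(f"{self.name}: reference sequence must be A/C/G/T")
        if self.reference_repeat_count is not None and (
            self.reference_repeat_count.remainder >= self.repeat_size
        ):
            raise LocusValidationError(
                f"{self.name}: reference repeat remainder must be < repeat size"
            )

    @property
    def categories(self) -> Optional[dict[int, str]]:
        """Optional map from whole-repeat count to a category label (e.g. X/Y)."""
        m = _CATEGORY_RE.search(self.notes)
        if not m:
            return None
        return {
            int(k): v
            for k, v in (pair.split(":") for pair in m.group(1).split(","))
        }

    def display_length(self, length: RepeatLength) -> str:
        """Render a repeat length, mapping through the category table if any."""
        cats = self.categories
        if cats is not None and not length.is_partial and length.whole in cats:
            return cats[length.whole]
        return str(length)

    def to_row(self) -> list[str]:
        return [
            self.name,
            self.reference_sequence,
            self.start_anchor,
            self.end_anchor,
            str(self.repeat_size),
            str(self.bp_modifier),
            "" if self.reference_repeat_count is None else str(self.reference_repeat_count),
            "" if self.snp_rule is None else self.snp_rule.encode(),
            self.notes,
        ]


@dataclass(frozen=True)
class Panel:
    """An ordered collection of loci typed together (one species' panel)."""

    species: str
    loci: tuple[LocusSpec, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [locus.name for locus in self.loci]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LocusValidationError(f"duplicate locus names in panel: {sorted(dupes)}")

    def __iter__(self) -> Iterator[LocusSpec]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, name: str) -> LocusSpec:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [locus.name for locus in self.loci]


@dataclass
class ValidationReport:
    """Outcome of checking one locus against its own reference sequence."""

    locus: str
    ok: bool
    computed_repeat_count: Optional[RepeatLength] = None
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def validate_locus(spec: LocusSpec) -> ValidationReport:
    """QC a locus definition against its bundled reference sequence.

    Each anchor must occur exactly once in the reference; the inter-anchor
    distance, corrected by ``bp_modifier`` (and the SNP rule if its trigger
    is present in the reference), must reproduce ``reference_repeat_count``.
    A count mismatch is a warning, not an error — it is the QC signal for a
    newly added locus whose table entries disagree with its reference.
    """
    report = ValidationReport(locus=spec.name, ok=True)
    ref = spec.reference_sequence
    if not ref:
        report.warnings.append("no reference sequence; QC check skipped")
        return report

    positions = {}
    for label, anchor in (("start", spec.start_anchor), ("end", spec.end_anchor)):
        n = ref.count(anchor)
        if n == 0:
            report.errors.append(f"{label} anchor not found in reference")
        elif n > 1:
            report.errors.append(f"{label} anchor occurs {n} times in reference")
        else:
            positions[label] = ref.index(anchor)
    if report.errors:
        report.ok = False
        return report

    span_start = positions["start"] + len(spec.start_anchor)
    span_end = positions["end"]
    if span_end < span_start:
        report.errors.append("end anchor precedes start anchor in reference")
        report.ok = False
        return report

    corrected = (span_end - span_start) - spec.bp_modifier
    if corrected < 0:
        report.errors.append(
            f"bp_modifier {spec.bp_modifier} exceeds inter-anchor distance "
            f"{span_end - span_start}"
        )
        report.ok = False
        return report

    computed = RepeatLength.from_bp(corrected, spec.repeat_size)
    if spec.snp_rule is not None and spec.snp_rule.trigger_sequence in ref:
        computed = computed.shifted(spec.snp_rule.increment)
    report.computed_repeat_count = computed
    if spec.reference_repeat_count is not None and computed != spec.reference_repeat_count:
        report.warnings.append(
            f"computed {computed} != declared {spec.reference_repeat_count}"
        )
    return report


# ---------------------------------------------------------------------------
# Nine-column table I/O


def _iter_rows(source) -> Iterator[tuple[int, list[str]]]:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle = open(source, newline="", encoding="utf-8")
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source
        close = False
    try:
        for lineno, row in enumerate(csv.reader(handle), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            yield lineno, row
    finally:
        if close:
            handle.close()


def parse_locus_table(source, *, species: str = "custom") -> Panel:
    """Parse a nine-column locus table into a validated :class:`Panel`.

    ``source`` may be a path, a file-like object, or the table text itself.
    The first non-comment row is treated as the header.
    """
    rows = _iter_rows(source)
    loci: list[LocusSpec] = []
    header_seen = False
    for lineno, row in rows:
        if not header_seen:
            header_seen = True  # header row; column names are not interpreted
            if len(row) != len(HEADER):
                raise LocusTableError(
                    f"row {lineno}: expected {len(HEADER)} columns in header, got {len(row)}"
                )
            continue
        if len(row) != len(HEADER):
            raise LocusTableError(
                f"row {lineno}: expected {len(HEADER)} columns, got {len(row)}"
            )
        (name, ref, start, end, size_s, bp_mod_s, ref_count_s, snp_s, notes) = (
            f.strip() for f in row
        )
        try:
            repeat_size = int(size_s)
            bp_modifier = int(bp_mod_s)
        except ValueError as exc:
            raise LocusTableError(
                f"row {lineno} ({name}): repeat size and bp_modifier must be integers"
            ) from exc
        try:
            ref_count = RepeatLength.parse(ref_count_s) if ref_count_s else None
        except ValueError as exc:
            raise LocusTableError(
                f"row {lineno} ({name}): bad reference repeat count {ref_count_s!r}"
            ) from exc
        try:
            loci.append(
                LocusSpec(
                    name=name,
                    reference_sequence=ref.upper(),
                    start_anchor=start.upper(),
                    end_anchor=end.upper(),
                    repeat_size=repeat_size,
                    bp_modifier=bp_modifier,
                    reference_repeat_count=ref_count,
                    snp_rule=SnpRule.decode(snp_s),
                    notes=notes,
                    panel=species,
                )
            )
        except LocusValidationError as exc:
            raise LocusTableError(f"row {lineno}: {exc}") from exc
    if not loci:
        raise LocusTableError("no locus rows")
    return Panel(species=species, loci=tuple(loci))


def panel_to_table(panel: Panel) -> str:
    """Serialize a panel back to the nine-column comma-separated format."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(HEADER)
    for locus in panel:
        writer.writerow(locus.to_row())
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Synthetic locus construction (shared with the read simulator)

_ANCHOR_LEN = 20


def _random_flank(rng: random.Random, length: int, motif: str) -> str:
    """A random flank that never contains the motif as a tandem run."""
    tandem = motif * 2
    for _ in range(1000):
        flank = "".join(rng.choice("ACGT") for _ in range(length))
        if tandem not in flank and motif * 1 != flank:
            return flank
    raise RuntimeError("could not draw a motif-free flank")  # pragma: no cover


def make_synthetic_locus(
    name: str,
    motif: str,
    reference_repeat_count,
    *,
    flank_length: int = 60,
    anchor_length: int = _ANCHOR_LEN,
    modifier_prefix: int = 0,
    span_suffix: str = "",
    snp_rule: Optional[SnpRule] = None,
    seed: int = 0,
    panel: str = "custom",
    notes: str = "",
) -> LocusSpec:
    """Build a locus with a synthetic reference sequence and placeholder anchors.

    The reference is laid out as::

        left flank | modifier prefix | repeat tract | span suffix | right flank

    with the start anchor being the last ``anchor_length`` bases of the left
    flank and the end anchor the first ``anchor_length`` bases of the right
    flank.  ``bp_modifier`` is therefore ``modifier_prefix + len(span_suffix)``
    — the non-repeat bases inside the measured span (``span_suffix`` models
    fixed termination sequence between the tract and the end anchor, as at
    D13S317).
    """
    if not (2 <= len(motif) <= 6):
        raise LocusValidationError(f"motif length must be in [2, 6], got {motif!r}")
    if not _DNA.match(motif):
        raise LocusValidationError(f"motif must be A/C/G/T, got {motif!r}")
    if flank_length < anchor_length:
        raise LocusValidationError(
            f"flank length {flank_length} shorter than anchor length {anchor_length}"
        )
    count = RepeatLength.coerce(reference_repeat_count)
    if count.remainder >= len(motif):
        raise LocusValidationError("reference repeat remainder must be < motif length")

    rng = random.Random(seed)
    tract = motif * count.whole + motif[: count.remainder]
    for _ in range(200):
        left = _random_flank(rng, flank_length, motif)
        right = _random_flank(rng, flank_length, motif)
        prefix = "".join(rng.choice("ACGT") for _ in range(modifier_prefix))
        reference = left + prefix + tract + span_suffix + right
        start_anchor = left[-anchor_length:]
        end_anchor = right[:anchor_length]
        if start_anchor == end_anchor:
            continue
        if reference.count(start_anchor) != 1 or reference.count(end_anchor) != 1:
            continue
        spec = LocusSpec(
            name=name,
            reference_sequence=reference,
            start_anchor=start_anchor,
            end_anchor=end_anchor,
            repeat_size=len(motif),
            bp_modifier=modifier_prefix + len(span_suffix),
            reference_repeat_count=count,
            snp_rule=snp_rule,
            notes=notes,
            panel=panel,
        )
        report = validate_locus(spec)
        if report.ok and not any("!=" in w for w in report.warnings):
            return spec
    raise RuntimeError(f"could not synthesize a consistent locus for {name}")


# ---------------------------------------------------------------------------
# Bundled panels
#
# Locus names and repeat motifs follow the published human (CODIS/ATCC) and
# mouse panels; reference sequences, flanks and anchors are deterministic
# synthetic placeholders for simulation and testing.  Users genotyping real
# data should load a table with primer-derived anchors instead.

_PANEL_NOTE = "synthetic placeholder reference/anchors"

# name, motif, reference repeat count, modifier prefix bases
_HUMAN_CORE = [
    ("CSF1PO", "AGAT", "12", 0),
    ("D13S317", "TATC", "11", 0),      # SNP rule added below
    ("D16S539", "GATA", "11", 0),
    ("D18S51", "AGAA", "18", 0),
    ("D19S433", "AAGG", "14", 2),
    ("D2S1338", "TGCC", "23", 0),
    ("D21S11", "TCTA", "29", 13),      # 13 fixed interrupting bases in the tract region
    ("D3S1358", "TCTA", "16", 0),
    ("D5S818", "AGAT", "11", 0),
    ("D7S820", "GATA", "10", 0),
    ("D8S1179", "TCTA", "13", 0),
    ("FGA", "TTTC", "21", 0),
    ("PentaD", "AAAGA", "10", 0),
    ("PentaE", "AAAGA", "12", 0),
    ("TH01", "AATG", "7", 0),
    ("TPOX", "AATG", "8", 0),
    ("vWA", "TCTA", "17", 0),
]

_MOUSE_LOCI = [
    ("18-3", "AGAT", "17", 0),
    ("4-2", "TAGA", "20", 0),
    ("5-5", "GATA", "14", 0),
    ("6-7", "CTAT", "12", 0),
    ("9-2", "TCTA", "15", 0),
    ("12-1", "GATA", "16", 0),
    ("15-3", "AGAT", "22", 0),
    ("X-1", "GATA", "25", 0),
    ("1-1", "TAGA", "16", 0),
    ("2-1", "AGAT", "15", 0),
    ("3-2", "TCTA", "13", 0),
    ("8-1", "GATA", "16", 0),
    ("11-2", "AGAT", "15", 0),
    ("17-2", "TAGA", "15", 0),
    ("19-2", "GATA", "12", 0),
]

D13S317_SNP_RULE = SnpRule("TATCAATCATC", +1)
_D13S317_TERMINATION = "AATCAATCATC"


def _build_human_panel() -> Panel:
    loci = []
    for i, (name, motif, count, mod) in enumerate(_HUMAN_CORE):
        kwargs = {}
        if name == "D13S317":
            # The tract terminates in a fixed 11-bp sequence inside the span;
            # an A>T variant at its first base creates one extra TATC repeat,
            # detected via the SNP rule rather than the measured distance.
            kwargs = {"span_suffix": _D13S317_TERMINATION, "snp_rule": D13S317_SNP_RULE}
        loci.append(
            make_synthetic_locus(
                name,
                motif,
                count,
                modifier_prefix=mod,
                seed=100 + i,
                panel="human",
                notes=_PANEL_NOTE,
                **kwargs,
            )
        )
    loci.append(_amelogenin(seed=199))
    return Panel(species="human", loci=tuple(loci), provenance=_PANEL_NOTE)


def _amelogenin(seed: int) -> LocusSpec:
    """Sex locus: X and Y amplicons differ by 6 bp, not by a repeat motif.

    Modeled with repeat_size 6 (the X/Y length difference): the X amplicon
    spans 0 extra bases (call 0 -> "X"), the Y amplicon 6 (call 1 -> "Y").
    The bundled reference is the Y form so the 6-bp insert is recoverable.
    """
    return make_synthetic_locus(
        "Amelogenin",
        "AAGTGC",  # placeholder for the Y-specific 6-bp insert
        "1",
        seed=seed,
        panel="human",
        notes=f"{_PANEL_NOTE}; sex locus; categories=0:X,1:Y",
    )


def _build_mouse_panel() -> Panel:
    loci = tuple(
        make_synthetic_locus(
            name,
            motif,
            count,
            modifier_prefix=mod,
            seed=300 + i,
            panel="mouse",
            notes=_PANEL_NOTE,
        )
        for i, (name, motif, count, mod) in enumerate(_MOUSE_LOCI)
    )
    return Panel(species="mouse", loci=loci, provenance=_PANEL_NOTE)


@functools.lru_cache(maxsize=1)
def builtin_panels() -> dict[str, Panel]:
    """The bundled human (18-locus) and mouse (15-locus) panels."""
    return {"human": _build_human_panel(), "mouse": _build_mouse_panel()}
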