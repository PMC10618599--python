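"""Report serialization: locus profiles, genotype tables, concordance, mixtures.

All data files are deterministic for identical inputs (no timestamps);
percentages carry two decimals, read counts are integers, and microvariant
repeat lengths are written in CE nomenclature ("13.2").  JSON documents
carry a ``schema_version`` field; the JSON profile is the lossless form and
can be re-loaded for comparison and mixture analysis.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Optional, Union

from .locus_config import Panel
from .mixture import MixtureResult
from .profiler import (
    ConcordanceReport,
    GenotypeCall,
    LocusProfile,
    SampleProfile,
)
from .repeat_caller import RunTally
from .repeats import RepeatLength

SCHEMA_VERSION = 1


def _display(panel: Optional[Panel], locus: str, length: RepeatLength) -> str:
    if panel is not None and locus in {l.name for l in panel}:
        return panel[locus].display_length(length)
    return str(length)


def profile_csv(sample: SampleProfile, panel: Optional[Panel] = None) -> str:
    """Per-locus spectrum rows: length, count, percent, class, top sequence."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["locus", "repeat_length", "reads", "percent", "class", "top_sequence"])
    for locus, profile in sample.profiles.items():
        for length in profile.spectrum:
            top_seq, _ = profile.top_sequences.get(length, ("", 0))
            writer.writerow(
                [
                    locus,
                    _display(panel, locus, length),
                    profile.spectrum[length],
                    f"{profile.percentages[length]:.2f}",
                    profile.class_labels.get(length, ""),
                    top_seq,
                ]
            )
    return buf.getvalue()


def genotype_csv(sample: SampleProfile, panel: Optional[Panel] = None) -> str:
    """One row per locus: called alleles, fractions, copy ratio, flags."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["locus", "alleles", "fractions", "copy_ratio", "flags"])
    for locus, call in sample.genotypes.items():
        writer.writerow(
            [
                locus,
                "/".join(_display(panel, locus, l) for l, _ in call.alleles),
                "/".join(f"{f:.2f}" for _, f in call.alleles),
                f"{call.copy_ratio[0]}:{call.copy_ratio[1]}" if call.copy_ratio else "",
                ";".join(call.flags),
            ]
        )
    return buf.getvalue()


def _profile_to_dict(profile: LocusProfile) -> dict:
    return {
        "total_calls": profile.total_calls,
        "flags": profile.flags,
        "spectrum": [
            {
                "length": str(length),
                "reads": profile.spectrum[length],
                "percent": round(profile.percentages[length], 2),
                "class": profile.class_labels.get(length),
                "top_sequence": profile.top_sequences.get(length, ("", 0))[0],
            }
            for length in profile.spectrum
        ],
    }


def _genotype_to_dict(call: GenotypeCall, panel: Optional[Panel], locus: str) -> dict:
    return {
        "alleles": [
            {
                "length": str(length),
                "display": _display(panel, locus, length),
                "fraction": fraction,
            }
            for length, fraction in call.alleles
        ],
        "copy_ratio": f"{call.copy_ratio[0]}:{call.copy_ratio[1]}" if call.copy_ratio else None,
        "flags": call.flags,
    }


def profile_json(sample: SampleProfile, panel: Optional[Panel] = None) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "sample": sample.name,
        "tally": vars(sample.tally) if sample.tally is not None else None,
        "loci": {},
    }
    for locus in sample.genotypes:
        entry = {}
        if locus in sample.profiles:
            entry["profile"] = _profile_to_dict(sample.profiles[locus])
        entry["genotype"] = _genotype_to_dict(sample.genotypes[locus], panel, locus)
        doc["loci"][locus] = entry
    return doc


def load_sample_profile(path: Union[str, Path]) -> SampleProfile:
    """Re-load a sample profile from its JSON report (lossless round trip of
    spectra, class labels and genotypes; display strings are derived)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported profile schema: {doc.get('schema_version')!r}")
    genotypes: dict[str, GenotypeCall] = {}
    profiles: dict[str, LocusProfile] = {}
    for locus, entry in doc["loci"].items():
        g = entry["genotype"]
        copy_ratio = None
        if g.get("copy_ratio"):
            a, b = g["copy_ratio"].split(":")
            copy_ratio = (int(a), int(b))
        genotypes[locus] = GenotypeCall(
            locus=locus,
            alleles=[
                (RepeatLength.parse(a["length"]), a["fraction"]) for a in g["alleles"]
            ],
            copy_ratio=copy_ratio,
            flags=list(g.get("flags", [])),
        )
        if "profile" in entry:
            p = entry["profile"]
            spectrum = {
                RepeatLength.parse(row["length"]): row["reads"] for row in p["spectrum"]
            }
            total = p["total_calls"]
            profiles[locus] = LocusProfile(
                locus=locus,
                total_calls=total,
                spectrum=spectrum,
                percentages={
                    l: 100.0 * c / total for l, c in spectrum.items()
                } if total else {},
                class_labels={
                    RepeatLength.parse(row["length"]): row["class"]
                    for row in p["spectrum"]
                    if row.get("class")
                },
                top_sequences={
                    RepeatLength.parse(row["length"]): (row.get("top_sequence", ""), 0)
                    for row in p["spectrum"]
                },
                flags=list(p.get("flags", [])),
            )
    tally = None
    if doc.get("tally"):
        tally = RunTally(**doc["tally"])
    return SampleProfile(doc["sample"], genotypes, profiles=profiles, tally=tally)


def concordance_json(report: ConcordanceReport) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "sample_a": report.sample_a,
        "sample_b": report.sample_b,
        "matched": report.matched,
        "total": report.total,
        "summary": report.summary(),
        "loci": [
            {
                "locus": c.locus,
                "match": c.match,
                "alleles_a": [str(l) for l in c.alleles_a],
                "alleles_b": [str(l) for l in c.alleles_b],
            }
            for c in report.comparisons
        ],
        "only_in_a": report.only_in_a,
        "only_in_b": report.only_in_b,
        "warnings": report.warnings,
    }


def concordance_csv(report: ConcordanceReport) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["locus", "match", "alleles_a", "alleles_b"])
    for c in report.comparisons:
        writer.writerow(
            [
                c.locus,
                "yes" if c.match else "no",
                "/".join(str(l) for l in c.alleles_a),
                "/".join(str(l) for l in c.alleles_b),
            ]
        )
    return buf.getvalue()


def mixture_json(result: MixtureResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "informative_alleles": [
            {
                "locus": o.allele.locus,
                "length": str(o.allele.length),
                "offset_bp": o.allele.offset_bp,
                "stutter_colliding": o.allele.stutter_colliding,
                "dose": o.allele.dose,
                "reads": o.reads,
                "locus_total": o.locus_total,
                "fraction": o.fraction,
            }
            for o in result.observations
        ],
        "pooled_reads": result.pooled_reads,
        "pooled_total": result.pooled_total,
        "pooled_fraction": result.pooled_fraction,
        "minor_fraction_estimate": result.minor_fraction_estimate,
        "confidence_interval": list(result.confidence_interval)
        if result.confidence_interval
        else None,
        "decision": result.decision,
        "rule": vars(result.rule) if result.rule else None,
        "supporting": [
            {"locus": a.locus, "length": str(a.length)} for a in result.supporting
        ],
        "warnings": result.warnings,
    }


def mixture_csv(result: MixtureResult) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["locus", "length", "offset_bp", "stutter_colliding", "reads", "locus_total", "fraction"]
    )
    for o in result.observations:
        writer.writerow(
            [
                o.allele.locus,
                str(o.allele.length),
                o.allele.offset_bp,
                "yes" if o.allele.stutter_colliding else "no",
                o.reads,
                o.locus_total,
                f"{o.fraction:.6f}",
            ]
        )
    return buf.getvalue()
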