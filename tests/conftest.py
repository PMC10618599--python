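import pytest

import strngs
from strngs import simulate
from strngs.repeats import RepeatLength


@pytest.fixture(scope="session")
def panels():
    return strngs.builtin_panels()


@pytest.fixture(scope="session")
def tatc_locus():
    """A clean synthetic TATC-motif tetranucleotide locus."""
    return simulate.make_locus("TATC1", "TATC", seed=7, reference_repeat_count=12)


@pytest.fixture(scope="session")
def six_locus_panel(panels):
    """A six-locus human sub-panel, as in a multiplexed PCR pool."""
    human = panels["human"]
    names = ["CSF1PO", "D5S818", "D7S820", "D8S1179", "TH01", "vWA"]
    return strngs.Panel(species="human6", loci=tuple(human[n] for n in names))


def clean_read(spec, length, orientation="forward"):
    """Assemble an error-free amplicon read carrying a given repeat length."""
    parts = simulate.locus_building_blocks(spec)
    length = RepeatLength.coerce(length)
    tract = parts.unit * length.whole + parts.unit[: length.remainder]
    seq = parts.left + parts.prefix + tract + parts.suffix + parts.right
    if orientation == "reverse-complement":
        seq = strngs.reverse_complement(seq)
    return seq
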