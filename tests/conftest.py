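import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from abequant.loci import AmpliconLocus, ReadRecord


def make_reference(spacer: str, pam: str = "TGG", left: int = 40, right: int = 40, seed: int = 11) -> tuple[str, int]:
    """Random flanks around spacer+PAM; returns (reference, spacer_start)."""
    rng = np.random.default_rng(seed)
    lflank = "".join(rng.choice(list("ACGT"), left))
    rflank = "".join(rng.choice(list("ACGT"), right))
    return lflank + spacer + pam + rflank, left


@pytest.fixture
def toy_locus() -> AmpliconLocus:
    """Spacer with adenines at protospacer positions 4, 5, 6, 9, 12; desired edit A5."""
    spacer = "GCTAAATCATCAGTCGCTGC"
    ref, start = make_reference(spacer)
    return AmpliconLocus("toy", ref, spacer, start, "TGG", frozenset({(5, "A", "G")}))


@pytest.fixture
def two_target_locus() -> AmpliconLocus:
    """Two desired adenines (positions 5 and 6), the multi-adenine-codon situation."""
    spacer = "GCTAAATCATCAGTCGCTGC"
    ref, start = make_reference(spacer, seed=12)
    return AmpliconLocus("twot", ref, spacer, start, "TGG", frozenset({(5, "A", "G"), (6, "A", "G")}))


def perfect_read(locus: AmpliconLocus, edits: dict[int, str] | None = None, q: int = 38, trim: int = 0) -> ReadRecord:
    """A full-reference read carrying the given {ref_pos: base} substitutions."""
    seq = list(locus.reference)
    for rp, b in (edits or {}).items():
        seq[rp] = b
    s = "".join(seq)
    if trim:
        s = s[trim:-trim]
    return ReadRecord("r", s, [q] * len(s))


def read_with_deletion(locus: AmpliconLocus, start: int, length: int, q: int = 38) -> ReadRecord:
    seq = locus.reference[:start] + locus.reference[start + length :]
    return ReadRecord("rdel", seq, [q] * len(seq))


def read_with_insertion(locus: AmpliconLocus, pos: int, ins: str, q: int = 38) -> ReadRecord:
    seq = locus.reference[:pos] + ins + locus.reference[pos:]
    return ReadRecord("rins", seq, [q] * len(seq))
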