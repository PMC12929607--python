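"""sgRNA spacer enumeration, PAM classification and codon-consequence annotation.

Candidate 20-nt spacers are enumerated so that the adenines required for a
desired amino-acid change fall inside the deaminase design window
(protospacer positions 3–11 by default), on either strand of the coding
context: an A-to-G edit on the antisense strand is a T-to-C change on the
coding strand.  PAMs are classed as NGG (canonical SpCas9), NRN or NYN
(PAM-relaxed nickases, by the middle base being a purine or pyrimidine).
Codon consequences are translated with the standard genetic code; the
canonical pitfall this catches is a multi-adenine codon where editing only
one adenine yields a different missense change than editing both (AAG→GAG,
K→E, versus AAG→GGG, K→G).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from Bio.Seq import Seq, reverse_complement

__all__ = [
    "SpacerCandidate",
    "CodonConsequence",
    "DesignError",
    "classify_pam",
    "enumerate_spacers",
    "annotate_consequences",
    "annotate_offtarget",
    "OffTargetReport",
]

_PURINES = {"A", "G"}


class DesignError(ValueError):
    """Raised when a requested change cannot be installed by A-to-G editing."""


def classify_pam(pam: str) -> str:
    """NGG if bases 2–3 are GG; else NRN (middle purine) or NYN."""
    pam = pam.upper()
    if len(pam) != 3 or set(pam) - set("ACGT"):
        raise ValueError(f"PAM must be 3 nt of A/C/G/T, got {pam!r}")
    if pam[1:] == "GG":
        return "NGG"
    return "NRN" if pam[1] in _PURINES else "NYN"


@dataclass
class CodonConsequence:
    protospacer_position: int
    codon_index: int  # codon number within the supplied context, 0-based
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    effect: str  # silent | missense | nonsense | stop_lost

    @staticmethod
    def effect_of(aa_before: str, aa_after: str) -> str:
        if aa_before == aa_after:
            return "silent"
        if aa_after == "*":
            return "nonsense"
        if aa_before == "*":
            return "stop_lost"
        return "missense"


@dataclass
class SpacerCandidate:
    spacer: str
    strand: str  # sense | antisense, relative to the coding sequence
    pam: str
    context_start: int  # protospacer-strand 5' end, in coding-strand coordinates
    target_positions: tuple[int, ...]
    window_adenines: tuple[int, ...] = ()
    consequences: list[CodonConsequence] = field(default_factory=list)
    pam_class: str = ""
    expression_spacer: str = ""  # 5' G prepended when needed for U6-type constructs

    def __post_init__(self) -> None:
        self.pam_class = classify_pam(self.pam)
        if not self.expression_spacer:
            self.expression_spacer = self.spacer if self.spacer.startswith("G") else "G" + self.spacer


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _edit_sets_for_change(codon: str, aa_to: str) -> list[tuple[int, ...]]:
    """All subsets of codon A-positions whose A→G conversion encodes *aa_to*."""
    a_pos = [i for i, b in enumerate(codon) if b == "A"]
    hits = []
    for r in range(1, len(a_pos) + 1):
        for subset in combinations(a_pos, r):
            edited = "".join("G" if i in subset else b for i, b in enumerate(codon))
            if _translate(edited) == aa_to:
                hits.append(subset)
    return _minimal_sets(hits)


def _minimal_sets(hits: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Drop edit sets that strictly contain another sufficient set."""
    return [
        h for h in hits
        if not any(set(o) < set(h) for o in hits)
    ]


def enumerate_spacers(
    context: str,
    codon_index: int,
    aa_from: str,
    aa_to: str,
    cds_frame: int = 0,
    window: tuple[int, int] = (3, 11),
    spacer_len: int = 20,
) -> list[SpacerCandidate]:
    """Enumerate spacer candidates installing *aa_from*→*aa_to* at a codon.

    *context* is the coding-strand sequence; codon *codon_index* (0-based)
    starts at ``cds_frame + 3*codon_index``.  Every candidate places all
    required adenines (coding-strand A→G for sense candidates; coding-strand
    T→C, i.e. antisense A→G, for antisense candidates) at protospacer
    positions within *window*.  Candidates are sorted by proximity of the
    target adenines to positions 5–6, then by fewest window adenines.
    """
    context = context.upper()
    lo, hi = window
    c0 = cds_frame + 3 * codon_index
    codon = context[c0 : c0 + 3]
    if len(codon) != 3:
        raise DesignError("context too short for the stated codon")
    if _translate(codon) != aa_from:
        raise DesignError(
            f"codon {codon} at index {codon_index} encodes {_translate(codon)}, not {aa_from}"
        )
    # sense: A→G on coding strand; antisense: T→C on coding strand
    sense_sets = _edit_sets_for_change(codon, aa_to)
    anti_sets_rc = _antisense_edit_sets(codon, aa_to)
    if not sense_sets and not anti_sets_rc:
        raise DesignError(f"change {aa_from}->{aa_to} is not reachable by A-to-G editing on either strand")

    candidates: list[SpacerCandidate] = []

    def add_candidates(strand: str, required_ctx: tuple[int, ...]) -> None:
        # required_ctx: coding-strand offsets of the bases that must be edited
        for start in range(0, len(context) - spacer_len + 1):
            if strand == "sense":
                spacer = context[start : start + spacer_len]
                pam = context[start + spacer_len : start + spacer_len + 3]
                proto = [off - start + 1 for off in required_ctx]
            else:
                # protospacer runs 3'→5' on the coding strand
                end = start + spacer_len
                spacer = reverse_complement(context[start:end])
                pam = reverse_complement(context[start - 3 : start]) if start >= 3 else ""
                proto = [end - 1 - off + 1 for off in required_ctx]
            if len(pam) != 3 or "N" in spacer or "N" in pam:
                continue
            if not all(lo <= p <= hi for p in proto):
                continue
            # sanity: required base is an adenine on the protospacer strand
            if not all(spacer[p - 1] == "A" for p in proto):
                continue
            window_as = tuple(i + 1 for i in range(lo - 1, hi) if spacer[i] == "A")
            candidates.append(
                SpacerCandidate(
                    spacer=spacer,
                    strand=strand,
                    pam=pam,
                    context_start=start if strand == "sense" else start + spacer_len - 1,
                    target_positions=tuple(sorted(proto)),
                    window_adenines=window_as,
                )
            )

    for subset in sense_sets:
        add_candidates("sense", tuple(c0 + i for i in subset))
    for subset in anti_sets_rc:
        # offsets within rc_codon map back to coding strand: rc index i ↔ c0 + 2 - i
        add_candidates("antisense", tuple(c0 + 2 - i for i in subset))

    candidates.sort(
        key=lambda c: (
            min(abs(p - 5.5) for p in c.target_positions),
            len(c.window_adenines),
            c.strand,
            c.spacer,
        )
    )
    return candidates


def _antisense_edit_sets(codon: str, aa_to: str) -> list[tuple[int, ...]]:
    """Subsets of rc-codon A positions whose edit gives aa_to on the coding strand."""
    rc = reverse_complement(codon)
    a_pos = [i for i, b in enumerate(rc) if b == "A"]
    hits = []
    for r in range(1, len(a_pos) + 1):
        for subset in combinations(a_pos, r):
            edited_rc = "".join("G" if i in subset else b for i, b in enumerate(rc))
            if _translate(reverse_complement(edited_rc)) == aa_to:
                hits.append(subset)
    return _minimal_sets(hits)


def annotate_consequences(
    candidate: SpacerCandidate,
    edited_positions: tuple[int, ...] | list[int],
    context: str,
    cds_frame: int = 0,
) -> list[CodonConsequence]:
    """Translate the codon changes caused by editing the given protospacer adenines.

    *edited_positions* are protospacer positions (1-based); each must hold an
    adenine on the protospacer strand.  Codons containing several edited
    adenines are evaluated jointly.  An empty edit set returns no
    consequences.
    """
    context = context.upper()
    if not edited_positions:
        return []
    ctx = list(context)
    ctx_offsets = []
    for p in edited_positions:
        if candidate.strand == "sense":
            off = candidate.context_start + (p - 1)
            if ctx[off] != "A":
                raise ValueError(f"protospacer position {p} is not an adenine")
            ctx[off] = "G"
        else:
            off = candidate.context_start - (p - 1)
            if ctx[off] != "T":
                raise ValueError(f"protospacer position {p} is not an adenine")
            ctx[off] = "C"
        ctx_offsets.append((p, off))
    edited = "".join(ctx)
    out = []
    seen: set[int] = set()
    for p, off in ctx_offsets:
        ci = (off - cds_frame) // 3
        if ci in seen or off < cds_frame:
            continue
        seen.add(ci)
        s = cds_frame + 3 * ci
        before, after = context[s : s + 3], edited[s : s + 3]
        if len(before) < 3:
            continue
        aa_b, aa_a = _translate(before), _translate(after)
        out.append(
            CodonConsequence(
                protospacer_position=p,
                codon_index=ci,
                codon_before=before,
                codon_after=after,
                aa_before=aa_b,
                aa_after=aa_a,
                effect=CodonConsequence.effect_of(aa_b, aa_a),
            )
        )
    return out


@dataclass
class OffTargetReport:
    mismatch_count: int
    mismatch_positions: tuple[int, ...]  # protospacer positions, 1-based
    display: str  # site spacer with mismatched bases lowercased
    pam: str
    pam_class: str


def annotate_offtarget(spacer: str, site_spacer: str, site_pam: str) -> OffTargetReport:
    """Compare an off-target site's protospacer to the on-target spacer."""
    spacer, site_spacer = spacer.upper(), site_spacer.upper()
    if len(spacer) != len(site_spacer):
        raise ValueError("spacer and site must have equal length")
    mism = tuple(i + 1 for i, (a, b) in enumerate(zip(spacer, site_spacer)) if a != b)
    display = "".join(
        b.lower() if (i + 1) in mism else b for i, b in enumerate(site_spacer)
    )
    return OffTargetReport(
        mismatch_count=len(mism),
        mismatch_positions=mism,
        display=display,
        pam=site_pam.upper(),
        pam_class=classify_pam(site_pam),
    )
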