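"""Semi-global pairwise alignment of reads to reference amplicons.

The alignment is global in the read and free of end-gap penalties in the
reference (an amplicon read is wholly contained in its reference), with
affine gap costs: a gap of length L scores ``gap_open + (L-1)*gap_extend``.
The engine is Bio.Align.PairwiseAligner; among co-optimal alignments the
first in its deterministic enumeration order is taken, so outputs are
bit-reproducible for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Seq import reverse_complement

from .loci import AmpliconLocus, ReadRecord

__all__ = ["Scoring", "AlignedRead", "semiglobal_align", "orient_and_align", "best_alignment_score"]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; defaults favour one substitution over two gaps."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


@dataclass
class AlignedRead:
    """A read's correspondence to its reference, in reference coordinates.

    ``ref_calls`` maps every reference position inside ``aligned_span``
    (half-open) to the observed base, with deletions recorded as ``'-'``.
    ``insertions`` holds ``(reference_gap_position, inserted_seq)`` pairs,
    the gap position being the reference offset *before which* the inserted
    bases sit.
    """

    read_id: str
    orientation: str  # "forward" | "reverse"
    ref_calls: dict[int, str]
    insertions: list[tuple[int, str]]
    aligned_span: tuple[int, int]
    score: float
    quals: dict[int, int] = field(default_factory=dict)

    @property
    def has_indel(self) -> bool:
        return bool(self.insertions) or "-" in self.ref_calls.values()

    def substitutions(self, reference: str) -> dict[int, str]:
        """Reference positions where the read disagrees (N and gaps excluded)."""
        return {
            p: b
            for p, b in self.ref_calls.items()
            if b not in ("N", "-") and b != reference[p]
        }

    def has_indel_in(self, win_start: int, win_end: int) -> bool:
        """True if any indel touches the half-open window [win_start, win_end).

        Deletions count when they delete a base inside the window; an
        insertion counts when its gap position lies anywhere from the
        window start to the window end inclusive (boundary insertions are
        window-adjacent events and are treated as overlapping).
        """
        for p, _seq in self.insertions:
            if win_start <= p <= win_end:
                return True
        for lo, hi in self._deletion_runs():
            if lo < win_end and hi >= win_start:
                return True
        return False

    def _deletion_runs(self) -> list[tuple[int, int]]:
        runs = []
        run_start = None
        prev = None
        for p in sorted(self.ref_calls):
            if self.ref_calls[p] == "-":
                if run_start is None:
                    run_start = p
                prev = p
            elif run_start is not None:
                runs.append((run_start, prev))
                run_start = None
        if run_start is not None:
            runs.append((run_start, prev))
        return runs

    def indel_intervals(self) -> list[tuple[int, int]]:
        """Closed reference intervals touched by indels.

        Deletions cover their deleted positions; an insertion before
        reference position p is represented as the zero-length interval
        (p, p) so boundary overlap with a window is detected.
        """
        return [(p, p) for p, _seq in self.insertions] + self._deletion_runs()


@lru_cache(maxsize=8)
def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    a.end_deletion_score = 0.0  # free end-gaps in the reference
    return a


def _check_dna(seq: str, what: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-DNA characters in {what}: {sorted(bad)}")
    if not seq:
        raise ValueError(f"empty {what}")


def best_alignment_score(read: str, reference: str, scoring: Scoring = Scoring()) -> float:
    """Best semi-global score of the read or its reverse complement."""
    aligner = _make_aligner(scoring)
    fwd = aligner.score(reference, read)
    rev = aligner.score(reference, reverse_complement(read))
    return max(fwd, rev)


def semiglobal_align(
    read: str,
    reference: str,
    scoring: Scoring = Scoring(),
    read_id: str = "",
    quals: list[int] | None = None,
    orientation: str = "forward",
) -> AlignedRead:
    """Align *read* to *reference*: global in the read, free reference ends."""
    read = read.upper()
    reference = reference.upper()
    _check_dna(read, "read")
    _check_dna(reference, "reference")
    aligner = _make_aligner(scoring)
    aln = aligner.align(reference, read)[0]
    ref_calls: dict[int, str] = {}
    qual_by_ref: dict[int, int] = {}
    insertions: list[tuple[int, str]] = []
    blocks = aln.aligned  # pairs of (target_block, query_block)
    tblocks = blocks[0]
    qblocks = blocks[1]
    prev_t_end = None
    prev_q_end = None
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if prev_t_end is not None:
            if t0 > prev_t_end and q0 == prev_q_end:
                for p in range(prev_t_end, t0):  # deletion in read
                    ref_calls[p] = "-"
            elif q0 > prev_q_end and t0 == prev_t_end:
                insertions.append((t0, read[prev_q_end:q0]))
            elif t0 > prev_t_end and q0 > prev_q_end:  # gap on both sides
                for p in range(prev_t_end, t0):
                    ref_calls[p] = "-"
                insertions.append((t0, read[prev_q_end:q0]))
        for p, q in zip(range(t0, t1), range(q0, q1)):
            ref_calls[p] = read[q]
            if quals is not None:
                qual_by_ref[p] = quals[q]
        prev_t_end, prev_q_end = t1, q1
    if not ref_calls:
        span = (0, 0)
    else:
        span = (min(ref_calls), max(ref_calls) + 1)
    # leading/trailing read overhang beyond the reference would appear as
    # insertions at the reference boundary; interior gaps were handled above.
    return AlignedRead(
        read_id=read_id,
        orientation=orientation,
        ref_calls=ref_calls,
        insertions=insertions,
        aligned_span=span,
        score=float(aln.score),
        quals=qual_by_ref,
    )


def orient_and_align(
    read: ReadRecord, locus: AmpliconLocus, scoring: Scoring = Scoring()
) -> AlignedRead:
    """Align the read and its reverse complement; keep the better (tie: forward)."""
    aligner = _make_aligner(scoring)
    rc = reverse_complement(read.seq)
    fwd_score = aligner.score(locus.reference, read.seq)
    rev_score = aligner.score(locus.reference, rc)
    if rev_score > fwd_score:
        return semiglobal_align(
            rc,
            locus.reference,
            scoring,
            read_id=read.read_id,
            quals=list(reversed(read.quals)),
            orientation="reverse",
        )
    return semiglobal_align(
        read.seq,
        locus.reference,
        scoring,
        read_id=read.read_id,
        quals=read.quals,
        orientation="forward",
    )
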