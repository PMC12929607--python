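"""Read-level allele classification, editing metrics and founder triage.

Each aligned read's quantification-window allele is placed in one of five
classes — wild-type, desired-only ("perfect"), desired + bystander(s),
bystander-only, or indel-containing — by comparing its window substitution
set against the locus's desired-edit set.  The class tallies map onto the
quantification-table columns (Reads_aligned_all_amplicons, Reads_aligned,
Unmodified, Modified, Discarded) from which the four editing metrics are
computed:

    specified incl. bystanders (%)    = Reads_aligned / Reads_aligned_all_amplicons × 100
    specified without bystanders (%)  = Unmodified / Reads_aligned_all_amplicons × 100
    product purity (%)                = Unmodified / Reads_aligned × 100
    indels (%)                        = Discarded / Reads_aligned_all_amplicons × 100

A founder is called high-confidence when its desired-only read fraction
reaches ``min_desired_only_pct`` and its unwanted-outcome fraction
(desired+bystander, bystander-only and indel reads combined) stays at or
below ``max_unwanted_pct``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .align import AlignedRead
from .loci import AmpliconLocus

__all__ = [
    "CLASS_NAMES",
    "AlleleClassCounts",
    "QuantTable",
    "EditingMetrics",
    "TriageThresholds",
    "classify_read",
    "tally",
    "to_quant_table",
    "compute_metrics",
    "founder_triage",
]

CLASS_NAMES = ("wt", "desired_only", "desired_bystander", "bystander_only", "indel", "short_read")


@dataclass
class AlleleClassCounts:
    total_aligned: int = 0
    wt: int = 0
    desired_only: int = 0
    desired_bystander: int = 0
    bystander_only: int = 0
    indel: int = 0
    short_reads_excluded: int = 0

    def __post_init__(self) -> None:
        parts = (
            self.wt
            + self.desired_only
            + self.desired_bystander
            + self.bystander_only
            + self.indel
            + self.short_reads_excluded
        )
        if parts != self.total_aligned:
            raise ValueError("allele class counts do not sum to total_aligned")


@dataclass
class QuantTable:
    """Quantification-table columns used by the editing metrics."""

    Reads_aligned_all_amplicons: int
    Reads_aligned: int
    Unmodified: int
    Modified: int
    Discarded: int

    def __post_init__(self) -> None:
        if self.Unmodified + self.Modified != self.Reads_aligned:
            raise ValueError("Unmodified + Modified must equal Reads_aligned")
        if self.Reads_aligned > self.Reads_aligned_all_amplicons:
            raise ValueError("Reads_aligned exceeds Reads_aligned_all_amplicons")


@dataclass
class EditingMetrics:
    specified_incl_bystanders_pct: float
    specified_without_bystanders_pct: float
    purity_pct: float | None  # None when no read carries the full desired set
    indels_pct: float


@dataclass(frozen=True)
class TriageThresholds:
    min_desired_only_pct: float = 20.0
    max_unwanted_pct: float = 2.5
    unwanted_inclusive: bool = True  # high-confidence requires unwanted <= (or <) threshold

    def __post_init__(self) -> None:
        if self.min_desired_only_pct < 0 or self.max_unwanted_pct < 0:
            raise ValueError("triage thresholds must be non-negative")


def classify_read(aligned: AlignedRead, locus: AmpliconLocus) -> str:
    """Assign one read to an allele class over the quantification window.

    Rules, in order: window not fully covered → ``short_read``; any indel
    overlapping the window → ``indel``; no window substitutions → ``wt``;
    substitution set equal to the desired set → ``desired_only``; strict
    superset → ``desired_bystander``; anything else → ``bystander_only``
    (this includes reads carrying only part of a multi-adenine desired set,
    e.g. one of two targeted adenines).  N calls never count as
    substitutions.
    """
    win_start, win_end = locus.quant_window()
    lo, hi = aligned.aligned_span
    if lo > win_start or hi < win_end:
        return "short_read"
    if aligned.has_indel_in(win_start, win_end):
        return "indel"
    subs = {
        (p, b)
        for p, b in aligned.substitutions(locus.reference).items()
        if win_start <= p < win_end
    }
    if not subs:
        return "wt"
    desired = locus.desired_ref_edits()
    if subs == desired:
        return "desired_only"
    if subs > desired:
        return "desired_bystander"
    return "bystander_only"


def tally(aligned_reads: Iterable[AlignedRead], locus: AmpliconLocus) -> AlleleClassCounts:
    counts = {name: 0 for name in CLASS_NAMES}
    total = 0
    for ar in aligned_reads:
        counts[classify_read(ar, locus)] += 1
        total += 1
    return AlleleClassCounts(
        total_aligned=total,
        wt=counts["wt"],
        desired_only=counts["desired_only"],
        desired_bystander=counts["desired_bystander"],
        bystander_only=counts["bystander_only"],
        indel=counts["indel"],
        short_reads_excluded=counts["short_read"],
    )


def to_quant_table(counts: AlleleClassCounts) -> QuantTable:
    """Map allele-class tallies onto the quantification-table columns.

    Reads carrying the full desired-edit set and no window indel make up
    ``Reads_aligned``; bystander-only and wild-type reads sit outside it,
    indel reads are ``Discarded``.
    """
    return QuantTable(
        Reads_aligned_all_amplicons=counts.total_aligned - counts.short_reads_excluded,
        Reads_aligned=counts.desired_only + counts.desired_bystander,
        Unmodified=counts.desired_only,
        Modified=counts.desired_bystander,
        Discarded=counts.indel,
    )


def compute_metrics(qt: QuantTable) -> EditingMetrics:
    total = qt.Reads_aligned_all_amplicons
    if total <= 0:
        raise ValueError("no aligned reads")
    purity = 100.0 * qt.Unmodified / qt.Reads_aligned if qt.Reads_aligned > 0 else None
    return EditingMetrics(
        specified_incl_bystanders_pct=100.0 * qt.Reads_aligned / total,
        specified_without_bystanders_pct=100.0 * qt.Unmodified / total,
        purity_pct=purity,
        indels_pct=100.0 * qt.Discarded / total,
    )


def founder_triage(
    metrics: EditingMetrics,
    counts: AlleleClassCounts,
    th: TriageThresholds = TriageThresholds(),
) -> str:
    """Call a founder ``high_confidence`` or ``not_high_confidence``.

    desired-only % is the specified-without-bystanders metric; unwanted %
    pools desired+bystander, bystander-only and indel reads over
    Reads_aligned_all_amplicons.
    """
    total = counts.total_aligned - counts.short_reads_excluded
    if total <= 0:
        return "not_high_confidence"
    unwanted_pct = 100.0 * (counts.desired_bystander + counts.bystander_only + counts.indel) / total
    desired_ok = metrics.specified_without_bystanders_pct >= th.min_desired_only_pct
    if th.unwanted_inclusive:
        unwanted_ok = unwanted_pct <= th.max_unwanted_pct
    else:
        unwanted_ok = unwanted_pct < th.max_unwanted_pct
    return "high_confidence" if desired_ok and unwanted_ok else "not_high_confidence"
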