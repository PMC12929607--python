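"""Per-position nucleotide profiles and position-level editing statistics.

A :class:`PositionProfile` is the per-position base-count table across the
spacer and its flanks (the nucleotide-percentage-summary view of an
amplicon).  From it come the per-adenine A-to-G frequencies, the cumulative
editing (sum of A-to-G percentages across the spacer, may exceed 100), and
the positional precision metric (second-highest adenine frequency divided
by the highest; lower = more precise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .align import AlignedRead
from .loci import AmpliconLocus

__all__ = [
    "BASE_SYMBOLS",
    "PositionProfile",
    "EditingStats",
    "build_profile",
    "a_to_g_frequencies",
    "indel_frequency",
    "cumulative_editing",
    "precision_metric",
    "percent_reduction",
    "editing_stats",
]

BASE_SYMBOLS = ("A", "C", "G", "T", "N", "-")


@dataclass
class PositionProfile:
    """Per-position base counts in protospacer numbering.

    ``positions`` are protospacer-frame labels (…,−2,−1,1..20,21,…; no 0),
    ``counts[pos][base]`` the number of reads calling *base* there, and
    ``depth[pos]`` the number of reads covering the position (the sum of
    its counts, N and gap calls included).
    """

    locus_id: str
    positions: list[int]
    counts: dict[int, dict[str, int]]
    depth: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.depth:
            self.depth = {p: sum(self.counts[p].values()) for p in self.positions}

    def frequencies(self) -> pd.DataFrame:
        """Percent of reads per base symbol and position (NaN at zero depth)."""
        data = {}
        for p in self.positions:
            d = self.depth[p]
            data[p] = {
                b: (100.0 * self.counts[p].get(b, 0) / d) if d else math.nan
                for b in BASE_SYMBOLS
            }
        return pd.DataFrame(data).reindex(index=list(BASE_SYMBOLS))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {p: {b: self.counts[p].get(b, 0) for b in BASE_SYMBOLS} for p in self.positions}
        ).reindex(index=list(BASE_SYMBOLS))


@dataclass
class EditingStats:
    """Position-level summary for one sample × locus."""

    a_to_g: dict[int, Optional[float]]
    indel_pct: float
    cumulative: float
    precision: float


def build_profile(
    aligned_reads: Iterable[AlignedRead],
    locus: AmpliconLocus,
    flank_upstream: int | None = None,
    flank_downstream: int | None = None,
) -> PositionProfile:
    """Tally per-position base calls on the protospacer strand.

    The profile spans the spacer plus flanks — by default the
    quantification-window extents.  Deletions count as ``'-'``; insertions
    do not shift the reference frame and are not tallied here.
    """
    w = locus.window_spec
    up = w.upstream_nt if flank_upstream is None else flank_upstream
    down = (w.pam_len + w.downstream_nt) if flank_downstream is None else flank_downstream
    start = max(locus.spacer_start - up, 0)
    end = min(locus.spacer_start + len(locus.spacer) + down, len(locus.reference))
    ref_positions = range(start, end)
    positions = [locus.protospacer_position(p) for p in ref_positions]
    counts = {pp: {b: 0 for b in BASE_SYMBOLS} for pp in positions}
    for ar in aligned_reads:
        for rp, pp in zip(ref_positions, positions):
            base = ar.ref_calls.get(rp)
            if base is not None:
                counts[pp][base] += 1
    return PositionProfile(locus_id=locus.locus_id, positions=positions, counts=counts)


def a_to_g_frequencies(
    profile: PositionProfile,
    locus: AmpliconLocus,
    include_flanks: bool = False,
) -> dict[int, Optional[float]]:
    """Percent G at every reference adenine, keyed by protospacer position.

    Spacer adenines (positions 1..20) are always reported; flank adenines
    (negative and post-spacer labels) when *include_flanks* is set.  A
    position with zero depth maps to None, never 0.
    """
    out: dict[int, Optional[float]] = {}
    for pp in profile.positions:
        in_spacer = 1 <= pp <= 20
        if not in_spacer and not include_flanks:
            continue
        rp = locus.reference_position(pp)
        if locus.reference[rp] != "A":
            continue
        d = profile.depth[pp]
        out[pp] = (100.0 * profile.counts[pp].get("G", 0) / d) if d else None
    return out


def indel_frequency(aligned_reads: Iterable[AlignedRead], locus: AmpliconLocus) -> float:
    """Percent of aligned reads with an indel overlapping the quantification window.

    Overlap is closed-interval: an insertion sitting exactly at a window
    boundary counts.
    """
    win_start, win_end = locus.quant_window()
    n = 0
    hits = 0
    for ar in aligned_reads:
        n += 1
        if ar.has_indel_in(win_start, win_end):
            hits += 1
    return 100.0 * hits / n if n else 0.0


def cumulative_editing(a_to_g: dict[int, Optional[float]]) -> float:
    """Sum of A-to-G percentages over spacer positions 1..20 (may exceed 100)."""
    return float(sum(v for p, v in a_to_g.items() if 1 <= p <= 20 and v is not None))


def precision_metric(a_to_g: dict[int, Optional[float]]) -> float:
    """Second-highest adenine A-to-G frequency divided by the highest.

    Returns 0 when only one adenine exists or the highest frequency is 0.
    Lower values indicate a more positionally concentrated editor.
    """
    if not a_to_g:
        raise ValueError("no adenine frequencies supplied")
    vals = sorted((v for v in a_to_g.values() if v is not None), reverse=True)
    if len(vals) < 2 or vals[0] == 0:
        return 0.0
    return vals[1] / vals[0]


def percent_reduction(before: float, after: float) -> float:
    """Relative reduction in percent between two activity levels."""
    if before == 0:
        raise ValueError("reference activity is zero")
    return 100.0 * (before - after) / before


def editing_stats(aligned_reads: list[AlignedRead], locus: AmpliconLocus) -> EditingStats:
    """Convenience: profile a read set and derive all position-level statistics."""
    profile = build_profile(aligned_reads, locus)
    freqs = a_to_g_frequencies(profile, locus)
    return EditingStats(
        a_to_g=freqs,
        indel_pct=indel_frequency(aligned_reads, locus),
        cumulative=cumulative_editing(freqs),
        precision=precision_metric(freqs) if freqs else 0.0,
    )
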