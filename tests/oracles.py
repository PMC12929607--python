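"""Independent brute-force oracles used to check the implementation.

These are written from first principles (plain-Python Gotoh dynamic
programming; literal rule-by-rule allele classification; exhaustive spacer
frame enumeration) and share no code with the package paths they verify.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_semiglobal_score(
    read: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> float:
    """Affine-gap semi-global alignment score: read global, reference ends free.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``.  Three-state
    Gotoh DP; leading/trailing unaligned reference is free, read overhangs
    pay normal gap costs.
    """
    m, n = len(read), len(ref)

    def s(a: str, b: str) -> float:
        return match if a == b else mismatch

    # state matrices indexed [i][j], i over read, j over ref
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in read (ref consumed)
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in ref (read consumed)
    M[0][0] = 0.0
    for j in range(1, n + 1):
        Ix[0][j] = 0.0  # free leading reference
    for i in range(1, m + 1):
        Iy[i][0] = gap_open + (i - 1) * gap_extend  # read overhang at start
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            if best_prev > NEG:
                M[i][j] = best_prev + s(read[i - 1], ref[j - 1])
            h_up = max(M[i - 1][j], Ix[i - 1][j], Iy[i - 1][j])
            Iy[i][j] = max(
                h_up + gap_open if h_up > NEG else NEG,
                Iy[i - 1][j] + gap_extend if Iy[i - 1][j] > NEG else NEG,
            )
            h_left = max(M[i][j - 1], Ix[i][j - 1], Iy[i][j - 1])
            Ix[i][j] = max(
                h_left + gap_open if h_left > NEG else NEG,
                Ix[i][j - 1] + gap_extend if Ix[i][j - 1] > NEG else NEG,
            )
    # trailing reference is free: stop after the last read base at any j.
    # A trailing run of reference gaps is entirely free, so the alignment
    # effectively ends in a match/mismatch or read-overhang column.
    return max(max(M[m][j], Iy[m][j]) for j in range(n + 1))


def classify_literal(
    window_subs: frozenset[tuple[int, str]],
    desired: frozenset[tuple[int, str]],
    covers_window: bool,
    indel_in_window: bool,
) -> str:
    """Literal transcription of the five-way classification rules."""
    if not covers_window:
        return "short_read"
    if indel_in_window:
        return "indel"
    if len(window_subs) == 0:
        return "wt"
    if window_subs == desired:
        return "desired_only"
    if window_subs > desired:
        return "desired_bystander"
    return "bystander_only"


def enumerate_frames_literal(
    context: str, required_offsets: tuple[int, ...], strand: str,
    window: tuple[int, int] = (3, 11), spacer_len: int = 20,
) -> set[tuple[str, str]]:
    """All (spacer, pam) frames placing the required bases in-window.

    *required_offsets* are coding-strand offsets that must fall at
    protospacer positions within *window* on the given strand.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def rc(s: str) -> str:
        return "".join(comp[b] for b in reversed(s))

    lo, hi = window
    out = set()
    for start in range(len(context) - spacer_len + 1):
        end = start + spacer_len
        if strand == "sense":
            spacer = context[start:end]
            pam = context[end : end + 3]
            proto = [off - start + 1 for off in required_offsets]
        else:
            spacer = rc(context[start:end])
            pam = rc(context[start - 3 : start]) if start >= 3 else ""
            proto = [end - off for off in required_offsets]
        if len(pam) != 3 or "N" in spacer or "N" in pam:
            continue
        if all(lo <= p <= hi for p in proto) and all(spacer[p - 1] == "A" for p in proto):
            out.add((spacer, pam))
    return out
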