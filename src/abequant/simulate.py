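"""Synthetic amplicon reads with the statistical structure of base-editing data.

The generative model: a molecule is engaged by the editor with probability
``engage_prob``; given engagement, each window adenine converts A→G
independently with its position's probability ``w_i``, each remaining
window adenine converts A→C with the (rare) ``atoc_prob``, each window
cytosine converts C→T with ``ctot_prob``, and an indel of 1–3 nt is placed
uniformly inside the quantification window with probability ``indel_prob``.
Sequencing then adds independent per-base substitution errors and emits
Phred+33 qualities.

Two sampling modes cover the study designs: a *population* mode where every
read is an independent molecule (transfected cell pools), and a *founder*
mode where a small number of cell lineages each carry one fixed allele and
reads are drawn from the lineage mixture (mosaic F0 animals, weights from a
Dirichlet draw).

Editor presets: ``abe9_like`` is active only at protospacer positions 4–6
with positions 5–6 dominant; ``abe8e_like`` is active across positions 2–14,
peaking at 5–6 with decaying shoulders.  Peak per-position activities follow
the reported per-position means (0.436 and 0.345 at A5); shoulder values are
a smooth interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .loci import AmpliconLocus, ReadRecord

__all__ = [
    "EditorModel",
    "SeqNoise",
    "MosaicFounder",
    "make_editor_profile",
    "simulate_founder",
    "simulate_reads",
    "simulate_population_reads",
    "expected_purity",
    "simulate_offtarget_panel",
]

ABE9_LIKE_PROFILE = {4: 0.03, 5: 0.345, 6: 0.30}
ABE8E_LIKE_PROFILE = {
    2: 0.08,
    3: 0.20,
    4: 0.32,
    5: 0.436,
    6: 0.42,
    7: 0.30,
    8: 0.22,
    9: 0.12,
    10: 0.08,
    11: 0.06,
    12: 0.05,
    13: 0.03,
    14: 0.02,
}


@dataclass(frozen=True)
class EditorModel:
    """A generative adenine base editor."""

    name: str
    engage_prob: float = 1.0
    window_profile: dict[int, float] = field(default_factory=dict)
    ctot_prob: float = 0.0
    atoc_prob: float = 0.0
    indel_prob: float = 0.0
    indel_len_dist: dict[int, float] = field(
        default_factory=lambda: {-3: 1 / 6, -2: 1 / 6, -1: 1 / 6, 1: 1 / 6, 2: 1 / 6, 3: 1 / 6}
    )

    def __post_init__(self) -> None:
        probs = [self.engage_prob, self.ctot_prob, self.atoc_prob, self.indel_prob]
        probs += list(self.window_profile.values())
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.indel_len_dist:
            if abs(sum(self.indel_len_dist.values()) - 1.0) > 1e-9:
                raise ValueError("indel_len_dist must sum to 1")
            if any(l == 0 or abs(l) > 3 for l in self.indel_len_dist):
                raise ValueError("indel lengths must be in {-3..-1, +1..+3}")


@dataclass(frozen=True)
class SeqNoise:
    """Per-base sequencing substitution error and emitted quality model."""

    sub_error: float = 0.001
    qual_mean: float = 33.0
    qual_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_error <= 0.05:
            raise ValueError("sub_error must be in [0, 0.05]")


NOISELESS = SeqNoise(sub_error=0.0, qual_mean=37.0, qual_sd=0.0)


@dataclass
class MosaicFounder:
    """A founder as a weighted mixture of cell-lineage alleles.

    Each lineage allele is ``(substitutions, indel)`` where substitutions
    maps reference position → base and indel is None or
    ``(ref_position, length)`` with negative length = deletion.
    """

    locus_id: str
    lineages: list[tuple[dict[int, str], tuple[int, int] | None]]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.lineages) < 1:
            raise ValueError("a founder needs at least one lineage")
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.lineages) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must match lineages and sum to 1")


def make_editor_profile(
    preset: str | dict[int, float],
    engage_prob: float = 1.0,
    peak: float | None = None,
    ctot_prob: float = 0.002,
    atoc_prob: float = 0.0005,
    indel_prob: float = 0.005,
) -> EditorModel:
    """Build an EditorModel from a preset name or an explicit position→w map.

    *peak* rescales the profile so its maximum equals the given value,
    allowing activity-matched comparisons between editors.
    """
    if isinstance(preset, str):
        try:
            profile = dict({"abe9_like": ABE9_LIKE_PROFILE, "abe8e_like": ABE8E_LIKE_PROFILE}[preset])
        except KeyError:
            raise ValueError(f"unknown editor preset {preset!r}") from None
        name = preset
    else:
        profile = dict(preset)
        name = "custom"
    if peak is not None:
        cur = max(profile.values())
        profile = {p: w * peak / cur for p, w in profile.items()}
    return EditorModel(
        name=name,
        engage_prob=engage_prob,
        window_profile=profile,
        ctot_prob=ctot_prob,
        atoc_prob=atoc_prob,
        indel_prob=indel_prob,
    )


# ---------------------------------------------------------------------------
# allele generation


def _draw_allele(
    locus: AmpliconLocus, editor: EditorModel, rng: np.random.Generator
) -> tuple[dict[int, str], tuple[int, int] | None]:
    """One molecule's edit outcome: (substitutions by ref position, indel)."""
    if rng.random() >= editor.engage_prob:
        return {}, None
    subs: dict[int, str] = {}
    for proto_pos, w in sorted(editor.window_profile.items()):
        rp = locus.reference_position(proto_pos)
        if not 0 <= rp < len(locus.reference) or locus.reference[rp] != "A":
            continue
        if rng.random() < w:
            subs[rp] = "G"
        elif editor.atoc_prob and rng.random() < editor.atoc_prob:
            subs[rp] = "C"
    if editor.ctot_prob:
        win_start, win_end = locus.quant_window()
        for rp in range(win_start, win_end):
            if locus.reference[rp] == "C" and rng.random() < editor.ctot_prob:
                subs[rp] = "T"
    indel = None
    if editor.indel_prob and rng.random() < editor.indel_prob:
        win_start, win_end = locus.quant_window()
        lengths = sorted(editor.indel_len_dist)
        probs = np.array([editor.indel_len_dist[l] for l in lengths])
        length = int(rng.choice(lengths, p=probs / probs.sum()))
        pos = int(rng.integers(win_start, win_end))
        indel = (pos, length)
    return subs, indel


def _apply_allele(
    reference: str, subs: dict[int, str], indel: tuple[int, int] | None
) -> str:
    seq = list(reference)
    for rp, b in subs.items():
        seq[rp] = b
    if indel is not None:
        pos, length = indel
        if length < 0:
            del seq[pos : pos - length]
        else:
            seq[pos:pos] = list("A" * length)  # inserted bases; content immaterial
    return "".join(seq)


def _emit_read(
    read_id: str, seq: str, noise: SeqNoise, rng: np.random.Generator
) -> ReadRecord:
    bases = np.frombuffer(seq.encode(), dtype="S1").copy()
    if noise.sub_error > 0:
        err = rng.random(len(bases)) < noise.sub_error
        if err.any():
            alphabet = np.array([b"A", b"C", b"G", b"T"])
            for i in np.flatnonzero(err):
                choices = alphabet[alphabet != bases[i]]
                bases[i] = choices[rng.integers(len(choices))]
    if noise.qual_sd > 0:
        quals = np.clip(np.rint(rng.normal(noise.qual_mean, noise.qual_sd, len(bases))), 2, 41)
    else:
        quals = np.full(len(bases), round(noise.qual_mean))
    return ReadRecord(read_id, bases.tobytes().decode(), [int(q) for q in quals])


# ---------------------------------------------------------------------------
# founder and read simulation


def simulate_founder(
    locus: AmpliconLocus,
    editor: EditorModel,
    k: int = 4,
    alpha: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> MosaicFounder:
    """Draw a mosaic founder: K lineage alleles with Dirichlet(alpha) weights."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lineages = [_draw_allele(locus, editor, rng) for _ in range(k)]
    weights = rng.dirichlet([alpha] * k) if k > 1 else np.array([1.0])
    return MosaicFounder(locus_id=locus.locus_id, lineages=lineages, weights=weights)


def simulate_reads(
    founder: MosaicFounder,
    locus: AmpliconLocus,
    noise: SeqNoise = SeqNoise(),
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[ReadRecord]:
    """Sample n reads from a founder's lineage mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    choices = rng.choice(len(founder.lineages), size=n, p=founder.weights)
    reads = []
    for i, li in enumerate(choices):
        subs, indel = founder.lineages[li]
        seq = _apply_allele(locus.reference, subs, indel)
        reads.append(_emit_read(f"{locus.locus_id}_read{i}", seq, noise, rng))
    return reads


def simulate_population_reads(
    locus: AmpliconLocus,
    editor: EditorModel,
    noise: SeqNoise = SeqNoise(),
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[ReadRecord]:
    """Sample n reads, each from an independently edited molecule (cell pool)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads = []
    for i in range(n):
        subs, indel = _draw_allele(locus, editor, rng)
        seq = _apply_allele(locus.reference, subs, indel)
        reads.append(_emit_read(f"{locus.locus_id}_read{i}", seq, noise, rng))
    return reads


# ---------------------------------------------------------------------------
# closed forms and off-target panel


def expected_purity(editor: EditorModel, locus: AmpliconLocus) -> float:
    """Closed-form product purity (%) under per-position independence.

    The probability that an engaged molecule carrying the full desired-edit
    set acquires no bystander: product of (1 − w_b)(1 − atoc(1 − w_b)-share)
    over non-desired window adenines and (1 − ctot) over window cytosines.
    Matches the Monte-Carlo purity of the generator exactly because the
    generator uses the same conditional independence.
    """
    desired_pos = {pos for pos, _r, _a in locus.desired_edits}
    p = 1.0
    for proto_pos, w in editor.window_profile.items():
        if proto_pos in desired_pos:
            continue
        rp = locus.reference_position(proto_pos)
        if not 0 <= rp < len(locus.reference) or locus.reference[rp] != "A":
            continue
        p *= (1.0 - w) * (1.0 - editor.atoc_prob)
    if editor.atoc_prob:
        # adenines in the window but outside the profile never convert; only
        # profile positions run the A→C lottery in the generator
        pass
    if editor.ctot_prob:
        win_start, win_end = locus.quant_window()
        n_c = locus.reference.count("C", win_start, win_end)
        p *= (1.0 - editor.ctot_prob) ** n_c
    return 100.0 * p


def simulate_offtarget_panel(
    spacer: str,
    sites: Sequence[tuple[AmpliconLocus, int]],
    editor: EditorModel,
    attenuation: Callable[[int], float] | dict[int, float] | None = None,
    noise: SeqNoise = SeqNoise(),
    n: int = 1000,
    seed: int = 0,
) -> dict[str, list[ReadRecord]]:
    """Simulate reads at off-target sites with mismatch-attenuated engagement.

    *sites* pairs each off-target locus with its spacer mismatch count m;
    per-site engagement is ``engage_prob × attenuation(m)``.  The default
    attenuation is 4^(−m); any supplied attenuation must have
    attenuation(0) = 1 and be non-increasing in m.
    """
    if attenuation is None:
        atten = lambda m: 4.0 ** (-m)
    elif isinstance(attenuation, dict):
        table = dict(attenuation)
        atten = lambda m: table[m]
    else:
        atten = attenuation
    ms = sorted({m for _l, m in sites} | {0})
    vals = [atten(m) for m in ms]
    if abs(vals[0] - 1.0) > 1e-9 and ms[0] == 0:
        raise ValueError("attenuation(0) must be 1")
    if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
        raise ValueError("attenuation must be non-increasing in mismatch count")
    out: dict[str, list[ReadRecord]] = {}
    rng = np.random.default_rng(seed)
    for site_locus, m in sites:
        site_editor = replace(editor, engage_prob=editor.engage_prob * atten(m))
        out[site_locus.locus_id] = simulate_population_reads(
            site_locus, site_editor, noise=noise, n=n, seed=rng
        )
    return out
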