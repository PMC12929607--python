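"""Locus configuration, FASTQ input, quality filtering and demultiplexing.

An :class:`AmpliconLocus` ties a reference amplicon to the 20-nt spacer it
was targeted with, the PAM, the set of desired A-to-G edits, and the
quantification window used for allele classification.  All downstream
analysis runs on the *protospacer strand*: if a spacer anneals to the
antisense strand of the sequenced amplicon, the reference is
reverse-complemented once at load time so A-to-G accounting always reads
5'→3' along the protospacer, positions 1..20 with position 20 adjacent to
the PAM.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "WindowSpec",
    "AmpliconLocus",
    "ReadRecord",
    "ConfigError",
    "load_locus_config",
    "read_fastq",
    "write_fastq",
    "mean_quality",
    "mean_quality_filter",
    "merge_read_pair",
    "demultiplex",
]

_DNA = set("ACGTN")


class ConfigError(ValueError):
    """Raised for malformed or inconsistent locus configurations."""


@dataclass(frozen=True)
class WindowSpec:
    """Quantification-window bounds around the spacer.

    The window runs from ``upstream_nt`` bases 5' of protospacer position 1
    to ``downstream_nt`` bases 3' of the PAM.  Defaults give the
    spacer−7nt .. spacer+PAM+3nt window (33 nt for a 20-nt spacer and 3-nt
    PAM).
    """

    upstream_nt: int = 7
    downstream_nt: int = 3
    pam_len: int = 3

    def __post_init__(self) -> None:
        if self.upstream_nt < 0 or self.downstream_nt < 0 or self.pam_len < 0:
            raise ConfigError("window extents must be non-negative")

    def length(self, spacer_len: int = 20) -> int:
        return self.upstream_nt + spacer_len + self.pam_len + self.downstream_nt


@dataclass
class AmpliconLocus:
    """A reference amplicon with spacer placement and desired edits.

    ``reference`` is stored on the protospacer strand.  ``desired_edits``
    is a set of ``(protospacer_position, ref_base, alt_base)`` tuples with
    positions in 1..20.
    """

    locus_id: str
    reference: str
    spacer: str
    spacer_start: int
    pam: str
    desired_edits: frozenset[tuple[int, str, str]] = frozenset()
    spacer_strand: str = "sense"
    window_spec: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        self.spacer = self.spacer.upper()
        self.pam = self.pam.upper()
        if set(self.reference) - _DNA:
            raise ConfigError(f"{self.locus_id}: non-DNA characters in reference")
        if len(self.spacer) != 20 or set(self.spacer) - set("ACGT"):
            raise ConfigError(f"{self.locus_id}: spacer must be 20 nt of A/C/G/T")
        if len(self.pam) != self.window_spec.pam_len or set(self.pam) - set("ACGT"):
            raise ConfigError(
                f"{self.locus_id}: PAM must be {self.window_spec.pam_len} nt of A/C/G/T"
            )
        if self.spacer_strand not in ("sense", "antisense"):
            raise ConfigError(f"{self.locus_id}: bad spacer_strand {self.spacer_strand!r}")
        if self.spacer_strand == "antisense":
            # normalise to the protospacer strand once, up front
            self.reference = reverse_complement(self.reference)
            self.spacer_start = len(self.reference) - self.spacer_start - len(self.spacer)
            self.spacer_strand = "sense"
        end = self.spacer_start + len(self.spacer)
        if self.spacer_start < 0 or self.reference[self.spacer_start : end] != self.spacer:
            raise ConfigError(
                f"{self.locus_id}: spacer not found on protospacer strand at offset "
                f"{self.spacer_start}"
            )
        if self.reference[end : end + len(self.pam)] != self.pam:
            raise ConfigError(f"{self.locus_id}: PAM does not follow spacer in reference")
        for pos, ref, alt in self.desired_edits:
            if not 1 <= pos <= 20:
                raise ConfigError(f"{self.locus_id}: desired-edit position {pos} outside 1..20")
            if ref != "A" or alt != "G":
                raise ConfigError(f"{self.locus_id}: desired edits must be A>G on the protospacer strand")
            if self.spacer[pos - 1] != "A":
                raise ConfigError(
                    f"{self.locus_id}: desired edit at position {pos} but spacer base is "
                    f"{self.spacer[pos - 1]}"
                )

    # -- coordinate helpers -------------------------------------------------

    def protospacer_position(self, ref_pos: int) -> int:
        """Protospacer numbering for a reference offset.

        Spacer bases are 1..20; the base immediately 5' of the spacer is −1
        (there is no position 0, matching A−2-style labels); PAM and
        downstream flank continue 21, 22, ...
        """
        off = ref_pos - self.spacer_start
        return off + 1 if off >= 0 else off

    def reference_position(self, proto_pos: int) -> int:
        if proto_pos == 0:
            raise ValueError("protospacer numbering has no position 0")
        off = proto_pos - 1 if proto_pos > 0 else proto_pos
        return self.spacer_start + off

    def quant_window(self) -> tuple[int, int]:
        """Half-open reference interval of the quantification window."""
        w = self.window_spec
        start = self.spacer_start - w.upstream_nt
        end = self.spacer_start + len(self.spacer) + w.pam_len + w.downstream_nt
        return max(start, 0), min(end, len(self.reference))

    def desired_ref_edits(self) -> frozenset[tuple[int, str]]:
        """Desired edits as (reference_position, alt_base)."""
        return frozenset(
            (self.reference_position(pos), alt) for pos, _ref, alt in self.desired_edits
        )


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred scores."""

    read_id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty read")
        if len(self.quals) != len(self.seq):
            raise ValueError("quality string length does not match sequence length")


# ---------------------------------------------------------------------------
# configuration loading


def _parse_desired_edits(token: str) -> frozenset[tuple[int, str, str]]:
    """Parse semicolon-joined ``pos:ref>alt`` tokens, e.g. ``5:A>G;6:A>G``."""
    edits = set()
    token = token.strip()
    if not token:
        return frozenset()
    for part in token.split(";"):
        part = part.strip()
        pos_s, _, change = part.partition(":")
        ref, _, alt = change.partition(">")
        if not pos_s or not ref or not alt:
            raise ConfigError(f"malformed desired-edit token {part!r}")
        edits.add((int(pos_s), ref.upper(), alt.upper()))
    return frozenset(edits)


_REQUIRED_FIELDS = ("locus_id", "reference", "spacer", "spacer_strand", "spacer_start", "pam")


def _locus_from_record(rec: dict) -> AmpliconLocus:
    for f in _REQUIRED_FIELDS:
        if f not in rec or rec[f] in ("", None):
            raise ConfigError(f"locus config missing required field {f!r}")
    edits = rec.get("desired_edits", "")
    if isinstance(edits, str):
        edits = _parse_desired_edits(edits)
    else:
        edits = frozenset((int(p), str(r).upper(), str(a).upper()) for p, r, a in edits)
    wkw = {
        k: int(rec[k]) for k in ("upstream_nt", "downstream_nt", "pam_len") if k in rec and rec[k] not in ("", None)
    }
    return AmpliconLocus(
        locus_id=str(rec["locus_id"]),
        reference=str(rec["reference"]),
        spacer=str(rec["spacer"]),
        spacer_strand=str(rec["spacer_strand"]),
        spacer_start=int(rec["spacer_start"]),
        pam=str(rec["pam"]),
        desired_edits=edits,
        window_spec=WindowSpec(**wkw),
    )


def load_locus_config(path: str | Path, references: Optional[str | Path] = None) -> list[AmpliconLocus]:
    """Load loci from a TSV (one locus per row) or JSON (list of objects).

    ``reference`` may be given inline or, when *references* points to a
    FASTA file, as the name of a record therein.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"locus config not found: {path}")
    ref_by_name: dict[str, str] = {}
    if references is not None:
        ref_by_name = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(references), "fasta")}

    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ConfigError("JSON locus config must be a list of objects")
    else:
        lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
        if not lines:
            raise ConfigError(f"empty locus config: {path}")
        header = lines[0].rstrip("\n").split("\t")
        records = [dict(zip(header, ln.rstrip("\n").split("\t"))) for ln in lines[1:]]

    loci = []
    for rec in records:
        if ref_by_name and rec.get("reference") in ref_by_name:
            rec = dict(rec, reference=ref_by_name[rec["reference"]])
        loci.append(_locus_from_record(rec))
    if len({l.locus_id for l in loci}) != len(loci):
        raise ConfigError("duplicate locus_id in config")
    return loci


# ---------------------------------------------------------------------------
# FASTQ I/O


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ or FASTQ.gz file (Sanger Phred+33)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            handle.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# filtering and merging


def mean_quality(read: ReadRecord) -> float:
    return sum(read.quals) / len(read.quals)


def mean_quality_filter(read: ReadRecord, threshold: float = 30.0) -> bool:
    """Pass iff the arithmetic mean Phred score is >= *threshold*."""
    if not read.seq:
        raise ValueError("empty read")
    return mean_quality(read) >= threshold


def merge_read_pair(r1: ReadRecord, r2: ReadRecord, min_overlap: int = 10) -> Optional[ReadRecord]:
    """Merge a read pair into a consensus read, or return None if unmergeable.

    r2 is reverse-complemented, the suffix of r1 is overlapped with the
    prefix of rc(r2) and the unique overlap length with the most matching
    bases (ties broken toward the longer overlap being rejected as
    ambiguous) is taken.  At disagreeing overlap positions the
    higher-quality base wins; agreeing positions keep the higher quality.
    """
    s2 = reverse_complement(r2.seq)
    q2 = list(reversed(r2.quals))
    best: Optional[tuple[int, int]] = None  # (matches, overlap_len)
    tie = False
    for ov in range(min(len(r1.seq), len(s2)), min_overlap - 1, -1):
        a = r1.seq[len(r1.seq) - ov :]
        b = s2[:ov]
        matches = sum(1 for x, y in zip(a, b) if x == y)
        if matches < 0.8 * ov:  # reject wildly discordant overlaps
            continue
        if best is None or matches > best[0]:
            best = (matches, ov)
            tie = False
        elif matches == best[0]:
            tie = True
    if best is None or tie:
        return None
    ov = best[1]
    off = len(r1.seq) - ov
    seq, quals = list(r1.seq[:off]), r1.quals[:off]
    for i in range(ov):
        b1, q1_ = r1.seq[off + i], r1.quals[off + i]
        b2, q2_ = s2[i], q2[i]
        if b1 == b2:
            seq.append(b1)
            quals.append(max(q1_, q2_))
        elif q2_ > q1_:
            seq.append(b2)
            quals.append(q2_)
        else:
            seq.append(b1)
            quals.append(q1_)
    seq.extend(s2[ov:])
    quals.extend(q2[ov:])
    return ReadRecord(r1.read_id, "".join(seq), quals)


# ---------------------------------------------------------------------------
# demultiplexing


def demultiplex(
    reads: Iterable[ReadRecord],
    loci: list[AmpliconLocus],
    min_score_frac: float = 0.6,
    margin: float = 1.0,
    scoring=None,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign pooled reads to loci by best semi-global alignment score.

    A read is assigned to the top-scoring locus (both orientations tried)
    when that score reaches ``min_score_frac`` of the read's self-alignment
    maximum and beats the runner-up by at least ``margin``; otherwise it
    goes to the unassigned bin.  Returns ``(assigned, unassigned)``.
    """
    from .align import Scoring, best_alignment_score

    if not loci:
        raise ValueError("at least one locus required")
    scoring = scoring or Scoring()
    assigned: dict[str, list[ReadRecord]] = {l.locus_id: [] for l in loci}
    unassigned: list[ReadRecord] = []
    for read in reads:
        self_max = scoring.match * len(read.seq)
        scores = sorted(
            ((best_alignment_score(read.seq, l.reference, scoring), l.locus_id) for l in loci),
            key=lambda t: (-t[0], t[1]),
        )
        best_score, best_id = scores[0]
        runner_up = scores[1][0] if len(scores) > 1 else float("-inf")
        if best_score >= min_score_frac * self_max and best_score - runner_up >= margin:
            assigned[best_id].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned
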