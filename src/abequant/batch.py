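"""Batch pipeline: QC → demultiplex → align → quantify → classify → triage.

One :func:`run_batch` call processes a sample sheet (sample_id, FASTQ
path(s), locus ids) against a locus configuration and writes, per
sample × locus, the position profile, editing statistics and allele-class /
quantification tables, plus one consolidated summary TSV.  Failures are
isolated per sample: one unreadable FASTQ yields an error row, not an
aborted batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .align import Scoring, orient_and_align
from .classify import TriageThresholds, compute_metrics, founder_triage, tally, to_quant_table
from .loci import (
    AmpliconLocus,
    ConfigError,
    mean_quality_filter,
    merge_read_pair,
    read_fastq,
)
from .quantify import a_to_g_frequencies, build_profile, cumulative_editing, indel_frequency, precision_metric

__all__ = ["RunConfig", "SampleResult", "run_batch", "load_sample_sheet", "analyze_reads"]


@dataclass
class RunConfig:
    sample_sheet: list[dict]  # rows: sample_id, fastq, [fastq2], locus_ids (list)
    loci: list[AmpliconLocus]
    output_dir: Path
    min_average_read_quality: float = 30.0
    merge_pairs: bool = False
    min_overlap: int = 10
    scoring: Scoring = field(default_factory=Scoring)
    min_score_frac: float = 0.6
    margin: float = 1.0
    triage: TriageThresholds = field(default_factory=TriageThresholds)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        known = {l.locus_id for l in self.loci}
        for row in self.sample_sheet:
            missing = set(row["locus_ids"]) - known
            if missing:
                raise ConfigError(
                    f"sample {row['sample_id']}: unknown locus id(s) {sorted(missing)}"
                )


@dataclass
class SampleResult:
    sample_id: str
    locus_id: str
    rows: dict
    error: Optional[str] = None


def load_sample_sheet(path: str | Path) -> list[dict]:
    """TSV with columns sample_id, fastq, optional fastq2, locus_ids (';'-joined)."""
    rows = []
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        rec = dict(zip(header, ln.split("\t")))
        if "sample_id" not in rec or "fastq" not in rec or "locus_ids" not in rec:
            raise ConfigError("sample sheet needs sample_id, fastq and locus_ids columns")
        rec["locus_ids"] = [x for x in rec["locus_ids"].split(";") if x]
        rows.append(rec)
    return rows


def analyze_reads(reads, locus: AmpliconLocus, scoring: Scoring = Scoring(), triage: TriageThresholds = TriageThresholds()) -> dict:
    """Run align → profile → classify → metrics → triage for one read set."""
    aligned = [orient_and_align(r, locus, scoring) for r in reads]
    profile = build_profile(aligned, locus)
    freqs = a_to_g_frequencies(profile, locus)
    counts = tally(aligned, locus)
    qt = to_quant_table(counts)
    metrics = compute_metrics(qt) if qt.Reads_aligned_all_amplicons > 0 else None
    call = founder_triage(metrics, counts, triage) if metrics else "not_high_confidence"
    return {
        "n_reads": len(reads),
        "profile": profile,
        "a_to_g": freqs,
        "indel_pct": indel_frequency(aligned, locus),
        "cumulative_pct": cumulative_editing(freqs),
        "precision": precision_metric(freqs) if freqs else 0.0,
        "counts": counts,
        "quant_table": qt,
        "metrics": metrics,
        "triage": call,
    }


def _summary_row(sample_id: str, locus_id: str, res: dict) -> dict:
    c, qt, m = res["counts"], res["quant_table"], res["metrics"]
    row = {
        "sample_id": sample_id,
        "locus_id": locus_id,
        "n_reads": res["n_reads"],
        "wt": c.wt,
        "desired_only": c.desired_only,
        "desired_bystander": c.desired_bystander,
        "bystander_only": c.bystander_only,
        "indel": c.indel,
        "short_reads_excluded": c.short_reads_excluded,
        "Reads_aligned_all_amplicons": qt.Reads_aligned_all_amplicons,
        "Reads_aligned": qt.Reads_aligned,
        "Unmodified": qt.Unmodified,
        "Modified": qt.Modified,
        "Discarded": qt.Discarded,
        "indel_pct": round(res["indel_pct"], 4),
        "cumulative_pct": round(res["cumulative_pct"], 4),
        "precision": round(res["precision"], 6),
        "triage": res["triage"],
        "error": "",
    }
    if m is not None:
        row.update(
            specified_incl_bystanders_pct=round(m.specified_incl_bystanders_pct, 4),
            specified_without_bystanders_pct=round(m.specified_without_bystanders_pct, 4),
            purity_pct="NA" if m.purity_pct is None else round(m.purity_pct, 4),
            indels_pct=round(m.indels_pct, 4),
        )
    return row


def run_batch(config: RunConfig) -> tuple[pd.DataFrame, int]:
    """Process every sample; returns (summary frame, exit status)."""
    from .loci import demultiplex

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    loci_by_id = {l.locus_id: l for l in config.loci}
    rows: list[dict] = []
    exit_status = 0

    header_lines = [
        f"# abequant {__version__}",
        f"# min_average_read_quality={config.min_average_read_quality}",
        f"# window=-{config.loci[0].window_spec.upstream_nt}..PAM+{config.loci[0].window_spec.downstream_nt}",
        f"# triage: desired_only>={config.triage.min_desired_only_pct}%, "
        f"unwanted{'<=' if config.triage.unwanted_inclusive else '<'}{config.triage.max_unwanted_pct}%",
        f"# scoring: match={config.scoring.match} mismatch={config.scoring.mismatch} "
        f"gap_open={config.scoring.gap_open} gap_extend={config.scoring.gap_extend}",
    ]

    for sample in sorted(config.sample_sheet, key=lambda r: r["sample_id"]):
        sid = sample["sample_id"]
        sample_loci = [loci_by_id[i] for i in sample["locus_ids"]]
        try:
            reads = list(read_fastq(sample["fastq"]))
            if config.merge_pairs and sample.get("fastq2"):
                mates = list(read_fastq(sample["fastq2"]))
                merged = []
                for r1, r2 in zip(reads, mates):
                    m = merge_read_pair(r1, r2, config.min_overlap)
                    if m is not None:
                        merged.append(m)
                reads = merged
            n_raw = len(reads)
            reads = [r for r in reads if mean_quality_filter(r, config.min_average_read_quality)]
            assigned, unassigned = demultiplex(
                reads, sample_loci, config.min_score_frac, config.margin, config.scoring
            )
        except Exception as exc:  # noqa: BLE001 — per-sample isolation
            exit_status = 1
            for locus in sample_loci:
                rows.append(
                    {"sample_id": sid, "locus_id": locus.locus_id, "error": str(exc)}
                )
            continue
        for locus in sample_loci:
            res = analyze_reads(assigned[locus.locus_id], locus, config.scoring, config.triage)
            res["n_raw"] = n_raw
            res["n_unassigned"] = len(unassigned)
            prefix = out / f"{sid}.{locus.locus_id}"
            res["profile"].frequencies().to_csv(
                f"{prefix}.nucleotide_percentage_summary.tsv", sep="\t", float_format="%.4f"
            )
            rows.append(_summary_row(sid, locus.locus_id, res))

    summary = pd.DataFrame(rows).sort_values(["sample_id", "locus_id"]).reset_index(drop=True)
    summary_path = out / "summary.tsv"
    with open(summary_path, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        summary.to_csv(fh, sep="\t", index=False)
    if (summary.get("error", pd.Series(dtype=str)).fillna("") != "").any():
        exit_status = 1
    return summary, exit_status
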