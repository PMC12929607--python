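# Methods

## Coordinate frame and windows

All analysis is performed on the protospacer strand. A locus whose spacer
anneals antisense to the sequenced amplicon is reverse-complemented once at
load; thereafter positions 1–20 run 5'→3' along the protospacer with
position 20 adjacent to the PAM. Upstream flank positions are labelled
−1, −2, … (no position 0), so the base two positions 5' of the spacer is
A−2 when it is an adenine. Internally coordinates are 0-based half-open;
protospacer labels appear only in reports.

Two windows serve two purposes, mirroring the two analysis modes of
amplicon base-editing quantification:

- the **spacer window** (positions 1–20 plus flanks) for per-position
  nucleotide profiles and A-to-G frequencies;
- the **quantification window** (spacer −7 nt … PAM +3 nt, 33 nt by
  default) for allele classification and indel accounting.

## Read processing

Reads pass a mean-Phred filter (arithmetic mean ≥ 30 by default). Paired
reads may be merged: the mate is reverse-complemented, the overlap with
the most matching bases (≥ `min_overlap`, ≤ 20% mismatches) is taken when
unique, and disagreements resolve to the higher-quality base. Ambiguous
overlaps (e.g. inside short repeats) leave the pair unmerged rather than
guessing. Pooled reads are demultiplexed to the locus with the best
semi-global alignment score over both orientations, requiring ≥ 60% of the
read's self-alignment score and a ≥ 1-point lead over the runner-up;
everything else lands in an explicit unassigned bin, so read attrition is
auditable.

## Alignment

Reads are aligned semi-globally: global in the read, free end gaps in the
reference, affine gap costs (a length-L gap scores `open + (L−1)·extend`).
Defaults `match=+2, mismatch=−4, gap_open=−10, gap_extend=−1` make one
substitution cheaper than two gaps, the usual regime for amplicon
resequencing; all four are configurable. The engine is Biopython's
`PairwiseAligner`; among co-optimal alignments the first in its
deterministic enumeration order is reported, so outputs are
bit-reproducible. Note that gap *placement* within a homopolymer run is
chosen among co-optimal shifts; counts of indels and their window overlap
do not depend on the choice. `N` calls are evidence of nothing: they are
never substitutions and are tallied separately in profiles. The test suite
checks scores against an independently written Gotoh dynamic program on
random sequence pairs.

## Per-position statistics

Profile depth at a position is the number of reads covering it (including
`N` and deletion calls); A-to-G percent is G count / depth × 100.
Zero-depth positions report *not available*, never 0 — no coverage is not
no editing. Percentages are computed over all covering reads, including
indel-carrying ones (whose deleted positions count as `-`, not as edits);
this choice is documented because tools differ on it. Cumulative editing
is the plain sum of A-to-G percentages over spacer positions 1–20 and may
exceed 100. The precision ratio divides the second-highest adenine
frequency by the highest; one adenine, or a zero maximum, gives 0.

## Allele classification and metrics

Within the quantification window each read is classified by its
substitution set `S` versus the locus's desired set `D`: short read (window
not covered) → excluded; any window-overlapping indel → *indel* (indels
trump substitutions, matching discard-indel-reads accounting); `S = ∅` →
*WT*; `S = D` → *desired-only*; `S ⊃ D` → *desired + bystander*; otherwise
*bystander-only*. Partial desired sets are deliberately bystander-only: at
a two-adenine target, editing one adenine encodes a different amino acid
than intended. Substitutions outside the window are ignored — the window
defines the allele. Indel overlap is closed-interval; an insertion at
either window boundary counts.

The class tallies map to quantification-table columns
(`Reads_aligned` = desired-only + desired+bystander, `Unmodified` =
desired-only, `Modified` = desired+bystander, `Discarded` = indel) and the
four metrics follow as simple ratios (README). When no read carries the
full desired set, purity is *not available* rather than 0 or 100. Founder
triage calls *high confidence* at desired-only ≥ 20% and unwanted ≤ 2.5%;
the comparator is inclusive (≤) by default and configurable, since both
strict and inclusive readings are in circulation and the difference is
negligible for continuous percentages.

## Guide design

Spacer enumeration brute-forces every 20-nt frame on both strands of the
coding context, keeping frames that place all required adenines (A→G on
the protospacer strand; equivalently T→C on the coding strand for
antisense guides) within the design window (default positions 3–11). Edit
sets are minimal: a superset of a sufficient edit set is not proposed.
Candidates sort by distance of the target adenine from positions 5–6, then
by fewest window adenines — a convention of this package, not a published
ranking. PAM classes partition N-free trimers: NGG (bases 2–3 = GG), NRN
(middle purine), NYN (middle pyrimidine). Codon consequences use the
standard genetic code only, evaluating multi-adenine codons jointly. A 5'
G is prepended to the expression-construct spacer when needed, but
protospacer numbering always refers to the 20-nt genomic spacer.
Off-target sites are supplied by the user (genome-wide discovery is out of
scope) and annotated with mismatch count/positions and a lowercased
display string.

## Simulator

A molecule is engaged with probability `engage_prob`; given engagement,
each profiled adenine converts A→G independently with probability `w_i`,
unconverted profiled adenines convert A→C with `atoc_prob`, window
cytosines convert C→T with `ctot_prob`, and with probability `indel_prob`
an indel of ±1–3 nt is placed uniformly in the quantification window.
Sequencing adds independent substitution errors (default 0.001) and Phred
scores drawn around Q33 (σ = 3, clamped to 2–41), keeping the Q30 filter
meaningful. Conditional independence of positions given engagement is the
simplest generative model consistent with per-position frequencies;
deaminase processivity (correlated co-editing) is deliberately not
modelled, so simulated desired+bystander co-occurrence is a lower bound on
what a processive enzyme would produce. Real-data features not emulated:
PCR duplicates and chimeras, position-dependent quality decay, strand
bias, and large structural variants — passing tests therefore demonstrate
correctness of the accounting, not robustness to every sequencing
artefact.

Editor presets anchor to reported per-position activity: `abe9_like` is
nonzero only at positions 4–6 (w = 0.03/0.345/0.30 — minimal A4, dominant
A5–A6), `abe8e_like` spans positions 2–14 peaking at A5 (0.436) with a
decaying shoulder through A13; shoulder values between the anchored points
are a smooth interpolation chosen once. A `peak` argument rescales a
profile for activity-matched comparisons.

Two sampling modes: *population* (every read an independent molecule — a
transfected cell pool; per-position read counts are exactly binomial,
which the parameter-recovery tests exploit) and *founder* (K lineage
alleles drawn once, weights from Dirichlet(α); reads sample lineages —
a mosaic F0 biopsy). Defaults K = 4, α = 1 (uniform simplex) expose
mosaicism as a tunable stressor; the biology of lineage number is not
claimed. The closed form

    purity = 100 × Π_{b ∉ D} (1 − w_b)(1 − atoc) × Π_{c ∈ window C} (1 − ctot)

gives the probability that an engaged, fully-desired-edited molecule picks
up no bystander, and matches Monte-Carlo pipeline purity because generator
and formula share the independence assumption. Off-target panels scale
engagement by an attenuation factor in the spacer mismatch count
(default 4^−m, configurable, required non-increasing with attenuation(0)=1)
— a simulator convention, not an empirical mismatch-tolerance law.

All randomness flows through one seeded `numpy` generator per call;
identical seeds give byte-identical FASTQ and reports.

## Problem sizes and numerical conventions

Simulation-based checks use 2,000–10,000 reads per condition and
80–120-nt amplicons, sizes at which binomial standard errors separate the
tested effects cleanly. Statistical recovery tests use 3-standard-error
bounds (≈ 99.7% coverage per comparison). Reported percentages are
rounded to 0.1 in TSV outputs but compared at full precision in tests.
Degenerate inputs are contracts, not crashes: empty read sets give
zero-depth profiles; zero aligned reads make ratio metrics errors or
*not available* as documented above.

## Known limitations

No long-range haplotype phasing beyond the amplicon; no zygosity or
mosaicism deconvolution from biopsy fractions (lineage weights are not
identifiable from marginal allele fractions alone); no adapter trimming or
index demultiplexing (assumed resolved upstream); numeric parity with any
particular external quantification tool is approximate since alignment
parameters and window conventions differ between tools, while the metric
identities (e.g. purity ≡ 100 × Unmodified / Reads_aligned) hold exactly.
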