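# Methods

## Scope and model

`vnarkit` characterizes repertoires of vNAR domains — the single variable
domains of shark IgNAR antibodies. A vNAR is a ~100–115-residue Ig-fold
β-sandwich pinned by a canonical disulfide between framework cysteines near
positions 22 and 83. It carries two antigen-contacting loops (CDR1, CDR3; no
CDR2) and two smaller hypervariable loops (HV2, HV4). Library clones are
inserted between NcoI (`CCATGG`) and NotI (`GCGGCCGC`) sites of a phagemid;
the ATG of the start codon is embedded in the NcoI site.

The pipeline has five analysis stages (IO/QC, region annotation, type
classification, diversity statistics, panning analysis) plus a synthetic
repertoire generator that provides ground-truth-labeled inputs.

## Reading-frame geometry

Flank detection is exact-match, choosing the first 5′-site occurrence and
the last 3′-site occurrence — the pair that maximizes the insert. Both
restriction sites are palindromes, so strand orientation cannot be decided
by motif presence alone; a read is reverse-complemented when the forward
strand lacks a valid 5′-before-3′ arrangement and the reverse strand has
one.

In this construct the NotI site lies in frame such that its first two bases
complete the insert's final codon. The coding region therefore runs from the
ATG inside `CCATGG` through the `GC` opening `GCGGCCGC`; its length equals
`NotI_start − NcoI_start` and is a multiple of three for an intact clone
(`CCATGG` + 330 nt + `GCGGCCGC` → a 336-nt coding region, 112 residues).
QC flags: `frameshift` when that length is not a codon multiple,
`premature_stop` when a stop codon precedes the 3′ site, `untranslatable`
when no ATG is available under the flank policy, `missing_5p/3p_flank` for
absent sites, and non-fatal `too_short` below 80 aa (configurable; vNAR
domains are ~100–115 aa, so 80 guards region annotation without discarding
truncation variants). Reads lacking a flank are flagged and excluded from
downstream statistics by default, since their insert boundaries are
undefined. FASTQ qualities are reduced to a per-read mean and never used for
filtering.

## Anchor-offset region scheme

Region boundaries are fixed offsets from the two canonical cysteines rather
than an IMGT/Kabat-style renumbering. Anchors are found by nearest-Cys
search in windows 22±3 and 83±6 (configurable). With anchors `c1`, `c2`:
FR1 ends at `c1+2`; CDR1 is the 9 residues `c1+3 … c1+11` (25–33 for
`c1 = 22`); HV2 and HV4 sit at offsets reproducing 44–51 and 60–65; FR3b
ends at `c2+3`; CDR3 starts at `c2+4` and ends before the first match of the
FR4 motif `[YW]G.G` (configurable) at or after the CDR3 start; FR4 runs to
the end. All coordinates are 1-based inclusive. Length-variant CDR3s are
absorbed between `c2+4` and the FR4 motif; CDR1 is fixed-width, with indels
pushed into FR2, which is the simplest faithful choice given the limited
CDR1 diversity of naive vNAR repertoires. This offset scheme is a
reconstruction — crystal-structure coordinates generalized by anchoring —
not a published numbering, and every offset is exposed on `RegionScheme`.

Degenerate inputs: a missing anchor gives status `no_anchor`; an
unplaceable layout, a missing FR4 motif, or a CDR3 length outside 4–34
gives `atypical_spacing`. Only status-`ok` clones (whose nine spans provably
tile `1..len`) enter classification and diversity statistics; the rest are
reported separately.

## Type rules

Evidence per clone: CDR1 cysteine positions, CDR3 cysteine count, and the
Cys29/Trp30 pair (positions resolved relative to `c1`). Rules fire in strict
precedence III → IIa → I → IIb → IV (see the classifier docstring). The
precedence resolves the overlaps in the textual definitions: a clone with
cysteines in both loops and an even CDR3 count is IIa (interloop-capable),
not I; an odd CDR3 count with a Cys-free CDR1 is IIb (the unpaired cysteine
cannot close a loop-loop bond). Trp30 without Cys29, or Cys29 without Trp30,
is not type III. CDR1 cysteines count anywhere in CDR1 by default
(`cdr1_cys_anywhere=False` restricts to position 29 — the alternative
reading). HV2/HV4 cysteines are ignored for typing but surfaced as
warnings. The canonical cysteines lie in framework spans and are excluded by
construction.

## Diversity statistics

Uniqueness is exact amino-acid identity over the full translated domain
(first occurrence kept). The unique-CDR3 partition counts clones whose CDR3
string occurs in exactly one unique clone; the CDR3 cysteine histogram is
taken over that unique-CDR3 subset, matching how library characterizations
report it. CDR1 variability is the percentage of unique clones whose CDR1
differs from the modal CDR1 string — an operational definition chosen here
(none is standard). Percentages are half-up at the printed precision (one
decimal for type shares, integers for CDR3-level shares); published tables
are not perfectly consistent in their rounding, and the convention is
centralized and documented rather than matched case by case.

## Panning arithmetic

A well set is positive when antigen OD ≥ 4 × the **maximum** negative
control (BSA, milk, unrelated antigen) — the conservative denominator choice;
the threshold is inclusive and configurable. With replicate assays a clone
is a consistent binder when positive in ≥ 3 replicates (all of them when
fewer were run); single-well screens reduce to the plain rule. Positives are
binned by mean antigen OD: high > 1.0, medium 0.5–1.0 (1.0 inclusive in
medium), low < 0.5. Round and antigen summaries report count-derived
percentages only; enrichment trajectories flag, but never enforce,
nondecreasing positivity and nonincreasing uniqueness.

## Synthetic repertoire generator

The generator emulates a naive bamboo-shark-style vNAR library:

* **Composition** — per-type counts by largest-remainder apportionment of
  the spec proportions (default: the published composition), exact at any n;
  defect and duplicate counts are likewise rounded counts, not Bernoulli
  draws. This makes small-library expectations exact while sequence content
  stays stochastic.
* **Scaffold** — one fixed framework (Cys22/Cys83, a `YGGG` FR4 anchor, no
  other framework cysteines) with per-position substitution noise (default
  0.01) over FR2/HV2/FR3a/HV4, drawn from an alphabet excluding C/G/W/Y so
  anchors, the FR4 motif and the type rules are never disturbed.
* **Loops** — CDR3 lengths from a discrete Gaussian-shaped model on 6–28
  renormalized so lengths 15–16 carry 0.5 mass (the published range and
  modal band; no fuller distribution is published, so the shape is this
  package's choice). Per-type CDR3 cysteine-count models are validated
  against the classification rules (type I even ≥ 2, IIa ≥ 1, IIb odd on
  its CDR3 branch, IV zero); type IIb clones split 50/50 between
  CDR1-only-Cys and odd-CDR3-Cys realizations. Cys/Trp placements (position
  27 for IIa/IIb, 29+30 for III) guarantee the intended rule fires. Leu31
  is present with probability 0.95 in every type; CDR3 content is
  rejection-sampled so no premature FR4-motif match can shorten annotation.
* **Nucleotides** — reverse translation through a fixed one-codon-per-residue
  table, embedded so the NcoI ATG starts the frame and the NotI `GC` closes
  it; defects are injected as a one-base NotI corruption, a TAA at scheme
  position 40, or a one-base deletion mid-insert.
* **Panning data** — exact per-round binder counts; positive ODs from a
  truncated normal whose mean rises 0.75 → 1.2 (sd 0.35) across rounds so
  ~70% of final-round positives exceed OD 1.0, always clearing four-fold
  over the strongest negative; non-binders draw folds strictly below four.
* **Determinism** — one seeded `numpy` generator threads through all draws;
  identical seeds give byte-identical libraries.

What the generator does **not** model: position-specific framework profiles
(one scaffold stands in for germline diversity), PCR amplification bias and
polymerase error spectra, phage growth competition between clones, and
sequencing error. Consequently, passing round-trip tests demonstrates the
internal consistency of QC, annotation, classification and counting — not
robustness to the alignment ambiguity and noise of real reads, where the
fixed-offset scheme would face indel-bearing frameworks it has not seen.

## Problem sizes and numerical choices

The test suite exercises libraries of 100–10,000 clones; the scaled
replication run uses 23,841 clones (one tenth of the published unique-sequence
count) and completes in seconds. Rounding is Decimal-based half-up
(`round_half_up`), avoiding float banker's rounding. Nearest-anchor ties
cannot arise with the default scaffold (exact Cys22/Cys83); for shifted
anchors the nearer candidate wins, with the earlier position on exact ties.
Apportionment ties break by type-label order, making every count
deterministic.

## Known limitations

* The anchor-offset scheme assumes a full-length domain beginning at the
  NcoI ATG; N-terminally truncated reads annotate as `no_anchor`.
* CDR1 is fixed-width: a genuine CDR1 indel shifts downstream framework
  offsets and will typically surface as `atypical_spacing` rather than a
  shifted CDR1.
* The CDR1-variability statistic is definition-dependent (distance from the
  modal CDR1) and counts label-driven cysteine placements as variability.
* Published percentage tables mix rounding conventions; this package's
  half-up convention reproduces most but not all printed values, and the
  unique-CDR3 subtotal it uses as a denominator is itself a printed
  approximation of the underlying counts.
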