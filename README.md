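# vnarkit

Characterization toolkit for shark **vNAR** repertoires — the ~12 kDa
variable domains of the IgNAR heavy-chain-only antibodies of cartilaginous
fish, cloned as phage-display libraries between NcoI (`CCATGG`) and NotI
(`GCGGCCGC`) restriction sites.

The package is aimed at groups building and screening naive single-domain
antibody libraries. It takes cloned-insert reads (Sanger or merged NGS
amplicons, FASTA/FASTQ) through the full characterization path:

1. **ORF quality control** (`vnarkit.io`) — exact-match flank detection with
   strand re-orientation, translation from the ATG embedded in the NcoI
   site, and flagging of defective ("bald") clones: missing flanks,
   premature stop codons, frameshifts.
2. **Region annotation** (`vnarkit.regions`) — the nine-region layout
   FR1 / CDR1 / FR2 / HV2 / FR3a / HV4 / FR3b / CDR3 / FR4, delimited by
   fixed offsets from the two canonical cysteines (Cys22/Cys83) that form
   the intradomain disulfide, with CDR3 length variation absorbed between
   the second anchor and a `[YW]G.G` FR4 motif. With the default scheme a
   10-residue CDR3 occupies positions 87–96, CDR1 25–33, HV2 44–51,
   HV4 60–65.
3. **Type classification** (`vnarkit.classify`) — the five-way vNAR typing
   from noncanonical loop cysteines, evaluated in strict precedence:
   **III** (Cys29+Trp30 in CDR1) → **IIa** (Cys in both CDR1 and CDR3, the
   interloop disulfide) → **I** (even CDR3 Cys count ≥ 2, Cys-free CDR1) →
   **IIb** (Cys in exactly one loop) → **IV** (no noncanonical Cys).
4. **Diversity statistics** (`vnarkit.diversity`) — unique protein
   sequences, per-type composition, unique-CDR3 partition, CDR3 length and
   cysteine histograms, CDR1 variability (all percentages half-up at the
   printed precision).
5. **Biopanning analysis** (`vnarkit.panning`) — the ≥4-fold-over-background
   phage-ELISA positivity rule (against the *maximum* negative control),
   OD binning (high > 1.0, medium 0.5–1.0, low < 0.5), per-round positivity
   and per-antigen unique-binder percentages, enrichment trajectories.
6. **Synthetic repertoires** (`vnarkit.simulate`) — a ground-truth-labeled
   generator of libraries and phage-ELISA screens with exact (apportioned)
   type/defect/binder counts, used throughout the test suite and for scaled
   replication of the published characterization.

## Worked example

```python
import vnarkit as vk

spec = vk.fig3a_spec(n_clones=5_000, seed=42)   # published type composition
library = vk.generate_library(spec)

records = [vk.translate_and_qc(c) for c in vk.library_to_clones(library)]
usable = [r for r in records if r.aa is not None and r.is_complete_insert]
unique, _ = vk.dedupe_sequences(usable)
maps = vk.annotate_repertoire(unique)
calls, _ = vk.classify_repertoire(maps, unique)
print(vk.summarize_repertoire(calls, maps).to_text())
```

prints

```
Unique vNAR protein sequences: 5,000
  type I         760  (15.2%)
  type IIa     1,198  (24.0%)
  type IIb     2,073  (41.5%)
  type III         0  (0.0%)
  type IV        969  (19.4%)
Clones with a unique CDR3: 5,000 (100%)
CDR3 length range: 6-28 aa
CDR3 cysteines (among unique CDR3s): 0 Cys: 40%, 1 Cys: 30%, 2 Cys: 19%, 3 Cys: 6%, 4 Cys: 3%, 5 Cys: 1%
CDR1 variability: 47.3%
```

The per-type percentages equal the generator's composition exactly because
type counts are apportioned by largest remainder rather than sampled; every
clone classifies back to its generated label. At n = 5,000 the eight
type-III seats of the full-scale composition round down to zero. The scripts
in `examples/` walk through this pipeline, the arithmetic on the published
counts, and a panning enrichment analysis.

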