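"""Characterize a synthetic naive vNAR library end to end.

Generates a 5,000-clone library with the published type composition, runs
flank/ORF QC, region annotation and type classification, and prints the
repertoire summary. The per-type percentages should match the generator's
composition exactly (type counts are apportioned, not sampled); CDR3 lengths
fall in 6-28 with roughly half the clones at 15-16 residues.
"""

import vnarkit as vk

spec = vk.fig3a_spec(n_clones=5_000, seed=42)
library = vk.generate_library(spec)

records = [vk.translate_and_qc(c) for c in vk.library_to_clones(library)]
print(f"Complete inserts: {100 * vk.completeness_rate(records):.1f}%")

usable = [r for r in records if r.aa is not None and r.is_complete_insert]
unique, multiplicity = vk.dedupe_sequences(usable)
maps = vk.annotate_repertoire(unique)
calls, excluded = vk.classify_repertoire(maps, unique)

summary = vk.summarize_repertoire(calls, maps)
print(summary.to_text())

lo, hi, band = vk.cdr3_length_stats(maps)
print(f"CDR3 lengths {lo}-{hi}; fraction at 15-16: {band:.2f}")
print(f"Leu31 conservation: {vk.leu31_fraction(maps):.3f}")

truth = {c.clone_id: c.true_label for c in library}
agreement = sum(c.label == truth[c.clone_id] for c in calls) / len(calls)
print(f"Classifier agreement with generator ground truth: {100 * agreement:.1f}%")
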