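"""Repertoire percentages from the published NGS characterization counts.

The study's per-type counts and CDR3 statistics are printed tables; this
script feeds them through the same percentage arithmetic the pipeline uses
(half-up rounding at the printed precision) to reproduce the headline
numbers: 15.2% type I, 41.5% type IIb, 38% unique CDR3s, and the CDR3
cysteine composition.
"""

import vnarkit as vk

total = sum(vk.FIG3A_COUNTS.values())
print(f"Unique vNAR protein sequences: {total:,}")

pct = vk.type_percentages(vk.FIG3A_COUNTS, ndigits=1)
for label in vk.TYPE_LABELS:
    print(f"  type {label:<3} {vk.FIG3A_COUNTS[label]:>9,}  ({pct[label]}%)")

print(
    f"Unique CDR3s: {vk.N_UNIQUE_CDR3:,} "
    f"({vk.percentage(vk.N_UNIQUE_CDR3, total, 0)}% of unique sequences)"
)
for n_cys, count in sorted(vk.FIG3C_CDR3_CYS_COUNTS.items()):
    print(
        f"  {n_cys} Cys in CDR3: {count:>7,} "
        f"({vk.percentage(count, vk.N_UNIQUE_CDR3, 0)}%)"
    )

print("\nPer-antigen screening (clones sequenced -> unique binders):")
for antigen, (n_seq, n_unique) in vk.TABLE1_SCREENING.items():
    print(f"  {antigen:<18} {n_unique:>2}/{n_seq:<2} ({vk.percentage(n_unique, n_seq, 0)}%)")
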