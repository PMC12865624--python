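"""Biopanning enrichment analysis on a synthetic phage-ELISA screen.

Simulates screens after rounds 2-4 with binder fractions rising 10% -> 20%
-> 40% (30 clones per round, as in a typical plate), applies the four-fold
ELISA positivity rule, and prints the per-round summaries and the
enrichment trajectory. Positivity should rise across rounds while the
high-OD share of positives grows toward ~70% by round 4.
"""

import vnarkit as vk

records, truth = vk.generate_panning_dataset(
    binder_fraction_by_round=[0.1, 0.2, 0.4], n_screened_per_round=30, seed=42
)

summaries = []
for rnd in (2, 3, 4):
    recs = [r for r in records if r.round_index == rnd]
    summ = vk.summarize_round(recs)
    summaries.append(summ)
    print(
        f"round {rnd}: {summ.n_positive}/{summ.n_screened} positive "
        f"({summ.positivity_pct}%), OD bins {summ.od_bins}, "
        f"high-OD share of positives {summ.high_od_fraction_of_positives:.2f}"
    )

# uniqueness among the positives, emulating per-round sequencing follow-up
antigen_summaries = {
    2: vk.AntigenScreenSummary("antigen", 3, 3, 100),
    3: vk.AntigenScreenSummary("antigen", 6, 5, 83),
    4: vk.AntigenScreenSummary("antigen", 12, 3, 25),
}
traj = vk.enrichment_trajectory(summaries, antigen_summaries)
print(traj.table.to_string(index=False))
print(
    f"positivity nondecreasing: {traj.positivity_nondecreasing}; "
    f"uniqueness nonincreasing: {traj.uniqueness_nonincreasing}"
)
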