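"""From raw awakening records to participant-based percentages.

Generates a small participant-level dataset in the shape of a
DREAM-database export, then applies the filtering rules: healthy
participants only, known sleep stages only, study-scoped participant
IDs, and per-participant report-type percentages kept only when backed
by at least three awakenings in the stage group (N1/N2/N3 pool to NREM).
"""

import dreamwake as dw

cfg = dw.SyntheticConfig(n_studies=4, participants_per_study=12, seed=5)
records, _ = dw.generate_awakenings(cfg)
print(f"{len(records)} awakenings from {records['participant_uid'].nunique()} participants\n")

for group in ("NREM", "REM"):
    rates = dw.participant_rates(records, group, min_n=3)
    n_kept = rates["participant_uid"].nunique()
    recall = rates[rates.report == "with_recall"]
    print(
        f"{group}: {n_kept} participants with >=3 awakenings; "
        f"mean with-recall {100 * recall['rate'].mean():.1f}%, "
        f"between-participant SD {dw.sd_statistic(100 * recall['rate']):.1f} pp"
    )

print(
    "\nEach participant contributes one percentage per report type and stage"
    "\ngroup, computed as an exact count ratio; participants with too few"
    "\nawakenings are dropped so a single lucky awakening cannot masquerade"
    "\nas a 100% recaller."
)
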