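"""Do participants differ in dream recall beyond age, sex and study?

Runs the stratified permutation test on two synthetic cohorts at the
scale of the participant-level database (18 studies, ~27 participants
each): one generated WITH inter-individual differences (a participant
random effect of SD 1.0 on the recall logit) and one without (the null).
Report labels are reshuffled only within study x sex x age-group (x NREM
substage) strata, so any excess variability in participant percentages
must come from participant identity itself.
"""

import dreamwake as dw

for tau, label in ((1.0, "with inter-individual differences (tau=1.0)"),
                   (0.0, "null cohort (tau=0)")):
    cfg = dw.SyntheticConfig(tau=tau, seed=1)
    records, _ = dw.generate_awakenings(cfg)
    res = dw.run_permutation_test(
        records,
        dw.PermutationConfig(
            stage_group="NREM", report="with_recall", n_resamples=2000, seed=2
        ),
    )
    print(f"{label}:")
    print(
        f"  observed SD {res.observed_sd:.1f} pp vs null mean {res.null_mean:.1f} pp"
        f" (null SD {res.null_sd:.2f}); p_raw = {res.p_raw:.4g}"
        f" [{res.n_participants} participants, {res.n_studies} studies,"
        f" B = {res.n_resamples}]"
    )

print(
    "\nWhen participants truly differ, the observed between-participant SD"
    "\nsits well above the permutation null and the upper-tail p-value is"
    "\ntiny.  In the null cohort the observed SD lands inside the shuffled"
    "\ndistribution; its p-value is uniform under the null, so single draws"
    "\ncan still be small by chance (the suite's calibration test checks"
    "\nthe long-run 5% rejection rate).  Percentages are NREM"
    "\nexperience-with-recall rates."
)
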