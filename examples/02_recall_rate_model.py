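"""Modelling recall rates against sleep stage and study context.

Study-level recall percentages are not published in machine-readable
form alongside the packaged context table, so this example simulates a
study table with a known ground truth — calling participants by name
raises experience-with-recall rates by 10 percentage points over an
alarm — and shows the model pipeline recovering that effect: OLS on
stacked (study x stage) observations, estimated-marginal-mean pairwise
contrasts, Benjamini-Hochberg correction over the model's test family,
and Cohen's d with effect-size categories.
"""

import dreamwake as dw
from dreamwake.review_stats import contrasts_to_frame

table, truth = dw.generate_study_table(
    coefficients={("method", "name"): 0.10},
    noise_sd=0.02,
    n_studies=60,
    seed=7,
)
print(f"simulated {len(table)} studies; true effects: {truth}\n")

fit, family = dw.review_model(table, "with_recall")
frame = contrasts_to_frame(family)
print(frame.round(4).to_string(index=False))

name_alarm = next(r for r in family if "name" in r.label and "alarm" in r.label)
print(
    f"\nThe {name_alarm.label} contrast is {name_alarm.estimate:+.3f} on the"
    "\nproportion scale: the simulated +0.10 name-vs-alarm advantage is"
    f"\nrecovered (d = {name_alarm.d:.2f}, {name_alarm.category}; BH-corrected"
    f"\np = {name_alarm.p_cor:.2g}).  Stage contrasts recover the built-in"
    "\nNREM deficit relative to REM and wake."
)
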