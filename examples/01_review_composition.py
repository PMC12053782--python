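"""Composition of the reviewed awakening studies.

Loads the packaged table of 69 awakening studies (2000-2024) and reports
how the study designs are distributed: which question participants were
asked after being woken, whether awakenings were repeated within a
recording, where the sleep happened, over how many days, and whether it
was night sleep or naps.
"""

import dreamwake as dw

table = dw.load_table1()
print(f"{len(table)} reviewed awakening studies\n")

for factor in ("question", "repeated", "setting", "days", "sleep_type", "method"):
    comp = dw.composition_stats(table, factor)
    shares = ", ".join(
        f"{level} {100 * prop:.1f}% ({comp.counts[level]})"
        for level, prop in sorted(comp.proportions.items(), key=lambda kv: -kv[1])
    )
    print(f"{factor:>10}: {shares}   [missing: {comp.n_missing}]")

print(
    "\nEach percentage is the share of studies (with a known level) using that"
    "\ndesign choice; e.g. asking 'What went through your mind?' dominates, and"
    "\nmost protocols woke participants repeatedly in the laboratory at night."
)
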