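"""Score go/no-go behaviour and plot accuracy around the task switches.

A trial is correct when the animal licks inside the 1-2.5 s response window
on rewarded (S+) trials and withholds licking on non-rewarded (S-) trials.
The switch-aligned curve shows how fast performance recovers after the task
changes (trial 0 = first post-switch trial).
"""

import bulbswitch as bw

cohort = bw.generate_cohort(bw.GeneratorConfig(lapse_rate=0.15), seed=4)
sessions = [s for s, _ in cohort]

for session in sessions:
    report = bw.score_behaviour(session)
    print(f"{session.session_id}: {report.percent_correct:.1f}% correct")

curves = bw.switching_curve(sessions)
fc = curves["fine_to_coarse"]
window = fc.loc[-3:3]
print("\naccuracy around the fine -> coarse switch (mean over sessions):")
for idx, row in window.iterrows():
    print(f"  trial {idx:+d}: {100 * row['mean']:5.1f}% +/- {100 * row['sem']:4.1f} "
          f"(n={int(row['n'])})")
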