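"""Postural balance on compliant and oscillating surfaces.

Runs scaled-down versions of the two standing-balance protocols on a
synthetic subject and reports TOTEX — the total excursion (path length)
of the net center of pressure.  More sway means a larger TOTEX and less
stable standing.  Trials here are 15 s (the full protocol uses 60 s) so
the example runs in seconds; the ordinal effects are the same.
"""

import collections

import numpy as np

from twinplat import default_subject, run_active_balance, run_passive_balance

subject = default_subject()

print("passive protocol: quiet standing on a rendered surface")
outcomes = run_passive_balance(subject, trials_per_level=2, seed=1, duration_s=15.0)
by_condition = collections.defaultdict(list)
for o in outcomes:
    by_condition[o.condition].append(o.totex_cm)
for label in ("k=10000", "k=500", "k=250"):
    vals = by_condition[label]
    print(f"  {label:>8} Nm/rad : TOTEX {np.mean(vals):6.1f} cm (n={len(vals)})")
print("  -> softer surfaces amplify sway: TOTEX rises as stiffness falls\n")

print("active protocol: 90deg-offset sinusoidal platform oscillation")
outcomes = run_active_balance(
    subject, amplitudes_deg=(0.5, 1.5), frequencies_hz=(0.5, 1.5),
    trials_per_cell=1, seed=1, duration_s=15.0,
)
for o in sorted(outcomes, key=lambda o: o.condition):
    print(f"  {o.condition:>18} : TOTEX {o.totex_cm:6.1f} cm")
print("  -> sway grows with both oscillation amplitude and frequency")
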