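"""Power lost to measurement error, and the sample size that buys it back.

For a design intended to detect a nutrient-outcome correlation with 80%
power at n = 50 (two-sided alpha = .05), an app measure that agrees with
the reference at correlation r attenuates the detectable association to
rho x r.  The printed loss is in percentage points of power; the inflation
is the percent increase in sample size restoring the 80% target.
"""

from nutripair import (
    PowerSimConfig,
    power_curves,
    power_loss_at_target,
    sample_size_inflation,
)

print(f"{'agreement r':>11s} {'power loss (pts)':>17s} {'inflation @50':>14s} {'@500':>7s}")
for r in (0.96, 0.90, 0.80, 0.53):
    curve = power_curves(config=PowerSimConfig(mode="analytic"), r_nm=r, n=50)
    loss = power_loss_at_target(curve, 0.80)
    i50 = sample_size_inflation(r, 50)
    i500 = sample_size_inflation(r, 500)
    print(f"{r:11.2f} {loss:17.1f} {i50:13.1f}% {i500:6.1f}%")

print(
    "\nA weakly agreeing measure (r ~ 0.5, typical for app-reported sodium "
    "or cholesterol)\nneeds roughly 3x the sample to restore the intended power."
)
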