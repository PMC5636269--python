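"""Simulated anti-PDL1 checkpoint blockade: one coupled treated/untreated pair.

Treatment from day 20 rescales the suppression probability by (1 - m_supp)
with m_supp = 0.8.  Both arms share the seed and the full pre-treatment
trajectory, so the printed difference is attributable to the blockade alone.
The shrinkage ratio is the post/pre total-cancer-count ratio
(1 equilibrium, 0 elimination, >1 progression).
"""

from tmesim import run_paired, quadrant_config, shrinkage_ratio

for quadrant in ("high_ka_high_ki", "low_ka_high_ki"):
    config = quadrant_config(quadrant, n=50, duration_days=35.0,
                             treatment_start_day=20.0)
    pair = run_paired(config, seed=1)

    def count(ts, day):
        row = ts.iloc[(ts["time_d"] - day).abs().idxmin()]
        return int(row.cancer_pdl1_neg + row.cancer_pdl1_pos)

    pre = count(pair.treated_ts, 20.0)
    post_t = count(pair.treated_ts, 35.0)
    post_u = count(pair.untreated_ts, 35.0)
    label = shrinkage_ratio(pair.treated_ts, 20.0, 35.0)
    print(f"{quadrant}: day-20 count {pre}, day-35 treated {post_t}, "
          f"day-35 untreated {post_u}")
    print(f"  shrinkage ratio {label.shrinkage_ratio:.2f} -> "
          f"{'responder' if label.responder else 'non-responder'}")

print(
    "\nHigh mutational burden (k_a = 20) supplies enough T-cell recruitment "
    "for the unleashed cytotoxic response to shrink the tumour; at low "
    "burden (k_a = 10) the same blockade cannot keep up with tumour growth."
)
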