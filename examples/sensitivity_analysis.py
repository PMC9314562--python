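"""Sensitivity variants with uncertainty intervals.

Re-runs the full pipeline under the four alternative assumptions (no
classical/e-bike mean-age gap; e-bike MET ratio 0.78; no protective effect
above age 74; the more favourable cycling dose-response of 19% [9-29%])
and at the low/central/high dose-response bounds for each.
"""

from active_travel_hia import DEFAULT_VARIANTS, RunConfig, generate_inputs, run_sensitivity

cfg = RunConfig()
inputs = generate_inputs(cfg)
table = run_sensitivity(inputs, cfg, DEFAULT_VARIANTS)

print(f"{'variant':<18} {'deaths 2045 [UI]':>28} {'cumulative deaths':>18}")
for _, r in table.iterrows():
    ui = (f"{r['deaths_prevented_annual_central']:,.0f} "
          f"[{r['deaths_prevented_annual_low']:,.0f}-"
          f"{r['deaths_prevented_annual_high']:,.0f}]")
    print(f"{r['variant']:<18} {ui:>28} {r['deaths_prevented_cumulative_central']:>18,.0f}")

print("\nIntervals come from re-running every mode jointly at its lower and "
      "upper 95% CI reduction. The alternative cycling dose-response roughly "
      "doubles the estimates; restricting effects to ages <75 removes the "
      "high-mortality 75-84 group and cuts deaths averted by about a third.")
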