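"""Run the full assessment on the default synthetic scenario.

Compares the modal-shift scenario against a reference in which active
travel stays at its 2021 level, and prints the headline measures: deaths
and years of life lost (YLL) averted, the period life-expectancy gain, and
monetized benefits at the year's value of a statistical life year.
"""

from active_travel_hia import RunConfig, generate_inputs, run_analysis

cfg = RunConfig()
inputs = generate_inputs(cfg)
result = run_analysis(inputs, cfg)

row = result.annual.set_index("year").loc[2045]
print("2045 (scenario minus frozen-2021 reference):")
print(f"  deaths averted:        {row['deaths_prevented']:,.0f} per year")
print(f"  YLL averted:           {row['yll_prevented']:,.0f} person-years")
print(f"  life-expectancy gain:  {row['le_gain_months']:.2f} months")
print(f"  monetized benefits:    {row['benefits_eur'] / 1e9:.1f} bn EUR (2020 euros)")

print(f"\ncumulative 2021-2050: {result.cumulative['deaths_prevented']:,.0f} deaths, "
      f"{result.cumulative['yll_prevented'] / 1e6:.2f} M YLL, "
      f"{result.cumulative['benefits_eur'] / 1e9:,.0f} bn EUR")

print("\nmode contributions to cumulative deaths averted:")
for _, r in result.mode_contributions.iterrows():
    print(f"  {r['mode']:>14}: {r['deaths_pct']:5.1f}% of deaths, "
          f"{r['yll_pct']:5.1f}% of YLL")
print("E-bikes dominate because they carry most late-horizon cycled km and "
      "skew toward older, higher-mortality ages.")
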