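"""Minimum detectable change of a paired monitoring design, by simulation.

For each candidate annual trend, networks are simulated, the random-slope
trend model fitted, and power is the fraction of significant global slopes.
The MDC is the smallest trend on the grid reaching the target power.
Simulation sizes here are kept small so the example runs in about a minute;
increase n_sim for smoother curves.
"""

from socmon import DesignSpec, find_mdc

design = DesignSpec(n_sites=28, n_campaigns=5, interval_years=5, n_replicates=4)
result = find_mdc(
    design,
    trend_grid=[0.2, 0.3, 0.4, 0.5],   # % per year
    alpha=0.05,
    power_target=0.8,
    n_sim=150,
    seed=3,
)

print(f"design: {design.n_sites} sites x {design.n_campaigns} campaigns "
      f"x {design.n_replicates} replicates, {design.interval_years:g}-yr interval")
print("trend (%/yr)  power")
for g, p in zip(result.trend_grid, result.power):
    print(f"   {g:5.2f}      {p:.2f}")
print(f"\nMDC at power {result.power_target}: {result.mdc} % per year")
print("i.e. the smallest sustained relative SOC change this design detects "
      "reliably after all campaigns.")
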