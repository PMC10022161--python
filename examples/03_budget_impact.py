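"""Ten-year budget impact of scaling up repair capacity nationally.

Scenario 1 caps spending at USD 10 million per year (providers do 50
repairs/year, up to 250 trainees/year over five years); scenario 2 buys
whatever it takes to clear the ~1.4 million-case backlog by 2030
(productivity 200/year, 400 trainees/year over three years).  Health gains
price each repair at the cohort model's per-patient DALYs averted.
"""

from herniacea import (
    ModelParameters,
    base_case_life_table,
    daly_averted_per_repair,
    run_bia,
    scenario_budget_cap,
    scenario_elimination,
)

params = ModelParameters()
life_table = base_case_life_table()
dpr = daly_averted_per_repair(params, life_table, "md")
print(f"DALYs averted per repair (from the cohort model): {dpr:.3f}\n")

for scenario in (
    scenario_budget_cap(params.cost_md),
    scenario_elimination(params.cost_md),
):
    traj = run_bia(scenario, dpr)
    print(f"--- {scenario.label} ---")
    print("  year   repairs   backlog(k)  cost(USD M)  providers")
    for _, row in traj.years.iterrows():
        print(
            f"  {int(row['year'])}  {row['repairs']:8,.0f}  "
            f"{row['backlog'] / 1e3:9.1f}  {row['annual_cost_usd_2020'] / 1e6:10.2f}  "
            f"{int(row['providers_trained_cumulative']):9d}"
        )
    print(
        f"  totals: {traj.total_repairs:,.0f} repairs, USD "
        f"{traj.total_cost / 1e6:.1f}M, {traj.total_dalys_averted / 1e6:.2f}M "
        f"DALYs averted, {traj.providers_trained} providers trained\n"
    )
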