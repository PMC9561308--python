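"""How much do unstated accumulation conventions move the results?

Runs the base case under (a) the default partitioned-survival occupancy,
with and without half-cycle correction, and (b) the
unconditional-increment Markov variant, in which per-cycle transition
probabilities are the raw survival drops S(t_k) - S(t_{k+1}) rather than
conditional hazards.  Variant (b) is a documented implementation pitfall
— it leaves exp(-1) of the cohort alive indefinitely — yet it roughly
doubles life years and QALYs in both arms, far exceeding every other
convention's effect.  Published cohort-model results that cannot be
matched by a correct partitioned-survival accumulation of the same
curves are often explained by exactly this choice.

Writes results/structural/variants.csv.
"""

from pathlib import Path

import pandas as pd

from psmcea import default_config, run_base_case

OUT = Path(__file__).resolve().parents[1] / "results" / "structural"

VARIANTS = {
    "partitioned (default)": {},
    "partitioned + half-cycle": {"econ.half_cycle_correction": True},
    "markov unconditional": {"econ.occupancy": "markov_unconditional"},
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    rows = []
    for name, overrides in VARIANTS.items():
        res = run_base_case(cfg, overrides)
        lp, ch = res.intervention, res.comparator
        rows.append(
            {"variant": name,
             "lp_cost": lp.total_cost, "lp_ly": lp.total_life_years,
             "lp_qaly": lp.total_qalys,
             "chemo_cost": ch.total_cost, "chemo_ly": ch.total_life_years,
             "chemo_qaly": ch.total_qalys,
             "delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly,
             "icer": res.icer}
        )
        print(f"{name:28s} LP {lp.total_life_years:.2f} LY / "
              f"{lp.total_qalys:.2f} QALY, chemo {ch.total_life_years:.2f} / "
              f"{ch.total_qalys:.2f}, ICER ${res.icer:,.0f}/QALY")
    pd.DataFrame(rows).to_csv(OUT / "variants.csv", index=False)
    print("\nHalf-cycle correction shifts totals by ~1-2%; the unconditional-"
          "increment Markov variant roughly doubles survival in both arms.")


if __name__ == "__main__":
    main()
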