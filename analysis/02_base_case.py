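"""Base-case cost-effectiveness: both arms, increments, ICER, verdict.

Writes results/base_case/base_case.csv (one row per arm, incremental
columns on the intervention row) plus per-arm cycle traces, and prints
the headline numbers.
"""

from pathlib import Path

from psmcea import default_config, run_base_case

OUT = Path(__file__).resolve().parents[1] / "results" / "base_case"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = run_base_case(default_config())
    res.to_frame().to_csv(OUT / "base_case.csv", index=False)
    for tag, arm in (("lp", res.intervention), ("chemo", res.comparator)):
        arm.trace.to_frame().to_csv(OUT / f"trace_{tag}.csv", index=False)
        print(f"{arm.strategy:30s} cost ${arm.total_cost:10,.2f}  "
              f"LY {arm.total_life_years:.3f}  QALY {arm.total_qalys:.3f}")
    print(f"incremental cost ${res.delta_cost:,.2f}, incremental QALY "
          f"{res.delta_qaly:.4f}, ICER ${res.icer:,.2f}/QALY")
    verdict = "cost-effective" if res.cost_effective else "NOT cost-effective"
    print(f"LP is {verdict} at a WTP of ${res.wtp:,.2f}/QALY (NMB ${res.nmb:,.2f})")


if __name__ == "__main__":
    main()
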