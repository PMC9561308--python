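"""One-way deterministic sensitivity analysis with tornado output.

Re-runs the full two-arm model at each parameter's range limits and
writes results/dsa/dsa_tornado.csv and tornado.png.  Also reports the
price-reduction scenario (pembrolizumab at $4.936/mg).
"""

from pathlib import Path

from psmcea import default_config, one_way_dsa, run_base_case
from psmcea.plots import tornado

OUT = Path(__file__).resolve().parents[1] / "results" / "dsa"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    base = run_base_case(cfg)
    table = one_way_dsa(cfg)
    table.to_csv(OUT / "dsa_tornado.csv", index=False)
    tornado(table, base.icer, str(OUT / "tornado.png"))

    print(f"base-case ICER ${base.icer:,.2f}/QALY; widest bars:")
    for _, row in table.head(5).iterrows():
        print(f"  {row['label']:35s} ICER {row['icer_at_low']:>11,.0f} .. "
              f"{row['icer_at_high']:>11,.0f}  (width {row['width']:,.0f})")

    cut = run_base_case(cfg, {"drug_prices.pembrolizumab": 4.936})
    print(f"pembrolizumab at $4.936/mg -> ICER ${cut.icer:,.2f}/QALY "
          f"({'below' if cut.icer < base.wtp else 'above'} the WTP threshold)")


if __name__ == "__main__":
    main()
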