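"""Probabilistic sensitivity analysis: 10,000 Monte-Carlo model runs.

Parameters are drawn from the gamma/beta distributions moment-matched to
the base values and ranges; each draw re-runs both arms.  Writes the
iteration cloud, CEAC table, summary JSON and the CEAC/CE-plane figures
under results/psa/.
"""

import json
from pathlib import Path

from psmcea import default_config, run_base_case, run_psa
from psmcea.config import build_econ
from psmcea.plots import ce_plane, ceac

OUT = Path(__file__).resolve().parents[1] / "results" / "psa"
SEED = 20240901
N = 10000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    econ = build_econ(cfg)
    base = run_base_case(cfg)
    psa = run_psa(cfg, n=N, seed=SEED)

    psa.iterations_frame().to_csv(OUT / "psa_iterations.csv", index=False)
    psa.ceac_frame().to_csv(OUT / "psa_ceac.csv", index=False)
    summary = {
        "n": psa.n,
        "seed": psa.seed,
        "prob_cost_effective_at_wtp": psa.prob_cost_effective(econ.wtp_per_qaly),
        "mean_delta_cost": float(psa.delta_cost.mean()),
        "mean_delta_qaly": float(psa.delta_qaly.mean()),
        "ellipse": psa.ellipse,
    }
    (OUT / "psa_summary.json").write_text(json.dumps(summary, indent=2))
    ceac(psa, econ.wtp_per_qaly, str(OUT / "ceac.png"))
    ce_plane(psa, econ.wtp_per_qaly, str(OUT / "ce_plane.png"),
             base_point=(base.delta_cost, base.delta_qaly))

    p = summary["prob_cost_effective_at_wtp"]
    print(f"{N} iterations (seed {SEED}): mean dC ${summary['mean_delta_cost']:,.0f}, "
          f"mean dQ {summary['mean_delta_qaly']:.3f}")
    print(f"P(LP cost-effective at WTP ${econ.wtp_per_qaly:,.2f}/QALY) = {p:.3f}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
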