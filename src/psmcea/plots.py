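"""Standard displays: tornado diagram, CEAC and cost-effectiveness plane."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def tornado(dsa_table, base_icer: float, path: str, top: int = 15) -> None:
    df = dsa_table.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1.5))
    lo = np.minimum(df["icer_at_low"], df["icer_at_high"])
    hi = np.maximum(df["icer_at_low"], df["icer_at_high"])
    ax.barh(df["label"], hi - lo, left=lo, color="#4878b0", alpha=0.85)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_xlabel("ICER (USD per QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac(psa_result, wtp: float, path: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(psa_result.wtp_grid, psa_result.ceac, label="LP vs chemotherapy")
    ax.plot(psa_result.wtp_grid, 1.0 - psa_result.ceac, ls=":", label="chemotherapy")
    ax.axvline(wtp, color="k", lw=1, ls="--", label=f"WTP ${wtp:,.0f}")
    ax.set_xlabel("Willingness to pay (USD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane(psa_result, wtp: float, path: str, base_point=None) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa_result.delta_qaly, psa_result.delta_cost, s=4, alpha=0.25, lw=0)
    ell = psa_result.ellipse
    if ell:
        theta = np.linspace(0, 2 * np.pi, 200)
        ang = np.radians(ell["angle_deg"])
        x = ell["semi_axis_major"] * np.cos(theta)
        y = ell["semi_axis_minor"] * np.sin(theta)
        ax.plot(
            ell["mean_dq"] + x * np.cos(ang) - y * np.sin(ang),
            ell["mean_dc"] + x * np.sin(ang) + y * np.cos(ang),
            color="crimson", lw=1.2, label="95% ellipse",
        )
    lim = ax.get_xlim()
    xs = np.linspace(min(lim[0], 0), lim[1], 50)
    ax.plot(xs, wtp * xs, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    if base_point is not None:
        ax.plot(*base_point[::-1], marker="*", ms=12, color="orange", label="base case")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
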