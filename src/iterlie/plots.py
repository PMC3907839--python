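"""Optional plot artifacts: correlation, permutation-scan and weight figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

KCAL_IN_KJ = 4.184


def correlation_plot(predictions, compounds, path, guide=KCAL_IN_KJ):
    """ΔG_calc vs ΔG_exp scatter with identity and ±1 kcal/mol guide lines."""
    exp = np.array([c.dg_exp for c in compounds])
    calc = np.array([predictions[c.compound_id].dg_calc for c in compounds])
    colors = ["black" if c.role == "train" else "red" for c in compounds]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lim = [min(exp.min(), calc.min()) - 2, max(exp.max(), calc.max()) + 2]
    ax.plot(lim, lim, "k-", lw=0.8)
    ax.plot(lim, [v + guide for v in lim], "k--", lw=0.6)
    ax.plot(lim, [v - guide for v in lim], "k--", lw=0.6)
    ax.scatter(exp, calc, c=colors, s=25, zorder=3)
    ax.set_xlabel(r"$\Delta G_{exp}$ (kJ mol$^{-1}$)")
    ax.set_ylabel(r"$\Delta G_{calc}$ (kJ mol$^{-1}$)")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def permutation_plot(results, path):
    """RMSE_tot of every scanned split against its fitted (α, β)."""
    alpha = [r.alpha for r in results]
    beta = [r.beta for r in results]
    rmse_tot = [r.rmse_tot for r in results]
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(alpha, beta, c=rmse_tot, s=12, cmap="viridis")
    fig.colorbar(sc, ax=ax, label=r"RMSE$_{tot}$ (kJ mol$^{-1}$)")
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel(r"$\beta$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def weight_decomposition_plot(decomposition, path):
    """Stacked per-template summed Boltzmann weights, one bar per compound."""
    cids = list(decomposition)
    templates = sorted({t for d in decomposition.values() for t in d})
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(cids)), 3.5))
    bottom = np.zeros(len(cids))
    for template in templates:
        vals = np.array([decomposition[c].get(template, 0.0) for c in cids])
        ax.bar(cids, vals, bottom=bottom, label=template)
        bottom += vals
    ax.set_ylabel("summed Boltzmann weight")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
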