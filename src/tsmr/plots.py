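"""Optional simple plots (scatter, forest, leave-one-out).

Matplotlib is imported lazily so the core pipeline has no plotting
dependency; install the ``plots`` extra to use these.
"""

from __future__ import annotations


def _mpl():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install tsmr[plots])") from exc
    return plt


def scatter_plot(results, path=None):
    """Exposure vs outcome effects with the fitted IVW (and Egger) lines."""
    plt = _mpl()
    variants = results.model.data.variants
    fig, ax = plt.subplots(figsize=(5, 4))
    for v in variants:
        ax.errorbar(v.beta_exp, v.beta_out, xerr=v.se_exp, yerr=v.se_out, fmt="o", color="0.3")
    xs = [0] + [v.beta_exp for v in variants]
    lo, hi = min(xs), max(xs)
    ivw = results.estimates["IVW"].beta
    ax.plot([lo, hi], [ivw * lo, ivw * hi], label=f"IVW (b={ivw:.2f})")
    if results.egger_fit is not None:
        a, b = results.egger_fit.intercept, results.egger_fit.slope.beta
        ax.plot([lo, hi], [a + b * lo, a + b * hi], "--", label=f"MR-Egger (b={b:.2f})")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def forest_plot(table, path=None, title="Per-variant causal estimates"):
    """Horizontal forest plot from a sensitivity table (label/beta/lci/uci)."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(table) + 1.2))
    ys = range(len(table))[::-1]
    for y, (_, row) in zip(ys, table.iterrows()):
        ax.plot([row["lci"], row["uci"]], [y, y], color="0.3")
        ax.plot(row["beta"], y, "s", color="0.1")
    ax.axvline(0, color="0.7", ls="--", lw=0.8)
    ax.set_yticks(list(ys))
    ax.set_yticklabels(table["label"])
    ax.set_xlabel("causal effect (log OR)")
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def leave_one_out_plot(table, path=None):
    return forest_plot(table, path=path, title="Leave-one-out IVW estimates")
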