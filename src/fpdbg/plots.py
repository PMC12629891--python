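"""Optional matplotlib figures: histogram + fit overlay, pile-up families.

Requires the ``plots`` extra (matplotlib); imported lazily so the core
package stays plotting-free.
"""

from __future__ import annotations

import numpy as np

from .characterize import ExpFitResult, IntensityHistogram


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_histogram_fit(
    hist: IntensityHistogram,
    fit: ExpFitResult | None = None,
    path: str | None = None,
    title: str = "Pooled intensity histogram",
):
    """Log-scale histogram with the exponential fit overlaid on its window."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    sel = hist.percent > 0
    ax.semilogy(hist.centers[sel], hist.percent[sel], ".", ms=2, label="histogram")
    if fit is not None:
        grid = np.linspace(fit.fit_lo, fit.fit_hi, 200)
        ax.semilogy(
            grid,
            fit.k_hat * np.exp(-fit.lam_hat * grid),
            "r-",
            label=f"fit: k={fit.k_hat:.3g}%, lambda={fit.lam_hat:.3g}",
        )
    ax.set_xlabel("pixel intensity above baseline (counts)")
    ax.set_ylabel("pixels (%)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_pileup_table(table, path: str | None = None):
    """Fitted decay coefficient and deviation across the multiplier ladder."""
    plt = _plt()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.semilogx(table["multiplier"], table["lambda_hat"], "o-")
    ax1.set_xlabel("dose-rate multiplier")
    ax1.set_ylabel("fitted lambda (/count)")
    ax2.loglog(table["multiplier"], table["deviation"], "o-", label="deviation")
    ax2.loglog(table["multiplier"], table["collision_fraction"], "s--",
               label="collision fraction")
    ax2.set_xlabel("dose-rate multiplier")
    ax2.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
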