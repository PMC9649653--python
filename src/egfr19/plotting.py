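"""Static figure export: Woods-style exchange plots and KM curves."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .hdx import ExchangeRecord
from .survival import KMCurve


def woods_plot(
    records: Sequence[ExchangeRecord],
    timepoint_index: int = 1,
    path: Optional[str | Path] = None,
    label: Optional[str] = None,
):
    """Percent exchange versus median residue number at one timepoint."""
    fig, ax = plt.subplots(figsize=(7, 3))
    x = [r.median_residue for r in records]
    y = [r.percent_exchange[timepoint_index] for r in records]
    e = [r.sd[timepoint_index] for r in records]
    ax.errorbar(x, y, yerr=e, fmt="o", ms=4, capsize=2, label=label)
    ax.set_xlabel("median residue number")
    ax.set_ylabel("% exchange")
    ax.set_ylim(0, 110)
    if label:
        ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def km_plot(
    curves: dict[str, KMCurve], path: Optional[str | Path] = None
):
    """Step-function survival curves for labelled groups."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, c in curves.items():
        ax.step([0, *c.times], [1.0, *c.survival], where="post", label=name)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
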