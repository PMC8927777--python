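"""Optional diagnostic plots (ENC-GC3, PR2, neutrality). Matplotlib Agg."""

from __future__ import annotations

from typing import Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .bias_analysis import NeutralityFit, Pr2Point  # noqa: E402
from .codon_stats import expected_enc  # noqa: E402


def plot_enc_gc3(enc_table, path) -> None:
    """ENC vs GC3 scatter with the expected-ENC curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(enc_table["gc3"], enc_table["enc"], s=6, alpha=0.5)
    grid = np.linspace(0.0, 1.0, 201)
    ax.plot(grid, [expected_enc(x) for x in grid], "k--", lw=1, label="expected")
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.legend(frameon=False)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_pr2(points: Sequence[Pr2Point], path) -> None:
    """PR2 scatter with the (0.5, 0.5) parity centre."""
    xs = [p.x for p in points if p.x is not None and p.y is not None]
    ys = [p.y for p in points if p.x is not None and p.y is not None]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(xs, ys, s=6, alpha=0.5)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_neutrality(profiles, fit: NeutralityFit, path) -> None:
    """GC12 vs GC3s scatter with the OLS fit line."""
    pts = [(p.gc3s, p.gc12) for p in profiles if p.gc3s is not None]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(xs, ys, s=6, alpha=0.5)
    grid = np.linspace(xs.min(), xs.max(), 2)
    ax.plot(grid, fit.slope * grid + fit.intercept, "r-", lw=1,
            label=f"slope={fit.slope:.3f}, r={fit.pearson_r:.3f}")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("GC12")
    ax.legend(frameon=False)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
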