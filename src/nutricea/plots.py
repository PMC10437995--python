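"""Figure analogues: group means by wave, tornado, CE plane, CEAC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def render_figures(bundle, out_dir: str | Path) -> list[Path]:
    """Render the four standard figures as PNG; returns paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if bundle.group_means is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for arm, row in bundle.group_means.iterrows():
            ax.plot(row.index.astype(str), row.values, marker="o", label=arm)
        ax.set_ylabel("Mean cognitive composite score")
        ax.set_xlabel("Assessment wave")
        ax.legend()
        path = out / "group_means.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    base_icer = bundle.deterministic.icer
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    entries = list(reversed(bundle.tornado))  # widest bar on top
    labels = [e.parameter for e in entries]
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - base_icer, left=base_icer, color="tab:blue")
        ax.barh(i, lo - base_icer, left=base_icer, color="tab:red")
    ax.axvline(base_icer, color="k", lw=0.8)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("ICER (USD per score unit)")
    path = out / "tornado.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    if bundle.psa.n_samples:
        s = bundle.psa.samples
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(s["delta_e"], s["delta_c"], s=6, alpha=0.4)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("Incremental effect (score units)")
        ax.set_ylabel("Incremental cost (USD)")
        path = out / "ce_plane.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(
            [p.wtp for p in bundle.ceac_points],
            [p.probability for p in bundle.ceac_points],
        )
        ax.set_xlabel("Willingness to pay (USD per score unit)")
        ax.set_ylabel("P(cost-effective)")
        ax.set_ylim(-0.02, 1.02)
        path = out / "ceac.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
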