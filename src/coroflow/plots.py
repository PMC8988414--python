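"""Scatter and Bland-Altman figures for the three method pairs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .compare import PAIR_LABELS, bland_altman
from .flow import SiteFlowReport, reports_to_frame

__all__ = ["comparison_plots"]


def comparison_plots(reports: list[SiteFlowReport], out_dir: str | Path) -> list[Path]:
    """One scatter + Bland-Altman panel pair per method pair; returns the
    written file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = reports_to_frame(reports)
    written: list[Path] = []
    for label, cx, cy in PAIR_LABELS:
        sub = df.dropna(subset=[cx, cy])
        if len(sub) < 2:
            continue
        x, y = sub[cx].to_numpy(), sub[cy].to_numpy()
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(x, y, s=18)
        lim = [0, max(x.max(), y.max()) * 1.08]
        ax1.plot(lim, lim, "k--", lw=0.8)
        ax1.set_xlabel(f"{cx} ")
        ax1.set_ylabel(cy)
        ax1.set_title(label)
        mean, (lo, hi) = bland_altman(x, y)
        ax2.scatter((x + y) / 2, x - y, s=18)
        for val, style in ((mean, "-"), (lo, "--"), (hi, "--")):
            ax2.axhline(val, color="k", ls=style, lw=0.8)
        ax2.set_xlabel("mean of methods (cc/s)")
        ax2.set_ylabel("difference (cc/s)")
        ax2.set_title("Bland-Altman")
        fig.tight_layout()
        path = out_dir / f"compare_{label.replace('/', '_vs_')}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
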