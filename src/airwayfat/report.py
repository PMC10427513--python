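"""Report rendering: plain-text comparison tables and histogram figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _fmt(value: float, digits: int = 1) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "-"
    return f"{value:.{digits}f}"


def render_comparison_text(summary: pd.DataFrame) -> str:
    """Render the cohort comparison as an aligned plain-text table.

    One row per metric: baseline and follow-up mean +/- SD, absolute and
    percent change, two-sided p (starred when < 0.05), and the effect size
    with its 95% CI and magnitude class.
    """
    headers = ["Metric", "Baseline", "Follow-up", "Change", "% Change", "P", "Effect size (95% CI)"]
    rows = []
    for _, r in summary.iterrows():
        if r.get("status") == "insufficient-pairs":
            rows.append([r["metric"], "-", "-", "-", "-", "-", "insufficient pairs"])
            continue
        p = r.get("p")
        p_text = "-" if p is None or np.isnan(p) else f"{p:.3f}" + ("*" if p < 0.05 else "")
        d = r.get("effect_size")
        if d is None or np.isnan(d):
            d_text = "undefined"
        else:
            d_text = (
                f"{d:.1f} ({r['effect_ci_low']:.1f}, {r['effect_ci_high']:.1f}) "
                f"[{r['magnitude']}]"
            )
        rows.append(
            [
                r["metric"],
                f"{_fmt(r['baseline_mean'])} ± {_fmt(r['baseline_sd'])}",
                f"{_fmt(r['followup_mean'])} ± {_fmt(r['followup_sd'])}",
                f"{_fmt(r['change_mean'])} ± {_fmt(r['change_sd'])}",
                f"{_fmt(r['pct_change_mean'])} ± {_fmt(r['pct_change_sd'])}",
                p_text,
                d_text,
            ]
        )
    widths = [max(len(h), *(len(row[i]) for row in rows)) if rows else len(h) for i, h in enumerate(headers)]
    lines = [
        "  ".join(h.ljust(w) for h, w in zip(headers, widths)),
        "  ".join("-" * w for w in widths),
    ]
    lines += ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows]
    lines.append("")
    lines.append("* P < 0.05 (paired t-test, two-sided; no multiple-comparison adjustment)")
    return "\n".join(lines) + "\n"


def plot_session_histograms(
    histograms: pd.DataFrame,
    path: str | Path,
    title: str = "",
) -> Path:
    """Pre/post voxel fat-fraction histogram overlays, one panel per tissue.

    ``histograms`` is long-format with columns structure, session,
    bin_left, bin_right, count. Counts are normalised to frequencies so
    sessions with different tissue sizes remain comparable; the median of
    each session (from the binned values) is drawn as a vertical line.
    """
    structures = list(dict.fromkeys(histograms["structure"]))
    n = len(structures)
    ncols = min(3, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows), squeeze=False)
    colors = {"baseline": "tab:blue", "followup": "tab:orange"}
    for ax, structure in zip(axes.flat, structures):
        for session in ("baseline", "followup"):
            sub = histograms[
                (histograms["structure"] == structure) & (histograms["session"] == session)
            ].sort_values("bin_left")
            if sub.empty:
                continue
            counts = sub["count"].to_numpy(dtype=float)
            total = counts.sum()
            freq = counts / total if total > 0 else counts
            centers = (sub["bin_left"].to_numpy() + sub["bin_right"].to_numpy()) / 2.0
            ax.step(centers, freq, where="mid", color=colors[session], label=session)
            if total > 0:
                cum = np.cumsum(counts)
                median_bin = int(np.searchsorted(cum, total / 2.0))
                ax.axvline(centers[median_bin], color=colors[session], ls="--", lw=0.8)
        ax.set_title(structure)
        ax.set_xlabel("voxel fat fraction (%)")
        ax.set_ylabel("frequency")
        ax.set_xlim(0, 100)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    handles, labels = axes.flat[0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper right")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
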