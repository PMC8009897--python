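"""Overlay rendering of pipeline results on the radiograph."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_overlay"]

_COLORS = {"sev": "tab:cyan", "av": "tab:red", "iev": "tab:orange"}


def plot_overlay(image, report, path) -> None:
    """Render MA, CSL, landmarks and per-segment Cobb values over the image."""
    fig, ax = plt.subplots(figsize=(5, 9))
    ax.imshow(image, cmap="gray", vmin=0, vmax=255)
    ax.plot(report.ma.x, report.ma.rows, color="tab:green", lw=1.2, label="MA")
    ax.plot(
        [report.csl.x, report.csl.x],
        [report.csl.top_row, report.csl.bottom_row],
        color="tab:blue",
        lw=1.2,
        ls="--",
        label="CSL",
    )
    for sr in report.segments:
        for name in ("sev", "av", "iev"):
            row, x = getattr(sr.landmarks, name)
            label = (sr.landmarks.vertebra_labels or {}).get(name, "")
            ax.plot(x, row, "o", ms=5, color=_COLORS[name])
            ax.annotate(
                f"{name.upper()} {label}",
                (x, row),
                textcoords="offset points",
                xytext=(8, 0),
                fontsize=7,
                color=_COLORS[name],
            )
        cobb = sr.angles.get("cobb")
        if cobb is not None:
            row, x = sr.landmarks.av
            ax.annotate(
                f"Cobb {cobb.value:.1f}°",
                (x, row),
                textcoords="offset points",
                xytext=(8, 12),
                fontsize=8,
                color="white",
            )
    ax.legend(loc="lower right", fontsize=7)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
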