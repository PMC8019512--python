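"""Grid plots of MB-VIOP profiles.

One panel per (block, profile kind): rows are blocks, columns are the
unique / local / global / total profiles, variables on the x-axis (1-based)
and a red horizontal line marking the importance threshold.  Panels for
profile kinds a block has no components of are drawn flat at zero with an
"n/a" annotation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; figures are written, not shown
import matplotlib.pyplot as plt
import numpy as np

from .importance import PROFILE_KINDS, VIOPProfiles

__all__ = ["plot_profiles"]


def plot_profiles(
    profiles: VIOPProfiles,
    path=None,
    threshold: float = 1.0,
    kinds: tuple[str, ...] = PROFILE_KINDS,
    figsize_per_panel: tuple[float, float] = (3.0, 1.8),
):
    """Draw the block x kind grid of profiles; optionally save to ``path``."""
    for kind in kinds:
        if kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {kind!r}")
    n_rows, n_cols = profiles.n_blocks, len(kinds)
    fig, axes = plt.subplots(
        n_rows,
        n_cols,
        figsize=(figsize_per_panel[0] * n_cols, figsize_per_panel[1] * n_rows),
        squeeze=False,
    )
    for d in range(n_rows):
        for j, kind in enumerate(kinds):
            ax = axes[d][j]
            v = profiles.get(d, kind)
            x = np.arange(1, v.size + 1)
            ax.plot(x, v, lw=0.9, color="tab:blue")
            ax.axhline(threshold, color="red", lw=0.8)
            if profiles.is_empty(d, kind):
                ax.annotate(
                    "n/a", xy=(0.5, 0.5), xycoords="axes fraction",
                    ha="center", va="center", color="gray",
                )
            if d == 0:
                ax.set_title(kind)
            if j == 0:
                ax.set_ylabel(profiles.block_names[d])
            if d == n_rows - 1:
                ax.set_xlabel("variable")
    fig.tight_layout()
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
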