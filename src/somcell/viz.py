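"""Optional rendering of portraits, set maps and CNV heatmaps (PNG).

Non-normative convenience output; nothing downstream depends on it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .cnv import CNVMatrix
from .som import Portrait


def portrait_png(portrait: Portrait, path: str | Path, cmap: str = "RdBu_r") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    lim = float(np.abs(portrait.values).max()) or 1.0
    im = ax.imshow(portrait.values, cmap=cmap, vmin=-lim, vmax=lim)
    ax.set_title(f"{portrait.label} ({portrait.kind})")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cnv_png(cnv: CNVMatrix, path: str | Path, cmap: str = "RdBu_r") -> None:
    fig, ax = plt.subplots(figsize=(10, 4))
    lim = float(np.abs(cnv.values).max()) or 1.0
    ax.imshow(cnv.values, aspect="auto", cmap=cmap, vmin=-lim, vmax=lim)
    # chromosome boundaries along the window axis
    chroms = cnv.windows["chromosome"].to_numpy()
    bounds = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    for b in bounds:
        ax.axvline(b - 0.5, color="black", lw=0.4)
    ax.set_xlabel("genomic windows")
    ax.set_ylabel("cells")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
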