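"""Minimal static functional-map plot.

Scatters an embedding and shades the nodes whose neighbourhoods carry each
functional domain; intentionally simple, for quick visual checks.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .embeddings import CartesianEmbedding, DiskEmbedding
from .safe import DomainSet, EnrichmentResult

__all__ = ["plot_functional_map"]


def plot_functional_map(
    embedding: CartesianEmbedding | DiskEmbedding,
    res: EnrichmentResult,
    domains: DomainSet,
    path: str | Path,
) -> None:
    """Save a PNG functional map: grey nodes, coloured domain members."""
    if isinstance(embedding, DiskEmbedding):
        embedding = embedding.to_cartesian()
    pos = embedding.as_dict()
    fig, ax = plt.subplots(figsize=(6, 6))
    xs = [pos[u][0] for u in embedding.nodes]
    ys = [pos[u][1] for u in embedding.nodes]
    ax.scatter(xs, ys, s=8, c="0.8", linewidths=0, zorder=1)
    cmap = plt.get_cmap("tab10")
    for i, dom in enumerate(domains.domains):
        members = sorted(dom.neighbourhoods & set(embedding.nodes))
        if not members:
            continue
        ax.scatter(
            [pos[u][0] for u in members],
            [pos[u][1] for u in members],
            s=14,
            color=cmap(i % 10),
            linewidths=0,
            zorder=2,
            label=" ".join(dom.keywords[:3]) or f"domain {i}",
        )
    ax.set_aspect("equal")
    ax.legend(fontsize=7, loc="upper right")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
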