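"""Readers and writers for edge lists, GMT annotations, alignment tables,
embeddings and result tables, plus the run configuration and the
embedding-comparison driver.

All tabular output is tab-separated with a single header line and ``.``
for missing values, so results diff cleanly between runs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .embeddings import (
    CartesianEmbedding,
    DiskEmbedding,
    gracoal_embed,
    graspring_embed,
    spectral_embed,
    coalescent_embed,
)
from .network import Network
from .safe import (
    AnnotationSet,
    DomainSet,
    EnrichmentResult,
    enrichment_summary,
    run_safe,
    union_enrichment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_blast_table",
    "write_pairs",
    "read_pairs",
    "write_embedding",
    "read_embedding",
    "write_enrichment",
    "write_domains",
    "RunConfig",
    "load_config",
    "run_comparison",
]

MISSING = "."


# ---------------------------------------------------------------------------
# networks


def read_edge_list(path: str | Path, header: bool = False) -> Network:
    """Read an undirected simple network from a two-column TSV edge list.

    Lines starting with ``#`` are ignored; duplicate edges and self-loops
    are dropped with logged counts; ``header=True`` skips the first
    non-comment line.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_dup = n_self = 0
    first = header
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if first:
                first = False
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line has fewer than two columns: {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            if u == v:
                n_self += 1
                continue
            key = (u, v) if u < v else (v, u)
            if key in edges:
                n_dup += 1
                continue
            edges.add(key)
            nodes |= {u, v}
    if not edges and not nodes:
        raise ValueError(f"{path}: no edges found")
    if n_dup or n_self:
        logger.info("%s: dropped %d duplicate edges, %d self-loops", path, n_dup, n_self)
    return Network(edges, nodes=nodes)


def write_edge_list(network: Network, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for u, v in network.edges:
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# annotations (GMT)


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read gene sets in GMT format: term, description, then genes."""
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("%s:%d: malformed GMT line skipped", path, lineno)
                continue
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                logger.info("%s:%d: term %s has no genes; skipped", path, lineno, term)
                continue
            terms.setdefault(term, set()).update(genes)
            descriptions[term] = desc
    if not terms:
        raise ValueError(f"{path}: no usable gene sets")
    return AnnotationSet.from_mapping(terms, descriptions)


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in ann.terms:
            desc = ann.descriptions.get(term, MISSING)
            genes = "\t".join(sorted(ann.term_to_genes[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# alignment tables and pair lists


def read_blast_table(path: str | Path) -> list[list[str]]:
    """Rows of a 12-column BLAST tabular (outfmt 6) file; no validation
    here — filtering and per-row error handling happen downstream."""
    rows = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def write_pairs(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted((min(p), max(p)) for p in pairs):
            fh.write(f"{u}\t{v}\n")


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with Path(path).open() as fh:
        header = True
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header:
                header = False
                if line.split("\t")[0] == "gene_a":
                    continue
            parts = line.split("\t")
            out.append((parts[0], parts[1]))
    return out


# ---------------------------------------------------------------------------
# embeddings


def write_embedding(emb: CartesianEmbedding | DiskEmbedding, path: str | Path) -> None:
    """node, angle, radius, x, y — with '.' where a column does not apply."""
    with Path(path).open("w") as fh:
        fh.write("node\tangle\tradius\tx\ty\n")
        if isinstance(emb, DiskEmbedding):
            cart = emb.to_cartesian()
            for u, a, r, (x, y) in zip(emb.nodes, emb.angles, emb.radii, cart.coords):
                fh.write(f"{u}\t{a:.12g}\t{r:.12g}\t{x:.12g}\t{y:.12g}\n")
        else:
            for u, (x, y) in zip(emb.nodes, emb.coords):
                fh.write(f"{u}\t{MISSING}\t{MISSING}\t{x:.12g}\t{y:.12g}\n")
        for u in emb.dropped:
            fh.write(f"{u}\t{MISSING}\t{MISSING}\t{MISSING}\t{MISSING}\n")


def read_embedding(path: str | Path) -> CartesianEmbedding:
    """Read back the Cartesian part of an embedding table."""
    import numpy as np

    nodes, coords, dropped = [], [], []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row["x"] == MISSING:
                dropped.append(row["node"])
            else:
                nodes.append(row["node"])
                coords.append((float(row["x"]), float(row["y"])))
    order = sorted(range(len(nodes)), key=lambda i: nodes[i])
    return CartesianEmbedding(
        tuple(nodes[i] for i in order),
        np.array([coords[i] for i in order], dtype=float),
        tuple(sorted(dropped)),
    )


# ---------------------------------------------------------------------------
# result tables


def write_enrichment(res: EnrichmentResult, path: str | Path) -> None:
    """Long-form table: neighbourhood node, term, raw p, adjusted p, significant."""
    sig = res.significant_mask()
    with Path(path).open("w") as fh:
        fh.write("node\tterm\traw_p\tadj_p\tsignificant\n")
        for i, u in enumerate(res.nodes):
            for j, t in enumerate(res.terms):
                fh.write(
                    f"{u}\t{t}\t{res.raw_p[i, j]:.6g}\t{res.adj_p[i, j]:.6g}\t"
                    f"{int(sig[i, j])}\n"
                )


def write_domains(domains: DomainSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("domain\tkeywords\tterms\n")
        for i, dom in enumerate(domains.domains):
            kw = ",".join(dom.keywords) if dom.keywords else MISSING
            fh.write(f"{i}\t{kw}\t{','.join(dom.terms)}\n")


# ---------------------------------------------------------------------------
# configuration and the comparison driver


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a comparative embedding + SAFE run.

    Defaults follow the standard SAFE settings: mean neighbourhood size 50,
    domains need >= 10 neighbourhoods, dendrogram cut at 75% of its height,
    significance 0.05.
    """

    methods: tuple[str, ...] = ("gracoal", "spectral", "graspring")
    graphlets: tuple[int, ...] = tuple(range(9))
    target_mean_size: int = 50
    min_neighbourhoods: int = 10
    cut_fraction: float = 0.75
    significance: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        bad = [g for g in self.graphlets if not 0 <= g <= 8]
        if bad:
            raise ValueError(f"graphlet indices outside 0..8: {bad}")
        known = {"gracoal", "spectral", "graspring", "ce"}
        unknown = [m for m in self.methods if m not in known]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; known: {sorted(known)}")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    if "methods" in data:
        data["methods"] = tuple(data["methods"])
    if "graphlets" in data:
        data["graphlets"] = tuple(int(g) for g in data["graphlets"])
    return RunConfig(**data)


def _embed(method: str, network: Network, graphlet: int):
    if method == "gracoal":
        return gracoal_embed(network, graphlet)
    if method == "spectral":
        return spectral_embed(network, graphlet)
    if method == "graspring":
        return graspring_embed(network, graphlet)
    if method == "ce":
        return coalescent_embed(network)
    raise ValueError(f"unknown embedding method {method!r}")


def run_comparison(
    config: RunConfig,
    network: Network,
    annotations: AnnotationSet,
) -> pd.DataFrame:
    """SAFE enrichment for every method x graphlet, plus per-method unions.

    Returns one row per (method, graphlet) with the enrichment percentages
    and one union row per method aggregating enriched genes across its
    graphlet adjacencies. Deterministic: rerunning with the same inputs
    reproduces the table exactly.
    """
    ann_net = annotations.restricted_to(network.nodes)
    all_annotated = ann_net.genes()
    rows = []
    by_method: dict[str, list[EnrichmentResult]] = {}
    for method in config.methods:
        graphlets: Sequence[int] = (0,) if method == "ce" else config.graphlets
        for g in graphlets:
            emb = _embed(method, network, g)
            res, nbhd = run_safe(
                network,
                emb,
                ann_net,
                target_mean_size=config.target_mean_size,
                significance=config.significance,
            )
            summary = enrichment_summary(res, ann_net, all_annotated)
            rows.append(
                {
                    "method": method,
                    "graphlet": g,
                    "alpha": nbhd.alpha,
                    "mean_nbhd_size": nbhd.mean_size(),
                    **summary,
                }
            )
            by_method.setdefault(method, []).append(res)
    for method, results in by_method.items():
        union = union_enrichment(results)
        rows.append(
            {
                "method": method,
                "graphlet": -1,  # union row
                "alpha": float("nan"),
                "mean_nbhd_size": float("nan"),
                "n_enriched_genes": float(len(union)),
                "n_annotated_genes": float(len(all_annotated)),
                "pct_enriched_genes": 100.0 * len(union) / max(len(all_annotated), 1),
                "n_enriched_terms": float("nan"),
                "n_terms": float(len(ann_net.terms)),
                "pct_enriched_terms": float("nan"),
            }
        )
    return pd.DataFrame(rows)
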