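"""Paralog pairs, triangle co-occurrence testing and domain paralog ratios.

Paralogs — genes duplicated within one species — are operationalized from
all-versus-all protein alignment tables: a gene pair is called paralogous
if sequence identity >= 85%, E-value <= 0.001 and bit score >= 50. When
paralogs retain redundant function they tend to interact genetically with
each other and with shared partners, forming triangles in the genetic
interaction network; the triangle co-occurrence test asks whether paralog
pairs touch significantly more triangles together than other node pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .graphlets import triangle_pair_counts
from .network import Network
from .safe import Domain, EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "IDENTITY_MIN",
    "EVALUE_MAX",
    "BITSCORE_MIN",
    "ParalogPairs",
    "TriangleTestResult",
    "filter_paralog_pairs",
    "triangle_cooccurrence_test",
    "domain_paralog_ratio",
]

IDENTITY_MIN = 85.0
EVALUE_MAX = 0.001
BITSCORE_MIN = 50.0


@dataclass(frozen=True)
class ParalogPairs:
    """Unordered paralogous gene pairs plus the filter provenance."""

    pairs: frozenset[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v in self.pairs:
            if u == v:
                raise ValueError(f"self-pair {u!r} not allowed")
            if u > v:
                raise ValueError("pairs must be stored sorted (u < v)")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], provenance: dict | None = None) -> "ParalogPairs":
        canon = frozenset(
            (u, v) if u < v else (v, u) for u, v in pairs if u != v
        )
        return cls(canon, dict(provenance or {}))

    def genes(self) -> frozenset[str]:
        return frozenset(g for pair in self.pairs for g in pair)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        u, v = pair
        return ((u, v) if u < v else (v, u)) in self.pairs


@dataclass(frozen=True)
class TriangleTestResult:
    p_value: float
    median_paralog: float
    median_background: float
    n_paralog: int
    n_background: int


def filter_paralog_pairs(
    records: Iterable[Sequence],
    identity_min: float = IDENTITY_MIN,
    evalue_max: float = EVALUE_MAX,
    bitscore_min: float = BITSCORE_MIN,
) -> ParalogPairs:
    """Filter alignment rows down to paralogous gene pairs.

    Rows follow the 12-column BLAST tabular (outfmt 6) order: query id,
    subject id, % identity, ..., E-value (col 11), bit score (col 12). A
    row is kept if identity >= 85, E <= 0.001 and bit score >= 50;
    self-hits are dropped and unordered pairs deduplicated. Malformed rows
    are skipped with a logged line number.
    """
    kept: set[tuple[str, str]] = set()
    for lineno, row in enumerate(records, start=1):
        try:
            q, s = str(row[0]), str(row[1])
            ident = float(row[2])
            evalue = float(row[10])
            bits = float(row[11])
        except (IndexError, ValueError, TypeError):
            logger.warning("skipping malformed alignment row %d: %r", lineno, row)
            continue
        if q == s:
            continue
        if ident >= identity_min and evalue <= evalue_max and bits >= bitscore_min:
            kept.add((q, s) if q < s else (s, q))
    return ParalogPairs(
        frozenset(kept),
        provenance={
            "identity_min": identity_min,
            "evalue_max": evalue_max,
            "bitscore_min": bitscore_min,
        },
    )


def triangle_cooccurrence_test(
    network: Network,
    pairs: ParalogPairs,
    max_background: int = 100_000,
    seed: int = 0,
) -> TriangleTestResult:
    """Do paralog pairs co-occur on more triangles than other pairs?

    Sample A holds the triangle co-occurrence counts c_uv(G2) of the
    paralog pairs present in the network; sample B those of all other
    unordered node pairs (a seeded uniform subsample of ``max_background``
    pairs when there are more). One-sided Mann–Whitney U, alternative
    A > B. Paralog pairs with either gene missing from the network are
    excluded (logged).
    """
    tri = triangle_pair_counts(network)
    nodes = network.nodes
    in_net = []
    absent = 0
    for u, v in sorted(pairs.pairs):
        if u in network and v in network:
            in_net.append((u, v))
        else:
            absent += 1
    if absent:
        logger.info("%d paralog pairs with a gene outside the network excluded", absent)
    if not in_net:
        raise ValueError("no paralog pair has both genes in the network")
    paralog_set = set(in_net)
    a = np.array([float(tri.get(p, 0)) for p in in_net])

    n = len(nodes)
    total_pairs = n * (n - 1) // 2
    n_background = total_pairs - len(paralog_set)
    rng = np.random.default_rng(seed)
    if n_background > max_background:
        # uniform subsample of unordered pairs via linear pair indices
        if total_pairs <= 4 * max_background:
            ks = rng.permutation(total_pairs)
        else:
            ks = np.unique(rng.integers(0, total_pairs, size=3 * max_background))
            rng.shuffle(ks)
        b_vals: list[float] = []
        for k in ks:
            k = int(k)
            i = int((2 * n - 1 - math.isqrt((2 * n - 1) ** 2 - 8 * k)) // 2)
            j = k - i * (2 * n - i - 1) // 2 + i + 1
            u, v = nodes[i], nodes[j]
            if (u, v) in paralog_set:
                continue
            b_vals.append(float(tri.get((u, v), 0)))
            if len(b_vals) == max_background:
                break
        b = np.array(b_vals)
    else:
        b = np.array(
            [
                float(tri.get((nodes[i], nodes[j]), 0))
                for i in range(n)
                for j in range(i + 1, n)
                if (nodes[i], nodes[j]) not in paralog_set
            ]
        )
    stat = mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return TriangleTestResult(
        p_value=float(stat.pvalue),
        median_paralog=float(np.median(a)),
        median_background=float(np.median(b)),
        n_paralog=len(a),
        n_background=len(b),
    )


def domain_paralog_ratio(
    domain: Domain,
    res: EnrichmentResult,
    pairs: ParalogPairs,
) -> float | None:
    """Fraction of a domain's enriched genes that are paralogous.

    A gene belongs to the domain's enriched genes if at least one of the
    domain's terms is enriched in the gene's own neighbourhood. Returns
    ``None`` (reported as missing) when the domain has no enriched genes.
    """
    if not domain.terms:
        raise ValueError("empty domain")
    term_idx = {t: j for j, t in enumerate(res.terms)}
    sig = res.significant_mask()
    cols = [term_idx[t] for t in domain.terms if t in term_idx]
    if not cols:
        return None
    any_sig = sig[:, cols].any(axis=1)
    enriched = {
        u
        for i, u in enumerate(res.nodes)
        if any_sig[i] and u in res.annotated_nodes
    }
    if not enriched:
        return None
    paralogous = pairs.genes()
    return len(enriched & paralogous) / len(enriched)
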