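"""ceRNA network assembly, lncRNA target/decoy classification, bridge-gene
detection, QTL co-localization, and generic over-representation testing.

Classification rule for a (lncRNA, miRNA) pair with binding-site evidence:
the lncRNA is a miRNA *target* when its expression correlates strongly
negatively with the miRNA (r <= -r_pair); it is a *decoy* (sponge) when it
is not a target but correlates strongly positively (r >= +r_pair) with at
least one mRNA target of that same miRNA.  Pairs matching neither rule
yield no edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .core import Config, ExpressionMatrix, GenomicInterval, TranscriptRecord
from .diffexpr import bh_adjust
from .targets import BindingSite, CorrelationEdge, correlation_matrix

NODE_TYPES = ("lncRNA", "miRNA", "mRNA")
EDGE_TYPES = ("lnc_mir_target", "lnc_mir_decoy", "mir_mrna")

_ROLE_BY_TYPE = {
    "miRNA": "mirna",
    "mRNA": "target_mrna",
}


@dataclass
class NetworkGraph:
    """Typed ceRNA network: nodes carry a type and (for lncRNAs) a role."""

    node_type: dict[str, str] = field(default_factory=dict)
    node_role: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add_edge(
        self, a: str, b: str, edge_type: str, r: float, site_evidence: bool
    ) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type}")
        if a == b:
            raise ValueError("self-edge")
        key = (min(a, b), max(a, b))
        if key in self.edges:
            return  # no duplicate undirected edges
        self.edges[key] = {"edge_type": edge_type, "r": r, "site": site_evidence}

    def set_node(self, node_id: str, node_type: str, role: str | None = None) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type}")
        self.node_type[node_id] = node_type
        self.node_role[node_id] = role or _ROLE_BY_TYPE.get(node_type, "none")

    def nodes(self) -> set[str]:
        return set(self.node_type)

    def node_triples(self) -> list[tuple[str, str, str]]:
        return [(n, self.node_type[n], self.node_role[n]) for n in self.node_type]

    def edge_triples(self) -> list[tuple[str, str, str]]:
        return [(a, b, meta["edge_type"]) for (a, b), meta in self.edges.items()]

    def neighbors(self, node_id: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == node_id:
                out.add(b)
            elif b == node_id:
                out.add(a)
        return out

    def validate(self) -> None:
        """Check all structural invariants; raise ValueError on violation."""
        touched: set[str] = set()
        for (a, b), meta in self.edges.items():
            touched.update((a, b))
            if a not in self.node_type or b not in self.node_type:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            types = {self.node_type[a], self.node_type[b]}
            et = meta["edge_type"]
            if et in ("lnc_mir_target", "lnc_mir_decoy"):
                if types != {"lncRNA", "miRNA"}:
                    raise ValueError(f"edge ({a}, {b}): {et} needs lncRNA-miRNA")
            elif types != {"miRNA", "mRNA"}:
                raise ValueError(f"edge ({a}, {b}): mir_mrna needs miRNA-mRNA")
        orphan = self.nodes() - touched
        if orphan:
            raise ValueError(f"nodes not in any pair: {sorted(orphan)[:5]}")


# ---------------------------------------------------------------------------
# lncRNA role classification
# ---------------------------------------------------------------------------

def classify_lncrna_roles(
    lnc_sites: Sequence[BindingSite],
    lnc_expr: ExpressionMatrix,
    mir_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    mir_mrna_edges: Sequence[CorrelationEdge],
    cfg: Config,
) -> tuple[dict[str, str], list[CorrelationEdge]]:
    """Assign target/decoy roles to lncRNAs with miRNA site evidence.

    Returns (role map lnc -> target|decoy, lnc_mir correlation edges).
    Only (lncRNA, miRNA) pairs backed by a retained binding site are
    considered; a lncRNA classified as target for one miRNA keeps that
    role even if it also decoys another (target takes precedence).
    """
    mrna_of_mir: dict[str, set[str]] = {}
    for e in mir_mrna_edges:
        mrna_of_mir.setdefault(e.a_id, set()).add(e.b_id)

    pairs = sorted({(s.target_id, s.mirna_id) for s in lnc_sites})
    r_lnc_mir = correlation_matrix(lnc_expr, mir_expr)
    r_lnc_mrna = correlation_matrix(lnc_expr, mrna_expr)
    lnc_pos = {f: i for i, f in enumerate(lnc_expr.feature_ids)}
    mir_pos = {f: i for i, f in enumerate(mir_expr.feature_ids)}
    mrna_pos = {f: i for i, f in enumerate(mrna_expr.feature_ids)}
    n = len(lnc_expr.sample_ids)

    roles: dict[str, str] = {}
    edges: list[CorrelationEdge] = []
    for lnc, mir in pairs:
        if lnc not in lnc_pos or mir not in mir_pos:
            continue
        r = r_lnc_mir[lnc_pos[lnc], mir_pos[mir]]
        if np.isnan(r):
            continue
        if r <= -cfg.r_pair:
            role = "target"
        else:
            partners = mrna_of_mir.get(mir, set())
            coexpr = any(
                m in mrna_pos
                and not np.isnan(r_lnc_mrna[lnc_pos[lnc], mrna_pos[m]])
                and r_lnc_mrna[lnc_pos[lnc], mrna_pos[m]] >= cfg.r_pair
                for m in partners
            )
            if not coexpr:
                continue
            role = "decoy"
        if roles.get(lnc) != "target":
            roles[lnc] = role
        edges.append(CorrelationEdge(lnc, mir, float(r), n, "lnc_mir"))
    return roles, edges


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(
    de_features: set[str],
    lnc_roles: Mapping[str, str],
    lnc_mir_edges: Sequence[CorrelationEdge],
    mir_mrna_candidates: Sequence[tuple[str, str, float, bool]],
    cfg: Config,
) -> NetworkGraph:
    """Assemble the ceRNA network under the pairing rules.

    A miRNA-mRNA edge is admitted iff it has binding-site evidence, |r| >
    r_pair, and both endpoints are differentially expressed; a
    lncRNA-miRNA edge iff both endpoints are DE.  Nodes with no admitted
    edge are dropped, so every node sits in at least one pair.

    *mir_mrna_candidates* are (mirna, mrna, r, site_evidence) tuples.
    """
    if not de_features:
        warnings.warn("empty DE set: network is empty")
    net = NetworkGraph()
    for mir, mrna, r, site in mir_mrna_candidates:
        if not site or abs(r) <= cfg.r_pair:
            continue
        if mir not in de_features or mrna not in de_features:
            continue
        net.set_node(mir, "miRNA")
        net.set_node(mrna, "mRNA")
        net.add_edge(mir, mrna, "mir_mrna", r, True)
    for e in lnc_mir_edges:
        lnc, mir = e.a_id, e.b_id
        role = lnc_roles.get(lnc)
        if role is None:
            continue
        if lnc not in de_features or mir not in de_features:
            continue
        net.set_node(mir, "miRNA")
        net.set_node(lnc, "lncRNA", "mir_target_lnc" if role == "target" else "decoy_lnc")
        net.add_edge(lnc, mir, f"lnc_mir_{role}", e.r, True)
    # drop any node that ended up with no admitted edge
    touched: set[str] = set()
    for a, b in net.edges:
        touched.update((a, b))
    for node in net.nodes() - touched:
        del net.node_type[node]
        del net.node_role[node]
    net.validate()
    return net


def find_bridges(net: NetworkGraph, min_mirna_degree: int = 2) -> list[tuple[str, int]]:
    """mRNA nodes linked to >= min_mirna_degree distinct miRNAs.

    Sorted by miRNA degree descending, then id ascending.
    """
    out = []
    for node, ntype in net.node_type.items():
        if ntype != "mRNA":
            continue
        deg = sum(1 for nb in net.neighbors(node) if net.node_type[nb] == "miRNA")
        if deg >= min_mirna_degree:
            out.append((node, deg))
    return sorted(out, key=lambda item: (-item[1], item[0]))


# ---------------------------------------------------------------------------
# QTL co-localization
# ---------------------------------------------------------------------------

@dataclass
class QTLCandidateSet:
    interval: GenomicInterval
    genes: set[str]
    lncrnas: set[str]


def qtl_colocalize(
    features: Sequence[TranscriptRecord],
    de_features: set[str],
    interval: GenomicInterval,
    cfg: Config,
) -> QTLCandidateSet:
    """DE features located within the QTL interval, split by class.

    Default semantics is full containment of the feature span; set
    ``cfg.qtl_overlap`` for any-overlap semantics.  lncRNA membership is
    decided by biotype (known_lncRNA or surviving novel_candidate); all
    other feature types count as genes.
    """
    chroms = {rec.interval.chrom for rec in features}
    if interval.chrom not in chroms:
        raise ValueError(f"QTL chromosome {interval.chrom!r} absent from annotation")
    hit = interval.overlaps if cfg.qtl_overlap else interval.contains
    genes: set[str] = set()
    lncrnas: set[str] = set()
    for rec in features:
        if rec.transcript_id not in de_features:
            continue
        if not hit(rec.interval):
            continue
        if rec.biotype in ("known_lncRNA", "novel_candidate"):
            lncrnas.add(rec.transcript_id)
        else:
            genes.add(rec.transcript_id)
    return QTLCandidateSet(interval=interval, genes=genes, lncrnas=lncrnas)


# ---------------------------------------------------------------------------
# Over-representation testing
# ---------------------------------------------------------------------------

def enrich_categories(
    query: set[str],
    universe: set[str],
    categories: Mapping[str, Iterable[str]],
) -> list[tuple[str, int, float, float]]:
    """Upper-tail hypergeometric over-representation per category, BH-adjusted.

    Returns rows (category, overlap, p, q) sorted by p then category name.
    p = P[X >= overlap] with X ~ Hypergeom(N=|universe|, K=|category|,
    n=|query|).
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    n_univ, n_query = len(universe), len(query)
    for name in sorted(categories):
        members = set(categories[name]) & universe
        overlap = len(members & query)
        p = float(hypergeom.sf(overlap - 1, n_univ, len(members), n_query))
        p = min(1.0, max(0.0, p))
        rows.append([name, overlap, p])
    qs = bh_adjust([row[2] for row in rows])
    out = [
        (name, overlap, p, q) for (name, overlap, p), q in zip(rows, qs)
    ]
    return sorted(out, key=lambda row: (row[2], row[0]))
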