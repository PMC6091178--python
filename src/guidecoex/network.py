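"""Sign-stratified bipartite guide-TF co-expression network and candidate report.

The network connects guide genes to transcription factors whose correlation
passes the network threshold (|r| > 0.6 by default), with each edge signed
by the sign of r. The network is strictly bipartite: TF-TF and guide-guide
edges are never emitted, and a guide that is itself an annotated TF is
excluded from the TF pool. Per-TF sign classification uses a majority rule
over the TF's edges (ties are "mixed" and logged), which yields the
positive/negative gene counts a practitioner reads off such a figure.
Candidate negative regulators are TFs with enough negative partners among
the guides.

Exports target Cytoscape: SIF (one ``guide<TAB>pos|neg<TAB>tf`` line per
edge) and GraphML with typed node and edge attributes, both byte-for-byte
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import networkx as nx
import pandas as pd

from guidecoex.correlation import CorrelationTable, ThresholdSpec
from guidecoex.io import TFFamilyAnnotation

__all__ = [
    "CandidateReport",
    "CoexEdge",
    "CoexNetwork",
    "SignSummary",
    "build_network",
    "count_edge_signs",
    "export_graphml",
    "export_sif",
    "read_sif",
    "select_negative_candidates",
    "write_candidates",
]

logger = logging.getLogger("guidecoex")

ALL_FAMILIES = "all"


@dataclass(frozen=True)
class CoexEdge:
    """A signed guide-TF edge; sign is determined by r."""

    guide_id: str
    tf_id: str
    r: float

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


@dataclass
class CoexNetwork:
    """Bipartite network of guide nodes and TF nodes with signed edges.

    TF nodes exist only if they carry at least one edge; guide nodes are
    always present. ``families`` maps each TF node to its family.
    """

    guide_ids: list[str]
    edges: list[CoexEdge]
    families: dict[str, str] = field(default_factory=dict)
    threshold_used: ThresholdSpec | None = None
    family_filter: str = ALL_FAMILIES

    def __post_init__(self) -> None:
        pairs = [(e.guide_id, e.tf_id) for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (guide, tf) edge")

    @property
    def tf_ids(self) -> list[str]:
        return sorted({e.tf_id for e in self.edges})

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_of_tf(self, tf_id: str) -> list[CoexEdge]:
        return [e for e in self.edges if e.tf_id == tf_id]

    def edge(self, guide_id: str, tf_id: str) -> CoexEdge | None:
        for e in self.edges:
            if e.guide_id == guide_id and e.tf_id == tf_id:
                return e
        return None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for guide in self.guide_ids:
            g.add_node(guide, type="guide", family="")
        for tf in self.tf_ids:
            g.add_node(tf, type="tf", family=self.families.get(tf, ""))
        for e in self.edges:
            g.add_edge(e.guide_id, e.tf_id, r=e.r, sign=e.sign)
        return g


@dataclass
class SignSummary:
    """Per-TF sign classification and class counts."""

    per_tf: dict[str, str]
    counts: dict[str, int]


@dataclass
class CandidateReport:
    """A TF's negative and positive guide partners (lists are disjoint)."""

    tf_id: str
    negative_partner_guides: list[str]
    positive_partner_guides: list[str]

    @property
    def n_negative(self) -> int:
        return len(self.negative_partner_guides)


def build_network(
    table: CorrelationTable,
    annotation: TFFamilyAnnotation,
    family: str = ALL_FAMILIES,
    spec: ThresholdSpec = ThresholdSpec(0.6),
) -> CoexNetwork:
    """One edge per (guide, TF) pair whose defined r passes the threshold.

    The TF pool is the annotated genes present in the table, optionally
    restricted to one family; guides never appear as TFs (self- and
    guide-guide pairs are excluded).
    """
    if family != ALL_FAMILIES:
        if family not in annotation.families:
            available = ", ".join(sorted(annotation.families))
            raise ValueError(f"unknown family {family!r}; available: {available}")
        pool = annotation.genes_in_family(family)
    else:
        pool = set(annotation.assignments)
    guide_set = set(table.guide_ids)
    pool = {g for g in pool if g in set(table.gene_ids) and g not in guide_set}

    edges: list[CoexEdge] = []
    for guide in table.guide_ids:
        row = table.r.loc[guide]
        for tf in sorted(pool):
            v = row[tf]
            if pd.notna(v) and spec.passes(float(v)):
                edges.append(CoexEdge(guide, tf, float(v)))
    families = {e.tf_id: annotation.assignments[e.tf_id] for e in edges}
    return CoexNetwork(
        guide_ids=list(table.guide_ids),
        edges=edges,
        families=families,
        threshold_used=spec,
        family_filter=family,
    )


def count_edge_signs(net: CoexNetwork) -> SignSummary:
    """Classify each TF node by the majority sign of its edges.

    A TF with equally many positive and negative edges is "mixed"
    (logged); counts are returned per class.
    """
    per_tf: dict[str, str] = {}
    counts = {"positive": 0, "negative": 0, "mixed": 0}
    for tf in net.tf_ids:
        signs = [e.sign for e in net.edges_of_tf(tf)]
        n_pos = signs.count("positive")
        n_neg = signs.count("negative")
        if n_pos > n_neg:
            cls = "positive"
        elif n_neg > n_pos:
            cls = "negative"
        else:
            cls = "mixed"
            logger.info("TF %s has a positive/negative edge tie; classified mixed", tf)
        per_tf[tf] = cls
        counts[cls] += 1
    return SignSummary(per_tf=per_tf, counts=counts)


def select_negative_candidates(
    net: CoexNetwork, min_negative_partners: int = 2
) -> list[CandidateReport]:
    """TFs with at least ``min_negative_partners`` negative guide edges.

    Sorted by number of negative partners descending, then tf_id.
    """
    if min_negative_partners < 1:
        raise ValueError("min_negative_partners must be >= 1")
    reports: list[CandidateReport] = []
    for tf in net.tf_ids:
        tf_edges = net.edges_of_tf(tf)
        neg = sorted(e.guide_id for e in tf_edges if e.sign == "negative")
        pos = sorted(e.guide_id for e in tf_edges if e.sign == "positive")
        if len(neg) >= min_negative_partners:
            reports.append(CandidateReport(tf, neg, pos))
    reports.sort(key=lambda c: (-c.n_negative, c.tf_id))
    return reports


def _sorted_edges(net: CoexNetwork) -> list[CoexEdge]:
    return sorted(net.edges, key=lambda e: (e.guide_id, e.tf_id))


def export_sif(net: CoexNetwork, path: str | Path) -> None:
    """Cytoscape SIF: one ``guide<TAB>pos|neg<TAB>tf`` line per edge.

    Edges sorted by (guide_id, tf_id); deterministic byte-for-byte.
    """
    lines = [
        f"{e.guide_id}\t{'pos' if e.sign == 'positive' else 'neg'}\t{e.tf_id}\n"
        for e in _sorted_edges(net)
    ]
    Path(path).write_text("".join(lines), encoding="utf-8")


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a SIF file back as (source, interaction, target) triples."""
    triples = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        src, kind, dst = line.split("\t")
        triples.append((src, kind, dst))
    return triples


def export_graphml(net: CoexNetwork, path: str | Path) -> None:
    """GraphML with node attributes type/family and edge attributes r/sign.

    r is printed with 6 decimals (round half to even); element ordering is
    deterministic: guides sorted, then TFs sorted, then edges sorted by
    (guide_id, tf_id).
    """
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">\n',
        '  <key id="d0" for="node" attr.name="type" attr.type="string"/>\n',
        '  <key id="d1" for="node" attr.name="family" attr.type="string"/>\n',
        '  <key id="d2" for="edge" attr.name="r" attr.type="double"/>\n',
        '  <key id="d3" for="edge" attr.name="sign" attr.type="string"/>\n',
        '  <graph edgedefault="undirected">\n',
    ]
    for guide in sorted(net.guide_ids):
        out.append(f'    <node id="{escape(guide, {chr(34): "&quot;"})}">\n')
        out.append("      <data key=\"d0\">guide</data>\n")
        out.append("      <data key=\"d1\"></data>\n")
        out.append("    </node>\n")
    for tf in net.tf_ids:
        fam = escape(net.families.get(tf, ""))
        out.append(f'    <node id="{escape(tf, {chr(34): "&quot;"})}">\n')
        out.append("      <data key=\"d0\">tf</data>\n")
        out.append(f"      <data key=\"d1\">{fam}</data>\n")
        out.append("    </node>\n")
    for e in _sorted_edges(net):
        src = escape(e.guide_id, {chr(34): "&quot;"})
        dst = escape(e.tf_id, {chr(34): "&quot;"})
        out.append(f'    <edge source="{src}" target="{dst}">\n')
        out.append(f"      <data key=\"d2\">{e.r:.6f}</data>\n")
        out.append(f"      <data key=\"d3\">{e.sign}</data>\n")
        out.append("    </edge>\n")
    out.append("  </graph>\n")
    out.append("</graphml>\n")
    Path(path).write_text("".join(out), encoding="utf-8")


def write_candidates(reports: list[CandidateReport], path: str | Path) -> None:
    """Candidate report TSV: tf_id, n_negative, partners semicolon-joined."""
    rows = [
        {
            "tf_id": c.tf_id,
            "n_negative": c.n_negative,
            "negative_partners": ";".join(c.negative_partner_guides),
            "positive_partners": ";".join(c.positive_partner_guides),
        }
        for c in reports
    ]
    pd.DataFrame.from_records(
        rows, columns=["tf_id", "n_negative", "negative_partners", "positive_partners"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
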