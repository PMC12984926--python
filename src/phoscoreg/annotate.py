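"""Annotation overlay, over-representation analysis and network export.

User-supplied tables (kinase-substrate edges, binary/complex interactors,
disease-expression labels, GMT gene sets) are overlaid onto co-regulation
screen results; protein sets are tested for over-representation with the
upper hypergeometric tail; the annotated anchor-partner graph is exported
as SIF, edge TSV or GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .coregulation import CoRegulationCall
from .ingest import SiteKey, ValidationError, parse_site_label

logger = logging.getLogger(__name__)

EDGE_TYPES = ("kinase_of", "substrate_of", "binary_interactor", "complex_interactor")
COREG_EDGE_TYPES = ("pos_coreg", "neg_coreg")
EXPORT_FORMATS = ("SIF", "edge_TSV", "GraphML")


@dataclass(frozen=True)
class AnnotationEdge:
    """One typed protein-protein relation from a user-supplied source."""

    source_protein: str
    target_protein: str
    edge_type: str
    evidence: str
    site_specific: SiteKey | None = None

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValidationError(
                f"edge_type {self.edge_type!r} not in {EDGE_TYPES}"
            )
        if not self.evidence:
            raise ValidationError("evidence must be non-empty")


@dataclass(frozen=True)
class ExpressionLabel:
    """Disease-context expression direction for one protein."""

    protein: str
    direction: str  # up | down
    context: str = ""
    activity_associated_sites: frozenset[SiteKey] = frozenset()

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction {self.direction!r} not in {{up, down}}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of a query set within one gene set."""

    gene_set_id: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p: float
    p_adj: float | None = None


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------


def overlay_annotations(
    calls: list[CoRegulationCall], edges: list[AnnotationEdge]
) -> list[CoRegulationCall]:
    """Attach to each call the edge types linking its partner protein to the anchor.

    Edges are matched in either orientation; calls without a matching edge
    are returned unchanged.  The output list has the same length and order
    as the input.
    """
    annotated = []
    for call in calls:
        anchor = call.pair.anchor.protein_symbol
        partner = call.pair.partner.protein_symbol
        types = frozenset(
            e.edge_type
            for e in edges
            if {e.source_protein.upper(), e.target_protein.upper()}
            == {anchor.upper(), partner.upper()}
        )
        annotated.append(replace(call, annotations=types) if types else call)
    return annotated


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------


def hypergeometric_ora(
    query_proteins: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    bh_adjust: bool = False,
) -> list[EnrichmentResult]:
    """Upper hypergeometric tail P(X >= k) per gene set, sorted by p.

    Gene sets are intersected with the universe; the query must be a
    subset of the universe.
    """
    if not universe:
        raise ValidationError("empty universe")
    stray = query_proteins - universe
    if stray:
        raise ValidationError(f"query proteins outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query_proteins)
    results = []
    for set_id in sorted(gene_sets):
        members = gene_sets[set_id] & universe
        K = len(members)
        k = len(members & query_proteins)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                gene_set_id=set_id, universe_size=N, set_size=K,
                query_size=n, overlap=k, p=min(p, 1.0),
            )
        )
    if bh_adjust and results:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [replace(r, p_adj=float(q)) for r, q in zip(results, adj)]
    results.sort(key=lambda r: (r.p, r.gene_set_id))
    return results


def enrichment_table(results: list[EnrichmentResult], path=None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "gene_set": r.gene_set_id, "universe_size": r.universe_size,
                "set_size": r.set_size, "query_size": r.query_size,
                "overlap": r.overlap, "p": r.p,
                "p_adj": r.p_adj if r.p_adj is not None else "",
            }
            for r in results
        ],
        columns=["gene_set", "universe_size", "set_size", "query_size",
                 "overlap", "p", "p_adj"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Network build / export
# ---------------------------------------------------------------------------


def _node_id(site: SiteKey) -> str:
    return f"{site.protein_symbol}:{site.site_label}"


def build_network(
    calls: list[CoRegulationCall],
    edges: list[AnnotationEdge] = (),
    labels: list[ExpressionLabel] = (),
) -> nx.MultiDiGraph:
    """Build the annotated co-regulation network around one anchor site.

    Nodes are phosphosites (anchor + partners of *passing* calls) with
    protein/position/residue attributes plus expression direction and the
    activity-associated flag from ``labels``.  Edges are signed
    co-regulation links (pos_coreg / neg_coreg, carrying the FET p-value
    and supporting count) plus any annotation edges between proteins
    present in the network.  Node insertion order is deterministic.
    """
    passing = [c for c in calls if c.passes_filters]
    g = nx.MultiDiGraph()
    anchors = sorted({c.pair.anchor for c in calls})
    label_by_protein = {lab.protein.upper(): lab for lab in labels}

    def add_site_node(site: SiteKey) -> None:
        lab = label_by_protein.get(site.protein_symbol.upper())
        g.add_node(
            _node_id(site),
            protein=site.protein_symbol,
            residue=site.residue,
            position=site.position,
            expression=lab.direction if lab else "",
            activity_associated=bool(lab and site in lab.activity_associated_sites),
        )

    for anchor in anchors:
        add_site_node(anchor)
    for call in sorted(
        passing, key=lambda c: (_node_id(c.pair.anchor), _node_id(c.pair.partner))
    ):
        add_site_node(call.pair.partner)
        interaction = "pos_coreg" if call.direction == "positive" else "neg_coreg"
        g.add_edge(
            _node_id(call.pair.anchor),
            _node_id(call.pair.partner),
            key=interaction,
            interaction=interaction,
            fet_p=call.fet_p,
            supporting=call.supporting_count,
            evidence="coregulation_screen",
        )
    proteins = {d["protein"].upper(): nid for nid, d in g.nodes(data=True)}
    for e in sorted(edges, key=lambda e: (e.source_protein, e.target_protein, e.edge_type)):
        s, t = e.source_protein.upper(), e.target_protein.upper()
        if s in proteins and t in proteins and s != t:
            g.add_edge(
                proteins[s], proteins[t], key=e.edge_type,
                interaction=e.edge_type, evidence=e.evidence,
            )
    return g


def export_network(network: nx.MultiDiGraph, fmt: str, path) -> None:
    """Export as ``SIF``, ``edge_TSV`` or ``GraphML`` (unknown format -> error)."""
    path = Path(path)
    if fmt == "SIF":
        lines = [
            f"{u}\t{d['interaction']}\t{v}"
            for u, v, d in sorted(network.edges(data=True),
                                  key=lambda x: (x[0], x[2]["interaction"], x[1]))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "edge_TSV":
        edge_tsv_frame(network).to_csv(path, sep="\t", index=False)
    elif fmt == "GraphML":
        nx.write_graphml(_graphml_safe(network), path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")


def edge_tsv_frame(network: nx.MultiDiGraph) -> pd.DataFrame:
    """Canonical, fully attributed edge list (round-trips via :func:`read_edge_tsv`)."""
    rows = []
    for u, v, d in network.edges(data=True):
        du, dv = network.nodes[u], network.nodes[v]
        rows.append(
            {
                "source": u, "target": v, "interaction": d["interaction"],
                "evidence": d.get("evidence", ""),
                # shortest-repr formatting so text round-trips bit-exactly
                "fet_p": repr(float(d["fet_p"])) if "fet_p" in d else "",
                "supporting": d.get("supporting", ""),
                "source_expression": du.get("expression", ""),
                "target_expression": dv.get("expression", ""),
                "target_activity_associated": dv.get("activity_associated", False),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["source", "target", "interaction", "evidence", "fet_p",
                 "supporting", "source_expression", "target_expression",
                 "target_activity_associated"],
    )
    return df.sort_values(["source", "interaction", "target"]).reset_index(drop=True)


def read_edge_tsv(path) -> nx.MultiDiGraph:
    """Re-import an edge TSV into the internal network model."""
    # dtype=str + float(): pandas' default float parser is not correctly
    # rounded, which would break byte-exact round-trips
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    g = nx.MultiDiGraph()
    for row in df.itertuples(index=False):
        for nid, expr in ((row.source, row.source_expression),
                          (row.target, row.target_expression)):
            if nid not in g:
                protein, label = nid.split(":", 1)
                residue, pos = parse_site_label(label)
                g.add_node(nid, protein=protein, residue=residue, position=pos,
                           expression=str(expr), activity_associated=False)
        if str(row.target_activity_associated).lower() == "true":
            g.nodes[row.target]["activity_associated"] = True
        attrs = {"interaction": row.interaction}
        if row.evidence != "":
            attrs["evidence"] = str(row.evidence)
        if row.fet_p != "":
            attrs["fet_p"] = float(row.fet_p)
        if row.supporting != "":
            attrs["supporting"] = int(float(row.supporting))
        g.add_edge(row.source, row.target, key=row.interaction, **attrs)
    return g


def _graphml_safe(network: nx.MultiDiGraph) -> nx.MultiDiGraph:
    g = network.copy()
    for _, d in g.nodes(data=True):
        for k, v in list(d.items()):
            if v is None:
                d[k] = ""
    return g


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------


def read_annotation_tsv(path) -> list[AnnotationEdge]:
    """Annotation TSV: source, target, edge_type, evidence, site (optional, e.g. 'S241')."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"source", "target", "edge_type", "evidence"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    edges = []
    for row in df.itertuples(index=False):
        site = None
        raw_site = getattr(row, "site", "")
        if raw_site:
            residue, pos = parse_site_label(raw_site)
            site = SiteKey(row.target.strip().upper(), residue, pos)
        edges.append(
            AnnotationEdge(
                source_protein=row.source.strip().upper(),
                target_protein=row.target.strip().upper(),
                edge_type=row.edge_type.strip(),
                evidence=row.evidence.strip(),
                site_specific=site,
            )
        )
    return edges


def read_label_tsv(path) -> list[ExpressionLabel]:
    """Label TSV: protein, direction, context, activity_sites (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"protein", "direction"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    labels = []
    for row in df.itertuples(index=False):
        protein = row.protein.strip().upper()
        sites = frozenset(
            SiteKey(protein, *parse_site_label(tok))
            for tok in getattr(row, "activity_sites", "").split(";")
            if tok.strip()
        )
        labels.append(
            ExpressionLabel(
                protein=protein,
                direction=row.direction.strip(),
                context=getattr(row, "context", ""),
                activity_associated_sites=sites,
            )
        )
    return labels


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: set id, description, then member symbols, tab-separated."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            gene_sets[parts[0]] = {p.strip().upper() for p in parts[2:] if p.strip()}
    return gene_sets
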