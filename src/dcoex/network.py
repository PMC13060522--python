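"""Differential Spearman co-expression networks with topology metrics.

Within each group a Spearman correlation matrix is computed over the node
genes (midranks; exact permutation p for n <= 8, t-approximation beyond).
The edge set is the union of a curated interaction list (SIF) and novel
data-driven pairs passing |rho| >= rho_min with within-group significance in
at least one group.  Every edge carries both groups' rho/p and a Fisher
r-to-z test of the between-group correlation change.  Topology metrics
follow the NetworkAnalyzer conventions (closeness as reciprocal of mean
shortest-path distance, Freeman degree centralization, heterogeneity as the
coefficient of variation of the degree distribution).

Outlier-screened values excluded from differential expression are retained
here: rank correlations are robust to extreme values, and the variance they
carry is informative for co-expression structure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EdgeStat",
    "TopologyReport",
    "spearman_with_exact_p",
    "fisher_z_change",
    "read_sif",
    "write_sif",
    "build_network",
    "topology",
    "annotate_and_export",
]

EXACT_PERMUTATION_MAX_N = 8


def spearman_with_exact_p(x, y) -> tuple[float, float]:
    """Midrank Spearman rho with a two-sided exact permutation p (n <= 8).

    For n <= 8 the p-value is the proportion of the n! permutations of y
    whose |rho| is at least the observed |rho|; beyond that the usual
    t-approximation on n-2 df is used.  Constant inputs raise ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_PERMUTATION_MAX_N:
        rxc = rx - rx.mean()
        denom_x = math.sqrt(float(rxc @ rxc))
        ryc = ry - ry.mean()
        denom_y = math.sqrt(float(ryc @ ryc))
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(ryc):
            r = float(rxc @ np.array(perm)) / (denom_x * denom_y)
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, p


def fisher_z_change(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test of equality of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p
    from the standard normal.  |r| = 1 is clamped to 1 - 1e-6.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("each group needs n > 3")
    clamp = 1.0 - 1e-6
    r1 = max(-clamp, min(clamp, float(r1)))
    r2 = max(-clamp, min(clamp, float(r2)))
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


@dataclass
class EdgeStat:
    gene_a: str
    gene_b: str
    source: str  # "curated" | "novel"
    rho_g1: float
    rho_g2: float
    p_g1: float
    p_g2: float
    n_g1: int
    n_g2: int
    z_change: float
    p_change: float
    direction: str  # "strengthened" | "weakened" | "unchanged"
    significance_class: str  # "solid" if min(p_g1, p_g2) < 0.05 else "dashed"


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    density: float
    clustering_coefficient: float
    char_path_length: float
    diameter: float
    radius: float
    heterogeneity: float
    centralization: float
    n_components: int
    flags: list[str] = field(default_factory=list)


def read_sif(path) -> list[tuple[str, str, str]]:
    """Read a SIF file into (source, interaction, target) triples."""
    triples = []
    for line in Path(path).read_text().splitlines():
        parts = line.strip().split("\t")
        if len(parts) < 3 or not parts[0]:
            if line.strip():
                parts = line.split()
            if len(parts) < 3:
                continue
        src, rel = parts[0], parts[1]
        for tgt in parts[2:]:
            triples.append((src, rel, tgt))
    return triples


def write_sif(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in graph.edges(data=True):
            fh.write(f"{u}\t{data.get('source', 'pp')}\t{v}\n")
        for node in graph.nodes:
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


def _group_correlations(expr: pd.DataFrame, cols) -> dict[tuple[str, str], tuple[float, float, int]]:
    out = {}
    genes = list(expr.index)
    sub = expr[list(cols)]
    for ga, gb in itertools.combinations(genes, 2):
        x = sub.loc[ga].to_numpy(dtype=float)
        y = sub.loc[gb].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        try:
            rho, p = spearman_with_exact_p(x[ok], y[ok])
        except ValueError:
            rho, p = math.nan, math.nan
        out[(ga, gb)] = (rho, p, n)
    return out


def build_network(
    expression: pd.DataFrame,
    groups: pd.Series,
    curated: list[tuple[str, str, str]] | None = None,
    *,
    control_label: str = "control",
    case_label: str = "case",
    rho_min: float = 0.9,
    p_max: float = 0.05,
    include_novel: bool = True,
) -> nx.Graph:
    """Curated ∪ data-driven gene network with per-edge differential stats.

    ``expression`` is genes x cases on the node gene set (outlier-retained
    values); group 1 is control, group 2 is case.  Novel edges are pairs
    with |rho| >= rho_min AND p < p_max in at least one group.  Curated
    edges referencing genes absent from the expression index are dropped
    (counted in graph attribute ``n_curated_dropped``).
    """
    groups = groups.reindex(expression.columns)
    ctrl_cols = groups.index[groups == control_label]
    case_cols = groups.index[groups == case_label]
    if len(ctrl_cols) == 0 or len(case_cols) == 0:
        raise ValueError("both groups must be present")
    genes = set(expression.index)

    corr1 = _group_correlations(expression, ctrl_cols)
    corr2 = _group_correlations(expression, case_cols)

    def key(a, b):
        return (a, b) if (a, b) in corr1 else (b, a)

    G = nx.Graph(n_curated_dropped=0)
    G.add_nodes_from(expression.index)

    curated_pairs: set[tuple[str, str]] = set()
    dropped = 0
    for src, _rel, tgt in curated or []:
        if src == tgt:
            continue
        if src not in genes or tgt not in genes:
            dropped += 1
            continue
        curated_pairs.add(key(src, tgt))
    G.graph["n_curated_dropped"] = dropped

    novel_pairs: set[tuple[str, str]] = set()
    if include_novel:
        for pair in corr1:
            r1, p1, _ = corr1[pair]
            r2, p2, _ = corr2[pair]
            hit1 = not math.isnan(r1) and abs(r1) >= rho_min and p1 < p_max
            hit2 = not math.isnan(r2) and abs(r2) >= rho_min and p2 < p_max
            if (hit1 or hit2) and pair not in curated_pairs:
                novel_pairs.add(pair)

    for pair in sorted(curated_pairs | novel_pairs):
        ga, gb = pair
        r1, p1, n1 = corr1[pair]
        r2, p2, n2 = corr2[pair]
        if not (math.isnan(r1) or math.isnan(r2)) and n1 > 3 and n2 > 3:
            # z is case-minus-control so positive = strengthened in cases
            z, pz = fisher_z_change(r2, n2, r1, n1)
        else:
            z, pz = math.nan, math.nan
        if math.isnan(z) or z == 0:
            direction = "unchanged"
        else:
            direction = "strengthened" if r2 - r1 > 0 else "weakened"
        sig = "solid" if min(p1, p2) < 0.05 else "dashed"
        G.add_edge(
            ga, gb,
            source="curated" if pair in curated_pairs else "novel",
            rho_g1=r1, rho_g2=r2, p_g1=p1, p_g2=p2, n_g1=n1, n_g2=n2,
            z_change=z, p_change=pz, direction=direction,
            significance_class=sig,
        )
    return G


def topology(G: nx.Graph) -> tuple[TopologyReport, pd.DataFrame]:
    """Global topology report plus per-node metrics.

    Per-node: degree, normalized betweenness, closeness (reciprocal of mean
    shortest-path distance), local clustering coefficient.  On disconnected
    graphs the path-based global metrics are averaged over components and
    flagged.
    """
    if any(u == v for u, v in G.edges):
        raise ValueError("graph must be simple (no self-loops)")
    n = G.number_of_nodes()
    e = G.number_of_edges()
    flags: list[str] = []
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    degrees = np.array([d for _, d in G.degree()], dtype=float)
    avg_neighbors = 2 * e / n if n else 0.0
    heterogeneity = (
        math.sqrt(float(np.var(degrees))) / degrees.mean() if degrees.mean() > 0 else math.nan
    )
    centralization = (
        n / (n - 2) * (degrees.max() / (n - 1) - density) if n > 2 else math.nan
    )

    components = list(nx.connected_components(G))
    n_comp = len(components)
    if n_comp == 1 and n > 1:
        cpl = nx.average_shortest_path_length(G)
        diam = float(nx.diameter(G))
        rad = float(nx.radius(G))
    else:
        flags.append("disconnected")
        cpls, diams, rads = [], [], []
        for comp in components:
            if len(comp) > 1:
                sub = G.subgraph(comp)
                cpls.append(nx.average_shortest_path_length(sub))
                diams.append(nx.diameter(sub))
                rads.append(nx.radius(sub))
        cpl = float(np.mean(cpls)) if cpls else math.nan
        diam = float(max(diams)) if diams else math.nan
        rad = float(min(rads)) if rads else math.nan

    clustering = nx.clustering(G)
    betweenness = nx.betweenness_centrality(G, normalized=True)
    # closeness within components: (n_comp_nodes - 1) / sum of distances
    closeness = {}
    for comp in components:
        sub = G.subgraph(comp)
        for node in comp:
            if len(comp) > 1:
                dists = nx.single_source_shortest_path_length(sub, node)
                closeness[node] = (len(comp) - 1) / sum(dists.values())
            else:
                closeness[node] = 0.0

    node_table = pd.DataFrame(
        {
            "degree": dict(G.degree()),
            "betweenness": betweenness,
            "closeness": closeness,
            "clustering": clustering,
        }
    )
    report = TopologyReport(
        n_nodes=n,
        n_edges=e,
        avg_neighbors=float(avg_neighbors),
        density=float(density),
        clustering_coefficient=float(np.mean(list(clustering.values()))) if n else math.nan,
        char_path_length=float(cpl),
        diameter=diam,
        radius=rad,
        heterogeneity=float(heterogeneity),
        centralization=float(centralization),
        n_components=n_comp,
        flags=flags,
    )
    return report, node_table


def annotate_and_export(
    G: nx.Graph,
    de_table: pd.DataFrame,
    pca_loadings: pd.DataFrame | None,
    out_dir,
    *,
    prefix: str = "network",
) -> dict[str, Path]:
    """Attach expression/module attributes to nodes and write all exports.

    Node attributes: fold_change, log2fc, direction_class (sign of log2fc),
    component (argmax |loading| among retained components), loading_abs, and
    the four per-node topology metrics.  Writes GraphML, SIF, a node table
    and an edge table; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _, node_metrics = topology(G)

    for node in G.nodes:
        attrs: dict = {}
        if node in de_table.index:
            fc = float(de_table.loc[node, "fc"])
            l2 = float(de_table.loc[node, "log2fc"])
            attrs["fold_change"] = fc
            attrs["log2fc"] = l2
            attrs["direction_class"] = "up" if l2 > 0 else ("down" if l2 < 0 else "flat")
        if pca_loadings is not None and node in pca_loadings.index:
            row = pca_loadings.loc[node].abs()
            comp = str(row.idxmax())
            attrs["component"] = comp
            attrs["loading_abs"] = float(row.max())
        for metric in ("degree", "betweenness", "closeness", "clustering"):
            attrs[metric] = float(node_metrics.loc[node, metric])
        G.nodes[node].update(attrs)

    paths = {
        "graphml": out_dir / f"{prefix}.graphml",
        "sif": out_dir / f"{prefix}.sif",
        "nodes": out_dir / f"{prefix}_nodes.tsv",
        "edges": out_dir / f"{prefix}_edges.tsv",
    }
    export = G.copy()
    for _, _, data in export.edges(data=True):
        for k, v in list(data.items()):
            if isinstance(v, float) and math.isnan(v):
                data[k] = "NA"
    nx.write_graphml(export, paths["graphml"])
    write_sif(G, paths["sif"])

    node_rows = []
    for node, data in G.nodes(data=True):
        node_rows.append({"gene_id": node, **data})
    pd.DataFrame(node_rows).set_index("gene_id").sort_index().to_csv(
        paths["nodes"], sep="\t", float_format="%.4g"
    )
    edge_rows = []
    for u, v, data in G.edges(data=True):
        edge_rows.append({"gene_a": u, "gene_b": v, **data})
    pd.DataFrame(edge_rows).to_csv(paths["edges"], sep="\t", index=False,
                                   float_format="%.4g")
    return paths
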