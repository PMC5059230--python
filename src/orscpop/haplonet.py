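"""Chloroplast haplotype collapse, parsimony networks, cpGroups, polarity.

Accession-level variant vectors (SNPs and single-character indel codes,
every polymorphism weighted as one mutational event) are collapsed to
exact-match haplotypes, then joined into a minimum-spanning-style
statistical-parsimony network: haplotype pairs are considered in order of
increasing Hamming distance and a connection of length j (introducing j-1
inferred intermediate nodes) is added whenever the pair is not already
joined by a path of j or fewer steps.  Equally short alternative
connections are all retained, which is what produces the loops seen in
real chloroplast networks.  The probabilistic connection limit of the TCS
statistical-parsimony calculation is taken as an input parameter
(default 6 steps for a ~25-site alignment).

Chloroplast groups (cpGroups) are the connected components that remain
after removing connections longer than a threshold; components with a
single sampled haplotype are flagged as independent haplotypes.  Ancestral
vs derived states are called per site from outgroup allele frequencies
(ancestral requires outgroup frequency above a threshold, default 65 %,
plus presence in the ingroup).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("orscpop")

CP_MISSING = "?"


@dataclass
class HaplotypeAlignment:
    """Per-accession allele vectors over the selected variant sites."""

    site_ids: list
    site_kind: list            # "SNP" or "indel" per site
    accession_ids: list
    alleles: np.ndarray        # (n_accessions, n_sites) of 1-char strings
    group_labels: list         # nuclear subpop / cultivar subpop / outgroup / admixed

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=object)
        n, s = len(self.accession_ids), len(self.site_ids)
        if self.alleles.shape != (n, s):
            raise ValueError("alleles must be (n_accessions, n_sites)")
        if len(self.group_labels) != n or len(self.site_kind) != s:
            raise ValueError("label lengths do not match")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


@dataclass
class Connection:
    """One added network connection between two sampled haplotypes."""

    hap_a: str
    hap_b: str
    length: int                # mutational steps
    intermediates: list        # inferred node names along the path


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph                   # nodes: sampled haplotypes + inferred intermediates
    haplotypes: pd.DataFrame          # collapse table (haplotype, sequence, count, groups)
    connections: list[Connection]
    connection_limit: int
    cp_groups: dict[str, str] = field(default_factory=dict)  # haplotype -> group name

    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("sampled")]


# ---------------------------------------------------------------------------
# collapse
# ---------------------------------------------------------------------------


def collapse_haplotypes(a: HaplotypeAlignment) -> pd.DataFrame:
    """Collapse identical allele vectors into haplotypes.

    Rows with any missing site are excluded (logged).  Haplotypes are
    numbered H1, H2, ... by (count descending, sequence lexicographic), so
    the numbering is deterministic.  The table carries total and per-group
    accession counts plus the member accession ids.
    """
    complete = np.array(
        [CP_MISSING not in row for row in a.alleles], dtype=bool
    )
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("collapse_haplotypes: excluded %d accession(s) with missing sites",
                    n_dropped)
    if not complete.any():
        raise ValueError("no complete haplotype rows to collapse")
    seqs: dict[str, list[int]] = {}
    for i in np.flatnonzero(complete):
        s = "".join(a.alleles[i])
        seqs.setdefault(s, []).append(i)
    ordered = sorted(seqs.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rows = []
    for h, (seq, members) in enumerate(ordered, start=1):
        groups = pd.Series([a.group_labels[i] for i in members]).value_counts().to_dict()
        rows.append(
            {
                "haplotype": f"H{h}",
                "sequence": seq,
                "count": len(members),
                "group_counts": groups,
                "accessions": [a.accession_ids[i] for i in members],
            }
        )
    return pd.DataFrame(rows)


def hamming(s: str, t: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(s, t))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def build_network(haps: pd.DataFrame, connection_limit: int = 6) -> HaplotypeNetwork:
    """Minimum-spanning-network construction with retained ties.

    Pairs are processed in (Hamming distance, haplotype number) order.  A
    connection is added when the pair's current network distance (in unit
    mutational steps, counting inferred intermediates) exceeds their
    Hamming distance d, and d <= connection_limit.  Each connection of
    length j contributes j-1 connection-private inferred nodes.
    """
    if len(haps) == 0:
        raise ValueError("no haplotypes")
    if connection_limit < 1:
        raise ValueError("connection_limit must be >= 1")
    G = nx.Graph()
    for _, row in haps.iterrows():
        G.add_node(row["haplotype"], sampled=True, count=int(row["count"]),
                   sequence=row["sequence"], group_counts=row["group_counts"])
    names = list(haps["haplotype"])
    seq = dict(zip(haps["haplotype"], haps["sequence"]))
    pairs = []
    for u, v in itertools.combinations(names, 2):
        d = hamming(seq[u], seq[v])
        pairs.append((d, int(u[1:]), int(v[1:]), u, v))
    pairs.sort()
    connections: list[Connection] = []
    n_inferred = 0
    for d, _, _, u, v in pairs:
        if d > connection_limit:
            continue
        try:
            cur = nx.shortest_path_length(G, u, v)
        except nx.NetworkXNoPath:
            cur = np.inf
        if cur <= d:
            continue
        inter = []
        prev = u
        for step in range(d - 1):
            n_inferred += 1
            node = f"m{n_inferred}"
            G.add_node(node, sampled=False, count=0)
            G.add_edge(prev, node)
            inter.append(node)
            prev = node
        G.add_edge(prev, v)
        connections.append(Connection(u, v, d, inter))
    return HaplotypeNetwork(graph=G, haplotypes=haps, connections=connections,
                            connection_limit=connection_limit)


# ---------------------------------------------------------------------------
# cpGroups
# ---------------------------------------------------------------------------


def delineate_groups(net: HaplotypeNetwork, threshold_limit: int | None = None) -> dict[str, str]:
    """Partition sampled haplotypes into cpGroups at a connection threshold.

    Connections longer than ``threshold_limit`` are removed; connected
    components with at least two sampled haplotypes become cpGroup I, II,
    ... (ordered by total accession count, descending); components with a
    single sampled haplotype are labelled ``independent``.
    """
    if threshold_limit is None:
        threshold_limit = net.connection_limit
    G = net.graph.copy()
    for conn in net.connections:
        if conn.length > threshold_limit:
            path = [conn.hap_a, *conn.intermediates, conn.hap_b]
            for x, y in zip(path[:-1], path[1:]):
                if G.has_edge(x, y):
                    G.remove_edge(x, y)
            G.remove_nodes_from(conn.intermediates)
    comps = []
    for comp in nx.connected_components(G):
        sampled = [n for n in comp if G.nodes[n].get("sampled")]
        if sampled:
            total = sum(G.nodes[n]["count"] for n in sampled)
            comps.append((total, sorted(sampled, key=lambda s: int(s[1:]))))
    comps.sort(key=lambda t: (-t[0], t[1]))
    assignment: dict[str, str] = {}
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
             "XI", "XII", "XIII", "XIV", "XV", "XVI"]
    g = 0
    for total, sampled in comps:
        if len(sampled) >= 2:
            name = f"cpGroup {roman[g]}" if g < len(roman) else f"cpGroup {g + 1}"
            g += 1
        else:
            name = "independent"
        for h in sampled:
            assignment[h] = name
    net.cp_groups = assignment
    return assignment


# ---------------------------------------------------------------------------
# ancestral / derived polarity
# ---------------------------------------------------------------------------


def classify_ancestral_derived(
    a: HaplotypeAlignment,
    outgroup_labels,
    freq_threshold: float = 0.65,
) -> pd.DataFrame:
    """Call ancestral and derived alleles per site from outgroup frequencies.

    An allele is ancestral when its frequency among outgroup accessions is
    strictly above ``freq_threshold`` and it also occurs in the ingroup;
    the alternative ingroup allele is then derived.  Monomorphic or
    ambiguous sites are reported unresolved.
    """
    outgroup_labels = set(outgroup_labels)
    is_out = np.array([lab in outgroup_labels for lab in a.group_labels], dtype=bool)
    if not is_out.any():
        raise ValueError("no outgroup accessions found")
    rows = []
    for s, site in enumerate(a.site_ids):
        col = a.alleles[:, s]
        called = col != CP_MISSING
        out_alleles = col[is_out & called]
        in_alleles = col[~is_out & called]
        status, anc, der = "unresolved", None, None
        all_alleles = sorted(set(col[called]))
        if len(all_alleles) >= 2 and len(out_alleles) > 0 and len(in_alleles) > 0:
            vals, counts = np.unique(out_alleles, return_counts=True)
            freqs = counts / counts.sum()
            top = int(np.argmax(freqs))
            if freqs[top] > freq_threshold and vals[top] in set(in_alleles):
                anc = str(vals[top])
                others = sorted(set(in_alleles) - {anc})
                if len(others) == 1:
                    der = others[0]
                    status = "resolved"
                elif len(others) == 0:
                    pass  # ingroup fixed for the ancestral allele
        rows.append({"site_id": site, "kind": a.site_kind[s], "status": status,
                     "ancestral": anc, "derived": der})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_alignment_tsv(path) -> HaplotypeAlignment:
    """Site x metadata TSV: columns accession_id, group, then one column per
    site named ``<site_id>:<kind>`` holding single-character alleles."""
    df = pd.read_csv(str(path), sep="\t", dtype=str).fillna(CP_MISSING)
    site_cols = [c for c in df.columns if c not in ("accession_id", "group")]
    site_ids, kinds = [], []
    for c in site_cols:
        sid, _, kind = c.partition(":")
        site_ids.append(sid)
        kinds.append(kind or "SNP")
    return HaplotypeAlignment(
        site_ids=site_ids,
        site_kind=kinds,
        accession_ids=list(df["accession_id"]),
        alleles=df[site_cols].to_numpy(dtype=object),
        group_labels=list(df["group"]),
    )


def write_alignment_tsv(a: HaplotypeAlignment, path) -> None:
    df = pd.DataFrame({"accession_id": a.accession_ids, "group": a.group_labels})
    for s, (sid, kind) in enumerate(zip(a.site_ids, a.site_kind)):
        df[f"{sid}:{kind}"] = a.alleles[:, s]
    df.to_csv(str(path), sep="\t", index=False)


def write_alignment_fasta(a: HaplotypeAlignment, path) -> None:
    """Concatenated variant-site alleles, one record per accession."""
    with open(str(path), "w") as fh:
        for i, acc in enumerate(a.accession_ids):
            fh.write(f">{acc} group={a.group_labels[i]}\n")
            fh.write("".join(a.alleles[i]) + "\n")


def write_network(net: HaplotypeNetwork, edges_path, gml_path=None) -> None:
    rows = [{"node_a": u, "node_b": v} for u, v in net.graph.edges()]
    pd.DataFrame(rows).to_csv(str(edges_path), sep="\t", index=False)
    if gml_path is not None:
        G = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            G.add_node(n, sampled=int(bool(d.get("sampled"))), count=int(d.get("count", 0)))
        G.add_edges_from(net.graph.edges())
        nx.write_gml(G, str(gml_path))


def write_group_assignments(net: HaplotypeNetwork, path) -> None:
    rows = []
    for _, row in net.haplotypes.iterrows():
        cp = net.cp_groups.get(row["haplotype"], "")
        for acc in row["accessions"]:
            rows.append({"accession_id": acc, "haplotype": row["haplotype"], "cp_group": cp})
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)
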