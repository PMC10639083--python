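"""Reciprocal-best-hit (RBH) orthology and maximal-clique ortholog clusters.

Pairwise protein similarity searches are consumed as 12-column tabular hits
(BLAST/DIAMOND outfmt 6).  For each species pair, the best hit per query gene is the
maximum-bitscore subject (ties broken by lexicographically smaller subject id) among
hits passing the E-value cutoff (default 1e-10); an RBH edge joins two genes that are
each other's best hits.  Maximal cliques of the resulting multi-species graph are the
ortholog clusters; a cluster is retained when it has exactly one gene from every
requested species.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import pandas as pd

from .errors import ParameterError

log = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path_or_frame) -> pd.DataFrame:
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
        if not set(("qseqid", "sseqid", "evalue", "bitscore")) <= set(df.columns):
            raise ParameterError("hit table needs qseqid/sseqid/evalue/bitscore columns")
        return df
    return pd.read_csv(path_or_frame, sep="\t", names=OUTFMT6_COLUMNS, comment="#")


def best_hits(hits, evalue_max: float = 1e-10) -> dict[str, str]:
    """Best subject per query gene: max bitscore, ties to the smaller subject id."""
    df = read_hit_table(hits)
    df = df[df["evalue"] <= evalue_max]
    if df.empty:
        log.info("hit table empty after E-value filter (cutoff %g)", evalue_max)
        return {}
    df = df.sort_values(["qseqid", "bitscore", "sseqid"],
                        ascending=[True, False, True], kind="mergesort")
    top = df.drop_duplicates("qseqid", keep="first")
    return dict(zip(top["qseqid"], top["sseqid"]))


def rbh_graph(
    pair_hits: dict[tuple[str, str], object],
    evalue_max: float = 1e-10,
    subset: dict[str, set[str]] | None = None,
) -> nx.Graph:
    """Build the RBH graph over all species pairs.

    ``pair_hits[(sp_a, sp_b)]`` holds hits with sp_a genes as queries and sp_b genes
    as subjects; both directions must be supplied (or the same key reused with
    roles swapped via a second entry).  Nodes are (species, gene_id); an edge exists
    iff the two genes are mutual best hits.  ``subset`` optionally restricts each
    species to a gene list before the search (e.g. minor intron-containing genes);
    this yields the same edges as the matching subgraph of a full run.
    """
    best: dict[tuple[str, str], dict[str, str]] = {}
    frames: dict[tuple[str, str], pd.DataFrame] = {}
    for (sp_q, sp_s), hits in pair_hits.items():
        if sp_q == sp_s:
            raise ParameterError("hit tables must relate two different species")
        df = read_hit_table(hits)
        if subset is not None:
            df = df[df["qseqid"].isin(subset.get(sp_q, set()))
                    & df["sseqid"].isin(subset.get(sp_s, set()))]
        frames[(sp_q, sp_s)] = df
        best[(sp_q, sp_s)] = best_hits(df, evalue_max)

    graph = nx.Graph()
    for (sp_q, sp_s), fwd in best.items():
        rev = best.get((sp_s, sp_q))
        if rev is None:
            continue
        for q, s in fwd.items():
            if rev.get(s) == q:
                graph.add_edge((sp_q, q), (sp_s, s),
                               bitscore=_edge_bitscore(frames[(sp_q, sp_s)], q, s))
    return graph


def _edge_bitscore(df: pd.DataFrame, q: str, s: str) -> float:
    rows = df[(df["qseqid"] == q) & (df["sseqid"] == s)]
    return float(rows["bitscore"].max()) if len(rows) else float("nan")


def ortholog_cliques(graph: nx.Graph, species_set) -> list[dict[str, str]]:
    """Maximal cliques spanning exactly one gene from each requested species.

    The graph is first restricted to the requested species; since no RBH edge joins
    two genes of the same species, any clique has at most one gene per species, so
    the retained cliques are those of size len(species_set).  Output is sorted for
    order-independence.
    """
    species_set = set(species_set)
    graph_species = {sp for sp, _ in graph.nodes}
    if not species_set <= graph_species:
        raise ParameterError(f"species {species_set - graph_species} not in graph")
    sub = graph.subgraph(n for n in graph.nodes if n[0] in species_set)
    out = []
    for clique in nx.find_cliques(sub):
        if len(clique) == len(species_set):
            out.append({sp: gene for sp, gene in clique})
    out.sort(key=lambda c: sorted(c.items()))
    return out


def cliques_to_frame(cliques: list[dict[str, str]]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(cliques, start=1):
        for sp in sorted(c):
            rows.append({"clique_id": f"clq{i:05d}", "species": sp, "gene_id": c[sp]})
    return pd.DataFrame(rows, columns=["clique_id", "species", "gene_id"])


# ---------------------------------------------------------------------------
# toy similarity scorer for synthetic end-to-end tests
# ---------------------------------------------------------------------------

def kmer_hit_table(
    queries: dict[str, str],
    subjects: dict[str, str],
    k: int = 4,
    min_shared: int = 1,
) -> pd.DataFrame:
    """Exact k-mer containment scorer standing in for an external similarity search.

    bitscore = number of shared k-mers; rows below ``min_shared`` are omitted.
    E-values are set to 0 so every reported hit passes downstream cutoffs.  Only
    suitable for small synthetic fixtures.
    """
    def kmers(s: str) -> set[str]:
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    sub_kmers = {name: kmers(seq) for name, seq in subjects.items()}
    rows = []
    for qname, qseq in queries.items():
        qk = kmers(qseq)
        for sname, sk in sub_kmers.items():
            shared = len(qk & sk)
            if shared >= min_shared:
                rows.append({
                    "qseqid": qname, "sseqid": sname, "pident": 100.0,
                    "length": shared, "mismatch": 0, "gapopen": 0,
                    "qstart": 1, "qend": len(qseq), "sstart": 1, "send": len(subjects[sname]),
                    "evalue": 0.0, "bitscore": float(shared),
                })
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def all_pair_hits(
    proteomes: dict[str, dict[str, str]], k: int = 4
) -> dict[tuple[str, str], pd.DataFrame]:
    """k-mer hit tables for every ordered species pair (synthetic fixtures)."""
    out = {}
    for sp_a, sp_b in itertools.permutations(proteomes, 2):
        out[(sp_a, sp_b)] = kmer_hit_table(proteomes[sp_a], proteomes[sp_b], k=k)
    return out
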