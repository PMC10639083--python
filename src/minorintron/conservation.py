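"""Intron-position mapping into protein alignments and conservation-state calling.

An intron interrupting a coding sequence after ``offset`` nt of CDS maps to a
protein residue and a phase: phase 0 introns sit at the codon boundary *after*
residue offset/3, phase 1/2 introns sit *inside* residue offset//3 + 1.  Two introns
from different species occupy the same site iff they map to the same alignment
column with the same phase.  Sites are filtered on local ungapped alignment quality
(>= 40% identity over the 10 columns on each side, no gaps), and per-site states are
called from the species' minor scores: minor above the minor threshold (default
> 90), major at or below the conversion ceiling (default <= 60); a site containing
any borderline score in (60, 90] is excluded from conversion tallies.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ParameterError

log = logging.getLogger(__name__)

GAP_CHARS = set("-.")


@dataclass
class AlignedIntronSite:
    """One (alignment column, phase) site with the per-species intron occupancy."""

    clique_id: str
    column: int                      # 0-based alignment column of the mapped residue
    phase: int
    species_introns: dict[str, tuple[str, float]] = field(default_factory=dict)
    # species -> (intron_id, minor_score); species absent from the dict but present
    # in the alignment are 'absent' at this site

    def occupancy(self, species: str) -> tuple[str, float] | None:
        return self.species_introns.get(species)


def _residue_columns(aligned_seq: str) -> list[int]:
    """Alignment column of each ungapped residue (0-based)."""
    return [i for i, c in enumerate(aligned_seq) if c not in GAP_CHARS]


def intron_residue_index(cds_offset: int, phase: int) -> int:
    """1-based residue the intron is assigned to (phase 0: residue just completed)."""
    return cds_offset // 3 if phase == 0 else cds_offset // 3 + 1


def map_intron_sites(
    alignment: dict[str, str],
    introns_by_species: dict[str, list],
    clique_id: str = "clq",
) -> list[AlignedIntronSite]:
    """Collate intron positions from clique members into shared alignment sites.

    ``alignment`` maps species -> aligned protein sequence (one per clique member);
    ``introns_by_species`` maps species -> IntronRecord-like objects with
    ``intron_id``, ``cds_offset`` and ``phase`` attributes (phase None, i.e.
    exon-defined introns, are ignored).  Scores may be attached later; records with
    a ``minor_score`` attribute carry it into the site.
    """
    columns = {sp: _residue_columns(seq) for sp, seq in alignment.items()}
    sites: dict[tuple[int, int], AlignedIntronSite] = {}
    for sp, introns in introns_by_species.items():
        if sp not in alignment:
            raise ParameterError(f"species {sp!r} has introns but no aligned sequence")
        cols = columns[sp]
        for r in introns:
            if r.phase is None:
                continue
            res = intron_residue_index(r.cds_offset, r.phase)
            if res < 1 or res > len(cols):
                log.warning("intron %s maps beyond its aligned sequence; skipped",
                            r.intron_id)
                continue
            key = (cols[res - 1], r.phase)
            site = sites.setdefault(key, AlignedIntronSite(clique_id, key[0], key[1]))
            site.species_introns[sp] = (r.intron_id, getattr(r, "minor_score", float("nan")))
    return [sites[k] for k in sorted(sites)]


def pair_quality(
    alignment: dict[str, str],
    column: int,
    sp_a: str,
    sp_b: str,
    window: int = 10,
    min_identity: float = 0.4,
) -> bool:
    """Local ungapped quality for one species pair around one column.

    The ``window`` columns ending at the site column and the ``window`` columns
    following it are evaluated separately; each side must be gap-free in both
    sequences and have >= ``min_identity`` identical residues.  Sites too close to
    an alignment edge fail.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    a, b = alignment[sp_a], alignment[sp_b]
    up = range(column - window + 1, column + 1)
    down = range(column + 1, column + window + 1)
    for side in (up, down):
        if side.start < 0 or side.stop > len(a):
            return False
        ident = 0
        for i in side:
            if a[i] in GAP_CHARS or b[i] in GAP_CHARS:
                return False
            if a[i] == b[i]:
                ident += 1
        if ident / window < min_identity:
            return False
    return True


def local_quality_filter(
    site: AlignedIntronSite,
    alignment: dict[str, str],
    window: int = 10,
    min_identity: float = 0.4,
) -> bool:
    """Site-level pass: every pair of aligned sequences passes around the site."""
    species = sorted(alignment)
    return all(
        pair_quality(alignment, site.column, a, b, window, min_identity)
        for a, b in itertools.combinations(species, 2)
    )


# ---------------------------------------------------------------------------
# state calling
# ---------------------------------------------------------------------------

def state_of(score: float, minor_min: float = 90.0, conversion_major_max: float = 60.0) -> str:
    if score > minor_min:
        return "minor"
    if score <= conversion_major_max:
        return "major"
    return "borderline"


@dataclass
class StateCallResult:
    states: pd.DataFrame             # one row per site x species, columns below
    pair_counts: pd.DataFrame        # per pair x type: n_cons, n_var
    conversion_candidates: pd.DataFrame
    shared_fractions: pd.DataFrame   # per row-species pair fraction of minor shared


def call_states(
    sites: list[AlignedIntronSite],
    alignment_species,
    minor_min: float = 90.0,
    conversion_major_max: float = 60.0,
    type_threshold: float = 90.0,
) -> StateCallResult:
    """Call per-site conservation states and tally pairwise counts.

    Standard type calls (minor iff score > ``type_threshold``) drive the
    conserved/variable counts; the stricter conversion thresholds drive the
    conversion tallies, from which any site with a borderline score in
    (conversion_major_max, minor_min] is excluded.
    """
    species = sorted(alignment_species)
    rows = []
    for k, site in enumerate(sites):
        for sp in species:
            occ = site.occupancy(sp)
            if occ is None:
                rows.append({"site": k, "column": site.column, "phase": site.phase,
                             "species": sp, "intron_id": None, "minor_score": float("nan"),
                             "type_call": "absent", "conversion_state": "absent"})
            else:
                iid, score = occ
                rows.append({
                    "site": k, "column": site.column, "phase": site.phase,
                    "species": sp, "intron_id": iid, "minor_score": score,
                    "type_call": "minor" if score > type_threshold else "major",
                    "conversion_state": state_of(score, minor_min, conversion_major_max),
                })
    states = pd.DataFrame(rows)

    pair_rows, conv_rows, shared_rows = [], [], []
    by_site = {k: g.set_index("species") for k, g in states.groupby("site")}
    for sp_a, sp_b in itertools.combinations(species, 2):
        for t in ("minor", "major"):
            n_cons = n_var = 0
            for g in by_site.values():
                ca, cb = g.loc[sp_a, "type_call"], g.loc[sp_b, "type_call"]
                if ca == t and cb == t:
                    n_cons += 1
                else:
                    n_var += int(ca == t) + int(cb == t)
            pair_rows.append({"species_a": sp_a, "species_b": sp_b, "intron_type": t,
                              "n_cons": n_cons, "n_var": n_var})
        # conversion candidates under the strict thresholds
        for k, g in by_site.items():
            sa, sb = g.loc[sp_a, "conversion_state"], g.loc[sp_b, "conversion_state"]
            if "borderline" in (sa, sb):
                continue
            if {sa, sb} == {"minor", "major"}:
                conv_rows.append({"site": k, "species_a": sp_a, "species_b": sp_b,
                                  "state_a": sa, "state_b": sb})
        # shared minor fractions, per row species (Figure-2 semantics)
        for row_sp, other in ((sp_a, sp_b), (sp_b, sp_a)):
            n_row = sum(g.loc[row_sp, "type_call"] == "minor" for g in by_site.values())
            n_shared = sum(
                (g.loc[row_sp, "type_call"] == "minor")
                and (g.loc[other, "type_call"] == "minor")
                for g in by_site.values()
            )
            shared_rows.append({"row_species": row_sp, "other_species": other,
                                "n_minor_in_alignments": n_row, "n_shared": n_shared,
                                "shared_fraction": n_shared / n_row if n_row else float("nan")})

    return StateCallResult(
        states=states,
        pair_counts=pd.DataFrame(pair_rows),
        conversion_candidates=pd.DataFrame(
            conv_rows, columns=["site", "species_a", "species_b", "state_a", "state_b"]),
        shared_fractions=pd.DataFrame(shared_rows),
    )


def presence_counts(
    sites: list[AlignedIntronSite],
    species_triple: tuple[str, str, str],
    intron_type: str = "minor",
    type_threshold: float = 90.0,
):
    """TriplePresenceCounts for the ancestral-count estimator from called sites.

    A species contributes to a pair/triple count when its intron at the site is of
    the requested type under the standard threshold.
    """
    from .ancestry import TriplePresenceCounts

    a, b, g = species_triple

    def has(site: AlignedIntronSite, sp: str) -> bool:
        occ = site.occupancy(sp)
        if occ is None:
            return False
        is_minor = occ[1] > type_threshold
        return is_minor if intron_type == "minor" else not is_minor

    n_ab = n_ag = n_bg = n_abg = 0
    for site in sites:
        pa, pb, pg = has(site, a), has(site, b), has(site, g)
        n_ab += pa and pb
        n_ag += pa and pg
        n_bg += pb and pg
        n_abg += pa and pb and pg
    return TriplePresenceCounts(n_ab=n_ab, n_ag=n_ag, n_bg=n_bg, n_abg=n_abg,
                                intron_type=intron_type)


# ---------------------------------------------------------------------------
# cross-alignment intron clusters for termini tallies
# ---------------------------------------------------------------------------

@dataclass
class IntronCluster:
    members: list[tuple[str, str]]          # (species, intron_id)


def build_intron_clusters(
    site_links,
    intron_meta: dict[tuple[str, str], tuple[str, str]],
    focal_type: str = "minor",
    min_same_type: int = 2,
) -> tuple[list[IntronCluster], pd.DataFrame]:
    """Connected components of the intron-sharing graph, plus a termini tally.

    ``site_links`` is an iterable of intron groups, each a list of (species,
    intron_id) that co-occur at one aligned site (from any pairwise or multi-species
    alignment; a hub species shared across alignments links them transitively).
    ``intron_meta`` maps (species, intron_id) -> (type, termini).  Termini are
    tallied only from clusters with >= ``min_same_type`` members of ``focal_type``
    (guarding against lone false-positive calls).
    """
    graph = nx.Graph()
    for group in site_links:
        group = list(group)
        graph.add_nodes_from(group)
        for u, v in itertools.combinations(group, 2):
            graph.add_edge(u, v)

    clusters = [IntronCluster(sorted(comp)) for comp in nx.connected_components(graph)]
    clusters.sort(key=lambda c: c.members)

    tally: Counter = Counter()
    for cluster in clusters:
        focal = [m for m in cluster.members if intron_meta[m][0] == focal_type]
        if len(focal) < min_same_type:
            continue
        for m in focal:
            tally[intron_meta[m][1]] += 1
    total = sum(tally.values())
    freq = pd.DataFrame(
        [{"termini": t, "count": c, "fraction": c / total if total else float("nan")}
         for t, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))],
        columns=["termini", "count", "fraction"],
    )
    return clusters, freq
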