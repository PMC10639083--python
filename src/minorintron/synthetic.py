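"""Synthetic-data generators for every stage of the survey pipeline.

Four generators, each fully determined by an explicit seed:

* :func:`simulate_three_taxon` — presence/absence evolution of ancestral minor and major
  introns along three lineages under independent per-lineage retention, with optional
  minor-to-major conversion of surviving minor introns and no parallel gain.
* :func:`generate_toy_genome` — a small genome (FASTA + GFF3 + truth table) with planted
  major/minor introns whose donor and branch-point sequences are drawn from per-type
  position frequency matrices.
* :func:`generate_junction_table` — junction read counts (two intron-exon junctions and
  one exon-exon junction) with Poisson depth so the expected splicing efficiency equals
  1 - retention.
* :func:`generate_expression_matrix` — a genes x samples expression matrix in which one
  designated "proliferating" cell type up-shifts a planted proliferation-index gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ancestry
from .errors import ParameterError

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# motif model
# ---------------------------------------------------------------------------

def _pfm(rows: list[dict[str, float]]) -> np.ndarray:
    """Build an (L, 4) position frequency matrix; unlisted bases share the remainder."""
    out = np.zeros((len(rows), 4))
    for i, row in enumerate(rows):
        rest = (1.0 - sum(row.values())) / (4 - len(row))
        for j, b in enumerate(BASES):
            out[i, j] = row.get(b, rest)
    return out


def _consensus_pfm(consensus: str) -> np.ndarray:
    return _pfm([{b: 1.0} for b in consensus])


@dataclass(frozen=True)
class MotifSpec:
    """Per-type intron sequence model: donor (first 8 nt), optional branch point
    (9 nt, planted ending 12 nt before the 3' end) and acceptor (last 2 nt)."""

    donor: np.ndarray
    acceptor: np.ndarray
    bps: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("donor", "acceptor", "bps"):
            mat = getattr(self, name)
            if mat is None:
                continue
            if mat.ndim != 2 or mat.shape[1] != 4 or (mat < 0).any():
                raise ParameterError(f"{name} PFM must be a non-negative (L, 4) matrix")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
                raise ParameterError(f"{name} PFM columns must each sum to 1 (tol 1e-6)")

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Draw one intron sequence of ``length`` nt (>= 30)."""
        if length < 30:
            raise ParameterError("introns shorter than 30 nt are outside the model")
        idx = rng.integers(0, 4, size=length)
        seq = np.array(list(BASES))[idx]

        def plant(mat: np.ndarray, start: int) -> None:
            for i in range(mat.shape[0]):
                seq[start + i] = BASES[rng.choice(4, p=mat[i])]

        plant(self.donor, 0)
        if self.bps is not None:
            plant(self.bps, length - 12 - self.bps.shape[0])
        plant(self.acceptor, length - 2)
        return "".join(seq)


# Minor (U12-type, GT-AG subtype) donor: GTATCCTT; branch point TTCCTTAAC.
# Major (U2-type) donor: GTAAGT plus two near-background positions.
MINOR_DONOR_CONSENSUS = "GTATCCTT"
MAJOR_DONOR_CONSENSUS = "GTAAGTNN"
MINOR_BPS_CONSENSUS = "TTCCTTAAC"


def default_minor_motifs() -> MotifSpec:
    donor = _pfm([
        {"G": 0.97}, {"T": 0.97}, {"A": 0.92}, {"T": 0.94},
        {"C": 0.90}, {"C": 0.88}, {"T": 0.90}, {"T": 0.85},
    ])
    bps = _pfm([
        {"T": 0.80}, {"T": 0.85}, {"C": 0.80}, {"C": 0.80}, {"T": 0.85},
        {"T": 0.88}, {"A": 0.97}, {"A": 0.85}, {"C": 0.75},
    ])
    acceptor = _pfm([{"A": 0.98}, {"G": 0.98}])
    return MotifSpec(donor=donor, acceptor=acceptor, bps=bps)


def default_major_motifs() -> MotifSpec:
    donor = _pfm([
        {"G": 0.98}, {"T": 0.98}, {"A": 0.60}, {"A": 0.70},
        {"G": 0.80}, {"T": 0.45}, {}, {},
    ])
    acceptor = _pfm([{"A": 0.98}, {"G": 0.98}])
    return MotifSpec(donor=donor, acceptor=acceptor, bps=None)


def consensus_minor_motifs() -> MotifSpec:
    return MotifSpec(
        donor=_consensus_pfm(MINOR_DONOR_CONSENSUS),
        acceptor=_consensus_pfm("AG"),
        bps=_consensus_pfm(MINOR_BPS_CONSENSUS),
    )


def consensus_major_motifs() -> MotifSpec:
    return MotifSpec(
        donor=_pfm([{"G": 1.0}, {"T": 1.0}, {"A": 1.0}, {"A": 1.0}, {"G": 1.0}, {"T": 1.0}, {}, {}]),
        acceptor=_consensus_pfm("AG"),
        bps=None,
    )


# ---------------------------------------------------------------------------
# three-taxon presence/absence simulation
# ---------------------------------------------------------------------------

def _normalise_rates(value, name: str) -> dict[str, dict[str, float]]:
    """Expand scalar / per-lineage / per-lineage-per-type rates to a nested dict."""
    out: dict[str, dict[str, float]] = {}
    for ln in ancestry.LINEAGES:
        v = value[ln] if isinstance(value, dict) else value
        if isinstance(v, dict):
            row = {t: float(v[t]) for t in ("minor", "major")}
        else:
            row = {"minor": float(v), "major": float(v)}
        for t, p in row.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}[{ln}][{t}]={p} outside [0, 1]")
        out[ln] = row
    return out


@dataclass
class ThreeTaxonSimulation:
    """Planted three-taxon intron evolution with known per-intron fates."""

    n_ancestral_minor: int
    n_ancestral_major: int
    retention: dict
    conversion_prob: dict
    seed: int
    states: pd.DataFrame = field(repr=False)

    def presence_counts(self, intron_type: str = "minor") -> ancestry.TriplePresenceCounts:
        return ancestry.counts_from_states(self.states, intron_type)


def simulate_three_taxon(
    n_ancestral_minor: int,
    n_ancestral_major: int,
    retention,
    conversion_prob=0.0,
    seed: int = 0,
) -> ThreeTaxonSimulation:
    """Simulate independent per-lineage retention and minor-to-major conversion.

    ``retention`` may be a scalar, a {lineage: p} dict or a {lineage: {type: p}} dict.
    ``conversion_prob`` (scalar or {lineage: p}) applies only to minor introns that
    survive in a lineage: conversion is a fate of a present intron, not a loss, so a
    converted intron is present-as-major in that lineage.
    """
    if n_ancestral_minor < 0 or n_ancestral_major < 0:
        raise ParameterError("ancestral intron counts must be non-negative")
    ret = _normalise_rates(retention, "retention")
    conv = _normalise_rates(conversion_prob, "conversion_prob")

    rng = np.random.default_rng(seed)
    anc = np.array(["minor"] * n_ancestral_minor + ["major"] * n_ancestral_major)
    n = anc.size
    cols = {"intron_id": [f"i{k:06d}" for k in range(n)], "ancestral_type": anc}
    for ln in ancestry.LINEAGES:
        p_keep = np.where(anc == "minor", ret[ln]["minor"], ret[ln]["major"])
        kept = rng.random(n) < p_keep
        state = np.where(kept, anc, "absent")
        converted = kept & (anc == "minor") & (rng.random(n) < conv[ln]["minor"])
        state = np.where(converted, "major", state)
        cols[f"state_{ln}"] = state
    return ThreeTaxonSimulation(
        n_ancestral_minor=n_ancestral_minor,
        n_ancestral_major=n_ancestral_major,
        retention=ret,
        conversion_prob=conv,
        seed=seed,
        states=pd.DataFrame(cols),
    )


# ---------------------------------------------------------------------------
# toy genome with planted introns
# ---------------------------------------------------------------------------

@dataclass
class ToyGenomeTruth:
    """A generated genome, its GFF3 annotation and the per-intron ground truth."""

    genome: dict[str, str]
    gff_lines: list[str]
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, str]:
        """Write genome.fa, annotation.gff3 and truth.tsv; byte-deterministic."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "annotation": os.path.join(outdir, "annotation.gff3"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        with open(paths["genome"], "w") as fh:
            for name in self.genome:
                fh.write(f">{name}\n")
                seq = self.genome[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(paths["annotation"], "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write("\n".join(self.gff_lines) + "\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_toy_genome(
    n_genes: int,
    introns_per_gene: int,
    minor_fraction: float,
    motif_spec: tuple[MotifSpec, MotifSpec] | None = None,
    seed: int = 0,
    wrong_strand_fraction: float = 0.0,
) -> ToyGenomeTruth:
    """Generate ``n_genes`` single-isoform genes, each with planted introns.

    ``motif_spec`` is a (minor, major) MotifSpec pair; default: realistic frequency
    matrices.  Each intron's type is an independent Bernoulli(minor_fraction) draw.
    Genes alternate strands; ``wrong_strand_fraction`` mis-annotates that fraction of
    genes on the opposite strand (for strand-sanity fixtures).  One contig per gene.
    """
    if not 0.0 <= minor_fraction <= 1.0:
        raise ParameterError("minor_fraction must be in [0, 1]")
    if n_genes < 1 or introns_per_gene < 0:
        raise ParameterError("n_genes must be >= 1 and introns_per_gene >= 0")
    minor_spec, major_spec = motif_spec or (default_minor_motifs(), default_major_motifs())

    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    gff: list[str] = []
    truth_rows: list[dict] = []

    for g in range(n_genes):
        gene_id = f"g{g + 1:04d}"
        tx_id = f"{gene_id}.t1"
        contig = f"chr{g + 1:04d}"
        strand = "+" if g % 2 == 0 else "-"
        # a mis-annotated gene keeps its true sequence and coordinates but the
        # annotation claims the opposite strand (extraction then sees CT-AC)
        wrong = bool(rng.random() < wrong_strand_fraction)
        annot_strand = ("-" if strand == "+" else "+") if wrong else strand

        n_exons = introns_per_gene + 1
        exon_lens = (3 * rng.integers(12, 41, size=n_exons)).tolist()
        intron_lens = rng.integers(60, 120, size=introns_per_gene).tolist()
        is_minor = (rng.random(introns_per_gene) < minor_fraction).tolist()

        # build the gene in sense orientation
        pieces, feature_spans, intron_spans = [], [], []
        pos = 0
        for i in range(n_exons):
            exon = "".join(np.array(list(BASES))[rng.integers(0, 4, exon_lens[i])])
            # keep planted ORF free of in-frame stops is unnecessary for these tests
            pieces.append(exon)
            feature_spans.append((pos, pos + exon_lens[i]))
            pos += exon_lens[i]
            if i < introns_per_gene:
                spec = minor_spec if is_minor[i] else major_spec
                iseq = spec.sample(int(intron_lens[i]), rng)
                pieces.append(iseq)
                intron_spans.append((pos, pos + len(iseq), iseq, bool(is_minor[i])))
                pos += len(iseq)
        gene_seq = "".join(pieces)
        flank = 30
        left = "".join(np.array(list(BASES))[rng.integers(0, 4, flank)])
        right = "".join(np.array(list(BASES))[rng.integers(0, 4, flank)])
        sense_contig = left + gene_seq + right
        genome[contig] = sense_contig if strand == "+" else revcomp(sense_contig)
        contig_len = len(sense_contig)

        def genomic(lo: int, hi: int) -> tuple[int, int]:
            """Sense-gene offsets -> 1-based inclusive genomic coordinates."""
            if strand == "+":
                return flank + lo + 1, flank + hi
            return contig_len - (flank + hi) + 1, contig_len - (flank + lo)

        g_lo, g_hi = genomic(0, len(gene_seq))
        gff.append(
            f"{contig}\ttoy\tgene\t{g_lo}\t{g_hi}\t.\t{annot_strand}\t.\tID={gene_id}"
        )
        gff.append(
            f"{contig}\ttoy\tmRNA\t{g_lo}\t{g_hi}\t.\t{annot_strand}\t.\tID={tx_id};Parent={gene_id}"
        )
        cum = 0
        cds_rows = []
        for lo, hi in feature_spans:
            s, e = genomic(lo, hi)
            frame = (3 - cum % 3) % 3
            cds_rows.append((s, e, frame))
            cum += hi - lo
        for s, e, frame in sorted(cds_rows):
            gff.append(f"{contig}\ttoy\texon\t{s}\t{e}\t.\t{annot_strand}\t.\tParent={tx_id}")
            gff.append(f"{contig}\ttoy\tCDS\t{s}\t{e}\t.\t{annot_strand}\t{frame}\tParent={tx_id}")

        cum = 0
        for i, (lo, hi, iseq, minor) in enumerate(intron_spans):
            cum += exon_lens[i]
            s, e = genomic(lo, hi)
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tx_id,
                    "intron_index": i + 1,
                    "contig": contig,
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "length": hi - lo,
                    "true_type": "minor" if minor else "major",
                    "phase": cum % 3,
                    "terminus_5": iseq[:2],
                    "terminus_3": iseq[-2:],
                    "cds_offset": cum,
                    "wrong_strand": wrong,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "transcript_id", "intron_index", "contig", "start", "end",
            "strand", "length", "true_type", "phase", "terminus_5", "terminus_3",
            "cds_offset", "wrong_strand",
        ],
    )
    return ToyGenomeTruth(genome=genome, gff_lines=gff, truth=truth)


# ---------------------------------------------------------------------------
# junction counts and expression matrices
# ---------------------------------------------------------------------------

def generate_junction_table(
    n_introns: int,
    true_retention,
    depth: float,
    seed: int = 0,
    n_replicates: int = 4,
) -> pd.DataFrame:
    """Per-intron, per-replicate junction read counts with known retention.

    Intron-exon junction counts are Poisson(depth * retention) and the exon-exon
    junction count Poisson(depth * (1 - retention)), i.e. Poisson sequencing around
    ``depth`` with binomial thinning by retention, so the expected splicing efficiency
    EE / (EE + mean(IE)) equals 1 - retention.
    """
    if depth <= 0:
        raise ParameterError("depth must be positive")
    if n_introns < 1 or n_replicates < 1:
        raise ParameterError("n_introns and n_replicates must be >= 1")
    r = np.broadcast_to(np.asarray(true_retention, dtype=float), (n_introns,)).copy()
    if ((r < 0) | (r > 1)).any():
        raise ParameterError("retention values must be in [0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        ie_l = rng.poisson(depth * r)
        ie_r = rng.poisson(depth * r)
        ee = rng.poisson(depth * (1.0 - r))
        for k in range(n_introns):
            rows.append(
                {
                    "intron_id": f"i{k:05d}",
                    "replicate": f"rep{rep}",
                    "ie_left": int(ie_l[k]),
                    "ie_right": int(ie_r[k]),
                    "ee": int(ee[k]),
                    "true_retention": r[k],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExpressionSim:
    matrix: pd.DataFrame          # genes x samples, normalized expression
    design: pd.Series             # sample -> cell type
    pi_genes: list[str]           # planted proliferation-index gene set
    proliferating: str            # the up-shifted cell type


def generate_expression_matrix(
    n_genes: int,
    cell_types,
    replicates_per_type: int,
    pi_gene_fraction: float = 0.05,
    effect_size: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.25,
) -> ExpressionSim:
    """Expression matrix where the first cell type proliferates.

    PI-labelled genes are multiplied by ``effect_size`` in the proliferating cell
    type's samples; ``effect_size=1`` is the null.  Values are log-normal around a
    per-gene baseline with multiplicative noise ``2**N(0, noise_sd)``.
    """
    cell_types = list(cell_types)
    if replicates_per_type < 2:
        raise ParameterError("replicates_per_type must be >= 2 (z-scores need variance)")
    if not 0.0 <= pi_gene_fraction <= 1.0:
        raise ParameterError("pi_gene_fraction must be in [0, 1]")
    if effect_size <= 0:
        raise ParameterError("effect_size must be positive")

    rng = np.random.default_rng(seed)
    genes = [f"gene{k:05d}" for k in range(n_genes)]
    n_pi = int(round(pi_gene_fraction * n_genes))
    pi_genes = list(rng.choice(genes, size=n_pi, replace=False))
    pi_mask = np.isin(genes, pi_genes)

    samples, types = [], []
    for ct in cell_types:
        for rep in range(1, replicates_per_type + 1):
            samples.append(f"{ct}_r{rep}")
            types.append(ct)
    design = pd.Series(types, index=samples, name="cell_type")
    proliferating = cell_types[0]

    base = rng.normal(5.0, 2.0, size=n_genes)
    mat = 2.0 ** (base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, len(samples))))
    shift = (design.to_numpy() == proliferating)[None, :] & pi_mask[:, None]
    mat = np.where(shift, mat * effect_size, mat)
    matrix = pd.DataFrame(mat, index=genes, columns=samples)
    return ExpressionSim(matrix=matrix, design=design, pi_genes=sorted(pi_genes),
                         proliferating=proliferating)
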