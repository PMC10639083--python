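"""Transcriptome building and intron extraction against forced-arithmetic fixtures
and the planted-truth toy genome."""

import numpy as np
import pytest

from minorintron import genome, synthetic
from minorintron.errors import InsufficientDataError


def _write(tmp_path, fasta: dict[str, str], gff_body: str):
    fa = tmp_path / "g.fa"
    with open(fa, "w") as fh:
        for name, seq in fasta.items():
            fh.write(f">{name}\n{seq}\n")
    gff = tmp_path / "a.gff3"
    gff.write_text("##gff-version 3\n" + gff_body)
    return fa, gff


def _gff_gene(contig, gene, strand, tx_cds: dict[str, list[tuple[int, int]]]):
    """gene/mRNA/CDS rows; cds are 1-based inclusive."""
    spans = [s for cds in tx_cds.values() for s in cds]
    lo, hi = min(s for s, _ in spans), max(e for _, e in spans)
    out = [f"{contig}\tt\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={gene}"]
    for tx, cds in tx_cds.items():
        out.append(f"{contig}\tt\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\tID={tx};Parent={gene}")
        for s, e in cds:
            out.append(f"{contig}\tt\tCDS\t{s}\t{e}\t.\t{strand}\t0\tParent={tx}")
    return "\n".join(out) + "\n"


class TestBuildTranscriptome:
    def test_longest_coding_isoform_selected(self, tmp_path):
        seq = "A" * 600
        body = _gff_gene("c1", "g1", "+", {"t_short": [(1, 300)],
                                           "t_long": [(1, 450)]})
        fa, gff = _write(tmp_path, {"c1": seq}, body)
        tx = genome.build_transcriptome(gff, genome.read_genome(fa))
        assert tx["g1"].transcript_id == "t_long"
        assert tx["g1"].coding_length == 450

    def test_tie_broken_lexicographically(self, tmp_path):
        body = _gff_gene("c1", "g1", "+", {"t_b": [(1, 300)], "t_a": [(1, 300)]})
        fa, gff = _write(tmp_path, {"c1": "A" * 400}, body)
        tx = genome.build_transcriptome(gff, genome.read_genome(fa))
        assert tx["g1"].transcript_id == "t_a"

    def test_single_exon_gene_yields_no_introns(self, tmp_path):
        body = _gff_gene("c1", "g1", "+", {"t1": [(1, 99)]})
        fa, gff = _write(tmp_path, {"c1": "A" * 120}, body)
        seqs = genome.read_genome(fa)
        tx = genome.build_transcriptome(gff, seqs)
        assert genome.extract_introns(tx, seqs) == []

    def test_out_of_bounds_cds_skips_gene(self, tmp_path):
        body = _gff_gene("c1", "g1", "+", {"t1": [(1, 500)]})
        fa, gff = _write(tmp_path, {"c1": "A" * 100}, body)
        assert genome.build_transcriptome(gff, genome.read_genome(fa)) == {}


class TestExtractIntrons:
    @pytest.fixture()
    def two_exon_gene(self, tmp_path):
        intron = "GT" + "C" * 96 + "AG"
        contig = "A" * 100 + intron + "G" * 100
        body = _gff_gene("c1", "g1", "+", {"t1": [(1, 100), (201, 300)]})
        fa, gff = _write(tmp_path, {"c1": contig}, body)
        seqs = genome.read_genome(fa)
        return genome.extract_introns(genome.build_transcriptome(gff, seqs), seqs)

    def test_forced_single_intron(self, two_exon_gene):
        (rec,) = two_exon_gene
        assert (rec.start, rec.end) == (101, 200)
        assert rec.length == 100
        assert rec.termini == "GT-AG"
        assert rec.phase == 100 % 3 == 1
        assert rec.relative_position == pytest.approx(0.5)

    def test_minus_strand_symmetry(self, tmp_path, two_exon_gene):
        intron = "GT" + "C" * 96 + "AG"
        contig = synthetic.revcomp("A" * 100 + intron + "G" * 100)
        body = _gff_gene("c1", "g1", "-", {"t1": [(1, 100), (201, 300)]})
        fa, gff = _write(tmp_path, {"c1": contig}, body)
        seqs = genome.read_genome(fa)
        (rec,) = genome.extract_introns(genome.build_transcriptome(gff, seqs), seqs)
        ref = two_exon_gene[0]
        assert rec.termini == ref.termini
        assert rec.phase == ref.phase
        assert rec.sequence == ref.sequence

    def test_short_gap_discarded(self, tmp_path):
        # 25-nt gap is below the 30-nt floor
        contig = "A" * 100 + "GT" + "C" * 21 + "AG" + "G" * 100
        body = _gff_gene("c1", "g1", "+", {"t1": [(1, 100), (126, 225)]})
        fa, gff = _write(tmp_path, {"c1": contig}, body)
        seqs = genome.read_genome(fa)
        assert genome.extract_introns(genome.build_transcriptome(gff, seqs), seqs) == []


class TestToyGenomeRoundTrip:
    def test_truth_table_recovered_exactly(self, toy_extraction):
        truth = toy_extraction["toy"].truth.sort_values(
            ["gene_id", "intron_index"]).reset_index(drop=True)
        got = genome.introns_to_frame(toy_extraction["introns"]).sort_values(
            ["gene_id", "intron_id"]).reset_index(drop=True)
        assert len(truth) == len(got)
        for col in ("start", "end", "phase", "cds_offset"):
            assert (truth[col].to_numpy() == got[col].to_numpy()).all()
        for col in ("terminus_5", "terminus_3", "strand"):
            assert (truth[col].to_numpy() == got[col].to_numpy()).all()

    def test_relative_position_non_decreasing_and_phase_consistent(self, toy_extraction):
        got = genome.introns_to_frame(toy_extraction["introns"])
        for _, g in got.groupby("transcript_id"):
            rel = g.sort_values("cds_offset")["relative_position"].to_numpy()
            assert (np.diff(rel) >= 0).all()
            assert ((g["relative_position"] >= 0) & (g["relative_position"] <= 1)).all()
        assert (got["phase"] == got["cds_offset"] % 3).all()


class TestStrandSanity:
    def test_clean_genome_no_warning(self, toy_extraction):
        rep = genome.strand_sanity_report(toy_extraction["introns"])
        assert rep.ct_ac_fraction == 0.0
        assert not rep.warning

    def test_planted_wrong_strand_raises_warning(self, tmp_path):
        toy = synthetic.generate_toy_genome(40, 3, 0.0, seed=9,
                                            wrong_strand_fraction=0.2)
        paths = toy.write(tmp_path)
        seqs = genome.read_genome(paths["genome"])
        tx = genome.build_transcriptome(paths["annotation"], seqs)
        recs = genome.extract_introns(tx, seqs)
        rep = genome.strand_sanity_report(recs)
        assert rep.warning
        assert rep.ct_ac_fraction > 0.01

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            genome.strand_sanity_report([])


class TestGenicIntronDensity:
    def test_forced_arithmetic(self, tmp_path):
        intron = "GT" + "C" * 56 + "AG"
        exons, pos, cds = [], 1, []
        contig_parts = []
        for k in range(4):                       # 4 exons of 375 nt -> 1500 coding
            contig_parts.append("A" * 375)
            cds.append((pos, pos + 374))
            pos += 375
            if k < 3:
                contig_parts.append(intron)
                pos += len(intron)
        body = _gff_gene("c1", "g1", "+", {"t1": cds})
        fa, gff = _write(tmp_path, {"c1": "".join(contig_parts)}, body)
        seqs = genome.read_genome(fa)
        tx = genome.build_transcriptome(gff, seqs)
        recs = genome.extract_introns(tx, seqs)
        df = genome.genic_intron_density(tx, recs)
        assert df.loc[0, "n_introns"] == 3
        assert df.loc[0, "coding_length"] == 1500
        assert df.loc[0, "genic_intron_density"] == pytest.approx(2.0)

    def test_intronless_gene_zero_density(self, tmp_path):
        body = _gff_gene("c1", "g1", "+", {"t1": [(1, 300)]})
        fa, gff = _write(tmp_path, {"c1": "A" * 400}, body)
        seqs = genome.read_genome(fa)
        tx = genome.build_transcriptome(gff, seqs)
        df = genome.genic_intron_density(tx, genome.extract_introns(tx, seqs))
        assert df.loc[0, "genic_intron_density"] == 0.0
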