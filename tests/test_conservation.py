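"""Intron-site mapping into protein alignments, quality filtering and state calls."""

from types import SimpleNamespace

import numpy as np
import pytest

from minorintron import ancestry, conservation, synthetic


def intron(iid, cds_offset, phase, score=95.0):
    return SimpleNamespace(intron_id=iid, cds_offset=cds_offset, phase=phase,
                           minor_score=score)


IDENT = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"      # 33 residues


class TestMapIntronSites:
    def test_identical_proteins_share_one_site(self):
        aln = {"hum": IDENT, "fly": IDENT}
        sites = conservation.map_intron_sites(
            aln, {"hum": [intron("h1", 31, 1)], "fly": [intron("f1", 31, 1)]})
        assert len(sites) == 1
        site = sites[0]
        # phase-1 intron after 31 nt sits inside residue 11 -> column 10 (0-based)
        assert (site.column, site.phase) == (10, 1)
        assert set(site.species_introns) == {"hum", "fly"}

    def test_same_column_different_phase_is_two_sites(self):
        aln = {"hum": IDENT, "fly": IDENT}
        sites = conservation.map_intron_sites(
            aln, {"hum": [intron("h1", 31, 1)], "fly": [intron("f1", 32, 2)]})
        assert len(sites) == 2
        assert all(len(s.species_introns) == 1 for s in sites)

    def test_gap_shifted_sequence_matches_through_columns(self):
        # fly has a 3-residue insertion at the start; the intron is 3 codons later
        aln = {"hum": "---" + IDENT, "fly": "AAA" + IDENT}
        sites = conservation.map_intron_sites(
            aln, {"hum": [intron("h1", 31, 1)],
                  "fly": [intron("f1", 31 + 9, 1)]})
        assert len(sites) == 1
        assert set(sites[0].species_introns) == {"hum", "fly"}

    def test_intron_beyond_sequence_end_skipped(self):
        aln = {"hum": IDENT}
        sites = conservation.map_intron_sites(
            aln, {"hum": [intron("h1", 3 * len(IDENT) + 30, 1)]})
        assert sites == []


class TestLocalQualityFilter:
    def test_identical_sequences_pass(self):
        aln = {"a": IDENT, "b": IDENT}
        site = conservation.AlignedIntronSite("c", 15, 0)
        assert conservation.local_quality_filter(site, aln)

    def test_low_identity_fails(self):
        # 3/10 identity upstream of column 10
        a = "AAAAAAAAAA" + IDENT[10:]
        b = "AAACCCCCCC" + IDENT[10:]
        site = conservation.AlignedIntronSite("c", 9, 0)
        assert not conservation.local_quality_filter(site, {"a": a, "b": b})

    def test_gap_in_window_fails(self):
        a = IDENT[:12] + "-" + IDENT[13:]
        site = conservation.AlignedIntronSite("c", 15, 0)
        assert not conservation.local_quality_filter(site, {"a": a, "b": IDENT})

    def test_threshold_is_forty_percent(self):
        # exactly 4/10 identical on each side (columns 6-15 and 16-25) passes
        a = IDENT
        up = "".join(a[6 + i] if i < 4 else "W" for i in range(10))
        down = "".join(a[16 + i] if i < 4 else "W" for i in range(10))
        b = a[:6] + up + down + a[26:]
        assert len(b) == len(a)
        site = conservation.AlignedIntronSite("c", 15, 0)
        assert conservation.local_quality_filter(site, {"a": a, "b": b})


def one_site(scores: dict[str, float]):
    site = conservation.AlignedIntronSite("c", 10, 1)
    for sp, sc in scores.items():
        site.species_introns[sp] = (f"{sp}_i", sc)
    return site


class TestCallStates:
    def test_both_high_scores_conserved_as_minor(self):
        res = conservation.call_states([one_site({"a": 95, "b": 95})], ["a", "b"])
        row = res.pair_counts.query("intron_type == 'minor'").iloc[0]
        assert row["n_cons"] == 1 and row["n_var"] == 0
        assert res.conversion_candidates.empty

    def test_minor_major_pair_is_conversion_candidate(self):
        res = conservation.call_states([one_site({"a": 95, "b": 40})], ["a", "b"])
        assert len(res.conversion_candidates) == 1
        row = res.pair_counts.query("intron_type == 'minor'").iloc[0]
        assert row["n_cons"] == 0 and row["n_var"] == 1

    def test_borderline_score_excluded_from_conversion(self):
        res = conservation.call_states([one_site({"a": 95, "b": 75})], ["a", "b"])
        assert res.conversion_candidates.empty
        # but the standard threshold still treats 75 as a major call
        states = res.states.set_index("species")
        assert states.loc["b", "type_call"] == "major"

    def test_symmetric_under_species_reordering(self):
        sites = [one_site({"a": 95, "b": 40}), one_site({"a": 30, "b": 97})]
        r1 = conservation.call_states(sites, ["a", "b"])
        r2 = conservation.call_states(sites, ["b", "a"])
        assert r1.pair_counts.equals(r2.pair_counts)

    def test_planted_three_taxon_states_recovered(self):
        sim = synthetic.simulate_three_taxon(150, 400, retention=0.8,
                                             conversion_prob=0.2, seed=21)
        sites = []
        score = {"minor": 95.0, "major": 40.0}
        for k, row in sim.states.iterrows():
            site = conservation.AlignedIntronSite("c", k, 0)
            for sp, ln in zip("abg", ancestry.LINEAGES):
                st = row[f"state_{ln}"]
                if st != "absent":
                    site.species_introns[sp] = (f"{sp}{k}", score[st])
            if site.species_introns:
                sites.append(site)
        for t in ("minor", "major"):
            got = conservation.presence_counts(sites, ("a", "b", "g"), t)
            want = sim.presence_counts(t)
            assert (got.n_ab, got.n_ag, got.n_bg, got.n_abg) == (
                want.n_ab, want.n_ag, want.n_bg, want.n_abg)


class TestIntronClusters:
    def test_hub_species_links_alignments_transitively(self):
        links = [[("hum", "h1"), ("fly", "f1")], [("hum", "h1"), ("bee", "b1")]]
        meta = {("hum", "h1"): ("minor", "AT-AC"), ("fly", "f1"): ("minor", "AT-AC"),
                ("bee", "b1"): ("minor", "AT-AC")}
        clusters, freq = conservation.build_intron_clusters(links, meta)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_minority_focal_type_cluster_excluded_from_tally(self):
        links = [[("a", "i1"), ("b", "i2"), ("c", "i3")]]
        meta = {("a", "i1"): ("minor", "AT-AA"), ("b", "i2"): ("major", "GT-AG"),
                ("c", "i3"): ("major", "GT-AG")}
        _, freq = conservation.build_intron_clusters(links, meta, focal_type="minor")
        assert freq.empty

    def test_planted_noncanonical_frequency_recovered(self):
        rng = np.random.default_rng(4)
        links, meta = [], {}
        planted = 0
        n = 400
        for k in range(n):
            noncanon = rng.random() < 0.05
            planted += 2 * noncanon
            term = "AT-AA" if noncanon else "GT-AG"
            pair = [("a", f"a{k}"), ("b", f"b{k}")]
            links.append(pair)
            for sp, iid in pair:
                meta[(sp, iid)] = ("minor", term)
        _, freq = conservation.build_intron_clusters(links, meta, focal_type="minor")
        got = freq.set_index("termini")["fraction"].get("AT-AA", 0.0)
        want = planted / (2 * n)
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(got - want) < 1e-12       # tally is exact given the planted set
        assert abs(got - 0.05) < 3 * se      # and the planted rate matches the draw
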