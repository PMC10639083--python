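"""Estimate an ancestral minor intron density from three-species shared counts.

For a species pair (alpha, beta) with outgroup gamma, introns shared by any two
of the three species are ancestral to the alpha/beta split (parallel gain is
negligible).  The estimator N_ab*N_ag*N_bg/N_abg^2 recovers the ancestral count
per intron type; the minor density is then normalised to a reference species.
The counts below are the published Chordata-Echinodermata example (human, acorn
worm, sea slug).
"""

from minorintron import ancestry

minor = ancestry.TriplePresenceCounts(127, 116, 136, 102, intron_type="minor")
major = ancestry.TriplePresenceCounts(14220, 14800, 14954, 13062, intron_type="major")

for lineage in ancestry.LINEAGES:
    est = ancestry.retention_fraction(minor, lineage)
    print(f"retention of ancestral minor introns in {lineage}: {est.p_hat:.3f}")

node = ancestry.reconstruct_node(minor, major, reference_density=0.828)
print(f"ancestral minor introns in aligned genes:  {node['n_minor_rounded']}")
print(f"ancestral major introns in aligned genes:  {node['n_major_rounded']}")
print(f"ancestral minor intron density:            {node['rho_pct']:.3f}%")
print(f"relative to the reference species (0.828%): {node['relative']:.2f}")
# A relative density of ~1.25 means the ancestor carried ~25% more minor introns
# (as a fraction of its introns) than the human genes in the same alignments.
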