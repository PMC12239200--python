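"""Classify gene copies into haplotypes and build a frequency spectrum.

Simulates a gene-copy table for a Ga1-like locus in 15 inbred genomes
(haplotype classes drawn from the neutral infinite-alleles model at
theta = 5), classifies copies by exact CDS identity, assembles per-genome
haplotype signatures and reduces them to the allele frequency spectrum the
neutrality test consumes.
"""

from gametokit.haplotypes import detect_premature_stop, locus_spectrum
from gametokit.synth import simulate_locus

copies = simulate_locus(genomes=15, theta=5.0, seed=42, stop_classes=[0])
spectrum, signatures, classes = locus_spectrum(copies, threshold=1.0)

print(f"{len(copies)} gene copies across {spectrum.n} genomes")
print(f"distinct haplotypes k = {spectrum.k}")
print("spectrum (j genomes -> a_j haplotypes):")
for j, aj in enumerate(spectrum.a, start=1):
    if aj:
        print(f"  {j:2d} -> {aj}")

stops = sum(detect_premature_stop(c.cds) for c in copies)
print(f"{stops} copies carry a premature stop codon (pseudogenized copies)")
# The spectrum entries a_j count haplotypes seen in exactly j genomes; a
# haplotype at unusually high j relative to neutral expectation (like the
# conserved ga1-Off haplotype) is what the neutrality test flags.
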