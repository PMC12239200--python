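"""Date a gene duplication from synonymous divergence.

Simulates a pair of 550-codon coding sequences that split 12 million years
ago (the Ga1p/Ga2p-scale divergence) under a Kimura two-parameter process at
the standard maize mutation rate, then estimates the divergence time back
from the synonymous distance: Ks -> T = Ks / (2 mu).
"""

from gametokit.dating import AlignedCodonPair, age_from_ks, ks_k2p
from gametokit.synth import simulate_codon_divergence

MU = 3.3e-8  # substitutions / site / generation; 1 generation = 1 year
T_TRUE = 1.2e7

seq_a, seq_b = simulate_codon_divergence(550, T_TRUE, MU, seed=20)
est = ks_k2p(AlignedCodonPair("Ga1p", "Ga2p", seq_a, seq_b))
age = age_from_ks(est.ks, MU)

print(f"synonymous sites S = {est.S:.1f}, synonymous differences = {est.sd:.1f}")
print(f"transition/transversion proportions Ps = {est.Ps:.4f}, Qs = {est.Qs:.4f}")
print(f"Ks = {est.ks:.4f} synonymous substitutions per synonymous site")
print(f"estimated divergence: {age/1e6:.1f} My (simulated truth {T_TRUE/1e6:.0f} My)")
# Dividing Ks by 2*mu converts per-site synonymous divergence into years,
# the 2 accounting for the two branches since the duplication.
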