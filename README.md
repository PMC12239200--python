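# gametokit

Analyses for the molecular evolution of the maize gametophytic-factor
(cross-incompatibility) loci *Tcb1*, *Ga1* and *Ga2*. Each locus encodes a
silk-expressed and a tightly linked pollen-expressed pectin methylesterase
(PME); matching activity lets pollen tubes grow down an active silk, and
mismatches create a unilateral prezygotic crossing barrier between maize and
teosinte populations. `gametokit` provides the four quantitative stages such
a study needs, as an importable library with a thin `gametokit` CLI on top:

1. **Haplotype classification** (`gametokit.haplotypes`) — group full-length
   gene copies into sequence-identity classes, render each genome's locus as
   an ordered, strand-canonical *haplotype signature* (copy class, silk/pollen
   role, orientation, >1 kb gap markers), flag premature stop codons, and
   reduce a sample of signatures to the allele frequency spectrum
   a = (a₁…a_n), where a_j counts haplotypes seen in exactly j genomes.
2. **Neutrality testing** (`gametokit.esf`) — the Ewens sampling formula
   (ESF) gives the neutral infinite-alleles probability of a configuration:

       P(a | θ) = n!/θ⁽ⁿ⁾ · ∏ⱼ θ^{a_j} / (j^{a_j} a_j!),   θ⁽ⁿ⁾ = θ(θ+1)…(θ+n−1)

   θ is fitted by grid-search maximum likelihood (k = Σa_j is sufficient) and
   the observed configuration is scored by an exact (or Monte-Carlo)
   goodness-of-fit p-value. A haplotype far more frequent than its diversity
   background permits — like the conserved, premature-stop-bearing *ga1-Off*
   allele — yields a tiny p.
3. **Divergence dating** (`gametokit.dating`) — Nei–Gojobori counting of
   synonymous sites and pathway-averaged differences, transition/transversion
   split, Kimura two-parameter correction on the synonymous proportions
   (Ks = −½ln(1−2Ps−Qs) − ¼ln(1−2Qs)), and conversion to time through
   T = Ks/(2μ) at the standard maize rate μ = 3.3×10⁻⁸ per site per
   generation, one generation per year.
4. **24-nt siRNA enrichment** (`gametokit.sirna`) — count unique 24-nt read
   sequences exactly matching silk- or pollen-gene references (either
   strand), normalize per 20 million reads, compare genotype classes with
   Welch's t-test, assign allele of origin by allele-specific containment
   and score 24-nt phasing registers.

`gametokit.synth` generates synthetic inputs with the statistical structure
each stage assumes (Chinese-restaurant-process haplotype samples, K2P-evolved
codon pairs, whole gene-copy tables, negative-binomial siRNA libraries), so
the entire pipeline runs and is tested without any external data.

## Worked example

```python
from gametokit import esf_neutrality_test, SpectrumConfig
from gametokit.core_io import RunConfig
from gametokit.synth import sample_esf_crp

cfg = RunConfig(seed=1)

neutral, _ = sample_esf_crp(n=52, theta=20.0, seed=202)
res = esf_neutrality_test(neutral, cfg, locus="Ga2")
print(f"neutral sample:  n={res.n} k={res.k} theta_hat={res.theta_hat:.0f} p={res.p_value:.4f}")

dominated = SpectrumConfig.from_counts([18] + [1] * 25)
res = esf_neutrality_test(dominated, cfg, locus="Ga1")
print(f"dominated sample: n={res.n} k={res.k} theta_hat={res.theta_hat:.0f} p={res.p_value:.2e}")
```

prints

```
neutral sample:  n=52 k=31 theta_hat=31 p=0.7470
dominated sample: n=43 k=26 theta_hat=27 p=2.29e-05
```

The first sample was drawn from the neutral model itself: the fitted θ is
close to the generating value and the configuration is unsurprising
(p = 0.75). The second sample carries one haplotype in 18 of 43 genomes
alongside 25 singletons; with that much background diversity the fitted
θ = 27 expects no such dominant allele, and neutrality is rejected at
p ≈ 2×10⁻⁵ — the population-genetic signature of a conserved functional
allele rather than drift.

The `examples/` directory has one short script per capability
(`haplotype_spectrum.py`, `neutrality_test.py`, `locus_dating.py`,
`sirna_enrichment.py`, `simulate_inputs.py`); each builds a small input,
runs the stage and explains what it prints. The same stages are available
from a shell via `gametokit classify | esf-test | date | sirna | simulate`.

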