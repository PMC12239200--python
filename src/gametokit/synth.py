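"""Synthetic-data generators matching each analysis stage's assumptions.

Every generator is a pure function of its seed: rerunning with the same seed
reproduces byte-identical output. The generators emulate:

- neutral infinite-alleles haplotype samples via the Chinese restaurant
  process (CRP), whose configuration distribution is exactly the Ewens
  sampling formula;
- codon sequence pairs diverged for a known time T under a Kimura
  two-parameter substitution process at total rate mu per site per
  generation with transition/transversion rate ratio kappa (exact
  matrix-exponential site probabilities, so any T is simulated without
  discretization error);
- whole gene-copy tables for a locus, with ESF-distributed haplotype
  classes rendered as ordered silk/pollen copies, sub- and super-kilobase
  inter-copy gaps and optional planted premature stops;
- small-RNA libraries with negative-binomial unique-match counts, a
  genotype-class effect on silk-gene targets and none on pollen-gene
  targets, with reads synthesized as exact 24-mer substrings of the
  references.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Optional, Sequence

import numpy as np

from gametokit.core_io import GeneCopy
from gametokit.errors import DomainError
from gametokit.haplotypes import SpectrumConfig

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
# transition partner and transversion partners per base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimParams:
    """Parameter container shared by the generators (seed is mandatory)."""

    seed: int
    theta: float = 20.0
    n: int = 50
    mu: float = 3.3e-8
    kappa: float = 2.0
    T_years: float = 1e6
    codons: int = 300
    effect_multiplier: float = 59.0
    dispersion: float = 10.0
    n_per_group: int = 3

    def __post_init__(self) -> None:
        for name in ("theta", "mu", "kappa", "T_years", "effect_multiplier", "dispersion"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.n < 1 or self.codons < 1 or self.n_per_group < 1:
            raise DomainError("n, codons and n_per_group must be >= 1")


def sample_crp_sizes(n: int, theta: float, rng: np.random.Generator) -> list[int]:
    """One Chinese restaurant process draw; returns class sizes.

    Individual i+1 joins an existing class of size m with probability
    m/(theta+i) and founds a new class with probability theta/(theta+i).
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if theta <= 0 or not np.isfinite(theta):
        raise DomainError("theta must be finite and > 0")
    sizes: list[int] = []
    for i in range(n):
        u = rng.random() * (theta + i)
        if u < theta:
            sizes.append(1)
        else:
            u -= theta
            acc = 0.0
            for idx, m in enumerate(sizes):
                acc += m
                if u < acc:
                    sizes[idx] += 1
                    break
    return sizes


def sample_crp_sizes_batch(
    n: int, theta: float, m: int, rng: np.random.Generator
) -> np.ndarray:
    """m independent CRP draws at once; returns an (m, n) class-size matrix.

    Row r holds the class sizes of draw r in founding order, zero-padded.
    Vectorized across draws: equivalent in distribution to m calls of
    :func:`sample_crp_sizes`.
    """
    if n < 1 or m < 1:
        raise DomainError("n and m must be >= 1")
    if theta <= 0 or not np.isfinite(theta):
        raise DomainError("theta must be finite and > 0")
    counts = np.zeros((m, n), dtype=np.int32)
    k = np.zeros(m, dtype=np.int64)
    rows = np.arange(m)
    for i in range(n):
        u = rng.random(m) * (theta + i)
        new = u < theta
        counts[rows[new], k[new]] = 1
        k[new] += 1
        old = ~new
        if old.any():
            v = u[old] - theta
            cum = np.cumsum(counts[old], axis=1)
            idx = (v[:, None] >= cum).sum(axis=1)
            counts[rows[old], idx] += 1
    return counts


def sample_esf_crp(n: int, theta: float, seed: int) -> tuple[SpectrumConfig, list[int]]:
    """ESF-distributed sample of n individuals: spectrum plus class labels.

    Labels are 0-based class indices in founding order, one per individual.
    """
    rng = np.random.default_rng(seed)
    labels: list[int] = []
    sizes: list[int] = []
    for i in range(n):
        u = rng.random() * (theta + i)
        if u < theta:
            labels.append(len(sizes))
            sizes.append(1)
        else:
            u -= theta
            acc = 0.0
            for idx, m in enumerate(sizes):
                acc += m
                if u < acc:
                    sizes[idx] += 1
                    labels.append(idx)
                    break
    return SpectrumConfig.from_counts(sizes), labels


def _k2p_site_probs(t: float, mu: float, kappa: float) -> tuple[float, float, float]:
    """K2P per-site change probabilities after time t.

    Rates: transition alpha = mu*kappa/(kappa+2), each transversion
    beta = mu/(kappa+2), so the total substitution rate is mu. Returns
    (p_same, p_transition, p_each_transversion) from the exact matrix
    exponential.
    """
    alpha = mu * kappa / (kappa + 2.0)
    beta = mu / (kappa + 2.0)
    e4b = exp(-4.0 * beta * t)
    e2ab = exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 - 0.25 * e4b
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    return p_same, p_ts, p_tv_each


def _evolve(seq: str, t: float, mu: float, kappa: float, rng: np.random.Generator) -> str:
    p_same, p_ts, p_tv = _k2p_site_probs(t, mu, kappa)
    out = []
    u = rng.random(len(seq))
    for base, ui in zip(seq, u):
        if ui < p_same:
            out.append(base)
        elif ui < p_same + p_ts:
            out.append(_TRANSITION[base])
        elif ui < p_same + p_ts + p_tv:
            out.append(_TRANSVERSIONS[base][0])
        else:
            out.append(_TRANSVERSIONS[base][1])
    return "".join(out)


def random_cds(codons: int, rng: np.random.Generator, terminal_stop: bool = False) -> str:
    """Random stop-free CDS of the given codon count (uniform over 61 sense codons)."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=codons)
    seq = "".join(_SENSE_CODONS[i] for i in idx)
    if terminal_stop:
        seq = seq[:-3] + "TGA"
    return seq


def simulate_codon_divergence(
    ancestor_codons: int,
    T_years: float,
    mu: float = 3.3e-8,
    kappa: float = 2.0,
    seed: int = 0,
    generation_time_years: float = 1.0,
) -> tuple[str, str]:
    """Two sequences diverged for T years from a random stop-free ancestor.

    Each descendant evolves independently along a branch of length
    T_years/generation_time_years generations, so the pair is separated by
    total time 2T and the expected all-site distance is 2*mu*T. Substitution
    probabilities are the exact K2P matrix exponential per site.
    """
    if ancestor_codons < 1:
        raise DomainError("ancestor_codons must be >= 1")
    if T_years < 0 or mu <= 0 or kappa <= 0 or generation_time_years <= 0:
        raise DomainError("T_years >= 0 and mu, kappa, generation time > 0 required")
    rng = np.random.default_rng(seed)
    ancestor = random_cds(ancestor_codons, rng)
    t = T_years / generation_time_years
    seq_a = _evolve(ancestor, t, mu, kappa, rng)
    seq_b = _evolve(ancestor, t, mu, kappa, rng)
    return seq_a, seq_b


@dataclass(frozen=True)
class _ClassLayout:
    """Blueprint for one haplotype class: copy CDSs, roles, spacing, stops."""

    cds: tuple[str, ...]
    roles: tuple[str, ...]
    gaps_bp: tuple[int, ...]  # inter-copy distances, len = copies - 1
    strand: str


def simulate_locus(
    genomes: int = 20,
    theta: float = 20.0,
    seed: int = 0,
    locus: str = "Ga1",
    codons: int = 60,
    planted_spectrum: Optional[Sequence[int]] = None,
    stop_classes: Sequence[int] = (),
) -> list[GeneCopy]:
    """Synthetic gene-copy table with ESF-distributed haplotype classes.

    Haplotype classes are drawn from a CRP at ``theta`` (or planted directly
    as per-class genome counts via ``planted_spectrum``). Each class gets a
    layout of 1–4 copies with random silk/pollen roles, distinct CDSs,
    inter-copy gaps drawn both under and over a kilobase, and a single
    strand; genomes of the same class render byte-identical layouts at
    shifted coordinates, so exact-identity classification recovers the
    planted spectrum. ``stop_classes`` plants a premature stop codon in the
    first copy of the given class indices.
    """
    rng = np.random.default_rng(seed)
    if planted_spectrum is not None:
        counts = [int(c) for c in planted_spectrum]
        if any(c < 1 for c in counts):
            raise DomainError("planted_spectrum entries must be >= 1")
        genomes = sum(counts)
    else:
        counts = sample_crp_sizes(genomes, theta, rng)

    used_cds: set[str] = set()

    def fresh_cds(with_stop: bool) -> str:
        while True:
            cds = random_cds(codons, rng)
            if cds in used_cds:
                continue
            used_cds.add(cds)
            if with_stop:
                mid = 3 * (codons // 2)
                cds = cds[:mid] + "TGA" + cds[mid + 3 :]
                if cds in used_cds:
                    continue
                used_cds.add(cds)
            return cds

    layouts: list[_ClassLayout] = []
    for cls_idx, _count in enumerate(counts):
        n_copies = int(rng.integers(1, 5))
        roles = tuple(
            "silk" if rng.random() < 0.5 else "pollen" for _ in range(n_copies)
        )
        cds = tuple(
            fresh_cds(with_stop=(cls_idx in stop_classes and i == 0))
            for i in range(n_copies)
        )
        gaps = tuple(
            int(rng.integers(200, 900)) if rng.random() < 0.5 else int(rng.integers(1500, 5000))
            for _ in range(n_copies - 1)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        layouts.append(_ClassLayout(cds=cds, roles=roles, gaps_bp=gaps, strand=strand))

    chrom = "chr4" if locus in ("Ga1", "Tcb1") else "chr5"
    copies: list[GeneCopy] = []
    genome_idx = 0
    for cls_idx, count in enumerate(counts):
        layout = layouts[cls_idx]
        for _ in range(count):
            genome_idx += 1
            gid = f"genome{genome_idx:03d}"
            start = 1000 + int(rng.integers(0, 5000))
            for i, (cds, role) in enumerate(zip(layout.cds, layout.roles)):
                end = start + len(cds) - 1
                copies.append(
                    GeneCopy(
                        copy_id=f"{gid}_{locus}_{i + 1}",
                        genome_id=gid,
                        locus=locus,
                        role=role,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=layout.strand,
                        cds=cds,
                        cleave_offset=0,
                    )
                )
                if i < len(layout.gaps_bp):
                    start = end + 1 + layout.gaps_bp[i]
    return copies


def _negbin(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    """Negative binomial with variance mean + mean^2/dispersion."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _distinct_kmers_from(
    refs: Sequence[tuple[str, str]], count: int, rng: np.random.Generator, k: int = 24
) -> list[str]:
    out: set[str] = set()
    attempts = 0
    while len(out) < count:
        attempts += 1
        if attempts > 100 * count + 1000:
            raise RuntimeError("references too short to yield enough distinct k-mers")
        _, seq = refs[int(rng.integers(0, len(refs)))]
        i = int(rng.integers(0, len(seq) - k + 1))
        out.add(seq[i : i + k])
    return sorted(out)


def simulate_sirna_libraries(
    params: SimParams,
    base_silk_mean: float = 2.0,
    pollen_mean: float = 5.5,
    ref_length: int = 600,
    total_reads: int = 20_000_000,
    stage: str = "0.4mm",
):
    """Synthetic anther siRNA libraries plus silk and pollen references.

    Per library, the number of unique 24-mers matching the silk references is
    negative-binomial with mean ``base_silk_mean * effect_multiplier`` in the
    ga1_O genotype class and ``base_silk_mean`` in the active-Ga1 class;
    pollen-target counts share one mean across classes. Matching reads are
    exact substrings of the references; a background of non-matching 24-mers
    and off-length reads is added. Returns
    ``(libraries, silk_refs, pollen_refs)``.
    """
    if params.n_per_group < 2:
        raise DomainError("n_per_group must be >= 2")
    from gametokit.sirna import SirnaLibrary, revcomp

    rng = np.random.default_rng(params.seed)
    silk_refs = [
        (name, "".join(rng.choice(_BASES, size=ref_length)))
        for name in ("Tcb1k", "Ga1k", "Ga2k")
    ]
    pollen_refs = [
        (name, "".join(rng.choice(_BASES, size=ref_length)))
        for name in ("Tcb1p", "Ga1p", "Ga2p")
    ]
    ref_kmers: set[str] = set()
    for _, seq in silk_refs + pollen_refs:
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - 23):
                ref_kmers.add(s[i : i + 24])

    libraries = []
    for cls, silk_mean in (
        ("ga1_O", base_silk_mean * params.effect_multiplier),
        ("Ga1_active", base_silk_mean),
    ):
        for rep in range(params.n_per_group):
            n_silk = _negbin(silk_mean, params.dispersion, rng)
            n_pollen = _negbin(pollen_mean, params.dispersion, rng)
            reads: dict[str, int] = {}
            for seq in _distinct_kmers_from(silk_refs, n_silk, rng):
                reads[seq] = int(rng.integers(1, 20))
            for seq in _distinct_kmers_from(pollen_refs, n_pollen, rng):
                reads[seq] = int(rng.integers(1, 20))
            # background: non-matching 24-mers and off-length reads
            n_bg = int(rng.integers(50, 100))
            while n_bg > 0:
                seq = "".join(rng.choice(_BASES, size=24))
                if seq in ref_kmers or seq in reads:
                    continue
                reads[seq] = int(rng.integers(1, 50))
                n_bg -= 1
            for _ in range(int(rng.integers(10, 30))):
                length = int(rng.choice([21, 22, 23]))
                seq = "".join(rng.choice(_BASES, size=length))
                reads.setdefault(seq, int(rng.integers(1, 50)))
            libraries.append(
                SirnaLibrary(
                    line_id=f"{cls}_line{rep + 1}",
                    genotype_class=cls,
                    tissue="anther",
                    stage=stage,
                    reads=reads,
                    total_reads=total_reads,
                )
            )
    return libraries, silk_refs, pollen_refs
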