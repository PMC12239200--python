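"""24-nt siRNA counting, enrichment testing, allele assignment, phasing.

A small-RNA library is scanned for reads of exactly 24 nt whose sequence (or
reverse complement) occurs as an exact substring of a reference gene; the
count of *unique* matching sequences per library (abundance ignored) is the
enrichment statistic. Counts are compared between genotype classes (lines
carrying the inactive-but-conserved ga1-O haplotype vs lines with active Ga1
alleles) with Welch's t-test, run separately for silk- and pollen-gene
reference sets. Allele of origin is assigned by containment against
allele-specific sequence sets, and a simple phase-register score measures
whether read 5' starts fall into one 24-nt register.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from gametokit.errors import DomainError, ParseError, UndefinedStatisticError

GENOTYPE_CLASSES = ("ga1_O", "Ga1_active")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SirnaLibrary:
    """One small-RNA library: reads with abundances plus the library size.

    ``total_reads`` is the library total across all read lengths and is the
    denominator for per-20-million normalization; it must be at least the
    summed abundance of the stored reads.
    """

    line_id: str
    genotype_class: str
    tissue: str
    stage: str
    reads: Mapping[str, int]
    total_reads: int

    def __post_init__(self) -> None:
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ParseError(
                f"{self.line_id}: genotype_class must be one of {GENOTYPE_CLASSES}"
            )
        if any(v < 1 for v in self.reads.values()):
            raise ParseError(f"{self.line_id}: abundances must be >= 1")
        if self.total_reads < sum(self.reads.values()):
            raise ParseError(
                f"{self.line_id}: total_reads smaller than stored abundances"
            )

    def reads_of_length(self, length: int) -> list[str]:
        return [s for s in self.reads if len(s) == length]


@dataclass(frozen=True)
class EnrichmentResult:
    """Welch-test comparison of unique siRNA target counts between genotypes."""

    target_set: str  # 'silk_refs' | 'pollen_refs'
    per_library_unique_counts: dict[str, int]
    normalized: dict[str, float]
    t_stat: float
    df: float
    p_value: float


def _kmer_index(references: Sequence[tuple[str, str]], k: int) -> dict[str, set[str]]:
    """Map every k-mer of each reference (both strands) to the gene ids holding it."""
    index: dict[str, set[str]] = {}
    for gene_id, seq in references:
        if not seq:
            raise ParseError(f"{gene_id}: empty reference sequence")
        seq = seq.upper()
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                index.setdefault(strand_seq[i : i + k], set()).add(gene_id)
    return index


def _matches_with_mismatches(read: str, seq: str, max_mm: int) -> bool:
    k = len(read)
    for i in range(len(seq) - k + 1):
        mm = 0
        for x, y in zip(read, seq[i : i + k]):
            if x != y:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return True
    return False


def match_sirnas(
    library: SirnaLibrary,
    references: Sequence[tuple[str, str]],
    read_length: int = 24,
    max_mismatches: int = 0,
) -> dict[str, set[str]]:
    """Unique read sequences of ``read_length`` matching each reference gene.

    A read matches when its sequence or reverse complement is a substring of
    the gene sequence (up to ``max_mismatches`` mismatches). Uniqueness is by
    distinct sequence; abundance plays no role here.
    """
    if not references:
        raise ParseError("references must be non-empty")
    reads = library.reads_of_length(read_length)
    out: dict[str, set[str]] = {gene_id: set() for gene_id, _ in references}
    if max_mismatches == 0:
        index = _kmer_index(references, read_length)
        for read in reads:
            for gene_id in index.get(read.upper(), ()):
                out[gene_id].add(read)
    else:
        refs = [(g, s.upper()) for g, s in references]
        for read in reads:
            r = read.upper()
            rc = revcomp(r)
            for gene_id, seq in refs:
                if _matches_with_mismatches(r, seq, max_mismatches) or (
                    _matches_with_mismatches(rc, seq, max_mismatches)
                ):
                    out[gene_id].add(read)
    return out


def unique_match_count(
    library: SirnaLibrary,
    references: Sequence[tuple[str, str]],
    read_length: int = 24,
    max_mismatches: int = 0,
) -> int:
    """Number of distinct read sequences matching any reference in the set."""
    per_gene = match_sirnas(library, references, read_length, max_mismatches)
    return len(set().union(*per_gene.values())) if per_gene else 0


def normalize_per_20m(count: float, total_reads: int) -> float:
    """Scale a count to a per-20-million-reads rate: count * 2e7 / total."""
    if total_reads <= 0:
        raise DomainError("total_reads must be > 0")
    return count * 2e7 / total_reads


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with the
    Welch–Satterthwaite degrees of freedom; p from the Student-t survival
    function. Swapping the groups negates t and leaves p unchanged.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DomainError("each group needs >= 2 observations")
    va = x.var(ddof=1)
    vb = y.var(ddof=1)
    if va == 0 and vb == 0:
        raise UndefinedStatisticError("both group variances are zero")
    se2_a = va / x.size
    se2_b = vb / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2_a + se2_b)
    df = (se2_a + se2_b) ** 2 / (
        se2_a**2 / (x.size - 1) + se2_b**2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(1.0, p))


def enrichment_pipeline(
    libraries: Sequence[SirnaLibrary],
    silk_refs: Sequence[tuple[str, str]],
    pollen_refs: Sequence[tuple[str, str]],
    stage_filter: str | None = None,
    read_length: int = 24,
    max_mismatches: int = 0,
    use_normalized: bool = False,
) -> dict[str, EnrichmentResult]:
    """Per-library unique-match counts and the Welch genotype comparison.

    Runs separately for the silk and pollen reference sets. The test is on
    raw unique counts by default; ``use_normalized=True`` tests the
    per-20-million values instead.
    """
    if stage_filter is not None:
        libraries = [lib for lib in libraries if lib.stage == stage_filter]
    by_class = Counter(lib.genotype_class for lib in libraries)
    for cls in GENOTYPE_CLASSES:
        if by_class[cls] < 2:
            raise DomainError(
                f"genotype class {cls!r} has {by_class[cls]} libraries after "
                "stage filtering; need >= 2 per class"
            )

    results = {}
    for target_set, refs in (("silk_refs", silk_refs), ("pollen_refs", pollen_refs)):
        counts = {
            lib.line_id: unique_match_count(lib, refs, read_length, max_mismatches)
            for lib in libraries
        }
        normalized = {
            lib.line_id: normalize_per_20m(counts[lib.line_id], lib.total_reads)
            for lib in libraries
        }
        values = normalized if use_normalized else counts
        grp_o = [values[l.line_id] for l in libraries if l.genotype_class == "ga1_O"]
        grp_a = [
            values[l.line_id] for l in libraries if l.genotype_class == "Ga1_active"
        ]
        try:
            t, df, p = welch_t_test(grp_o, grp_a)
        except UndefinedStatisticError:
            # both groups constant: no within-group variability to test
            # against, so equal means are maximally unsurprising and unequal
            # means maximally surprising
            equal = float(np.mean(grp_o)) == float(np.mean(grp_a))
            t, df, p = (0.0 if equal else np.inf), float("nan"), (1.0 if equal else 0.0)
        results[target_set] = EnrichmentResult(
            target_set=target_set,
            per_library_unique_counts=counts,
            normalized=normalized,
            t_stat=t,
            df=df,
            p_value=p,
        )
    return results


def assign_allele_origin(
    sirna_seq: str,
    allele_a_seqs: Sequence[str],
    allele_b_seqs: Sequence[str],
) -> str:
    """Classify a 24-mer by containment in allele-specific sequence sets.

    Returns ``a_specific`` / ``b_specific`` / ``shared`` / ``unassigned``.
    Containment is exact-substring on either strand; a read spanning an
    allele-private SNP is thereby specific to that allele.
    """
    if len(sirna_seq) != 24:
        raise DomainError("sirna_seq must be exactly 24 nt")
    read = sirna_seq.upper()
    rc = revcomp(read)

    def hits(seqs) -> bool:
        return any(read in s.upper() or rc in s.upper() for s in seqs)

    in_a = hits(allele_a_seqs)
    in_b = hits(allele_b_seqs)
    if in_a and in_b:
        return "shared"
    if in_a:
        return "a_specific"
    if in_b:
        return "b_specific"
    return "unassigned"


def phase_register_score(
    read_start_positions: Sequence[int], register: int = 24
) -> float:
    """Fraction of reads whose 5' start falls in the modal register class.

    Perfectly phased 24-nt siRNA clusters place every read start in one
    residue class modulo the register, scoring 1.0; uniform random starts
    score about 1/register. A deliberately simple register statistic, not a
    reproduction of any published phasing formula. Single-read input scores
    1.0 (degenerate).
    """
    if register < 2:
        raise DomainError("register must be >= 2")
    pos = np.asarray(read_start_positions, dtype=int)
    if pos.size < 1:
        raise DomainError("need at least one read position")
    classes = np.bincount(pos % register, minlength=register)
    return float(classes.max() / pos.size)
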