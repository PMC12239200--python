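"""Haplotype classification and allele frequency spectra.

A haplotype at a gametophytic-factor locus is the ordered sequence of
full-length gene copies along the chromosome, each labelled by its
sequence-identity class, its silk/pollen role, its orientation relative to the
haplotype's majority strand, and whether more than ``gap_threshold_bp`` of
intervening distance precedes it. Two genomes carry the same allele exactly
when their canonical signature keys are equal; the distinct signatures among n
genomes reduce to a frequency-of-frequencies vector a, with a_j the number of
distinct haplotypes seen in exactly j genomes — the sufficient statistic for
the Ewens-sampling-formula neutrality test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from gametokit.core_io import GeneCopy
from gametokit.errors import DomainError, FrameError, ParseError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class CopyClassSet:
    """A partition of gene copies into sequence-identity classes.

    Labels are deterministic: each class is named by its lexicographically
    smallest member copy_id, which is also the class representative.
    """

    threshold: float
    classes: dict[str, frozenset[str]]
    representative: dict[str, str]

    def label_of(self, copy_id: str) -> str:
        for label, members in self.classes.items():
            if copy_id in members:
                return label
        raise KeyError(copy_id)


@dataclass(frozen=True)
class HaplotypeSignature:
    """One genome's ordered copy-class layout at one locus.

    ``elements`` are (class_label, role, orientation, gap_before) tuples
    ordered by genomic start; ``signature_key`` is a canonical rendering
    invariant to which genomic strand the haplotype was assembled on.
    """

    genome_id: str
    locus: str
    elements: tuple[tuple[str, str, str, bool], ...]
    signature_key: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "signature_key", _canonical_key(self.elements))


def _render(elements) -> str:
    parts = []
    for label, role, orient, gap in elements:
        prefix = "~" if gap else ""
        parts.append(f"{prefix}{label}:{role}:{orient}")
    return "|".join(parts)


def _flip(elements) -> tuple:
    """Read the haplotype from the opposite genomic strand.

    Element order reverses, orientations flip, and the >threshold gap markers
    move with the physical gaps: a gap before element i becomes a gap before
    the (reversed) successor of i-1, i.e. gap flags shift one slot.
    """
    n = len(elements)
    rev = []
    for idx in range(n - 1, -1, -1):
        label, role, orient, _gap = elements[idx]
        # the gap that preceded element idx+1 now precedes this element
        gap = elements[idx + 1][3] if idx + 1 < n else False
        rev.append((label, role, "rev" if orient == "fwd" else "fwd", gap))
    if rev:
        rev[0] = (rev[0][0], rev[0][1], rev[0][2], False)
    return tuple(rev)


def _canonical_key(elements) -> str:
    fwd = _render(elements)
    rev = _render(_flip(elements))
    return min(fwd, rev)


def _identity(seq_a: str, seq_b: str) -> float:
    """Ungapped identity between equal-length CDS; N excluded pairwise.

    Unequal-length pairs are compared after codon-level global alignment
    (gapped columns then drop out of the comparison).
    """
    if len(seq_a) != len(seq_b):
        from gametokit.dating import align_codon_pair

        pair = align_codon_pair(seq_a, seq_b)
        seq_a, seq_b = pair.seq_a, pair.seq_b
    matches = 0
    total = 0
    for x, y in zip(seq_a, seq_b):
        if x in "N-" or y in "N-":
            continue
        total += 1
        if x == y:
            matches += 1
    return matches / total if total else 0.0


def classify_copies(copies: Sequence[GeneCopy], threshold: float = 1.0) -> CopyClassSet:
    """Group same-role gene copies into sequence-identity classes.

    Single-linkage: two copies share a class when a chain of pairwise CDS
    identities >= threshold connects them. With the default threshold 1.0 a
    class is a set of byte-identical CDSs. Deterministic and order-invariant:
    classes are labelled by their lexicographically smallest member.
    """
    if not copies:
        raise ParseError("classify_copies: empty input")
    roles = {c.role for c in copies}
    if len(roles) > 1:
        raise ParseError(f"classify_copies: mixed roles {sorted(roles)}")
    loci = {c.locus for c in copies}
    if len(loci) > 1:
        raise ParseError(f"classify_copies: mixed loci {sorted(loci)}")
    if not 0 < threshold <= 1:
        raise DomainError("identity threshold must be in (0, 1]")

    ordered = sorted(copies, key=lambda c: c.copy_id)
    ids = [c.copy_id for c in ordered]
    if len(set(ids)) != len(ids):
        raise ParseError("classify_copies: duplicate copy_id")
    seqs = {c.copy_id: c.cds.upper() for c in ordered}

    # union-find over single-linkage edges
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            # keep the lexicographically smaller id as root
            if rj < ri:
                ri, rj = rj, ri
            parent[rj] = ri

    for i_pos, i in enumerate(ids):
        for j in ids[i_pos + 1 :]:
            if seqs[i] == seqs[j] or _identity(seqs[i], seqs[j]) >= threshold:
                union(i, j)

    classes: dict[str, set[str]] = {}
    for i in ids:
        classes.setdefault(find(i), set()).add(i)
    frozen = {label: frozenset(members) for label, members in sorted(classes.items())}
    reps = {label: label for label in frozen}
    return CopyClassSet(threshold=threshold, classes=frozen, representative=reps)


def build_haplotype(
    genome_id: str,
    locus: str,
    copies: Sequence[GeneCopy],
    classes: CopyClassSet,
    gap_threshold_bp: int = 1000,
) -> HaplotypeSignature:
    """Assemble one genome's haplotype signature at one locus.

    Copies are ordered by genomic start (1-based closed coordinates); the
    distance between consecutive copies is ``start - previous_end - 1`` and a
    gap marker is set when it exceeds ``gap_threshold_bp``. Orientation is
    relative to the majority strand so the signature is a property of the
    haplotype, not of the assembly's arbitrary strand choice; the canonical
    key makes strand-flipped renderings compare equal.
    """
    if not copies:
        raise ParseError(f"{genome_id}/{locus}: no copies")
    chroms = {c.chrom for c in copies}
    if len(chroms) > 1:
        raise ParseError(
            f"{genome_id}/{locus}: copies on multiple chromosomes {sorted(chroms)}"
        )
    for c in copies:
        if c.genome_id != genome_id or c.locus != locus:
            raise ParseError(f"{c.copy_id}: genome/locus mismatch")

    ordered = sorted(copies, key=lambda c: (c.start, c.end, c.copy_id))
    n_plus = sum(1 for c in ordered if c.strand == "+")
    majority = "+" if n_plus * 2 >= len(ordered) else "-"

    elements = []
    prev_end = None
    for c in ordered:
        orient = "fwd" if c.strand == majority else "rev"
        gap = prev_end is not None and (c.start - prev_end - 1) > gap_threshold_bp
        elements.append((classes.label_of(c.copy_id), c.role, orient, gap))
        prev_end = c.end
    return HaplotypeSignature(genome_id=genome_id, locus=locus, elements=tuple(elements))


def detect_premature_stop(cds: str) -> bool:
    """True iff an in-frame TAA/TAG/TGA occurs before the terminal codon.

    A stop in the last codon position is the normal terminator and does not
    count. Length must be a multiple of 3 and at least two codons; no silent
    padding or trimming is performed.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0 or len(cds) < 6:
        raise FrameError(
            f"CDS length {len(cds)} is not a multiple of 3 (>= 6) — pad or trim "
            "explicitly before calling"
        )
    return any(
        cds[i : i + 3] in STOP_CODONS for i in range(0, len(cds) - 3, 3)
    )


@dataclass(frozen=True)
class SpectrumConfig:
    """Allele frequency spectrum: a_j = number of haplotypes seen in j genomes.

    The sufficient data object for the Ewens-sampling-formula test. n is the
    number of genomes in which the locus is present (absence never counts as
    an allele); k = sum(a_j) is the number of distinct haplotypes.
    """

    n: int
    a: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("spectrum needs n >= 1")
        if len(self.a) != self.n:
            raise DomainError(f"a must have length n = {self.n}")
        if any(aj < 0 for aj in self.a):
            raise DomainError("a_j must be >= 0")
        if sum(j * aj for j, aj in enumerate(self.a, start=1)) != self.n:
            raise DomainError("spectrum invariant sum(j * a_j) == n violated")

    @property
    def k(self) -> int:
        return sum(self.a)

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "SpectrumConfig":
        """Build from per-allele sample counts, e.g. [18, 1, 1] -> a_1=2, a_18=1."""
        n = sum(counts)
        a = [0] * n
        for c in counts:
            if c < 1:
                raise DomainError("allele counts must be >= 1")
            a[c - 1] += 1
        return cls(n=n, a=tuple(a))

    def class_counts(self) -> list[int]:
        """Observed allele counts in decreasing order, e.g. [18, 1, 1]."""
        out: list[int] = []
        for j, aj in enumerate(self.a, start=1):
            out.extend([j] * aj)
        return sorted(out, reverse=True)


def classify_locus_copies(
    copies: Sequence[GeneCopy], threshold: float = 1.0
) -> CopyClassSet:
    """Classify silk and pollen copies separately and merge the partitions.

    Labels are copy_ids, so the merged map has no collisions; the merged set
    is what :func:`build_haplotype` consumes for a mixed-role locus.
    """
    merged_classes: dict[str, frozenset[str]] = {}
    merged_reps: dict[str, str] = {}
    for role in ("silk", "pollen"):
        role_copies = [c for c in copies if c.role == role]
        if not role_copies:
            continue
        ccs = classify_copies(role_copies, threshold)
        merged_classes.update(ccs.classes)
        merged_reps.update(ccs.representative)
    if not merged_classes:
        raise ParseError("classify_locus_copies: empty input")
    return CopyClassSet(
        threshold=threshold, classes=merged_classes, representative=merged_reps
    )


def locus_spectrum(
    copies: Sequence[GeneCopy],
    threshold: float = 1.0,
    gap_threshold_bp: int = 1000,
) -> tuple[SpectrumConfig, list[HaplotypeSignature], CopyClassSet]:
    """Full haplotype stage: classify copies, build signatures, reduce to a.

    All copies must share one locus; genomes lacking the locus simply do not
    appear and therefore never contribute to n.
    """
    loci = {c.locus for c in copies}
    if len(loci) != 1:
        raise ParseError(f"locus_spectrum: expected one locus, got {sorted(loci)}")
    locus = loci.pop()
    classes = classify_locus_copies(copies, threshold)
    by_genome: dict[str, list[GeneCopy]] = {}
    for c in copies:
        by_genome.setdefault(c.genome_id, []).append(c)
    signatures = [
        build_haplotype(genome_id, locus, genome_copies, classes, gap_threshold_bp)
        for genome_id, genome_copies in sorted(by_genome.items())
    ]
    return spectrum_from_haplotypes(signatures), signatures, classes


def spectrum_from_haplotypes(signatures: Sequence[HaplotypeSignature]) -> SpectrumConfig:
    """Collapse per-genome signatures into a frequency spectrum.

    One signature per genome (homozygous inbred assumption); duplicate
    genome_ids are rejected rather than deduplicated.
    """
    if not signatures:
        raise ParseError("no signatures")
    loci = {s.locus for s in signatures}
    if len(loci) > 1:
        raise ParseError(f"mixed loci {sorted(loci)}")
    genomes = [s.genome_id for s in signatures]
    if len(set(genomes)) != len(genomes):
        raise ParseError("duplicate genome_id in signatures")
    counts: dict[str, int] = {}
    for s in signatures:
        counts[s.signature_key] = counts.get(s.signature_key, 0) + 1
    return SpectrumConfig.from_counts(list(counts.values()))
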