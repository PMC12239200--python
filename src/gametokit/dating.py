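"""Synonymous divergence (Ks) and duplication dating.

The dating pipeline estimates when two gene copies diverged from their common
ancestor: count synonymous sites and differences codon-by-codon in the
Nei–Gojobori (1986) framework, split the synonymous differences into
transitions and transversions, correct for multiple hits with the Kimura
two-parameter formula applied to the synonymous proportions, and convert the
corrected distance to time with T = Ks / (2 mu) (two branches since the
split, mu substitutions/site/generation, generations scaled to years).

Site counting follows classic NG86: at each codon position the synonymous
fraction is the share of the 3 possible single-nucleotide changes that leave
the amino acid unchanged (changes producing a stop codon count as
nonsynonymous); S is averaged between the two sequences. Differences between
codons differing at 2 or 3 positions are averaged over all substitution
orders, excluding pathways that pass through a stop codon (all pathways are
used if every one is blocked). Codon columns containing a gap or N in either
sequence are wholly excluded.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from math import log
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from gametokit.core_io import GeneCopy, RunConfig, apply_cleavage
from gametokit.errors import (
    DomainError,
    FrameError,
    SaturationError,
    UndefinedStatisticError,
)

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
for _stop in STOP_CODONS:
    CODON_TABLE[_stop] = "*"


def _syn_site_fractions(kappa: float) -> dict[str, float]:
    """Per-codon synonymous site count, changes weighted by mutation rate.

    A transition change carries weight kappa and each transversion weight 1
    (total kappa + 2 per position), so the synonymous site count reflects the
    fraction of *mutations*, not of possible changes, that are synonymous.
    kappa = 1 recovers classic NG86 counting; kappa > 1 is the modified
    Nei–Gojobori counting that removes the bias a transition/transversion
    rate ratio induces. Changes producing a stop codon are nonsynonymous.
    """
    out = {}
    for codon, aa in CODON_TABLE.items():
        if aa == "*":
            continue
        syn = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if CODON_TABLE[mut] == aa:  # stop codons translate to '*', never equal
                    syn += kappa if (codon[pos], b) in _TRANSITIONS else 1.0
        out[codon] = syn / (kappa + 2.0)
    return out


_SYN_SITES_CACHE: dict[float, dict[str, float]] = {}


def _syn_sites(kappa: float) -> dict[str, float]:
    if kappa not in _SYN_SITES_CACHE:
        _SYN_SITES_CACHE[kappa] = _syn_site_fractions(kappa)
    return _SYN_SITES_CACHE[kappa]


@dataclass(frozen=True)
class AlignedCodonPair:
    """Two in-frame aligned CDSs (equal length, multiple of 3, '-' gaps)."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise FrameError(f"{self.id_a}/{self.id_b}: aligned lengths differ")
        if len(self.seq_a) % 3 != 0:
            raise FrameError(
                f"{self.id_a}/{self.id_b}: aligned length {len(self.seq_a)} "
                "not a multiple of 3"
            )

    def included_codons(self) -> list[tuple[str, str]]:
        """Codon columns free of gaps and Ns in both sequences."""
        out = []
        for i in range(0, len(self.seq_a), 3):
            ca = self.seq_a[i : i + 3].upper()
            cb = self.seq_b[i : i + 3].upper()
            if set(ca + cb) <= set(_BASES):
                out.append((ca, cb))
        return out


@dataclass(frozen=True)
class KsEstimate:
    """Pairwise synonymous-distance record with the derived age."""

    id_a: str
    id_b: str
    S: float  # synonymous sites (averaged between sequences)
    N_sites: float  # nonsynonymous sites
    sd: float  # synonymous differences (pathway-averaged)
    Ps: float  # synonymous transitions per synonymous site
    Qs: float  # synonymous transversions per synonymous site
    ks: float  # K2P-corrected synonymous substitutions per synonymous site
    age_years: Optional[float] = None


def align_codon_pair(seq_a: str, seq_b: str, id_a: str = "a", id_b: str = "b") -> AlignedCodonPair:
    """Global codon-level alignment (match +1, mismatch -1, gap -2).

    Needleman–Wunsch over codons, deterministic tie-break preferring the
    diagonal move, then the vertical (gap in b). Identical sequences
    round-trip unchanged.
    """
    if len(seq_a) % 3 or len(seq_b) % 3:
        raise FrameError("sequences must be in frame (length multiple of 3)")
    a = [seq_a[i : i + 3].upper() for i in range(0, len(seq_a), 3)]
    b = [seq_b[i : i + 3].upper() for i in range(0, len(seq_b), 3)]
    la, lb = len(a), len(b)
    GAP = -2.0
    score = [[0.0] * (lb + 1) for _ in range(la + 1)]
    move = [[""] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        score[i][0] = i * GAP
        move[i][0] = "U"
    for j in range(1, lb + 1):
        score[0][j] = j * GAP
        move[0][j] = "L"
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            match = 1.0 if a[i - 1] == b[j - 1] else -1.0
            diag = score[i - 1][j - 1] + match
            up = score[i - 1][j] + GAP
            left = score[i][j - 1] + GAP
            # tie-break: diagonal, then up (gap in b), then left
            best, mv = diag, "D"
            if up > best:
                best, mv = up, "U"
            if left > best:
                best, mv = left, "L"
            score[i][j] = best
            move[i][j] = mv
    out_a, out_b = [], []
    i, j = la, lb
    while i or j:
        mv = move[i][j]
        if mv == "D":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif mv == "U":
            out_a.append(a[i - 1])
            out_b.append("---")
            i -= 1
        else:
            out_a.append("---")
            out_b.append(b[j - 1])
            j -= 1
    return AlignedCodonPair(
        id_a=id_a,
        id_b=id_b,
        seq_a="".join(reversed(out_a)),
        seq_b="".join(reversed(out_b)),
    )


def _codon_path_diffs(ca: str, cb: str) -> tuple[float, float, float, float]:
    """Pathway-averaged (syn, nonsyn, syn_ts, syn_tv) differences for one codon pair.

    Averages over all orders of the differing positions; pathways passing
    through a stop codon are excluded (all retained if every pathway is
    blocked).
    """
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    if not diff_pos:
        return 0.0, 0.0, 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = ca
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if CODON_TABLE[nxt] == "*" and nxt != cb:
                blocked = True
            syn = (
                CODON_TABLE[current] == CODON_TABLE[nxt]
                and CODON_TABLE[nxt] != "*"
            )
            ts = (current[pos], nxt[pos]) in _TRANSITIONS
            steps.append((syn, ts))
            current = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = s_ts = s_tv = 0.0
    for steps in usable:
        for syn, ts in steps:
            if syn:
                sd += 1
                if ts:
                    s_ts += 1
                else:
                    s_tv += 1
            else:
                nd += 1
    m = len(usable)
    return sd / m, nd / m, s_ts / m, s_tv / m


def count_syn_sites_diffs(
    pair: AlignedCodonPair, on_internal_stop: str = "warn", kappa: float = 1.0
) -> tuple[float, float, float, float, float]:
    """NG86 synonymous/nonsynonymous sites and pathway-averaged differences.

    Returns ``(S, N_sites, sd, syn_transitions, syn_transversions)``. With
    the default ``kappa=1`` site counting is classic NG86 (every possible
    change weighted equally); ``kappa>1`` weights transitions by the ts/tv
    rate ratio (modified Nei–Gojobori). Codons that are stop codons in either
    sequence are excluded with a warning (``on_internal_stop='error'`` raises
    instead); gap/N columns are excluded silently.
    """
    syn_sites = _syn_sites(kappa)
    s_a = s_b = 0.0
    n_codons = 0
    n_stop_excluded = 0
    sd = s_ts = s_tv = 0.0
    for ca, cb in pair.included_codons():
        if CODON_TABLE[ca] == "*" or CODON_TABLE[cb] == "*":
            if on_internal_stop == "error":
                raise FrameError(
                    f"{pair.id_a}/{pair.id_b}: stop codon {ca}/{cb}"
                )
            n_stop_excluded += 1
            continue
        n_codons += 1
        s_a += syn_sites[ca]
        s_b += syn_sites[cb]
        d_syn, _d_non, d_ts, d_tv = _codon_path_diffs(ca, cb)
        sd += d_syn
        s_ts += d_ts
        s_tv += d_tv
    if n_stop_excluded:
        warnings.warn(
            f"{pair.id_a}/{pair.id_b}: {n_stop_excluded} stop-containing "
            "codon column(s) excluded",
            stacklevel=2,
        )
    S = (s_a + s_b) / 2.0
    N_sites = 3.0 * n_codons - S
    return S, N_sites, sd, s_ts, s_tv


def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    P and Q are the observed transition and transversion proportions per
    site. Raises :class:`SaturationError` when the observed divergence is at
    or beyond the formula's domain boundary.
    """
    if P < 0 or Q < 0:
        raise DomainError("P and Q must be >= 0")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P correction undefined for P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    return -0.5 * log(w1) - 0.25 * log(w2)


def k2p_distance_all_sites(pair: AlignedCodonPair) -> float:
    """Plain K2P distance over every aligned non-gap/N site (no NG86 framing)."""
    ts = tv = total = 0
    for ca, cb in pair.included_codons():
        for x, y in zip(ca, cb):
            total += 1
            if x == y:
                continue
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if total == 0:
        raise UndefinedStatisticError("no comparable sites")
    return k2p_distance(ts / total, tv / total)


DEFAULT_KAPPA = 2.0


def ks_k2p(
    pair: AlignedCodonPair,
    on_internal_stop: str = "warn",
    kappa: float = DEFAULT_KAPPA,
) -> KsEstimate:
    """K2P-corrected synonymous distance for one aligned pair (age unset).

    Modified Nei–Gojobori with K2P correction: synonymous sites are counted
    with transition changes weighted by ``kappa`` (default 2, a typical
    nuclear ts/tv rate ratio), then Ps = synonymous transitions / S,
    Qs = synonymous transversions / S and ks = K2P(Ps, Qs). ``kappa=1``
    reduces to plain NG86 counting.
    """
    S, N_sites, sd, s_ts, s_tv = count_syn_sites_diffs(pair, on_internal_stop, kappa)
    if S <= 0:
        raise UndefinedStatisticError(
            f"{pair.id_a}/{pair.id_b}: zero synonymous sites, Ks undefined"
        )
    Ps, Qs = s_ts / S, s_tv / S
    ks = k2p_distance(Ps, Qs)
    return KsEstimate(
        id_a=pair.id_a, id_b=pair.id_b, S=S, N_sites=N_sites, sd=sd, Ps=Ps, Qs=Qs, ks=ks
    )


def age_from_ks(ks: float, mu: float, generation_time_years: float = 1.0) -> float:
    """Divergence time in years: T = ks / (2 mu) * generation_time_years.

    The factor 2 accounts for the two branches descending from the shared
    ancestral node; mu is per site per generation.
    """
    if mu <= 0:
        raise DomainError("mu must be > 0")
    if generation_time_years <= 0:
        raise DomainError("generation_time_years must be > 0")
    if ks < 0:
        raise DomainError("ks must be >= 0")
    return ks / (2.0 * mu) * generation_time_years


def ks_between_copies(
    copy_a: GeneCopy, copy_b: GeneCopy, config: RunConfig | None = None
) -> KsEstimate:
    """Ks and age between two gene copies (signal peptides cleaved first)."""
    config = config or RunConfig()
    cds_a = apply_cleavage(copy_a)
    cds_b = apply_cleavage(copy_b)
    pair = align_codon_pair(cds_a, cds_b, id_a=copy_a.copy_id, id_b=copy_b.copy_id)
    est = ks_k2p(pair)
    return replace(
        est, age_years=age_from_ks(est.ks, config.mu, config.generation_time_years)
    )


def mean_pairwise_age(
    group_a: Sequence[GeneCopy],
    group_b: Sequence[GeneCopy],
    config: RunConfig | None = None,
) -> tuple[float, list[KsEstimate]]:
    """Mean divergence time over all cross pairs between two gene groups.

    Within-group pairs are excluded; saturated pairs are reported in the
    per-pair list with ``ks=nan`` via a warning and excluded from the mean.
    """
    config = config or RunConfig()
    if not group_a or not group_b:
        raise DomainError("both groups must be non-empty")
    ids_a = {c.copy_id for c in group_a}
    ids_b = {c.copy_id for c in group_b}
    if ids_a & ids_b:
        raise DomainError(f"groups overlap: {sorted(ids_a & ids_b)}")
    estimates: list[KsEstimate] = []
    ages: list[float] = []
    for ca in group_a:
        for cb in group_b:
            try:
                est = ks_between_copies(ca, cb, config)
            except SaturationError as exc:
                warnings.warn(str(exc), stacklevel=2)
                continue
            estimates.append(est)
            ages.append(est.age_years)
    if not ages:
        raise SaturationError("every pair saturated; no mean age")
    return sum(ages) / len(ages), estimates
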