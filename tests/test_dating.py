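import itertools
import warnings

import numpy as np
import pytest

from gametokit.dating import (
    _TRANSITIONS,
    CODON_TABLE,
    AlignedCodonPair,
    align_codon_pair,
    age_from_ks,
    count_syn_sites_diffs,
    k2p_distance,
    ks_k2p,
    mean_pairwise_age,
)
from gametokit.errors import (
    DomainError,
    FrameError,
    SaturationError,
    UndefinedStatisticError,
)
from gametokit.synth import random_cds, simulate_codon_divergence

SENSE = [c for c, aa in CODON_TABLE.items() if aa != "*"]


class TestAlignCodonPair:
    def test_identical_round_trip(self):
        pair = align_codon_pair("ATGAAACCC", "ATGAAACCC")
        assert pair.seq_a == pair.seq_b == "ATGAAACCC"

    def test_length_difference_gets_codon_gap(self):
        pair = align_codon_pair("ATGAAA", "ATG")
        assert pair.seq_a == "ATGAAA"
        assert pair.seq_b in ("ATG---", "---ATG")
        assert pair.seq_b == "ATG---"  # diagonal-first tie-break

    def test_frame_violation_rejected(self):
        with pytest.raises(FrameError):
            align_codon_pair("ATGA", "ATG")

    def test_score_matches_brute_force(self, rng):
        """NW codon alignment score equals exhaustive search, <= 4 codons."""

        def brute_best(a, b):
            # enumerate all alignments recursively
            def rec(i, j):
                if i == len(a) and j == len(b):
                    return 0.0
                best = -np.inf
                if i < len(a) and j < len(b):
                    best = max(
                        best, (1.0 if a[i] == b[j] else -1.0) + rec(i + 1, j + 1)
                    )
                if i < len(a):
                    best = max(best, -2.0 + rec(i + 1, j))
                if j < len(b):
                    best = max(best, -2.0 + rec(i, j + 1))
                return best

            return rec(0, 0)

        def score_of(pair):
            s = 0.0
            for i in range(0, len(pair.seq_a), 3):
                ca, cb = pair.seq_a[i : i + 3], pair.seq_b[i : i + 3]
                if "-" in ca or "-" in cb:
                    s -= 2.0
                else:
                    s += 1.0 if ca == cb else -1.0
            return s

        for _ in range(30):
            na, nb = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            a = [SENSE[i] for i in rng.integers(0, len(SENSE), na)]
            b = [SENSE[i] for i in rng.integers(0, len(SENSE), nb)]
            pair = align_codon_pair("".join(a), "".join(b))
            assert score_of(pair) == pytest.approx(brute_best(a, b))


def pathway_oracle(ca, cb):
    """Straightforward pathway enumeration for the difference counts."""
    diff = [p for p in range(3) if ca[p] != cb[p]]
    results = []
    for order in itertools.permutations(diff):
        cur = ca
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if CODON_TABLE[nxt] == "*" and nxt != cb:
                ok = False
            syn = CODON_TABLE[cur] == CODON_TABLE[nxt] and CODON_TABLE[nxt] != "*"
            steps.append((syn, (cur[pos], nxt[pos]) in _TRANSITIONS))
            cur = nxt
        results.append((ok, steps))
    kept = [s for ok, s in results if ok] or [s for _, s in results]
    sd = sum(syn for steps in kept for syn, _ in steps) / len(kept)
    ts = sum(syn and t for steps in kept for syn, t in steps) / len(kept)
    tv = sum(syn and not t for steps in kept for syn, t in steps) / len(kept)
    return sd, ts, tv


class TestCountSynSitesDiffs:
    @pytest.mark.parametrize(
        "ca,cb,S,sd",
        [
            ("AAA", "AAA", 1 / 3, 0.0),  # Lys: 1 of 3 third-position changes syn
            ("AAA", "AAG", 1 / 3, 1.0),  # synonymous transition
            ("TTT", "CTT", 2 / 3, 0.0),  # Phe->Leu nonsynonymous
        ],
    )
    def test_single_codon_examples(self, ca, cb, S, sd):
        pair = AlignedCodonPair("a", "b", ca, cb)
        S_got, N_got, sd_got, ts, tv = count_syn_sites_diffs(pair)
        assert S_got == pytest.approx(S)
        assert S_got + N_got == pytest.approx(3.0)
        assert sd_got == pytest.approx(sd)
        assert ts + tv == pytest.approx(sd_got)

    def test_sites_sum_to_three_per_included_codon(self, rng):
        a = random_cds(50, rng)
        b = random_cds(50, rng)
        pair = align_codon_pair(a, b)
        S, N, *_ = count_syn_sites_diffs(pair)
        assert S + N == pytest.approx(3 * len(pair.included_codons()))

    def test_pathway_averaging_matches_enumeration_sample(self, rng):
        """Spot-check against the oracle on random multi-difference pairs
        (the exhaustive all-pairs sweep runs in the acceptance suite)."""
        checked = 0
        while checked < 60:
            ca = SENSE[int(rng.integers(len(SENSE)))]
            cb = SENSE[int(rng.integers(len(SENSE)))]
            ndiff = sum(x != y for x, y in zip(ca, cb))
            if ndiff < 2:
                continue
            checked += 1
            pair = AlignedCodonPair("a", "b", ca, cb)
            _, _, sd, ts, tv = count_syn_sites_diffs(pair)
            o_sd, o_ts, o_tv = pathway_oracle(ca, cb)
            assert (sd, ts, tv) == pytest.approx((o_sd, o_ts, o_tv))

    def test_gap_and_n_columns_excluded(self):
        pair = AlignedCodonPair("a", "b", "AAA---ATN", "AAAGGGATG")
        S, N, *_ = count_syn_sites_diffs(pair)
        assert S + N == pytest.approx(3.0)  # only the first codon counts

    def test_internal_stop_excluded_with_warning(self):
        pair = AlignedCodonPair("a", "b", "TAAAAA", "TACAAA")
        with pytest.warns(UserWarning, match="stop"):
            S, N, sd, *_ = count_syn_sites_diffs(pair)
        assert S + N == pytest.approx(3.0)
        with pytest.raises(FrameError):
            count_syn_sites_diffs(pair, on_internal_stop="error")


class TestK2PDistance:
    def test_zero_at_zero(self):
        assert k2p_distance(0.0, 0.0) == 0.0

    def test_hand_example(self):
        assert k2p_distance(0.1, 0.05) == pytest.approx(0.1701812, abs=5e-7)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(0.4, 0.2)

    def test_small_distance_limit(self):
        # d ~ P + Q for tiny divergence
        for P, Q in [(0.004, 0.004), (0.007, 0.002), (0.001, 0.009)]:
            d = k2p_distance(P, Q)
            assert d == pytest.approx(P + Q, rel=0.02)

    def test_monotone_in_each_argument(self):
        assert k2p_distance(0.10, 0.05) > k2p_distance(0.08, 0.05)
        assert k2p_distance(0.10, 0.05) > k2p_distance(0.10, 0.03)


class TestKsK2p:
    def test_identical_sequences_give_zero(self, rng):
        cds = random_cds(100, rng)
        est = ks_k2p(align_codon_pair(cds, cds))
        assert est.ks == 0.0

    def test_nonsynonymous_only_differences_give_zero(self):
        # TTT->CTT (Phe->Leu) is purely nonsynonymous
        pair = align_codon_pair("TTTAAA", "CTTAAA")
        assert ks_k2p(pair).ks == 0.0

    def test_recovers_simulated_divergence(self):
        mu, T = 3.3e-8, 1e6
        vals = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(60):
                a, b = simulate_codon_divergence(300, T, mu, seed=7000 + s)
                vals.append(ks_k2p(align_codon_pair(a, b)).ks)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 2 * mu * T) < 3 * se

    def test_zero_synonymous_sites_rejected(self):
        # Met/Trp codons have no synonymous changes
        pair = align_codon_pair("ATGTGG", "ATGTGG")
        with pytest.raises(UndefinedStatisticError):
            ks_k2p(pair)


class TestAgeFromKs:
    @pytest.mark.parametrize(
        "ks,expected_years",
        [(0.0, 0.0), (0.01254, 190_000.0), (1.122, 1.7e7)],
    )
    def test_examples(self, ks, expected_years):
        assert age_from_ks(ks, 3.3e-8, 1.0) == pytest.approx(expected_years)

    def test_linear_in_ks(self):
        assert age_from_ks(0.2, 3.3e-8) == pytest.approx(2 * age_from_ks(0.1, 3.3e-8))

    def test_invalid_mu_rejected(self):
        with pytest.raises(DomainError):
            age_from_ks(0.1, 0.0)


class TestMeanPairwiseAge:
    def test_singleton_groups_equal_single_pair(self, gene_copy_factory):
        a, b = simulate_codon_divergence(120, 5e5, seed=11)
        ca = gene_copy_factory(copy_id="a", cds=a)
        cb = gene_copy_factory(copy_id="b", genome_id="g2", cds=b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_age, ests = mean_pairwise_age([ca], [cb])
        assert len(ests) == 1
        assert mean_age == pytest.approx(ests[0].age_years)

    def test_identical_groups_age_zero(self, gene_copy_factory, rng):
        cds = random_cds(100, rng)
        ga = [gene_copy_factory(copy_id=f"a{i}", cds=cds) for i in range(2)]
        gb = [
            gene_copy_factory(copy_id=f"b{i}", genome_id="g2", cds=cds)
            for i in range(2)
        ]
        mean_age, ests = mean_pairwise_age(ga, gb)
        assert mean_age == 0.0
        assert len(ests) == 4  # all cross pairs, no within-group pairs

    def test_mean_is_arithmetic_mean_of_pair_ages(self, gene_copy_factory):
        mu = 3.3e-8
        ga, gb = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, T in enumerate([2e5, 8e5]):
                a, b = simulate_codon_divergence(150, T, seed=100 + i)
                ga.append(gene_copy_factory(copy_id=f"a{i}", cds=a))
                gb.append(
                    gene_copy_factory(copy_id=f"b{i}", genome_id="g2", cds=b)
                )
            mean_age, ests = mean_pairwise_age(ga, gb)
        assert mean_age == pytest.approx(np.mean([e.age_years for e in ests]))
        # converting then averaging equals averaging ks then converting
        assert mean_age == pytest.approx(
            age_from_ks(float(np.mean([e.ks for e in ests])), mu)
        )

    def test_overlapping_groups_rejected(self, gene_copy_factory):
        c = gene_copy_factory(copy_id="x")
        with pytest.raises(DomainError):
            mean_pairwise_age([c], [c])
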