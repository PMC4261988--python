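"""Summary statistics against closed forms and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecotypeabc.coalescent_sim import MultiMarkerDataset
from ecotypeabc.sumstats import (
    aflp_allele_freqs,
    aflp_fst_pair,
    aflp_heterozygosity,
    assemble_vector,
    jaccard_distance,
    k2p_distance,
    phi_st,
    pi_k2p,
    tajimas_d,
)

A, C, G, T = 0, 1, 2, 3


def seqs(*rows):
    return np.array(rows, dtype=np.int8)


class TestK2P:
    def test_identical_sequences(self):
        s = seqs([A, C, G, T] * 25)
        assert k2p_distance(s[0:1][0], s[0:1][0]) == 0.0

    def test_one_transition_per_hundred_sites(self):
        a = np.full(100, A, dtype=np.int8)
        b = a.copy()
        b[0] = G
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.98))

    def test_two_transversions_per_hundred_sites(self):
        # P = 0, Q = 0.02: d = -1/2 ln(1 - Q) - 1/4 ln(1 - 2Q) evaluated
        # from the standard formula = 0.020307
        a = np.full(100, A, dtype=np.int8)
        b = a.copy()
        b[0] = C
        b[1] = C
        expected = -0.5 * math.log(1 - 0.04 / 2 - 0.0) - 0.25 * math.log(1 - 0.04)
        assert expected == pytest.approx(0.0203068, abs=1e-6)
        assert k2p_distance(a, b) == pytest.approx(expected)

    def test_saturation_flagged_as_nan(self):
        a = np.full(4, A, dtype=np.int8)
        b = np.full(4, G, dtype=np.int8)  # P = 1: log argument <= 0
        assert math.isnan(k2p_distance(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            k2p_distance(np.zeros(3, dtype=np.int8), np.zeros(4, dtype=np.int8))


class TestPi:
    def test_monomorphic(self):
        assert pi_k2p(seqs([A, C, G], [A, C, G], [A, C, G])) == 0.0

    def test_two_sequences_equal_their_distance(self):
        aln = seqs([A] * 100, [G] * 5 + [A] * 95)
        assert pi_k2p(aln) == pytest.approx(k2p_distance(aln[0], aln[1]))

    def test_four_sequence_mean_over_six_pairs(self, rng):
        aln = rng.integers(0, 4, size=(4, 200)).astype(np.int8)
        # make it mostly monomorphic so no pair saturates
        aln[1:] = aln[0]
        aln[1, :3] = (aln[0, :3] + 1) % 4
        aln[2, 5] = (aln[0, 5] + 2) % 4
        expected = np.mean([k2p_distance(aln[i], aln[j])
                            for i, j in itertools.combinations(range(4), 2)])
        assert pi_k2p(aln) == pytest.approx(expected)

    def test_single_sequence_sentinel(self):
        assert math.isnan(pi_k2p(seqs([A, C])))


def _tajima_oracle(aln):
    """Independent textbook computation from first principles."""
    n, L = aln.shape
    S = sum(len(set(aln[:, j])) > 1 for j in range(L))
    if S == 0:
        return 0.0
    pi = np.mean([(aln[i] != aln[j]).sum()
                  for i, j in itertools.combinations(range(n), 2)])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregating_sites_is_zero(self):
        assert tajimas_d(np.zeros((5, 30), dtype=np.int8)) == 0.0

    def test_matches_first_principles_oracle(self, rng):
        for _ in range(20):
            aln = np.zeros((6, 50), dtype=np.int8)
            nmut = rng.integers(1, 8)
            for _ in range(nmut):
                i, j = rng.integers(0, 6), rng.integers(0, 50)
                aln[i, j] = rng.integers(1, 4)
            assert tajimas_d(aln) == pytest.approx(_tajima_oracle(aln))

    def test_excess_singletons_negative(self):
        # star-like alignment: every variant private to one sequence
        aln = np.zeros((6, 60), dtype=np.int8)
        for i in range(6):
            aln[i, i * 3:(i + 1) * 3] = C
        assert tajimas_d(aln) < 0


def _phi_oracle(ga, gb):
    """Brute-force two-group AMOVA on the squared K2P distance matrix."""
    aln = np.concatenate([ga, gb])
    na, nb = len(ga), len(gb)
    N = na + nb
    d2 = np.zeros((N, N))
    for i, j in itertools.combinations(range(N), 2):
        d2[i, j] = d2[j, i] = k2p_distance(aln[i], aln[j]) ** 2
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_within = (d2[:na, :na][np.triu_indices(na, 1)].sum() / na
                 + d2[na:, na:][np.triu_indices(nb, 1)].sum() / nb)
    ss_among = ss_total - ss_within
    sw = ss_within / (N - 2)
    nc = (N - (na**2 + nb**2) / N) / 1
    sa = (ss_among / 1 - sw) / nc
    return sa / (sa + sw)


class TestPhiST:
    def test_statistically_identical_groups_centre_on_zero(self, rng):
        # two samples from one haplotype pool: mean estimate ~ 0 (exact
        # duplication drives the estimate negative, since between-group
        # pairs then include zero self-distances; negatives are retained)
        pool = np.zeros((40, 60), dtype=np.int8)
        for i in range(40):
            pool[i, rng.integers(0, 60, size=3)] = rng.integers(1, 4, size=3)
        vals = []
        for _ in range(200):
            pick = rng.permutation(40)
            vals.append(phi_st(pool[pick[:5]], pool[pick[5:10]]))
        assert abs(np.mean(vals)) < 0.02
        g = seqs([A, C, G, T], [A, C, C, T], [G, C, G, T])
        assert phi_st(g, g.copy()) <= 0.0  # literal duplication

    def test_fixed_difference_is_one(self):
        ga = np.tile(seqs([A] * 20), (3, 1))
        gb = np.tile(seqs([G] + [A] * 19), (3, 1))
        assert phi_st(ga, gb) == pytest.approx(1.0)

    def test_matches_brute_force_amova(self, rng):
        for _ in range(10):
            base = rng.integers(0, 4, size=60).astype(np.int8)
            ga = np.tile(base, (3, 1))
            gb = np.tile(base, (3, 1))
            for row in (*ga, *gb):
                for _ in range(rng.integers(0, 4)):
                    row[rng.integers(0, 60)] = rng.integers(0, 4)
            assert phi_st(ga, gb) == pytest.approx(_phi_oracle(ga, gb))

    def test_small_group_sentinel(self):
        assert math.isnan(phi_st(seqs([A, C]), seqs([A, C], [A, G])))


class TestAflp:
    def test_allele_freq_arithmetic(self):
        m = np.array([[1], [1], [1], [0]], dtype=np.int8)  # f0 = 0.25
        assert aflp_allele_freqs(m)[0] == pytest.approx(0.5)
        assert aflp_allele_freqs(np.ones((4, 1), np.int8))[0] == 0.0
        assert aflp_allele_freqs(np.zeros((4, 1), np.int8))[0] == 1.0

    def test_fixed_difference_fst_one(self):
        a = np.ones((6, 1), dtype=np.int8)  # p = 1
        b = np.zeros((6, 1), dtype=np.int8)  # p = 0
        mean, sd, per = aflp_fst_pair(a, b)
        assert mean == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        a = np.array([[1, 0]] * 4 + [[0, 1]] * 4, dtype=np.int8)
        mean, _, _ = aflp_fst_pair(a, a.copy())
        assert abs(mean) < 0.2  # exactly equal freqs: only the variance correction remains
        # and the uncorrected numerator is exactly zero:
        q = aflp_allele_freqs(a)
        assert np.allclose(q, aflp_allele_freqs(a.copy()))

    def test_three_locus_hand_oracle(self):
        # group A: 4 individuals, bands (1,1,0,0), (1,0,1,0) per locus etc.
        a = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 0, 1]], dtype=np.int8)
        b = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=np.int8)
        mean, sd, per = aflp_fst_pair(a, b)
        # hand computation with the same square-root frequencies and
        # delta-method variance correction
        exp = []
        for j in range(3):
            q1 = math.sqrt(1 - a[:, j].mean())
            q2 = math.sqrt(1 - b[:, j].mean())
            p1, p2 = 1 - q1, 1 - q2
            v1 = (1 - q1**2) / 16 if 0 < q1 < 1 else 0.0
            v2 = (1 - q2**2) / 16 if 0 < q2 < 1 else 0.0
            pbar = (p1 + p2) / 2
            ht = 2 * pbar * (1 - pbar)
            exp.append((((p1 - p2) ** 2) - v1 - v2) / 2 / ht)
        assert per == pytest.approx(exp)
        assert mean == pytest.approx(np.mean(exp))
        assert sd == pytest.approx(np.std(exp, ddof=1))

    def test_monomorphic_pair_sentinel(self):
        a = np.ones((4, 2), dtype=np.int8)
        mean, sd, per = aflp_fst_pair(a, a.copy())
        assert math.isnan(mean)

    def test_heterozygosity_bounds(self, rng):
        m = rng.integers(0, 2, size=(10, 40)).astype(np.int8)
        assert 0.0 <= aflp_heterozygosity(m) <= 0.5


class TestJaccard:
    def test_identical_individuals(self):
        m = np.array([[1, 0, 1]], dtype=np.int8)
        assert jaccard_distance(m, m.copy()) == 0.0

    def test_disjoint_band_sets(self):
        a = np.array([[1, 1, 0, 0]], dtype=np.int8)
        b = np.array([[0, 0, 1, 1]], dtype=np.int8)
        assert jaccard_distance(a, b) == 1.0

    def test_two_by_two_enumeration(self):
        a = np.array([[1, 1, 0], [1, 0, 0]], dtype=np.int8)
        b = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
        pairs = [(0, 0), (0, 1), (1, 0), (1, 1)]
        exp = np.mean([1 - (a[i] & b[j]).sum() / (a[i] | b[j]).sum()
                       for i, j in pairs])
        assert jaccard_distance(a, b) == pytest.approx(exp)

    @given(st.integers(0, 2**12 - 1), st.integers(1, 2**12 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounded_unit_interval(self, x, y):
        a = np.array([[int(b) for b in format(x, "012b")]], dtype=np.int8)
        b = np.array([[int(b) for b in format(y, "012b")]], dtype=np.int8)
        d = jaccard_distance(a, b)
        assert math.isnan(d) or 0.0 <= d <= 1.0


def _toy_dataset(rng, n_per_group=4, n_ind=4, n_aflp=12, n_loci=4):
    groups = tuple(f"loc{i}-{e}" for i in (1, 2) for e in ("crab", "wave"))
    sequences = {}
    for li in range(n_loci):
        by = {}
        for g in groups:
            aln = np.zeros((n_per_group, 40), dtype=np.int8)
            aln[rng.integers(0, n_per_group), rng.integers(0, 40)] = 1
            by[g] = aln
        sequences[f"locus{li}"] = by
    aflp = rng.integers(0, 2, size=(n_ind * 4, n_aflp)).astype(np.int8)
    labels = np.repeat(groups, n_ind)
    return MultiMarkerDataset(groups=groups, sequences=sequences, aflp=aflp,
                              aflp_groups=labels,
                              aflp_locus_names=tuple(f"l{i}" for i in range(n_aflp)))


class TestAssembleVector:
    def test_cardinalities(self, rng):
        ds = _toy_dataset(rng)
        assert len(assemble_vector(ds, "sequence")) == 56
        assert len(assemble_vector(ds, "aflp")) == 22
        assert len(assemble_vector(ds, "combined")) == 78

    def test_invariant_to_individual_order_within_groups(self, rng):
        ds = _toy_dataset(rng)
        v1 = assemble_vector(ds)
        # shuffle sequence rows and AFLP individuals within each group
        for locus in ds.sequences:
            for g in ds.groups:
                perm = rng.permutation(ds.sequences[locus][g].shape[0])
                ds.sequences[locus][g] = ds.sequences[locus][g][perm]
        for g in ds.groups:
            ix = np.where(ds.aflp_groups == g)[0]
            ds.aflp[ix] = ds.aflp[rng.permutation(ix)]
        v2 = assemble_vector(ds)
        assert np.allclose(v1.to_numpy(), v2.to_numpy(), equal_nan=True)

    def test_wrong_group_count_rejected(self, rng):
        ds = _toy_dataset(rng)
        bad = MultiMarkerDataset(groups=ds.groups[:3], sequences=ds.sequences,
                                 aflp=ds.aflp, aflp_groups=ds.aflp_groups)
        with pytest.raises(ValueError):
            assemble_vector(bad)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            assemble_vector(_toy_dataset(rng), "everything")
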