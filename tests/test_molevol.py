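import math
import warnings

import numpy as np
import pytest

from mitochar.molevol import (
    AlignedMatrix, DistanceMatrix, _pair_base_freqs, distance_matrix, f84,
    group_means, k2p, nei_gojobori, nucleotide_diversity, pair_diffs,
    saturation_profile, sliding_pi,
)
from mitochar.synthetic_data import simulate_codon_pair, simulate_nucleotide_pair


class TestPairDiffs:
    def test_identical(self):
        d = pair_diffs("AAAA", "AAAA")
        assert (d.sites, d.transitions, d.transversions) == (4, 0, 0)

    def test_single_transition(self):
        d = pair_diffs("AG", "GG")
        assert (d.transitions, d.transversions) == (1, 0)

    def test_single_transversion(self):
        d = pair_diffs("AG", "CG")
        assert (d.transitions, d.transversions) == (0, 1)

    def test_gaps_and_ambiguity_excluded_pairwise(self):
        d = pair_diffs("A-GN", "AAGA")
        assert d.sites == 2

    def test_zero_comparable_sites(self):
        with pytest.raises(ValueError, match="zero comparable"):
            pair_diffs("--", "AA")

    def test_exact_recovery_of_implanted_changes(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), size=1000))
        other = list(base)
        pos = rng.choice(1000, size=50, replace=False)
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        transversions = {"A": "C", "G": "T", "C": "A", "T": "G"}
        for p in pos[:30]:
            other[p] = transitions[other[p]]
        for p in pos[30:]:
            other[p] = transversions[other[p]]
        d = pair_diffs(base, "".join(other))
        assert (d.transitions, d.transversions) == (30, 20)


class TestK2P:
    def test_zero_divergence(self):
        assert k2p(pair_diffs("ACGT", "ACGT")) == 0

    def test_closed_form_value(self):
        # P = 0.1, Q = 0.05 over 20 sites; frozen independent evaluation of
        # -(1/2) ln((1-2P-Q) sqrt(1-2Q))
        rows = ["AAAAAAAAAAAAAAAAAAGC", "GGAAAAAAAAAAAAAAAATC"]
        d = pair_diffs(*rows)
        assert (d.P, d.Q) == (0.1, 0.05)
        assert k2p(d) == pytest.approx(0.1701811651403471, abs=1e-12)

    def test_matches_ape_on_simulated_pair(self):
        """Frozen oracle: dist.dna(model='K80'/'F84') on this exact pair."""
        s1, s2 = simulate_nucleotide_pair(2000, 0.15, 4.0, seed=7)
        d = pair_diffs(s1, s2)
        assert k2p(d) == pytest.approx(0.1591669, abs=5e-7)
        assert f84(d, _pair_base_freqs(s1, s2)) == pytest.approx(0.1591703, abs=5e-7)

    def test_correction_inflates_p_distance(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            s1, s2 = simulate_nucleotide_pair(1500, 0.05 * (seed + 1), 3.0,
                                              seed=100 + seed)
            d = pair_diffs(s1, s2)
            est = k2p(d)
            if est is not None and d.p_distance > 0:
                assert est > d.p_distance

    def test_saturation_returns_missing(self):
        d = pair_diffs("A" * 10, "G" * 10)  # P = 1
        assert k2p(d) is None

    def test_parameter_recovery_within_three_se(self):
        """Pairs simulated at true divergence 0.10 over 10 kb, 20
        replicates: mean K2P estimate within 3 SE of truth."""
        true_d = 0.10
        ests = []
        for rep in range(20):
            s1, s2 = simulate_nucleotide_pair(10_000, true_d, 4.0, seed=900 + rep)
            ests.append(k2p(pair_diffs(s1, s2)))
        mean, se = np.mean(ests), np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(mean - true_d) < 3 * se


class TestF84:
    def test_identical_sequences(self):
        d = pair_diffs("ACGTACGT", "ACGTACGT")
        assert f84(d, {"A": .25, "C": .25, "G": .25, "T": .25}) == 0

    def test_equal_frequencies_reduce_to_k2p(self):
        for seed in range(5):
            s1, s2 = simulate_nucleotide_pair(3000, 0.12, 5.0, seed=300 + seed)
            d = pair_diffs(s1, s2)
            eq = {"A": .25, "C": .25, "G": .25, "T": .25}
            assert f84(d, eq) == pytest.approx(k2p(d), abs=1e-9)

    def test_mean_divergence_monotone_in_time(self):
        means = []
        for scale in (0.02, 0.08, 0.2):
            vals = []
            for rep in range(5):
                s1, s2 = simulate_nucleotide_pair(3000, scale, 4.0,
                                                  seed=500 + rep)
                d = pair_diffs(s1, s2)
                vals.append(f84(d, _pair_base_freqs(s1, s2)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_bad_frequencies_rejected(self):
        d = pair_diffs("ACGT", "ACGT")
        with pytest.raises(ValueError, match="sum to 1"):
            f84(d, {"A": .5, "C": .5, "G": .5, "T": .5})


class TestSlidingPi:
    def test_identical_rows_zero_everywhere(self):
        m = AlignedMatrix(["a", "b", "c"], ["ACGT" * 100] * 3)
        prof = sliding_pi(m)
        assert all(v == 0 for v in prof.pi)

    def test_hand_counted_window(self):
        row1 = "A" * 200
        row2 = "C" * 10 + "A" * 190  # 10 differences in one 200-bp window
        prof = sliding_pi(AlignedMatrix(["a", "b"], [row1, row2]))
        assert prof.pi == [pytest.approx(0.05)]

    def test_window_partition_conserves_whole_alignment_pi(self):
        rng = np.random.default_rng(12)
        rows = ["".join(rng.choice(list("ACGT"), size=600)) for _ in range(4)]
        m = AlignedMatrix(list("abcd"), rows)
        prof = sliding_pi(m, window=50, step=50)  # exact partition, gap-free
        weights = [50] * len(prof.pi)
        combined = sum(w * p for w, p in zip(weights, prof.pi)) / sum(weights)
        assert combined == pytest.approx(nucleotide_diversity(m), abs=1e-12)

    def test_hypervariable_insert_is_argmax(self):
        rng = np.random.default_rng(31)
        cons = "".join(rng.choice(list("ACGT"), size=1000))
        rows = []
        for _ in range(4):
            arr = list(cons)
            for i in range(1000):
                rate = 0.30 if 400 <= i < 600 else 0.01
                if rng.random() < rate:
                    arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
            rows.append("".join(arr))
        prof = sliding_pi(AlignedMatrix(list("wxyz"), rows))
        best = prof.starts[int(np.argmax(prof.pi))]
        assert 300 < best < 600  # peak window overlaps the insert

    def test_short_alignment_single_truncated_window(self):
        m = AlignedMatrix(["a", "b"], ["ACGT" * 10, "ACGT" * 10])
        prof = sliding_pi(m, window=200, step=25)
        assert len(prof.pi) == 1 and prof.last_truncated

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            sliding_pi(AlignedMatrix(["a"], ["ACGT"]))


class TestNeiGojobori:
    def test_identical_genes(self):
        r = nei_gojobori("ATGAAACCC", "ATGAAACCC")
        assert r.ka == 0 and r.ks == 0 and r.ratio is None

    def test_single_synonymous_change(self):
        r = nei_gojobori("ATGGGACCC", "ATGGGGCCC")  # GGA -> GGG (both Gly)
        assert r.ka == 0
        assert r.ks > 0
        assert r.syn_diffs == pytest.approx(1.0)

    def test_single_nonsynonymous_change(self):
        r = nei_gojobori("ATGAAACCC", "ATGGAACCC")  # Lys -> Glu
        assert r.ks == 0 and r.ka > 0

    def test_symmetry(self):
        c1, c2, _ = simulate_codon_pair(200, 0.3, 4.0, 0.1, seed=42)
        r12, r21 = nei_gojobori(c1, c2), nei_gojobori(c2, c1)
        assert r12.ka == pytest.approx(r21.ka)
        assert r12.ks == pytest.approx(r21.ks)

    def test_site_counts_span_the_alignment(self):
        c1, c2, _ = simulate_codon_pair(150, 0.2, 2.0, 0.2, seed=5)
        r = nei_gojobori(c1, c2)
        assert r.syn_sites + r.nonsyn_sites == pytest.approx(3 * 150, abs=1e-9)

    def test_agrees_with_independent_ng86_implementation(self):
        """Cross-check against Bio.codonalign's NG86 under table 2."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from Bio.Data import CodonTable
        t2 = CodonTable.unambiguous_dna_by_id[2]
        for seed in (3, 19, 77):
            c1, c2, _ = simulate_codon_pair(300, 0.4, 4.0, 0.05, seed=seed)
            mine = nei_gojobori(c1, c2)
            dn, ds = cal_dn_ds(CodonSeq(c1), CodonSeq(c2), method="NG86",
                               codon_table=t2)
            assert mine.ka == pytest.approx(dn, abs=1e-9)
            assert mine.ks == pytest.approx(ds, abs=1e-9)

    def test_omega_recovery_under_purifying_selection(self):
        """Codon pairs simulated at ω = 0.05, κ = 4, 500 codons: the NG86
        ratio lands in the simulation-calibrated band [0.02, 0.12]."""
        ratios = []
        for rep in range(20):
            c1, c2, _ = simulate_codon_pair(500, 0.4, 4.0, 0.05, seed=7000 + rep)
            r = nei_gojobori(c1, c2)
            assert r.ratio is not None
            ratios.append(r.ratio)
        assert 0.02 <= np.mean(ratios) <= 0.12
        assert all(r < 1 for r in ratios)  # purifying selection throughout


class TestDistanceMatrix:
    def test_identical_rows(self):
        m = AlignedMatrix(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        D = distance_matrix(m)
        assert np.allclose(D.values, 0)

    def test_group_means_match_brute_force(self):
        rng = np.random.default_rng(6)
        anc = rng.choice(list("ACGT"), size=400)
        rows = []
        for _ in range(6):  # congeneric-scale divergence from one ancestor
            arr = anc.copy()
            idx = rng.choice(400, size=30, replace=False)
            arr[idx] = [rng.choice([b for b in "ACGT" if b != arr[i]])
                        for i in idx]
            rows.append("".join(arr))
        labels = [f"t{i}" for i in range(6)]
        groups = {"t0": "X", "t1": "X", "t2": "X", "t3": "Y", "t4": "Y", "t5": "Z"}
        D = distance_matrix(AlignedMatrix(labels, rows), "K2P")
        table = group_means(D, groups)
        import itertools
        for _, row in table.iterrows():
            expected = [
                D.values[i, j]
                for i, j in itertools.combinations(range(6), 2)
                if {groups[labels[i]], groups[labels[j]]} ==
                ({row.group_a} if row.group_a == row.group_b
                 else {row.group_a, row.group_b})
            ]
            if expected:
                assert row["mean"] == pytest.approx(np.mean(expected))

    def test_unassigned_label_is_an_error(self):
        m = AlignedMatrix(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ValueError, match="without group"):
            group_means(distance_matrix(m), {"a": "X"})

    def test_saturated_entry_is_nan_and_excluded_from_mean(self):
        m = AlignedMatrix(["a", "b", "c"],
                          ["A" * 40, "G" * 40, "A" * 40])
        D = distance_matrix(m, "K2P")
        assert math.isnan(D.get("a", "b"))
        assert D.overall_mean == pytest.approx(0.0)  # only the defined pair

    def test_saturation_profile_columns(self):
        m = AlignedMatrix(["a", "b", "c"], ["ACGTACGT", "ACGAACGT", "ACGTACTT"])
        prof = saturation_profile(m)
        assert len(prof) == 3
        assert {"s", "v", "f84"} <= set(prof.columns)
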