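"""Degeneracy classification, substitution counting, K2P and Ka/Ks estimation."""

import math

import numpy as np
import pytest

from dendrodiv import molevol as me
from dendrodiv import synthetic_data as sd


class TestDegeneracy:
    @pytest.mark.parametrize(
        "codon,pos,expected",
        [
            ("GGG", 3, me.FOURFOLD),      # glycine: any third base
            ("ATG", 1, me.NONDEGENERATE),  # Met has no first-position synonym
            ("AAA", 3, me.TWOFOLD),        # AAA/AAG both Lys
            ("ATC", 3, me.TWOFOLD),        # three-fold Ile folds into two-fold
            ("CGA", 1, me.TWOFOLD),        # CGA/AGA both Arg
        ],
    )
    def test_known_classes(self, codon, pos, expected):
        assert me.classify_codon_degeneracy(codon, pos) == expected

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            me.classify_codon_degeneracy("TAA", 3)

    def test_class_matches_direct_enumeration(self):
        # recount synonymous alternatives straight from the genetic code
        import itertools

        for codon in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
            aa = me.translate_codon(codon)
            if aa is None:
                continue
            for pos in (1, 2, 3):
                n_syn = sum(
                    me.translate_codon(codon[: pos - 1] + alt + codon[pos:]) == aa
                    for alt in "ACGT"
                    if alt != codon[pos - 1]
                )
                want = {0: me.NONDEGENERATE, 3: me.FOURFOLD}.get(n_syn, me.TWOFOLD)
                assert me.classify_codon_degeneracy(codon, pos) == want


class TestSubstitutionCounting:
    def test_identical_sequences_have_no_differences(self):
        aln = me.CodonAlignment("g", "ATGGCTAAA", "ATGGCTAAA")
        c = me.count_pairwise_substitutions(aln)
        assert all(v == 0 for v in c.P.values()) and all(v == 0 for v in c.Q.values())
        assert c.n_codons_compared == 3

    def test_six_codon_toy_fourfold_transition(self):
        # one A<->G change at GGA's four-fold third position
        seq_a = "GGA" + "ATG" + "TGG" + "AAA" + "CCT" + "TTC"
        seq_b = "GGG" + "ATG" + "TGG" + "AAA" + "CCT" + "TTC"
        c = me.count_pairwise_substitutions(me.CodonAlignment("g", seq_a, seq_b))
        # independent L4 tally over the six codons' positions
        l4 = 0.0
        for codon in (seq_a[i : i + 3] for i in range(0, 18, 3)):
            for pos in (1, 2, 3):
                if me.classify_codon_degeneracy(codon, pos) == me.FOURFOLD:
                    l4 += 1.0
        assert c.L[me.FOURFOLD] == pytest.approx(l4)
        assert c.P[me.FOURFOLD] == pytest.approx(1.0 / l4)
        assert c.Q[me.FOURFOLD] == 0.0
        assert c.P[me.NONDEGENERATE] == 0.0 and c.P[me.TWOFOLD] == 0.0

    def test_gap_and_stop_columns_skipped(self):
        aln = me.CodonAlignment("g", "ATG---TAAGCT", "ATGGCTTAAGCT")
        c = me.count_pairwise_substitutions(aln)
        assert c.n_codons_compared == 2 and c.n_codons_skipped == 2

    def test_site_count_conservation(self, rng):
        aln, _ = sd.simulate_codon_pair(sd.CodonSimSpec(n_codons=400, seed=9))
        c = me.count_pairwise_substitutions(aln)
        assert sum(c.L.values()) == pytest.approx(3 * c.n_codons_compared)

    def test_counts_match_simulator_event_log_at_low_divergence(self):
        # at low branch length no site is hit twice, so raw difference
        # counts equal the event-log tallies (no multiple-hit masking)
        spec = sd.CodonSimSpec(n_codons=300, branch_length=0.02, seed=4)
        aln, events = sd.simulate_codon_pair(spec)
        sites = [(e.codon_index, e.position) for e in events]
        assert len(sites) == len(set(sites))  # instance without repeat hits
        c = me.count_pairwise_substitutions(aln)
        n_ts = sum(c.P[cls] * c.L[cls] for cls in c.P)
        n_tv = sum(c.Q[cls] * c.L[cls] for cls in c.Q)
        assert n_ts == pytest.approx(sum(e.transition for e in events))
        assert n_tv == pytest.approx(sum(not e.transition for e in events))


class TestK2P:
    def test_zero_divergence(self):
        assert me.k2p_components(0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_closed_form_value(self):
        A, B, K = me.k2p_components(0.1, 0.05)
        want_K = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert K == pytest.approx(want_K)
        assert K == pytest.approx(0.1702, abs=5e-5)
        assert A + B == pytest.approx(K)

    def test_saturation_flagged(self):
        with pytest.raises(me.SaturatedDistanceError):
            me.k2p_components(0.5, 0.0)
        with pytest.raises(me.SaturatedDistanceError):
            me.k2p_components(0.0, 0.5)

    def test_monotone_in_p_and_q(self):
        ps = np.linspace(0.0, 0.3, 10)
        ks = [me.k2p_components(p, 0.05)[2] for p in ps]
        assert np.all(np.diff(ks) > 0)
        qs = np.linspace(0.0, 0.3, 10)
        ks = [me.k2p_components(0.05, q)[2] for q in qs]
        assert np.all(np.diff(ks) > 0)

    @pytest.mark.parametrize("p,q", [(0.005, 0.004), (0.008, 0.001), (0.002, 0.002)])
    def test_small_distance_limit_k_approx_p_plus_q(self, p, q):
        _, _, K = me.k2p_components(p, q)
        assert abs(K - (p + q)) / (p + q) < 0.05


class TestLiKaKs:
    def make_counts(self, L, P=None, Q=None):
        zero = {me.NONDEGENERATE: 0.0, me.TWOFOLD: 0.0, me.FOURFOLD: 0.0}
        return me.SubstitutionCounts(
            L=dict(zip((me.NONDEGENERATE, me.TWOFOLD, me.FOURFOLD), L)),
            P=P or dict(zero),
            Q=Q or dict(zero),
            n_codons_compared=int(sum(L) // 3),
            n_codons_skipped=0,
        )

    def test_no_differences_gives_zero_rates(self):
        ka, ks, ratio = me.li_ka_ks(self.make_counts((100.0, 60.0, 40.0)))
        assert ka == 0.0 and ks == 0.0 and ratio == 0.0

    def test_hand_evaluated_fourfold_only(self):
        # choose P4 so the K2P transition component A4 is exactly 0.05
        p4 = (1 - math.exp(-0.1)) / 2
        counts = self.make_counts(
            (100.0, 60.0, 40.0),
            P={me.NONDEGENERATE: 0.0, me.TWOFOLD: 0.0, me.FOURFOLD: p4},
        )
        ka, ks, _ = me.li_ka_ks(counts)
        assert ks == pytest.approx((40.0 * 0.05) / 100.0)
        assert ka == 0.0

    def test_neutral_simulation_ratio_near_one(self):
        vals = []
        for i in range(10):
            aln, _ = sd.simulate_codon_pair(
                sd.CodonSimSpec(n_codons=1000, branch_length=0.2, omega=1.0, seed=50 + i)
            )
            vals.append(me.li_ka_ks(me.count_pairwise_substitutions(aln))[2])
        assert 0.85 <= np.mean(vals) <= 1.15


class TestRateTable:
    def test_short_gene_excluded(self):
        short, _ = sd.simulate_codon_pair(sd.CodonSimSpec(n_codons=90, seed=1), "short")
        long_, _ = sd.simulate_codon_pair(sd.CodonSimSpec(n_codons=300, seed=2), "long")
        table, _ = me.compute_rate_table([short, long_], min_aa=100)
        assert list(table.index) == ["long"]

    def test_identical_pairs_summarize_to_zero(self):
        alns = [
            me.CodonAlignment(f"g{i}", "ATGGCTGGG" * 60, "ATGGCTGGG" * 60)
            for i in range(3)
        ]
        table, summary = me.compute_rate_table(alns, min_aa=100)
        assert summary.loc["Ks", "mean"] == 0.0
        assert summary.loc["Ka", "mean"] == 0.0

    def test_parameter_recovery_on_simulated_genes(self):
        # planted neutral divergence: Ks and Ka recovered within 2 stderr
        alns = []
        for i in range(20):
            aln, _ = sd.simulate_codon_pair(
                sd.CodonSimSpec(n_codons=800, branch_length=0.15, omega=0.3, seed=700 + i),
                f"g{i}",
            )
            alns.append(aln)
        table, summary = me.compute_rate_table(alns, min_aa=100)
        assert len(table) == 20
        assert 0.2 <= summary.loc["KaKs", "mean"] <= 0.4
        assert summary.loc["Ks", "mean"] > summary.loc["Ka", "mean"]

    def test_utr_distance_computed_when_present(self):
        aln, _ = sd.simulate_codon_pair(
            sd.CodonSimSpec(n_codons=200, branch_length=0.2, utr_length=300, seed=8)
        )
        table, _ = me.compute_rate_table([aln], min_aa=100)
        assert np.isfinite(table["K_utr5"].iloc[0])
        assert np.isfinite(table["K_utr3"].iloc[0])


class TestKruskalWallis:
    def test_identical_groups_p_one(self):
        h, p = me.kruskal_wallis_rates([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50) + 2 * (np.percentile(a, 75) - np.percentile(a, 25))
        _, p = me.kruskal_wallis_rates([a, b])
        assert p < 0.001

    def test_three_group_toy_matches_hand_formula(self):
        groups = [[1.0, 4.0, 7.0, 10.0, 13.0], [2.0, 5.0, 8.0, 11.0, 14.0], [3.0, 6.0, 9.0, 12.0, 15.0]]
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        from scipy.stats import rankdata

        pooled = np.concatenate(groups)
        ranks = rankdata(pooled)
        n = len(pooled)
        h_hand = 0.0
        start = 0
        for g in groups:
            r = ranks[start : start + len(g)]
            h_hand += len(g) * (r.mean() - (n + 1) / 2) ** 2
            start += len(g)
        h_hand *= 12 / (n * (n + 1))
        h, _ = me.kruskal_wallis_rates(groups)
        assert h == pytest.approx(h_hand)

    def test_small_group_is_error(self):
        with pytest.raises(ValueError):
            me.kruskal_wallis_rates([[1.0], [2.0, 3.0]])
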