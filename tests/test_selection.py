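"""NG86 counting, GY94 likelihoods, site-model fits, LRT, NEB and FEL."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from mhchap import selection as sel
from mhchap.selection import (
    CODON_INDEX,
    CODONS,
    CodonAlignment,
    balanced_tree,
    beta_categories,
    bonferroni,
    codon_loglik,
    f3x4_frequencies,
    fel_scan,
    fit_model_pair,
    fit_site_model,
    lrt,
    neb_sites,
    ng86_dnds,
    simulate_alignment,
)

UNIFORM_PI = np.ones(61) / 61


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _ng86_oracle(seq1, seq2):
    """Independent NG86 computation by direct enumeration (site fractions
    per codon, path averaging with stop exclusion, Jukes-Cantor)."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    table = unambiguous_dna_by_id[1]
    stops = set(table.stop_codons)

    def aa(c):
        return table.forward_table[c]

    S = N = Sd = Nd = 0.0
    for k in range(len(seq1) // 3):
        c1, c2 = seq1[3 * k:3 * k + 3], seq2[3 * k:3 * k + 3]
        for c in (c1, c2):
            syn = sum(
                1
                for pos in range(3)
                for b in "ACGT"
                if b != c[pos]
                and (alt := c[:pos] + b + c[pos + 1:]) not in stops
                and aa(alt) == aa(c)
            )
            S += syn / 3.0 / 2.0
            N += (3.0 - syn / 3.0) / 2.0
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        paths = []
        for order in itertools.permutations(diffs):
            cur, s, n, ok = c1, 0, 0, True
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                if nxt in stops:
                    ok = False
                    break
                s, n = s + (aa(cur) == aa(nxt)), n + (aa(cur) != aa(nxt))
                cur = nxt
            if ok:
                paths.append((s, n))
        if paths:
            Sd += sum(p[0] for p in paths) / len(paths)
            Nd += sum(p[1] for p in paths) / len(paths)
    dS = -0.75 * math.log(1 - 4 * (Sd / S) / 3)
    dN = -0.75 * math.log(1 - 4 * (Nd / N) / 3)
    return dN, dS


class TestNg86:
    def test_identical_sequences(self):
        r = ng86_dnds("ATGAAA", "ATGAAA")
        assert (r.dN, r.dS, r.ratio) == (0.0, 0.0, None)

    def test_hand_worked_toy_pair(self):
        # one synonymous third-position change (ACT->ACA) and one
        # nonsynonymous first-position change (GAT->CAT) over 6 codons;
        # hand count: S = 4, N = 14, Sd = 1, Nd = 1
        s1 = "TTTAAAGGGCCCACTGAT"
        s2 = "TTTAAAGGGCCCACACAT"
        r = ng86_dnds(s1, s2)
        assert r.dS == pytest.approx(-0.75 * math.log(1 - (4 / 3) * 0.25))
        assert r.dN == pytest.approx(-0.75 * math.log(1 - (4 / 3) / 14))
        assert r.ratio == pytest.approx(0.2468361803656942)
        oN, oS = _ng86_oracle(s1, s2)
        assert r.dN == pytest.approx(oN)
        assert r.dS == pytest.approx(oS)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetry_and_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        s1 = "".join(rng.choice(CODONS, 12))
        # a handful of stop-safe substitutions keeps the pair unsaturated
        s2 = list(s1)
        changed = 0
        while changed < 5:
            pos = int(rng.integers(len(s2)))
            base = str(rng.choice(list("ACGT")))
            old = s2[pos]
            if base == old:
                continue
            s2[pos] = base
            start = (pos // 3) * 3
            if "".join(s2[start:start + 3]) in sel.STOP_CODONS:
                s2[pos] = old
                continue
            changed += 1
        s2 = "".join(s2)
        r12, r21 = ng86_dnds(s1, s2), ng86_dnds(s2, s1)
        assert (r12.dN, r12.dS) == (r21.dN, r21.dS)
        oN, oS = _ng86_oracle(s1, s2)
        assert r12.dN == pytest.approx(oN)
        assert r12.dS == pytest.approx(oS)

    def test_gap_codons_excluded_pairwise(self):
        r = ng86_dnds("ATG---AAA", "ATGCCTAAA")
        assert r.n_codons_used == 2


class TestF3x4:
    def test_uniform_composition_gives_uniform_pi(self):
        aln = CodonAlignment.from_sequences(
            {"a": "AAA", "b": "CCC", "c": "GGG", "d": "TTT"}
        )
        pi = f3x4_frequencies(aln)
        assert np.allclose(pi, 1 / 61)

    def test_single_sequence_forced_case(self):
        aln = CodonAlignment.from_sequences({"a": "ATGATG"})
        pi = f3x4_frequencies(aln)
        assert pi[CODON_INDEX["ATG"]] == pytest.approx(1.0)

    def test_normalisation(self):
        rng = np.random.default_rng(3)
        aln = CodonAlignment.from_sequences(
            {f"s{i}": "".join(rng.choice(CODONS, 20)) for i in range(5)}
        )
        assert f3x4_frequencies(aln).sum() == pytest.approx(1.0, abs=1e-12)


class TestCodonLoglik:
    def test_single_sequence_closed_form(self):
        aln = CodonAlignment.from_sequences({"a": "ATGAAAGGG"})
        pi = np.full(61, 1 / 61)
        ll = codon_loglik(aln, "a;", 2.0, [(1.0, 0.5)], pi)
        assert ll == pytest.approx(3 * math.log(1 / 61))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_three_taxon_brute_force_marginalisation(self, seed):
        rng = np.random.default_rng(seed)
        seqs = {n: "".join(rng.choice(CODONS, 3)) for n in "ABC"}
        aln = CodonAlignment.from_sequences(seqs)
        kappa, omega = 2.5, 0.4
        ll = codon_loglik(aln, "(A:0.1,B:0.2,C:0.15);", kappa,
                          [(1.0, omega)], UNIFORM_PI)
        # independent route: matrix exponential + explicit state sum
        Q = sel._unscaled_rate_matrix(kappa, omega, UNIFORM_PI)
        Q /= -(UNIFORM_PI * np.diag(Q)).sum()
        P = {t: expm(Q * t) for t in (0.1, 0.2, 0.15)}
        expected = 0.0
        for s in range(3):
            o = {n: CODON_INDEX[seqs[n][3 * s:3 * s + 3]] for n in "ABC"}
            site = sum(
                UNIFORM_PI[y] * P[0.1][y, o["A"]] * P[0.2][y, o["B"]]
                * P[0.15][y, o["C"]]
                for y in range(61)
            )
            expected += math.log(site)
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_four_taxon_two_internal_nodes_brute_force(self):
        rng = np.random.default_rng(5)
        seqs = {n: "".join(rng.choice(CODONS, 2)) for n in "ABCD"}
        aln = CodonAlignment.from_sequences(seqs)
        newick = "((A:0.1,B:0.2):0.05,C:0.15,D:0.12);"
        kappa, omega = 1.5, 1.2
        ll = codon_loglik(aln, newick, kappa, [(1.0, omega)], UNIFORM_PI)
        Q = sel._unscaled_rate_matrix(kappa, omega, UNIFORM_PI)
        Q /= -(UNIFORM_PI * np.diag(Q)).sum()
        P = {t: expm(Q * t) for t in (0.1, 0.2, 0.05, 0.15, 0.12)}
        expected = 0.0
        for s in range(2):
            o = {n: CODON_INDEX[seqs[n][3 * s:3 * s + 3]] for n in "ABCD"}
            site = 0.0
            for root in range(61):       # root = the trifurcating node
                for inner in range(61):  # ancestor of A and B
                    site += (
                        UNIFORM_PI[root]
                        * P[0.05][root, inner]
                        * P[0.1][inner, o["A"]] * P[0.2][inner, o["B"]]
                        * P[0.15][root, o["C"]] * P[0.12][root, o["D"]]
                    )
            expected += math.log(site)
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_zero_branch_limit_on_identical_sequences(self):
        seq = "ATGAAAGGGTGC"
        aln = CodonAlignment.from_sequences({"a": seq, "b": seq})
        pi = f3x4_frequencies(aln)
        ll = codon_loglik(aln, "(a:1e-9,b:1e-9);", 2.0, [(1.0, 0.5)], pi)
        expected = sum(
            math.log(pi[CODON_INDEX[seq[3 * i:3 * i + 3]]]) for i in range(4)
        )
        assert ll == pytest.approx(expected, abs=1e-5)

    def test_mixture_weights_validated(self):
        aln = CodonAlignment.from_sequences({"a": "ATG"})
        with pytest.raises(ValueError, match="weights"):
            codon_loglik(aln, "a;", 2.0, [(0.5, 0.2), (0.4, 1.0)], UNIFORM_PI)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment.from_sequences({"a": "ATGTAAGGG"})


class TestBetaDiscretisation:
    def test_category_weights_and_mean(self):
        cats = beta_categories(2.0, 3.0)
        assert len(cats) == 10
        assert sum(w for w, _ in cats) == pytest.approx(1.0)
        mean = sum(w * m for w, m in cats)
        assert mean == pytest.approx(2.0 / 5.0, abs=1e-3)
        assert all(0 < m < 1 for _, m in cats)


class TestFits:
    def test_m1a_parameter_recovery(self):
        tree = balanced_tree(12, 0.25)
        for seed in (1, 2, 3):
            aln, _ = simulate_alignment(
                tree, 2.0, [(0.7, 0.2), (0.3, 1.0)], UNIFORM_PI, 90, seed=seed
            )
            fit = fit_site_model(aln, tree, "M1a", n_starts=2)
            assert abs(fit.params["p0"] - 0.7) <= 0.15
            assert abs(fit.params["omega0"] - 0.2) <= 0.15

    def test_nesting_m2a_dominates_m1a(self):
        tree = balanced_tree(8, 0.3)
        aln, _ = simulate_alignment(
            tree, 2.0, [(0.6, 0.3), (0.4, 1.0)], UNIFORM_PI, 40, seed=9
        )
        null, alt = fit_model_pair(aln, tree, ("M1a", "M2a"), n_starts=1)
        assert alt.log_likelihood >= null.log_likelihood - 1e-6

    def test_nesting_m8_dominates_m7(self):
        tree = balanced_tree(8, 0.3)
        aln, _ = simulate_alignment(
            tree, 2.0, [(0.6, 0.3), (0.4, 1.0)], UNIFORM_PI, 30, seed=10
        )
        null, alt = fit_model_pair(aln, tree, ("M7", "M8"), n_starts=1)
        assert alt.log_likelihood >= null.log_likelihood - 1e-6

    def test_unknown_model_rejected(self):
        aln = CodonAlignment.from_sequences({"a": "ATG"})
        with pytest.raises(ValueError, match="unknown model"):
            fit_site_model(aln, "a;", "M99")


class TestLrt:
    @staticmethod
    def _fit(model, ll):
        return sel.SiteModelFit(model=model, params={}, kappa=2.0, scale=1.0,
                                log_likelihood=ll)

    def test_equal_likelihoods(self):
        r = lrt(self._fit("M1a", -100.0), self._fit("M2a", -100.0))
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_chi_squared_df2_closed_form(self):
        # upper tail of chi-squared(2) is exp(-x/2): independent oracle
        r = lrt(self._fit("M1a", -100.0), self._fit("M2a", -100.0 + 5.99 / 2))
        assert r.statistic == pytest.approx(5.99)
        assert r.p_value == pytest.approx(math.exp(-5.99 / 2))
        assert r.p_value == pytest.approx(0.050, abs=5e-4)

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError, match="not nested"):
            lrt(self._fit("M7", -10.0), self._fit("M2a", -9.0))

    def test_negative_difference_clamped(self):
        r = lrt(self._fit("M1a", -99.9), self._fit("M2a", -100.0))
        assert r.statistic == 0.0


class TestBonferroni:
    def test_three_tests_matches_reported_threshold(self):
        assert round(bonferroni(0.05, 3), 3) == 0.017

    def test_single_test_unchanged(self):
        assert bonferroni(0.05, 1) == 0.05

    def test_two_tests(self):
        assert bonferroni(0.05, 2) == 0.025

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)


@pytest.fixture(scope="module")
def strong_selection_run():
    tree = balanced_tree(16, 0.25)
    aln, classes = simulate_alignment(
        tree, 2.0, [(0.6, 0.2), (0.3, 1.0), (0.1, 5.0)], UNIFORM_PI,
        100, seed=7,
    )
    null, alt = fit_model_pair(aln, tree, ("M1a", "M2a"), n_starts=2)
    return tree, aln, classes, alt


class TestSiteScans:

    def test_neb_posteriors_normalised(self, strong_selection_run):
        tree, aln, _, fit = strong_selection_run
        scan = neb_sites(fit, aln, tree)
        assert np.allclose(scan.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert ((scan.positive_posterior >= 0) &
                (scan.positive_posterior <= 1)).all()

    def test_neb_invariant_sites_never_flagged(self, strong_selection_run):
        tree, aln, _, fit = strong_selection_run
        scan = neb_sites(fit, aln, tree)
        invariant = [
            s for s in range(aln.n_codons)
            if len({aln.sequences[n][3 * s:3 * s + 3] for n in aln.names}) == 1
        ]
        assert invariant  # the simulation produces some
        for s in invariant:
            assert not scan.flags[s]
            # posterior mass concentrates off the positive class
            assert scan.positive_posterior[s] < 0.5

    def test_neb_detects_strongly_selected_sites(self, strong_selection_run):
        tree, aln, classes, fit = strong_selection_run
        scan = neb_sites(fit, aln, tree)
        selected = classes == 2
        assert scan.flags[selected].mean() >= 0.5
        assert scan.flags[~selected].mean() <= 0.05

    def test_fel_invariant_site_p_one(self):
        tree = balanced_tree(8, 0.4)
        seq = "ATGAAAGGG"
        aln = CodonAlignment.from_sequences(
            {f"t{i + 1}": seq for i in range(8)}
        )
        scan = fel_scan(aln, tree)
        assert np.allclose(scan.p_values, 1.0)

    def test_fel_flags_strong_selection_one_sided(self):
        tree = balanced_tree(8, 0.4)
        aln, classes = simulate_alignment(
            tree, 2.0, [(0.8, 0.1), (0.2, 8.0)], UNIFORM_PI, 20, seed=3
        )
        scan = fel_scan(aln, tree)
        # flags are one-sided by construction
        assert not (scan.flags & (scan.beta <= scan.alpha)).any()
        selected = classes == 1
        assert scan.flags[selected].any()
        assert scan.flags[~selected].mean() <= 0.1
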