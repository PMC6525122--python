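"""IUPAC superposition and minimal-subset genotype calling."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhchap import deconvolve, synth
from mhchap.deconvolve import (
    CODE_TO_BASES,
    NO_PRODUCT,
    GenotypeCall,
    LengthConflictError,
    MixedSequence,
    call_genotype,
    explain_mixture,
    is_compatible,
    iupac_union,
)

SEQ12 = st.text(alphabet="ACGT", min_size=12, max_size=12)


class TestIupacUnion:
    def test_single_sequence_unchanged(self):
        assert iupac_union(["ACGT"]).codes == "ACGT"

    def test_code_table_forced_cases(self):
        assert iupac_union(["AAGA", "GCGT"]).codes == "RMGW"
        assert iupac_union(["A", "C", "G", "T"]).codes == "N"
        assert iupac_union(["AA", "GA"]).codes == "RA"

    def test_unequal_lengths_signal_conflict(self):
        with pytest.raises(LengthConflictError):
            iupac_union(["ACGT", "ACG"])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(SEQ12, min_size=1, max_size=4))
    def test_matches_brute_force_per_position_sets(self, seqs):
        observed = iupac_union(seqs).codes
        for i, code in enumerate(observed):
            expected = frozenset(s[i] for s in seqs)
            assert CODE_TO_BASES[code] == expected

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(SEQ12, min_size=1, max_size=4))
    def test_commutative_and_idempotent(self, seqs):
        forward = iupac_union(seqs).codes
        assert iupac_union(list(reversed(seqs))).codes == forward
        assert iupac_union(seqs + seqs).codes == forward


class TestIsCompatible:
    def test_member_of_union_is_compatible(self):
        seqs = ["ACGTACGTACGT", "ACGAACGTACCT", "TCGTACGTACGA"]
        observed = iupac_union(seqs)
        for s in seqs:
            assert is_compatible(s, observed)

    def test_base_outside_code_set(self):
        observed = MixedSequence("R")  # {A, G}
        assert not is_compatible("C", observed)
        assert is_compatible("A", observed)

    def test_genuine_n_requires_all_four_bases_by_default(self):
        # any base is *compatible* with an observed N (it is one of the four
        # peaks), but by default an N must be *produced* by all four bases;
        # the no-call dialect instead drops the position from the equality
        assert is_compatible("C", MixedSequence("N"))
        obs = iupac_union(["A", "C", "G", "T"])
        assert explain_mixture(obs, {"a": "A", "c": "C"}) == []
        # with the position dropped, every singleton candidate "explains"
        assert explain_mixture(obs, {"a": "A", "c": "C"},
                               treat_n_as_missing=True) == \
            [frozenset({"a"}), frozenset({"c"})]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            is_compatible("AC", MixedSequence("A"))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(SEQ12, min_size=1, max_size=4))
    def test_union_members_always_compatible(self, seqs):
        observed = iupac_union(seqs)
        assert all(is_compatible(s, observed) for s in seqs)


def brute_force_explanations(observed, candidates, kmax):
    """Independent oracle: enumerate every subset, keep minimal exact unions."""
    found = {}
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(sorted(candidates), size):
            ok = all(
                frozenset(candidates[k][i] for k in combo)
                == CODE_TO_BASES[observed.codes[i]]
                for i in range(len(observed.codes))
            )
            if ok:
                found.setdefault(size, []).append(frozenset(combo))
        if size in found or size >= kmax:
            break
    sizes = [s for s in found if s <= kmax]
    return sorted(found[min(sizes)]) if sizes else []


class TestExplainMixture:
    def test_identity_single_explanation(self):
        cands = {"a": "ACGTACGTACGT", "b": "ACGAACGTACCT"}
        obs = MixedSequence(cands["a"])
        assert explain_mixture(obs, cands) == [frozenset({"a"})]

    def test_toy_five_allele_case_matches_brute_force(self):
        rng_seqs = {
            "a1": "ACGTACGTACGT",
            "a2": "ACGTACGTACGA",
            "a3": "TCGTACCTACGT",
            "a4": "ACGTACGTTCGT",
            "a5": "AGGTACGTACGT",
        }
        obs = iupac_union([rng_seqs["a1"], rng_seqs["a3"]])
        got = explain_mixture(obs, rng_seqs)
        assert got == [frozenset({"a1", "a3"})]
        assert got == brute_force_explanations(obs, rng_seqs, 4)

    def test_unexplainable_base_gives_empty_result(self):
        cands = {"a": "AAAA", "b": "AACA"}
        obs = MixedSequence("AAAW")  # W = {A, T}; no candidate has T there
        assert explain_mixture(obs, cands) == []

    def test_kmax_must_be_positive(self):
        with pytest.raises(ValueError, match="kmax"):
            explain_mixture(MixedSequence("A"), {"a": "A"}, kmax=0)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=1),
            st.text(alphabet="ACG", min_size=6, max_size=6),
            min_size=1, max_size=8,
        ),
        st.data(),
    )
    def test_equals_brute_force_on_random_instances(self, cands, data):
        subset = data.draw(
            st.lists(st.sampled_from(sorted(cands)), min_size=1, max_size=4,
                     unique=True)
        )
        obs = iupac_union([cands[k] for k in subset])
        assert sorted(explain_mixture(obs, cands, kmax=4)) == \
            brute_force_explanations(obs, cands, 4)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=1),
            st.text(alphabet="ACGT", min_size=6, max_size=6),
            min_size=1, max_size=8,
        ),
        st.data(),
    )
    def test_generation_explanation_round_trip_soundness(self, cands, data):
        """Any generating subset appears among the explanations of its union,
        and is the unique minimal one when no smaller subset shares the union."""
        subset = data.draw(
            st.lists(st.sampled_from(sorted(cands)), min_size=1, max_size=4,
                     unique=True)
        )
        obs = iupac_union([cands[k] for k in subset])
        target = frozenset(
            k for k in cands
            if any(cands[k] == cands[s] for s in subset)
        )
        explanations = explain_mixture(obs, cands, kmax=4)
        union_of = lambda combo: iupac_union([cands[k] for k in combo]).codes
        smaller_exists = any(
            union_of(c) == obs.codes
            for size in range(1, len(subset))
            for c in itertools.combinations(sorted(cands), size)
        )
        if not smaller_exists:
            assert any(exp <= target and union_of(exp) == obs.codes
                       for exp in explanations)


class TestCallGenotype:
    def test_no_product_status(self, db, assay_map):
        call = call_genotype(NO_PRODUCT, db, assay_map["DQA1"])
        assert call.status == "no_product"
        assert call.explanations == ()

    def test_exon2_identical_pair_called_as_group(self, db, panel, assay_map):
        ind = synth.Individual("x", ("D", "D"))
        obs = synth.simulate_assay(ind, assay_map["DQB1"], panel, db)
        call = call_genotype(obs, db, assay_map["DQB1"])
        assert call.status == "called"
        assert ("DQB1*07:01:01", "DQB1*07:02:01") in call.entry_set

    def test_four_allele_coamplification_called(self, db, panel, assay_map):
        ind = synth.Individual("x", ("A", "E"))
        obs = synth.simulate_assay(ind, assay_map["DQA2"], panel, db)
        call = call_genotype(obs, db, assay_map["DQA2"])
        assert call.status == "called"
        assert len(call.entry_set) == 4

    def test_length_conflict_is_uncallable_frameshift(self, db, panel, assay_map):
        ind = synth.Individual("x", ("B", "E"))  # E carries the 1-bp deletion
        obs = synth.simulate_assay(ind, assay_map["DRB1_full"], panel, db)
        assert obs.length_conflict
        call = call_genotype(obs, db, assay_map["DRB1_full"])
        assert call.status == "uncallable_frameshift"

    def test_injected_novel_allele_suspected(self, db, panel, assay_map):
        parent = db["DQA2*07:01:01"]
        novel = synth.mutate_allele(parent, n_subs=3, seed=42)
        ind = synth.Individual("x", ("C", "C"))
        obs = synth.simulate_assay(
            ind, assay_map["DQA2"], panel, db,
            overrides={(0, parent.name): novel},
        )
        call = call_genotype(obs, db, assay_map["DQA2"])
        assert call.status == "novel_suspected"

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_noise_free_simulation_never_novel(self, db, panel, assays,
                                               assay_map, seed):
        cfg = synth.SimConfig(frequencies=[1 / 8] * 8, n=40, seed=seed)
        cohort = synth.simulate_cohort(panel, db, assays, cfg)
        for od in cohort.observations.values():
            for name, obs in od.items():
                call = call_genotype(obs, db, assay_map[name])
                assert call.status != "novel_suspected"

    def test_group_collapse_preserves_explanation_count(self, db, assay_map):
        """Expanding an ambiguity group into its members yields the same
        explanations up to substituting group members."""
        assay = assay_map["DQB1"]
        ind = synth.Individual("x", ("D", "D"))
        panel = __import__("mhchap.fixture", fromlist=["f"]).fixture_panel(db)
        obs = synth.simulate_assay(ind, assay, panel, db)
        grouped = call_genotype(obs, db, assay)
        # ungrouped search over raw candidate sequences
        cands = {a.name: assay.region_sequence(a.sequence)
                 for a in db.by_locus("DQB1")}
        raw = explain_mixture(obs, {k: v for k, v in cands.items()
                                    if len(v) == len(obs)})
        collapse = {
            name: next(
                entry for exp in grouped.explanations for entry in exp
                if name in entry
            )
            for exp in raw for name in exp
        }
        mapped = {frozenset(collapse[n] for n in exp) for exp in raw}
        assert mapped == set(grouped.explanations)

    def test_call_invariants(self):
        with pytest.raises(ValueError, match="exactly one"):
            GenotypeCall(status="called", explanations=())
        with pytest.raises(ValueError, match=">= 2"):
            GenotypeCall(status="ambiguous",
                         explanations=(frozenset({("x",)}),))


def test_observation_fasta_round_trip(db, panel, assays, assay_map, tmp_path):
    cfg = synth.SimConfig(frequencies=[1 / 8] * 8, n=10, seed=5)
    cohort = synth.simulate_cohort(panel, db, assays, cfg)
    path = tmp_path / "obs.fasta"
    deconvolve.write_observations(cohort.observations, path)
    back = deconvolve.read_observations(
        path, [i.id for i in cohort.individuals], [a.name for a in assays]
    )
    for ind, od in cohort.observations.items():
        for name, obs in od.items():
            if obs is NO_PRODUCT:
                assert back[ind][name] is NO_PRODUCT
            else:
                assert back[ind][name].codes == obs.codes
                assert back[ind][name].length_conflict == obs.length_conflict
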