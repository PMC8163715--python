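import numpy as np
import pytest

from diagchar import (
    AnalysisConfig,
    DataError,
    DiagnosisSet,
    classify_sequence,
    column_profile,
    diagnose,
    find_combined_diagnostics,
    find_single_diagnostics,
)
from conftest import make_alignment, make_partition, random_instance
from _oracle import oracle_duos, oracle_singles


class TestColumnProfile:
    def test_uniform_group_yields_state(self):
        aln = make_alignment({"a": "A", "b": "A", "c": "A"})
        assert column_profile(aln, 1, ["a", "b", "c"]).query_state == "A"

    def test_non_uniform_group_yields_none(self):
        aln = make_alignment({"a": "A", "b": "A", "c": "G"})
        assert column_profile(aln, 1, ["a", "b", "c"]).query_state is None

    def test_ambiguous_uniform_group_yields_none(self):
        aln = make_alignment({"a": "N", "b": "N"})
        assert column_profile(aln, 1, ["a", "b"]).query_state is None

    def test_conservative_expansion_with_gap(self):
        aln = make_alignment({"a": "C", "b": "Y", "c": "-"})
        prof = column_profile(aln, 1, ["a", "b", "c"], policy="conservative")
        assert prof.possible_states == frozenset({"C", "T", "-"})

    def test_strict_keeps_literal_symbols(self):
        aln = make_alignment({"a": "C", "b": "Y", "c": "-"})
        prof = column_profile(aln, 1, ["a", "b", "c"], policy="strict")
        assert prof.possible_states == frozenset({"C", "Y", "-"})


class TestSingleDiagnostics:
    def test_toy_single_found(self, toy_two_species):
        aln, part = toy_two_species
        found = find_single_diagnostics(aln, part, "S0")
        assert [(c.positions, c.states) for c in found] == [((1,), "A")]

    def test_identical_groups_have_no_diagnostics(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT", "d": "ACGT"})
        part = make_partition({"a": "X", "b": "X", "c": "Y", "d": "Y"})
        assert find_single_diagnostics(aln, part, "X") == []

    def test_reference_ambiguity_blocks_under_conservative_only(self):
        # query uniform G; reference carries R = {A,G}
        aln = make_alignment({"q1": "G", "q2": "G", "r1": "R"})
        part = make_partition({"q1": "X", "q2": "X", "r1": "Y"})
        conservative = find_single_diagnostics(aln, part, "X")
        strict = find_single_diagnostics(
            aln, part, "X", AnalysisConfig(ambiguity_policy="strict")
        )
        assert conservative == []
        assert [(c.positions, c.states) for c in strict] == [((1,), "G")]

    def test_reference_gap_never_equals_a_base(self):
        aln = make_alignment({"q1": "A", "q2": "A", "r1": "-"})
        part = make_partition({"q1": "X", "q2": "X", "r1": "Y"})
        found = find_single_diagnostics(aln, part, "X")
        assert [(c.positions, c.states) for c in found] == [((1,), "A")]

    def test_unknown_species_raises(self, toy_two_species):
        aln, part = toy_two_species
        with pytest.raises(DataError, match="absent"):
            find_single_diagnostics(aln, part, "nope")


class TestCombinedDiagnostics:
    def test_toy_duo_found(self, toy_two_species):
        aln, part = toy_two_species
        found = find_combined_diagnostics(aln, part, "S0")
        assert [(c.positions, c.states) for c in found] == [((3, 4), "AG")]

    def test_spec_minimal_duo(self):
        # query rows AG/AG; reference rows AT/CG: neither column single,
        # pair AG absent from the reference pairs
        aln = make_alignment({"q1": "AG", "q2": "AG", "r1": "AT", "r2": "CG"})
        part = make_partition({"q1": "X", "q2": "X", "r1": "Y", "r2": "Y"})
        found = find_combined_diagnostics(aln, part, "X")
        assert [(c.positions, c.states) for c in found] == [((1, 2), "AG")]

    def test_duo_containing_single_position_excluded(self, toy_two_species):
        aln, part = toy_two_species
        positions = {p for c in find_combined_diagnostics(aln, part, "S0") for p in c.positions}
        singles = {c.positions[0] for c in find_single_diagnostics(aln, part, "S0")}
        assert not positions & singles

    def test_reference_joint_ambiguity_blocks_conservatively(self):
        # reference row NG jointly admits the query duo AG only when N
        # is expanded; literal comparison finds no AG pair
        aln = make_alignment({"q1": "AG", "q2": "AG", "r1": "NG", "r2": "AC"})
        part = make_partition({"q1": "X", "q2": "X", "r1": "Y", "r2": "Y"})
        assert find_combined_diagnostics(aln, part, "X") == []
        strict = find_combined_diagnostics(
            aln, part, "X", AnalysisConfig(ambiguity_policy="strict")
        )
        assert [(c.positions, c.states) for c in strict] == [((1, 2), "AG")]


class TestOracleEquivalence:
    def test_finders_match_bruteforce_on_random_instances(self):
        """Definitional soundness on 60 seeded instances, both policies."""
        rng = np.random.default_rng(20240917)
        for _ in range(60):
            aln, part = random_instance(rng)
            policy = "conservative" if rng.random() < 0.5 else "strict"
            config = AnalysisConfig(ambiguity_policy=policy)
            for sp in part.species:
                got_s = [
                    (c.positions[0], c.states)
                    for c in find_single_diagnostics(aln, part, sp, config)
                ]
                got_d = [
                    (c.positions, c.states)
                    for c in find_combined_diagnostics(aln, part, sp, config)
                ]
                assert got_s == oracle_singles(aln, part, sp, policy)
                assert got_d == oracle_duos(aln, part, sp, policy)


class TestDiagnose:
    def test_two_marker_diagnosis_and_counts(self, toy_two_species):
        aln, part = toy_two_species
        aln28 = make_alignment({"q1": "GG", "r1": "GC"}, marker="28S")
        diag = diagnose({"COI": aln, "28S": aln28}, part)
        assert diag.entries[("S0", "COI")].n_sequences == 2
        assert diag.entries[("S0", "28S")].n_sequences == 1
        # singles precede combined in each entry
        kinds = [c.kind for c in diag.entries[("S0", "COI")].characters]
        assert kinds == sorted(kinds, key=lambda k: k != "single")

    def test_species_missing_from_marker_gets_empty_entry(self, toy_two_species):
        aln, part = toy_two_species
        aln28 = make_alignment({"q1": "GG", "r1": "GC"}, marker="28S")
        diag = diagnose({"COI": aln, "28S": aln28}, part)
        assert diag.entries[("S1", "28S")].n_sequences == 1
        assert diag.entries[("S0", "28S")].characters  # q1 uniform, r1 differs

    def test_single_species_dataset_rejected(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        part = make_partition({"a": "X", "b": "X"})
        with pytest.raises(DataError, match="two species"):
            diagnose({"COI": aln}, part)

    def test_unassigned_sequences_dropped_with_warning(self, toy_two_species):
        aln, part = toy_two_species
        extra = make_alignment(
            dict(list(zip(aln.ids, aln.seqs)) + [("ghost", "AAAAA")])
        )
        with pytest.warns(UserWarning, match="unassigned"):
            diag = diagnose({"COI": extra}, part)
        assert diag.entries[("S0", "COI")].characters == diagnose({"COI": aln}, part).entries[("S0", "COI")].characters

    def test_determinism_byte_identical_json(self, toy_two_species):
        aln, part = toy_two_species
        a = diagnose({"COI": aln}, part).to_json()
        b = diagnose({"COI": aln}, part).to_json()
        assert a == b

    def test_json_round_trip(self, toy_two_species):
        aln, part = toy_two_species
        diag = diagnose({"COI": aln}, part)
        again = DiagnosisSet.from_json(diag.to_json())
        assert again.entries == diag.entries
        assert again.marker_columns == diag.marker_columns


class TestAntitonicity:
    """Growing either group never creates diagnostic information.

    Singles are strictly antitone.  Combined duos are antitone modulo
    single subsumption: a duo may surface with the larger group only
    when a member column was single-diagnostic with the smaller one (the
    'not individually diagnostic' condition stops applying)."""

    @staticmethod
    def _subsumed(big_s, big_d, small_s, small_d):
        assert {c.positions[0] for c in big_s} <= {c.positions[0] for c in small_s}
        small_pos = {c.positions[0] for c in small_s}
        small_keys = {(c.positions, c.states) for c in small_d}
        for duo in big_d:
            assert (duo.positions, duo.states) in small_keys or (
                set(duo.positions) & small_pos
            )

    def test_growing_reference_never_adds_information(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            aln, part = random_instance(rng)
            species = part.species
            target = species[0]
            if len(species) < 3:
                continue
            small = AnalysisConfig(reference_scope=species[1:2])
            self._subsumed(
                find_single_diagnostics(aln, part, target),
                find_combined_diagnostics(aln, part, target),
                find_single_diagnostics(aln, part, target, small),
                find_combined_diagnostics(aln, part, target, small),
            )

    def test_growing_query_never_adds_information(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            aln, part = random_instance(rng)
            target = part.species[0]
            members = part.members(target)
            if len(members) < 2:
                continue
            reduced = make_partition(
                {i: sp for i, sp in part.assignments.items()
                 if sp != target or i == members[0]}
            )
            reduced_aln = aln.subset(reduced.assignments)
            self._subsumed(
                find_single_diagnostics(aln, part, target),
                find_combined_diagnostics(aln, part, target),
                find_single_diagnostics(reduced_aln, reduced, target),
                find_combined_diagnostics(reduced_aln, reduced, target),
            )


class TestClassify:
    def test_training_sequence_classified_to_own_species(self, toy_two_species):
        aln, part = toy_two_species
        diag = diagnose({"COI": aln}, part)
        result = classify_sequence(aln.sequence("q1"), diag, "COI")
        assert result.verdict == "unique"
        assert result.best == "S0"
        assert result.scores["S0"] == 1.0

    def test_gap_at_every_diagnostic_position_is_no_call(self, toy_two_species):
        aln, part = toy_two_species
        diag = diagnose({"COI": aln}, part)
        result = classify_sequence("-----", diag, "COI")
        assert result.verdict == "no_call"

    def test_ambiguity_possible_match_conservative_vs_strict(self):
        aln = make_alignment({"q1": "A", "q2": "A", "r1": "C", "r2": "C"})
        part = make_partition({"q1": "X", "q2": "X", "r1": "Y", "r2": "Y"})
        diag = diagnose({"COI": aln}, part)
        assert classify_sequence("N", diag, "COI").verdict == "ambiguous"
        assert classify_sequence("N", diag, "COI", policy="strict").verdict == "no_call"

    def test_length_mismatch_rejected(self, toy_two_species):
        aln, part = toy_two_species
        diag = diagnose({"COI": aln}, part)
        with pytest.raises(DataError, match="length"):
            classify_sequence("ACGT", diag, "COI")

    def test_species_without_diagnostics_excluded_with_warning(self):
        aln = make_alignment({"a": "AA", "b": "AA", "c": "CC"})
        part = make_partition({"a": "W", "b": "X", "c": "Y"})
        diag = diagnose({"COI": aln}, part)
        assert not diag.entries[("W", "COI")].characters
        with pytest.warns(UserWarning, match="no COI diagnostics"):
            result = classify_sequence("AA", diag, "COI")
        assert "W" not in result.scores


def test_config_rejects_unsupported_window_and_policy():
    with pytest.raises(ValueError, match="k_window"):
        AnalysisConfig(k_window=3)
    with pytest.raises(ValueError, match="policy"):
        AnalysisConfig(ambiguity_policy="lenient")
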