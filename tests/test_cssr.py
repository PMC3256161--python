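"""Null-aware subsequence counting, causal-state splitting, determinisation."""

import numpy as np
import pytest

from fretcssr import (
    NULL,
    CausalStateMachine,
    ConfigurationError,
    CssrConfig,
    GaussianComponent,
    InsufficientDataError,
    NonErgodicError,
    attach_emissions,
    count_windows,
    determinize,
    infer_causal_states,
    prune_transitions,
    remove_transients,
    suggest_max_length,
)
from fretcssr import test_equivalence as equivalence_test
from fretcssr.discretize import MixtureModel

from conftest import exhaustive_window_counts, golden_mean_sequence


def infer_machine(symbols: np.ndarray, max_length: int = 2, alpha: float = 0.05):
    counts = count_windows(symbols, max_length=max_length)
    states = infer_causal_states(counts, CssrConfig(alpha=alpha, max_length=max_length))
    return remove_transients(determinize(states, counts))


class TestCountWindows:
    def test_hand_counted_example_with_null(self):
        # H L H L U with H=1, L=0: pairs HL, LH, HL; LU discarded whole
        seq = np.array([1, 0, 1, 0, NULL])
        sc = count_windows(seq, max_length=1)
        assert sc.counts[((1,), 0)] == 2
        assert sc.counts[((0,), 1)] == 1
        assert ((0,), NULL) not in sc.counts
        assert sc.totals[(1,)] == 2 and sc.totals[(0,)] == 1
        assert sc.n_certain_windows[2] == 3

    def test_all_null_sequence_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            count_windows(np.full(50, NULL), max_length=1)

    def test_isolated_certain_symbols_are_an_error(self):
        with pytest.raises(InsufficientDataError, match="certain"):
            count_windows(np.array([0, NULL, 1, NULL, 0]), max_length=1)

    def test_matches_direct_window_scan(self):
        rng = np.random.default_rng(42)
        seq = rng.choice([0, 1, NULL], size=800, p=[0.4, 0.4, 0.2])
        sc = count_windows(seq, max_length=2)
        for m in (2, 3):
            oracle = exhaustive_window_counts(seq, m)
            assert sc.n_certain_windows[m] == sum(oracle.values())
            for window, c in oracle.items():
                assert sc.counts[(window[:-1], window[-1])] >= 0
        # length-2 identity: every certain adjacent pair is counted once
        pairs = exhaustive_window_counts(seq, 2)
        got = {
            (h[0], a): c for (h, a), c in sc.counts.items() if len(h) == 1
        }
        assert got == {(h, a): c for (h, a), c in pairs.items()}

    def test_totals_are_row_sums(self):
        rng = np.random.default_rng(43)
        seq = rng.choice([0, 1, NULL], size=300)
        sc = count_windows(seq, max_length=2)
        for h, tot in sc.totals.items():
            assert tot == sum(
                c for (hh, _a), c in sc.counts.items() if hh == h
            )


class TestSuggestMaxLength:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (60, 2, 1),  # expected count floor reached immediately
            (150, 2, 2),  # sparse spectrum scale
            (10_000, 2, 8),  # largest L with 10000 / 2^L >= 25
            (5000, 3, 4),
        ],
    )
    def test_largest_supported_depth(self, n, k, expected):
        assert suggest_max_length(n, k) == expected


class TestEquivalence:
    def test_identical_vectors_are_equivalent(self):
        eq, p = equivalence_test(np.array([30, 70]), np.array([30, 70]))
        assert eq and p == pytest.approx(1.0)

    def test_opposite_vectors_are_distinct(self):
        eq, p = equivalence_test(np.array([90, 10]), np.array([10, 90]), alpha=0.05)
        assert not eq
        # direct 2x2 chi-squared: stat = 128, p << 0.05
        assert p < 1e-20

    def test_small_expected_cells_are_merged(self):
        eq, p = equivalence_test(np.array([50, 1, 0]), np.array([48, 0, 1]))
        assert eq
        assert 0 <= p <= 1

    def test_type_one_error_rate_matches_alpha(self):
        """Rejection rate on same-distribution samples is ~alpha (1000 reps)."""
        rng = np.random.default_rng(77)
        alpha = 0.05
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.multinomial(200, [0.7, 0.3])
            b = rng.multinomial(200, [0.7, 0.3])
            eq, _p = equivalence_test(a, b, alpha=alpha)
            rejections += not eq
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3 * se

    def test_ks_variant_runs(self):
        eq, _ = equivalence_test(np.array([90, 10]), np.array([10, 90]), test="ks")
        assert not eq


class TestInferCausalStates:
    def test_iid_sequence_yields_single_state(self):
        rng = np.random.default_rng(5)
        seq = rng.choice([0, 1], size=2000, p=[0.6, 0.4])
        machine = infer_machine(seq, max_length=2)
        assert machine.n_states == 1
        p0 = machine.transitions[(machine.states[0], 0)][1]
        assert p0 == pytest.approx(0.6, abs=0.05)

    def test_deterministic_alternation_yields_two_states(self):
        seq = np.tile([1, 0], 200)
        machine = infer_machine(seq, max_length=2)
        assert machine.n_states == 2
        # each state has exactly one outgoing edge with probability 1
        for s in machine.states:
            edges = [(a, v) for (ss, a), v in machine.transitions.items() if ss == s]
            assert len(edges) == 1
            assert edges[0][1][1] == pytest.approx(1.0)

    def test_golden_mean_process_yields_two_states(self):
        """No-consecutive-ones process: state is determined by the last symbol.

        The exact causal partition (enumerable from the process definition)
        groups histories by whether they end in 1; the reconstruction must
        agree on every maximal history.
        """
        seq = golden_mean_sequence(5000, seed=6)
        machine = infer_machine(seq, max_length=2)
        assert machine.n_states == 2
        for state, hists in machine.suffixes.items():
            endings = {h[-1] for h in hists if h}
            assert len(endings) == 1, f"state {state} mixes last symbols {endings}"
        # after a 1: always 0; after a 0: fair coin
        by_last = {}
        for state, hists in machine.suffixes.items():
            last = next(h[-1] for h in hists if h)
            by_last[last] = state
        assert machine.transitions[(by_last[1], 0)][1] == pytest.approx(1.0)
        assert ((by_last[1], 1)) not in machine.transitions
        assert machine.transitions[(by_last[0], 0)][1] == pytest.approx(0.5, abs=0.03)

    def test_state_members_are_pairwise_equivalent(self):
        """Self-consistency audit: co-grouped histories share a morph at alpha."""
        rng = np.random.default_rng(8)
        seq = rng.choice([0, 1], size=3000, p=[0.5, 0.5])
        counts = count_windows(seq, max_length=2)
        config = CssrConfig(alpha=0.05, max_length=2)
        states = infer_causal_states(counts, config)
        for s in states:
            members = sorted(s)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    eq, _ = equivalence_test(
                        counts.morph(members[i]), counts.morph(members[j]), alpha=0.05
                    )
                    assert eq

    def test_nulls_do_not_fabricate_transitions(self):
        # alternation with every 3rd symbol masked: remaining pairs still
        # alternate; splicing across nulls would instead see repeats
        seq = np.tile([1, 0], 300).astype(int)
        masked = seq.copy()
        masked[::3] = NULL
        machine = infer_machine(masked, max_length=1)
        assert machine.n_states == 2
        for (s, a), (t, p) in machine.transitions.items():
            assert s != t  # pure alternation: no self-loops


class TestDeterminize:
    def test_unifilar_grouping_unchanged(self):
        seq = np.tile([1, 0], 100)
        counts = count_windows(seq, max_length=1)
        states = [{(1,)}, {(0,)}]
        machine = determinize(states, counts)
        assert machine.n_states == 2
        for (s, a), (t, p) in machine.transitions.items():
            assert p == pytest.approx(1.0)

    def test_non_unifilar_grouping_is_split(self):
        """Histories sharing a symbol but leading to different states get split.

        In the period-4 sequence 0 2 1 2 ..., histories (0,) and (1,) both
        continue with symbol 2 yet lead to (0, 2) and (1, 2), which live in
        different states — grouping them is non-unifilar over the 3-symbol
        alphabet and determinisation must pull them apart.
        """
        seq = np.tile([0, 2, 1, 2], 150)
        counts = count_windows(seq, max_length=2)
        grouping = [
            {(0,), (1,)},  # deliberately non-unifilar
            {(2,)},
            {(0, 2)},
            {(1, 2)},
            {(2, 0)},
            {(2, 1)},
        ]
        machine = determinize(grouping, counts)
        # exhaustive successor check: every (state, symbol) maps to one state
        seen = {}
        for (s, a), (t, _p) in machine.transitions.items():
            assert seen.setdefault((s, a), t) == t
        state_of = {h: s for s, hs in machine.suffixes.items() for h in hs}
        assert state_of[(0,)] != state_of[(1,)]

    def test_result_is_always_unifilar_and_row_stochastic(self):
        rng = np.random.default_rng(11)
        seq = rng.choice([0, 1, NULL], size=1500, p=[0.45, 0.45, 0.1])
        machine = infer_machine(seq, max_length=2)
        machine.validate()  # row sums, unifilarity by construction
        rows = {}
        for (s, _a), (_t, p) in machine.transitions.items():
            rows[s] = rows.get(s, 0) + p
        assert all(abs(v - 1) < 1e-9 for v in rows.values())


class TestRemoveTransients:
    @pytest.fixture
    def cycle_with_transients(self):
        # t0 -> t1 -> (a <-> b): the 2-cycle is the unique terminal SCC
        return CausalStateMachine(
            states=["t0", "t1", "a", "b"],
            alphabet=[0, 1],
            transitions={
                ("t0", 0): ("t1", 1.0),
                ("t1", 0): ("a", 1.0),
                ("a", 0): ("b", 1.0),
                ("b", 1): ("a", 1.0),
            },
        )

    def test_strongly_connected_machine_unchanged(self, two_state):
        assert remove_transients(two_state) is two_state

    def test_unreachable_state_removed(self):
        m = CausalStateMachine(
            states=["a", "b", "orphan"],
            alphabet=[0, 1],
            transitions={
                ("a", 0): ("b", 1.0),
                ("b", 1): ("a", 1.0),
                ("orphan", 0): ("a", 1.0),
            },
        )
        assert set(remove_transients(m).states) == {"a", "b"}

    def test_transient_chain_stripped_to_cycle(self, cycle_with_transients):
        reduced = remove_transients(cycle_with_transients)
        assert set(reduced.states) == {"a", "b"}

    def test_two_terminal_components_rejected(self):
        m = CausalStateMachine(
            states=["a", "b"],
            alphabet=[0],
            transitions={("a", 0): ("a", 1.0), ("b", 0): ("b", 1.0)},
        )
        with pytest.raises(NonErgodicError):
            remove_transients(m)


class TestPruneTransitions:
    @pytest.fixture
    def leaky_machine(self):
        return CausalStateMachine(
            states=["a", "b"],
            alphabet=[0, 1],
            transitions={
                ("a", 0): ("a", 0.9),
                ("a", 1): ("b", 0.1),
                ("b", 1): ("b", 0.9),
                ("b", 0): ("a", 0.1),
            },
        )

    def test_threshold_zero_is_identity(self, leaky_machine):
        assert prune_transitions(leaky_machine, 0.0) is leaky_machine

    def test_small_edge_removed_and_row_renormalised(self):
        m = CausalStateMachine(
            states=["a", "b"],
            alphabet=[0, 1, 2],
            transitions={
                ("a", 0): ("a", 0.899),
                ("a", 1): ("b", 0.1),
                ("a", 2): ("b", 0.001),
                ("b", 1): ("b", 0.9),
                ("b", 0): ("a", 0.1),
            },
        )
        pruned = prune_transitions(m, 0.01)
        assert ("a", 2) not in pruned.transitions
        row = sum(p for (s, _), (_, p) in pruned.transitions.items() if s == "a")
        assert row == pytest.approx(1.0)
        assert pruned.transitions[("a", 0)][1] == pytest.approx(0.899 / 0.999)

    def test_disconnecting_threshold_rejected(self, two_state):
        with pytest.raises(NonErgodicError, match="lower threshold"):
            prune_transitions(two_state, 0.5)


class TestAttachEmissions:
    def make_mixture(self, *means_sds):
        comps = tuple(
            GaussianComponent(1 / len(means_sds), m, s) for m, s in means_sds
        )
        return MixtureModel(
            components=tuple(sorted(comps, key=lambda c: c.mean)),
            loglik=0.0,
            n_params=3 * len(comps) - 1,
            aic=0.0,
        )

    def test_two_component_binding_in_mean_order(self):
        seq = np.tile([1, 0], 100)
        machine = infer_machine(seq, max_length=1)
        mix = self.make_mixture((0.7, 0.1), (0.3, 0.1))  # shuffled input order
        bound = attach_emissions(machine, mix)
        assert bound.emissions[0].mean == pytest.approx(0.3)
        assert bound.emissions[1].mean == pytest.approx(0.7)

    def test_size_mismatch_rejected(self):
        seq = np.tile([1, 0], 100)
        machine = infer_machine(seq, max_length=1)
        with pytest.raises(ConfigurationError):
            attach_emissions(machine, self.make_mixture((0.5, 0.1)))

    def test_single_component_binding(self):
        rng = np.random.default_rng(13)
        seq = np.zeros(200, dtype=int)
        machine = infer_machine(seq, max_length=1)
        bound = attach_emissions(machine, self.make_mixture((0.5, 0.1)))
        assert bound.emissions[0].mean == pytest.approx(0.5)
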