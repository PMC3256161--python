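"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive — exhaustive path enumeration for
likelihoods and decoding, direct window scans for counting, quadrature for
partition masses — so they stay independent of the implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import norm

from fretcssr import (
    CausalStateMachine,
    GaussianComponent,
    Trace,
)
from fretcssr.models import degenerate_four_state_machine, two_state_machine


@pytest.fixture
def two_state():
    return two_state_machine()


@pytest.fixture
def degenerate():
    return degenerate_four_state_machine()


@pytest.fixture
def single_state():
    return CausalStateMachine(
        states=["S"],
        alphabet=[0],
        transitions={("S", 0): ("S", 1.0)},
        emissions={0: GaussianComponent(1.0, 0.5, 0.1)},
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_loglik(machine: CausalStateMachine, trace: Trace) -> float:
    """Exhaustive sum over every (start state, transition path) of the trace.

    Start states weighted by the stationary distribution, matching the
    likelihood convention under test; feasible only for tiny machines/traces.
    """
    from fretcssr import stationary_distribution

    values = trace.values
    pi = stationary_distribution(machine)
    edges = {}
    for (s, a), (t, p) in machine.transitions.items():
        edges.setdefault(s, []).append((a, t, p))
    total = 0.0
    emissions = machine.emissions

    def recurse(state: str, i: int, prob: float, dens: float) -> float:
        if prob == 0.0:
            return 0.0
        if i == len(values):
            return prob * dens
        acc = 0.0
        for a, t, p in edges.get(state, []):
            d = math.exp(norm.logpdf(values[i], emissions[a].mean, emissions[a].sd))
            acc += recurse(t, i + 1, prob * p, dens * d)
        return acc

    for si, s in enumerate(machine.states):
        total += recurse(s, 0, float(pi[si]), 1.0)
    return math.log(total)


def brute_force_viterbi(machine: CausalStateMachine, trace: Trace) -> tuple[float, list[str]]:
    """Best path by exhaustive enumeration; returns (log prob, state path).

    Ties resolved toward the lexicographically-smallest state-index path, the
    same convention the implementation promises.
    """
    from fretcssr import stationary_distribution

    values = trace.values
    pi = stationary_distribution(machine)
    idx = {s: i for i, s in enumerate(machine.states)}
    edges = {}
    for (s, a), (t, p) in sorted(machine.transitions.items()):
        if p > 0:
            edges.setdefault(s, []).append((a, t, p))
    best: list[tuple[float, list[int]]] = []

    def recurse(state: str, i: int, logp: float, path: list[str]) -> None:
        if i == len(values):
            best.append((logp, [idx[s] for s in path]))
            return
        for a, t, p in edges.get(state, []):
            lp = logp + math.log(p) + norm.logpdf(
                values[i], machine.emissions[a].mean, machine.emissions[a].sd
            )
            recurse(t, i + 1, lp, path + [t])

    for s in machine.states:
        if pi[idx[s]] > 0:
            recurse(s, 0, math.log(pi[idx[s]]), [])
    # highest log prob; among near-ties (within float noise) smallest index path
    top = max(lp for lp, _ in best)
    candidates = sorted(p for lp, p in best if lp > top - 1e-12)
    return top, [machine.states[i] for i in candidates[0]]


def random_unifilar_machine(
    rng: np.random.Generator, max_states: int = 3, alphabet_size: int = 2
) -> CausalStateMachine:
    """A random strongly-connected unifilar machine with Gaussian emissions."""
    for _attempt in range(200):
        n = int(rng.integers(1, max_states + 1))
        states = [f"q{i}" for i in range(n)]
        transitions = {}
        for i, s in enumerate(states):
            symbols = [a for a in range(alphabet_size) if rng.random() < 0.8]
            if not symbols:
                symbols = [int(rng.integers(alphabet_size))]
            probs = rng.dirichlet(np.ones(len(symbols)))
            for a, p in zip(symbols, probs):
                transitions[(s, a)] = (states[int(rng.integers(n))], float(p))
        try:
            machine = CausalStateMachine(
                states=states,
                alphabet=list(range(alphabet_size)),
                transitions=transitions,
                emissions={
                    a: GaussianComponent(
                        1.0 / alphabet_size,
                        float(0.2 + 0.5 * a + 0.1 * rng.random()),
                        float(0.05 + 0.1 * rng.random()),
                    )
                    for a in range(alphabet_size)
                },
            )
        except Exception:
            continue
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(states)
        for (s, _a), (t, p) in transitions.items():
            if p > 0:
                g.add_edge(s, t)
        if nx.is_strongly_connected(g):
            return machine
    raise RuntimeError("could not build a random machine")


def exhaustive_window_counts(symbols: np.ndarray, length: int) -> dict:
    """Direct scan over all contiguous windows of ``length`` certain symbols."""
    from fretcssr import NULL

    out: dict = {}
    for i in range(len(symbols) - length + 1):
        w = symbols[i : i + length]
        if NULL in w:
            continue
        key = tuple(int(x) for x in w)
        out[key] = out.get(key, 0) + 1
    return out


def golden_mean_sequence(n: int, seed: int) -> np.ndarray:
    """Golden-mean process: after a 1 always 0; after a 0 a fair coin."""
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=int)
    prev = 0
    for i in range(n):
        out[i] = 0 if prev == 1 else int(rng.integers(2))
        prev = out[i]
    return out


def generator_edge_set(machine: CausalStateMachine) -> set[tuple[str, int, str]]:
    """Architecture of a machine with states renamed by their self-loop symbol.

    For last-symbol-context machines (each state entered on a unique symbol)
    this canonical form makes architectures comparable across runs.
    """
    entry: dict[str, set[int]] = {s: set() for s in machine.states}
    for (s, a), (t, p) in machine.transitions.items():
        if p > 0:
            entry[t].add(a)
    rename = {}
    for s, symbols in entry.items():
        assert len(symbols) == 1, f"state {s} entered on several symbols {symbols}"
        rename[s] = f"ctx{symbols.pop()}"
    return {
        (rename[s], a, rename[t]) for (s, a), (t, p) in machine.transitions.items() if p > 0
    }
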