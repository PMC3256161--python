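"""Symbol-emitting, Gaussian-observed hidden Markov machines.

A :class:`CausalStateMachine` is a unifilar (deterministic) HMM: each state has
outgoing transitions labelled by a discrete symbol, each ``(state, symbol)``
pair leads to exactly one successor state, and each symbol may carry a Gaussian
emission density so the machine can generate — and assign likelihoods to —
continuous traces.  This is the common representation for both the generating
models used in simulation studies and the causal-state machines reconstructed
from data.

Observations are emitted *on transitions*: at each step the current state draws
a (symbol, successor) pair, the symbol's Gaussian is sampled, and the state
advances.  The hidden path reported by :func:`simulate_trace` and
:func:`viterbi_path` is the state *after* each emission, which for the usual
smFRET convention (symbol = destination level) aligns hidden-state runs with
observable dwell periods.

Likelihoods use the stationary distribution as the initial state law (the whole
analysis assumes stationarity), and the model distance between two machines is
the per-sample difference of their log-likelihoods on one observation sequence,
after Rabiner.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, NonErgodicError

__all__ = [
    "GaussianComponent",
    "Trace",
    "CausalStateMachine",
    "DistanceResult",
    "simulate_trace",
    "stationary_distribution",
    "forward_loglik",
    "viterbi_path",
    "model_distance",
    "statistical_complexity",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian emission/mixture component (weight, mean, sd)."""

    weight: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"sd must be > 0, got {self.sd}")
        if not 0.0 <= self.weight <= 1.0 + _PROB_TOL:
            raise ConfigurationError(f"weight must be in [0, 1], got {self.weight}")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return norm.logpdf(x, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class Trace:
    """A real-valued time series sampled at a fixed interval ``dt`` (seconds)."""

    values: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) * self.dt


@dataclass
class CausalStateMachine:
    """Unifilar symbol-emitting HMM / causal-state machine.

    Parameters
    ----------
    states
        Ordered state identifiers (strings).
    alphabet
        Ordered certain symbols (integers ``0..K-1`` by convention).
    transitions
        Map ``(state, symbol) -> (next_state, probability)``.  Unifilarity is
        implied by the mapping type; rows must sum to one.
    suffixes
        Optional map ``state -> set of history tuples`` (empty for hand-built
        generators).
    emissions
        Optional map ``symbol -> GaussianComponent``.
    counts
        Optional map ``(state, symbol) -> observed continuation count``.
    """

    states: list[str]
    alphabet: list[int]
    transitions: dict[tuple[str, int], tuple[str, float]]
    suffixes: dict[str, set[tuple[int, ...]]] = field(default_factory=dict)
    emissions: dict[int, GaussianComponent] | None = None
    counts: dict[tuple[str, int], int] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if not self.states:
            raise ConfigurationError("machine must have at least one state")
        if len(set(self.states)) != len(self.states):
            raise ConfigurationError("duplicate state ids")
        row = {s: 0.0 for s in self.states}
        for (s, a), (t, p) in self.transitions.items():
            if s not in row or t not in row:
                raise ConfigurationError(f"transition ({s},{a})->{t} uses unknown state")
            if a not in self.alphabet:
                raise ConfigurationError(f"symbol {a} not in alphabet")
            if not -_PROB_TOL <= p <= 1.0 + _PROB_TOL:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
            row[s] += p
        for s, total in row.items():
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(f"outgoing probabilities of state {s} sum to {total}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        return self.states.index(state)

    def transition_matrix(self) -> np.ndarray:
        """State-to-state matrix ``P[i, j]`` summed over symbols."""
        idx = {s: i for i, s in enumerate(self.states)}
        P = np.zeros((self.n_states, self.n_states))
        for (s, _a), (t, p) in self.transitions.items():
            P[idx[s], idx[t]] += p
        return P

    def symbol_matrices(self) -> dict[int, np.ndarray]:
        """Per-symbol matrices ``T_a[i, j] = P(emit a, go to j | i)``."""
        idx = {s: i for i, s in enumerate(self.states)}
        mats = {a: np.zeros((self.n_states, self.n_states)) for a in self.alphabet}
        for (s, a), (t, p) in self.transitions.items():
            mats[a][idx[s], idx[t]] += p
        return mats

    def graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.states)
        for (s, a), (t, p) in self.transitions.items():
            g.add_edge(s, t, symbol=a, probability=p)
        return g

    def require_emissions(self) -> dict[int, GaussianComponent]:
        if self.emissions is None:
            raise ConfigurationError("machine has no emission densities attached")
        missing = [a for a in self.alphabet if a not in self.emissions]
        if missing:
            raise ConfigurationError(f"no emission density for symbols {missing}")
        return self.emissions

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "states": list(self.states),
            "alphabet": list(self.alphabet),
            "suffixes": {
                s: sorted("".join(map(str, h)) for h in hs) for s, hs in self.suffixes.items()
            },
            "transitions": [
                {
                    "from": s,
                    "symbol": a,
                    "to": t,
                    "p": p,
                    "count": (self.counts or {}).get((s, a)),
                }
                for (s, a), (t, p) in sorted(self.transitions.items())
            ],
        }
        if self.emissions is not None:
            d["emissions"] = {
                str(a): {"weight": c.weight, "mean": c.mean, "sd": c.sd}
                for a, c in sorted(self.emissions.items())
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CausalStateMachine":
        transitions = {}
        counts = {}
        for e in d["transitions"]:
            transitions[(e["from"], e["symbol"])] = (e["to"], e["p"])
            if e.get("count") is not None:
                counts[(e["from"], e["symbol"])] = e["count"]
        emissions = None
        if "emissions" in d:
            emissions = {
                int(a): GaussianComponent(c["weight"], c["mean"], c["sd"])
                for a, c in d["emissions"].items()
            }
        suffixes = {
            s: {tuple(int(ch) for ch in h) for h in hs}
            for s, hs in d.get("suffixes", {}).items()
        }
        return cls(
            states=list(d["states"]),
            alphabet=list(d["alphabet"]),
            transitions=transitions,
            suffixes=suffixes,
            emissions=emissions,
            counts=counts or None,
        )

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CausalStateMachine":
        return cls.from_dict(json.loads(text))

    def to_dot(self) -> str:
        """GraphViz DOT rendering; edges labelled ``symbol : probability``."""
        lines = ["digraph machine {", "  rankdir=LR;"]
        for s in self.states:
            label = s
            lines.append(f'  "{s}" [label="{label}"];')
        for (s, a), (t, p) in sorted(self.transitions.items()):
            lbl = f"{a} : {p:.3f}"
            if self.emissions is not None and a in self.emissions:
                lbl = f"{a} (μ={self.emissions[a].mean:.2f}) : {p:.3f}"
            lines.append(f'  "{s}" -> "{t}" [label="{lbl}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalStateMachine):
            return NotImplemented
        return self.to_dict() == other.to_dict()


@dataclass(frozen=True)
class DistanceResult:
    """Rabiner model distance: per-sample log-likelihood gap (nats/sample)."""

    distance: float
    loglik_gen: float
    loglik_inf: float
    length: int


# ---------------------------------------------------------------------------
# stationary analysis


def _terminal_sccs(machine: CausalStateMachine) -> list[set[str]]:
    g = nx.DiGraph()
    g.add_nodes_from(machine.states)
    for (s, _a), (t, p) in machine.transitions.items():
        if p > 0:
            g.add_edge(s, t)
    cond = nx.condensation(g)
    return [
        cond.nodes[n]["members"] for n in cond.nodes if cond.out_degree(n) == 0
    ]


def stationary_distribution(machine: CausalStateMachine) -> np.ndarray:
    """Left fixed point of the state-to-state transition matrix.

    Requires a single recurrent class; transient states receive probability
    zero.  Raises :class:`NonErgodicError` naming the offending recurrent
    classes otherwise.
    """
    terminals = _terminal_sccs(machine)
    if len(terminals) != 1:
        raise NonErgodicError(
            "machine is reducible: multiple recurrent classes "
            + ", ".join(sorted("{" + ",".join(sorted(t)) + "}" for t in terminals))
        )
    recurrent = sorted(terminals[0], key=machine.states.index)
    sub_idx = [machine.states.index(s) for s in recurrent]
    P = machine.transition_matrix()[np.ix_(sub_idx, sub_idx)]
    n = len(sub_idx)
    # solve pi (P - I) = 0 with sum(pi) = 1
    A = np.vstack([(P.T - np.eye(n)), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi_sub, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi_sub = np.clip(pi_sub, 0.0, None)
    pi_sub /= pi_sub.sum()
    pi = np.zeros(machine.n_states)
    pi[sub_idx] = pi_sub
    return pi


def statistical_complexity(machine: CausalStateMachine) -> float:
    """Shannon entropy (bits) of the stationary distribution over states."""
    pi = stationary_distribution(machine)
    nz = pi[pi > 0]
    return float(-(nz * np.log2(nz)).sum())


# ---------------------------------------------------------------------------
# simulation


def simulate_trace(
    machine: CausalStateMachine,
    n: int,
    seed: int | np.random.Generator,
    dt: float = 1.0,
) -> tuple[Trace, list[str], np.ndarray]:
    """Sample a length-``n`` continuous trace from the machine.

    The start state is drawn from the stationary distribution.  At each step a
    ``(symbol, successor)`` transition is drawn from the current state, the
    symbol's Gaussian is sampled for the observation, and the state advances.

    Returns ``(trace, hidden_states, symbols)`` where ``hidden_states[t]`` is
    the state occupied *after* emitting ``trace.values[t]``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    emissions = machine.require_emissions()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out = {s: [] for s in machine.states}
    for (s, a), (t, p) in sorted(machine.transitions.items()):
        if p > 0:
            out[s].append((a, t, p))
    for s, edges in out.items():
        if not edges:
            raise ConfigurationError(f"state {s} has no outgoing transitions")

    pi = stationary_distribution(machine)
    state = machine.states[rng.choice(machine.n_states, p=pi)]

    symbols = np.empty(n, dtype=int)
    path: list[str] = []
    for t_i in range(n):
        edges = out[state]
        probs = np.array([p for _, _, p in edges])
        j = rng.choice(len(edges), p=probs / probs.sum())
        a, nxt, _ = edges[j]
        symbols[t_i] = a
        state = nxt
        path.append(state)

    means = np.array([emissions[a].mean for a in symbols])
    sds = np.array([emissions[a].sd for a in symbols])
    values = rng.normal(means, sds)
    return Trace(values, dt=dt), path, symbols


# ---------------------------------------------------------------------------
# likelihood / decoding


def _emission_logpdfs(machine: CausalStateMachine, values: np.ndarray) -> dict[int, np.ndarray]:
    emissions = machine.require_emissions()
    return {a: emissions[a].logpdf(values) for a in machine.alphabet}


def forward_loglik(machine: CausalStateMachine, trace: Trace) -> float:
    """Log-probability (nats) of the trace under the machine.

    Forward recursion over (state, symbol, successor) transitions with the
    emitted symbol's Gaussian density as the per-sample likelihood; the initial
    state law is the stationary distribution.  Log-space scaling keeps the
    recursion finite for arbitrarily long traces.
    """
    values = trace.values
    if len(values) == 0:
        return 0.0
    logB = _emission_logpdfs(machine, values)
    mats = machine.symbol_matrices()
    alpha = stationary_distribution(machine)
    total = 0.0
    for t in range(len(values)):
        # per-symbol densities are shared across transitions emitting that symbol
        dens = {a: math.exp(logB[a][t] - max(lb[t] for lb in logB.values())) for a in machine.alphabet}
        shift = max(lb[t] for lb in logB.values())
        nxt = np.zeros_like(alpha)
        for a, T_a in mats.items():
            nxt += (alpha @ T_a) * dens[a]
        norm_t = nxt.sum()
        if norm_t <= 0.0:
            return -math.inf
        total += math.log(norm_t) + shift
        alpha = nxt / norm_t
    return float(total)


def viterbi_path(machine: CausalStateMachine, trace: Trace) -> list[str]:
    """Jointly most probable hidden state path (state after each emission).

    Ties are broken toward the lowest state index for reproducibility.
    """
    values = trace.values
    n = len(values)
    if n == 0:
        return []
    logB = _emission_logpdfs(machine, values)
    idx = {s: i for i, s in enumerate(machine.states)}
    S = machine.n_states

    # edges grouped by destination, ordered by source index for tie-breaking
    incoming: list[list[tuple[int, int, float]]] = [[] for _ in range(S)]
    for (s, a), (t, p) in sorted(machine.transitions.items()):
        if p > 0:
            incoming[idx[t]].append((idx[s], a, math.log(p)))
    for lst in incoming:
        lst.sort()

    with np.errstate(divide="ignore"):
        delta = np.log(stationary_distribution(machine))
    back = np.zeros((n, S), dtype=int)
    for t in range(n):
        nxt = np.full(S, -np.inf)
        for j in range(S):
            best = -np.inf
            best_i = 0
            for i, a, logp in incoming[j]:
                score = delta[i] + logp + logB[a][t]
                if score > best:  # strict: first (lowest-index) winner kept on ties
                    best = score
                    best_i = i
            nxt[j] = best
            back[t, j] = best_i
        delta = nxt
    j = int(np.argmax(delta))  # argmax takes the lowest index on ties
    path = [j]
    for t in range(n - 1, 0, -1):
        j = int(back[t, j])
        path.append(j)
    path.reverse()
    return [machine.states[j] for j in path]


def model_distance(
    gen: CausalStateMachine, inf: CausalStateMachine, trace: Trace
) -> DistanceResult:
    """Rabiner model distance between two machines on one observation sequence.

    ``D = (log P(O | gen) - log P(O | inf)) / T`` in nats per sample.  Zero for
    statistically identical models; the sign is preserved (an inferred model
    may fit the particular realisation better than the generator).
    """
    if len(trace) == 0:
        raise ConfigurationError("model distance requires a nonempty trace")
    lg = forward_loglik(gen, trace)
    li = forward_loglik(inf, trace)
    return DistanceResult(
        distance=(lg - li) / len(trace),
        loglik_gen=lg,
        loglik_inf=li,
        length=len(trace),
    )
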