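"""Null-aware Causal State Splitting Reconstruction (CSSR).

Causal states are equivalence classes of history suffixes that share the same
conditional next-symbol distribution (their *morph*).  CSSR estimates them from
suffix counts: starting from the single state holding the empty history, each
history is extended one symbol into the past; a child whose morph differs
significantly from its parent state's is moved to the best-matching existing
state or founds a new one.  The resulting partition is then *determinised*
(split until each (state, symbol) pair has a unique successor), transient
states are removed, and transition probabilities are read off the pooled
continuation frequencies.

The adaptation for noisy symbolised data: subsequence counting only ever uses
windows of consecutive *certain* symbols.  Windows touching a null symbol are
discarded whole — deleting nulls and splicing the flanks would fabricate
transitions across uncertain gaps, whereas whole-window discarding (combined
with the equalised partition) censors every subsequence at the same rate and so
leaves the relative frequencies, hence the estimated transition probabilities,
unbiased.

Histories are tuples of symbols in time order; the *suffix* relation means the
child of history ``h`` under symbol ``a`` (one step further into the past) is
``(a,) + h``, while appending symbol ``a`` to the present turns ``h`` into
``h + (a,)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import chi2_contingency, ks_2samp

import numpy as np

from .discretize import NULL, MixtureModel, SymbolSequence
from .errors import ConfigurationError, InsufficientDataError, NonErgodicError
from .machine import CausalStateMachine, _terminal_sccs

__all__ = [
    "SuffixCounts",
    "CssrConfig",
    "count_windows",
    "suggest_max_length",
    "test_equivalence",
    "infer_causal_states",
    "determinize",
    "remove_transients",
    "prune_transitions",
    "attach_emissions",
]

History = tuple[int, ...]

log = logging.getLogger(__name__)

# Heuristic floor on expected counts per longest history for the test to have
# any power; below this, longer histories are not worth examining.
MIN_EXPECTED_PER_HISTORY = 25


@dataclass
class SuffixCounts:
    """Next-symbol counts of certain-symbol windows, per history length.

    ``counts[(h, a)]`` is the number of windows reading history ``h`` followed
    by symbol ``a``; only windows of ``len(h) + 1`` consecutive non-null
    symbols contribute.  ``n_certain_windows[m]`` is the number of length-``m``
    all-certain windows.
    """

    max_length: int
    alphabet: tuple[int, ...]
    counts: dict[tuple[History, int], int] = field(default_factory=dict)
    totals: dict[History, int] = field(default_factory=dict)
    n_certain_windows: dict[int, int] = field(default_factory=dict)

    def morph(self, h: History) -> np.ndarray:
        """Next-symbol count vector of history ``h`` (alphabet order)."""
        return np.array([self.counts.get((h, a), 0) for a in self.alphabet], dtype=float)

    def pooled_morph(self, histories) -> np.ndarray:
        v = np.zeros(len(self.alphabet))
        for h in histories:
            v += self.morph(h)
        return v


@dataclass(frozen=True)
class CssrConfig:
    """Knobs of the reconstruction.

    ``alpha`` is the significance level of the morph-equivalence test (0.05 by
    convention); ``max_length`` the longest history examined (``None`` lets
    :func:`suggest_max_length` pick it from the data volume); ``test`` is
    ``"chi2"`` or ``"ks"``; transitions with probability below
    ``prune_threshold`` are dropped after inference (0 disables pruning).
    """

    alpha: float = 0.05
    max_length: int | None = 2
    test: str = "chi2"
    prune_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.max_length is not None and self.max_length < 1:
            raise ConfigurationError("max_length must be >= 1")
        if not 0 <= self.prune_threshold < 1:
            raise ConfigurationError("prune_threshold must be in [0, 1)")
        if self.test not in ("chi2", "ks"):
            raise ConfigurationError(f"unknown test {self.test!r}")


# ---------------------------------------------------------------------------
# counting


def count_windows(symbols: SymbolSequence | np.ndarray, max_length: int) -> SuffixCounts:
    """Count (history, next-symbol) continuations over all-certain windows.

    Windows of length ``m`` (for every ``m <= max_length + 1``) containing a
    null contribute nothing at that length; they are discarded whole, not
    spliced around the null.
    """
    if max_length < 1:
        raise ConfigurationError("max_length must be >= 1")
    arr = symbols.symbols if isinstance(symbols, SymbolSequence) else np.asarray(symbols, dtype=int)
    certain_alphabet = tuple(sorted(int(a) for a in np.unique(arr) if a != NULL))
    sc = SuffixCounts(max_length=max_length, alphabet=certain_alphabet)
    n = len(arr)
    ok = arr != NULL
    # prefix sums of certainty for O(1) window checks
    cum = np.concatenate([[0], np.cumsum(ok)])
    for m in range(1, max_length + 2):
        if m > n:
            sc.n_certain_windows[m] = 0
            continue
        starts = np.nonzero(cum[m:] - cum[:-m] == m)[0]
        sc.n_certain_windows[m] = len(starts)
        for s in starts:
            h = tuple(int(x) for x in arr[s : s + m - 1])
            a = int(arr[s + m - 1])
            sc.counts[(h, a)] = sc.counts.get((h, a), 0) + 1
            sc.totals[h] = sc.totals.get(h, 0) + 1
    if sc.n_certain_windows.get(2, 0) == 0:
        raise InsufficientDataError(
            "insufficient certain data: no adjacent pair of certain symbols"
        )
    return sc


def suggest_max_length(n_certain: int, k: int, alpha: float = 0.05) -> int:
    """Largest history length the data volume can support.

    Picks the largest ``L`` with an expected ``n_certain / k^L`` occurrences
    per length-``L`` history of at least 25, the usual floor for the
    equivalence test to have useful power; never below 1.
    """
    if k < 1:
        raise ConfigurationError("alphabet size must be >= 1")
    L = 1
    while n_certain / (k ** (L + 1)) >= MIN_EXPECTED_PER_HISTORY:
        L += 1
    return L


# ---------------------------------------------------------------------------
# equivalence testing


def test_equivalence(
    counts_a: np.ndarray, counts_b: np.ndarray, alpha: float = 0.05, test: str = "chi2"
) -> tuple[bool, float]:
    """Two-sample test that two next-symbol count vectors share one morph.

    Returns ``(equivalent, p_value)``; distinct iff ``p < alpha``.  The default
    is a chi-squared homogeneity test on the 2xK contingency table with
    pooled-expected cells; cells whose pooled expectation falls below 1 are
    merged into their neighbour.  ``test="ks"`` uses a two-sample KS statistic
    on the symbol CDFs instead.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    na, nb = a.sum(), b.sum()
    if na <= 0 or nb <= 0:
        raise ConfigurationError("both count vectors must have positive totals")
    if test == "ks":
        xa = np.repeat(np.arange(len(a)), a.astype(int))
        xb = np.repeat(np.arange(len(b)), b.astype(int))
        p = float(ks_2samp(xa, xb).pvalue)
        return p >= alpha, p
    pooled = (a + b) / (na + nb)
    # merge cells with tiny pooled expectation into the previous kept cell
    exp_min = np.minimum(pooled * na, pooled * nb)
    groups: list[list[int]] = []
    for i in np.argsort(-pooled):  # large cells first so small ones join them
        if groups and exp_min[i] < 1.0:
            groups[-1].append(i)
        else:
            groups.append([i])
    A = np.array([a[g].sum() for g in groups])
    B = np.array([b[g].sum() for g in groups])
    if len(groups) < 2:
        return True, 1.0
    if np.array_equal(A / na, B / nb):
        return True, 1.0
    # scipy applies Yates' continuity correction for 2x2 tables (dof == 1),
    # the standard small-sample safeguard for this homogeneity test
    _stat, p, _dof, _exp = chi2_contingency(np.vstack([A, B]))
    p = float(p)
    return p >= alpha, p


# ---------------------------------------------------------------------------
# state splitting (CSSR phases I-II)


def infer_causal_states(
    counts: SuffixCounts, config: CssrConfig
) -> list[set[History]]:
    """Partition observed histories into estimated causal states.

    Phase I/II of CSSR: the empty history seeds the first state; for each
    length ``l < max_length``, every history in every state is extended one
    symbol into the past and the child's morph is tested against its parent
    state's pooled morph.  A rejected child joins the existing state with the
    highest test p-value above ``alpha``, or founds a new state.  Assignments
    are re-tested until stable at each length.  Histories never observed are
    not instantiated.
    """
    L = config.max_length if config.max_length is not None else counts.max_length
    if L > counts.max_length:
        raise ConfigurationError(
            f"max_length {L} exceeds counted window depth {counts.max_length}"
        )
    if () not in counts.totals:
        raise InsufficientDataError("no certain symbols at all")

    states: list[set[History]] = [{()}]
    assignment: dict[History, int] = {(): 0}

    def state_morph(si: int, exclude: History | None = None) -> np.ndarray:
        hs = [h for h in states[si] if h != exclude]
        if not hs:
            return counts.morph(exclude)  # singleton state: compare to itself
        return counts.pooled_morph(hs)

    def place(h: History) -> int:
        """Index of the state history ``h`` should live in (given others fixed)."""
        parent_si = assignment[h]
        m = counts.morph(h)
        ref = state_morph(parent_si, exclude=h)
        equiv, _p = test_equivalence(m, ref, config.alpha, config.test)
        if equiv:
            return parent_si
        best_si, best_p = None, config.alpha
        for si in range(len(states)):
            if si == parent_si or not states[si]:
                continue
            ok, p = test_equivalence(m, state_morph(si), config.alpha, config.test)
            if ok and p > best_p:
                best_si, best_p = si, p
        if best_si is not None:
            return best_si
        return -1  # new state

    for length in range(L):
        # children of all length-`length` histories, in deterministic order
        parents = sorted(h for h in assignment if len(h) == length)
        children = []
        for h in parents:
            for a in counts.alphabet:
                child = (a,) + h
                if counts.totals.get(child, 0) > 0:
                    children.append(child)
        children.sort()
        # tentatively seed each child in its parent's state
        for child in children:
            parent = child[1:]
            si = assignment[parent]
            states[si].add(child)
            assignment[child] = si
        # relax to a fixed point: move children whose morph rejects their state
        for _sweep in range(100):
            moved = False
            for child in children:
                si = assignment[child]
                target = place(child)
                if target == -1:
                    states.append(set())
                    target = len(states) - 1
                if target != si:
                    states[si].discard(child)
                    states[target].add(child)
                    assignment[child] = target
                    moved = True
            if not moved:
                break
    return [s for s in states if s]


# ---------------------------------------------------------------------------
# determinisation (phase III) and finalisation


def _successor_history(h: History, a: int, counts: SuffixCounts) -> History | None:
    """Longest instantiated suffix of ``h + (a,)`` (None if unobserved)."""
    ext = h + (a,)
    if len(ext) > counts.max_length:
        ext = ext[len(ext) - counts.max_length :]
    while True:
        if counts.totals.get(ext, 0) > 0:
            return ext
        if not ext:
            return None
        ext = ext[1:]


def determinize(
    states: list[set[History]], counts: SuffixCounts
) -> CausalStateMachine:
    """Split states until each (state, symbol) pair has a unique successor.

    For each member history ``h`` and symbol ``a``, the successor is the state
    holding the (longest instantiated suffix of) ``h + (a,)``.  Histories whose
    continuation was never observed cast no vote; when voters disagree the
    state is split by successor, non-voters joining the first group.  Iterates
    to a fixed point, then reads transition probabilities off the pooled
    continuation frequencies.
    """
    if not states or all(not s for s in states):
        raise ConfigurationError("empty state partition")
    parts: list[set[History]] = [set(s) for s in states if s]

    def locate(h: History) -> int | None:
        for si, s in enumerate(parts):
            if h in s:
                return si
        return None

    changed = True
    while changed:
        changed = False
        for si in range(len(parts)):
            for a in counts.alphabet:
                votes: dict[History, int | None] = {}
                for h in sorted(parts[si]):
                    if counts.counts.get((h, a), 0) == 0:
                        votes[h] = None
                        continue
                    succ = _successor_history(h, a, counts)
                    votes[h] = None if succ is None else locate(succ)
                targets = sorted({t for t in votes.values() if t is not None})
                if len(targets) > 1:
                    # split by successor; non-voters follow the first target group
                    groups: dict[int, set[History]] = {t: set() for t in targets}
                    for h, t in votes.items():
                        groups[t if t is not None else targets[0]].add(h)
                    ordered = [groups[t] for t in targets]
                    parts[si] = ordered[0]
                    parts.extend(ordered[1:])
                    changed = True
                    break
            if changed:
                break

    parts = [s for s in parts if s]
    names = _state_names(parts)
    name_of = {}
    for si, s in enumerate(parts):
        for h in s:
            name_of[h] = names[si]

    def is_maximal(h: History) -> bool:
        """No longer instantiated history refines h's context.

        A history's windows are the union of its one-symbol-longer children's
        (plus boundary effects), so pooling a history together with its
        children would count the same windows twice; probability estimates use
        only the maximal members of each state.
        """
        if len(h) >= counts.max_length:
            return True
        return not any(counts.totals.get((a,) + h, 0) > 0 for a in counts.alphabet)

    raw: dict[tuple[str, int], tuple[str, int]] = {}  # (state, symbol) -> (succ, count)
    for si, s in enumerate(parts):
        pooled = {a: 0 for a in counts.alphabet}
        succ_of: dict[int, str] = {}
        for h in s:
            for a in counts.alphabet:
                c = counts.counts.get((h, a), 0)
                if c == 0:
                    continue
                if is_maximal(h):
                    pooled[a] += c
                succ = _successor_history(h, a, counts)
                if succ is not None:
                    succ_of[a] = name_of[succ]
        # a state of non-maximal histories only (rare): fall back to all members
        if sum(pooled.values()) == 0:
            for h in s:
                for a in counts.alphabet:
                    pooled[a] += counts.counts.get((h, a), 0)
        for a, c in pooled.items():
            if c > 0 and a in succ_of:
                raw[(names[si], a)] = (succ_of[a], c)

    # drop states left with no observed outgoing continuation (and edges into
    # them) until consistent
    keep = {s for (s, _a) in raw}
    while True:
        filtered = {
            (s, a): (t, c) for (s, a), (t, c) in raw.items() if s in keep and t in keep
        }
        still = {s for (s, _a) in filtered}
        if still == keep:
            raw = filtered
            break
        keep = still
    if not raw:
        raise InsufficientDataError("no state has an observed continuation")

    rows: dict[str, int] = {}
    for (s, _a), (_t, c) in raw.items():
        rows[s] = rows.get(s, 0) + c
    transitions = {(s, a): (t, c / rows[s]) for (s, a), (t, c) in raw.items()}
    trans_counts = {(s, a): c for (s, a), (t, c) in raw.items()}
    kept = sorted(keep, key=names.index)
    suffixes = {names[si]: set(s) for si, s in enumerate(parts) if names[si] in keep}
    return CausalStateMachine(
        states=kept,
        alphabet=list(counts.alphabet),
        transitions=transitions,
        suffixes=suffixes,
        counts=trans_counts,
    )


def _state_names(parts: list[set[History]]) -> list[str]:
    """Stable, human-readable state ids: S0, S1, ... in shortest-suffix order."""
    keys = [min((len(h), h) for h in s) for s in parts]
    order = sorted(range(len(parts)), key=lambda i: keys[i])
    names = [""] * len(parts)
    for rank, i in enumerate(order):
        names[i] = f"S{rank}"
    return names


def remove_transients(machine: CausalStateMachine) -> CausalStateMachine:
    """Restrict the machine to its unique terminal strongly-connected component.

    States that cannot be returned to are artefacts of short-history seeding;
    dropping them leaves the recurrent machine on which stationary analysis is
    well-posed.  More than one terminal component means the sequence mixes
    irreconcilable regimes and is an error.
    """
    terminals = _terminal_sccs(machine)
    if len(terminals) != 1:
        raise NonErgodicError(
            "no unique recurrent class: "
            + ", ".join(sorted("{" + ",".join(sorted(t)) + "}" for t in terminals))
        )
    keep = sorted(terminals[0], key=machine.states.index)
    if set(keep) == set(machine.states):
        return machine
    transitions = {}
    counts = {}
    rows: dict[str, float] = {}
    for (s, a), (t, p) in machine.transitions.items():
        if s in terminals[0] and t in terminals[0]:
            transitions[(s, a)] = (t, p)
            rows[s] = rows.get(s, 0.0) + p
            if machine.counts and (s, a) in machine.counts:
                counts[(s, a)] = machine.counts[(s, a)]
    transitions = {(s, a): (t, p / rows[s]) for (s, a), (t, p) in transitions.items()}
    return CausalStateMachine(
        states=keep,
        alphabet=list(machine.alphabet),
        transitions=transitions,
        suffixes={s: machine.suffixes.get(s, set()) for s in keep},
        emissions=machine.emissions,
        counts=counts or None,
    )


def prune_transitions(
    machine: CausalStateMachine, threshold: float
) -> CausalStateMachine:
    """Drop transitions with probability below ``threshold`` and renormalise.

    Rare misassignments of points in the far tails of the mixture components
    show up as spurious low-probability edges; they are easily identified
    because genuine transitions carry much larger probability.  Transient
    removal is re-run afterwards.  Raises if pruning disconnects the machine.
    """
    if not 0 <= threshold < 1:
        raise ConfigurationError("threshold must be in [0, 1)")
    if threshold == 0:
        return machine
    transitions = {}
    counts = {}
    rows: dict[str, float] = {}
    for (s, a), (t, p) in machine.transitions.items():
        if p < threshold:
            log.info("pruned transition (%s, %s) -> %s with p=%.4g", s, a, t, p)
            continue
        transitions[(s, a)] = (t, p)
        rows[s] = rows.get(s, 0.0) + p
        if machine.counts and (s, a) in machine.counts:
            counts[(s, a)] = machine.counts[(s, a)]
    if not transitions or set(rows) != set(machine.states):
        raise NonErgodicError(
            "pruning removed every outgoing transition of some state; "
            "try a lower threshold"
        )
    transitions = {(s, a): (t, p / rows[s]) for (s, a), (t, p) in transitions.items()}
    pruned = CausalStateMachine(
        states=list(machine.states),
        alphabet=list(machine.alphabet),
        transitions=transitions,
        suffixes=dict(machine.suffixes),
        emissions=machine.emissions,
        counts=counts or None,
    )
    try:
        return remove_transients(pruned)
    except NonErgodicError as exc:
        raise NonErgodicError(
            f"pruning at threshold {threshold} disconnected the machine "
            f"({exc}); try a lower threshold"
        ) from exc


def attach_emissions(
    machine: CausalStateMachine, mixture: MixtureModel
) -> CausalStateMachine:
    """Bind symbol ``i`` to mixture component ``i`` (ascending-mean order).

    This turns the reconstructed symbolic machine into a generative model of
    the raw continuous trace, directly comparable with a generating machine
    through the model distance.
    """
    if len(machine.alphabet) != mixture.k:
        raise ConfigurationError(
            f"alphabet size {len(machine.alphabet)} != component count {mixture.k}"
        )
    comps = sorted(mixture.components, key=lambda c: c.mean)
    emissions = {a: comps[i] for i, a in enumerate(sorted(machine.alphabet))}
    return CausalStateMachine(
        states=list(machine.states),
        alphabet=list(machine.alphabet),
        transitions=dict(machine.transitions),
        suffixes=dict(machine.suffixes),
        emissions=emissions,
        counts=dict(machine.counts) if machine.counts else None,
    )
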