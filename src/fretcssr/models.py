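"""Hand-built generating machines for simulation studies.

These are the built-in study conditions: a two-state switcher emulating a
typical two-level smFRET system, and a four-state machine with two *degenerate*
states — distinct hidden states sharing one observable level, distinguishable
only through transition structure.  Defaults reproduce the standard simulation
setups (two-state: levels 0.3/0.7, sd 0.1; degenerate: levels 0.1/0.5/0.9,
sd 0.09).
"""

from __future__ import annotations

from .machine import CausalStateMachine, GaussianComponent

__all__ = ["two_state_machine", "degenerate_four_state_machine"]


def two_state_machine(
    stay: float = 0.9,
    means: tuple[float, float] = (0.3, 0.7),
    sd: float = 0.1,
) -> CausalStateMachine:
    """Two-state switcher; the emitted symbol is the destination state's level.

    Each state stays with probability ``stay`` (emitting its own level) and
    switches with ``1 - stay`` (emitting the other level), the classic
    two-level smFRET kinetic scheme.
    """
    if not 0 < stay < 1:
        raise ValueError("stay probability must be in (0, 1)")
    switch = 1.0 - stay
    return CausalStateMachine(
        states=["L", "H"],
        alphabet=[0, 1],
        transitions={
            ("L", 0): ("L", stay),
            ("L", 1): ("H", switch),
            ("H", 1): ("H", stay),
            ("H", 0): ("L", switch),
        },
        emissions={
            0: GaussianComponent(0.5, means[0], sd),
            1: GaussianComponent(0.5, means[1], sd),
        },
    )


def degenerate_four_state_machine(
    stay_a: float = 0.95,
    stay_d: float = 0.60,
    means: tuple[float, float, float] = (0.1, 0.5, 0.9),
    sd: float = 0.09,
) -> CausalStateMachine:
    """Four-state machine with two degenerate states at the lowest level.

    States ``A`` and ``D`` both emit the lowest level (symbol 0) but with
    different persistence (``stay_a`` vs ``stay_d``); ``B`` emits the middle
    level and ``C`` the highest.  ``A`` is reached from ``B`` and ``D`` from
    ``C``, so the two degenerate states occur in distinct observable contexts
    ``(1, 0)`` vs ``(2, 0)`` and the transition structure — not the emission —
    is what separates them.  Any method forced to assign one state per
    observable level can recover at most three states from traces of this
    machine.

    Because both degenerate states self-loop on symbol 0, a run of 0s never
    fully identifies the hidden state; the free transition probabilities here
    are balanced so the minority state ``D`` stays rare enough
    (``pi_D / pi_A`` about 0.05) that ambiguous 0-run contexts are dominated
    by ``A``, while the ``C -> D`` flux keeps the revealing ``(2, 0)`` context
    well sampled.
    """
    return CausalStateMachine(
        states=["A", "B", "C", "D"],
        alphabet=[0, 1, 2],
        transitions={
            ("A", 0): ("A", stay_a),
            ("A", 1): ("B", 1.0 - stay_a),
            ("B", 1): ("B", 0.58),
            ("B", 0): ("A", 0.30),
            ("B", 2): ("C", 0.12),
            ("C", 2): ("C", 0.8),
            ("C", 0): ("D", 0.2),
            ("D", 0): ("D", stay_d),
            ("D", 1): ("B", 1.0 - stay_d),
        },
        emissions={
            0: GaussianComponent(1 / 3, means[0], sd),
            1: GaussianComponent(1 / 3, means[1], sd),
            2: GaussianComponent(1 / 3, means[2], sd),
        },
    )
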