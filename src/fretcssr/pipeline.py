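"""End-to-end inference: raw trace -> symbolised data -> causal-state machine.

``fit_pipeline`` chains the discretisation (mixture fit, AIC selection,
permille partition, mass equalisation, symbolisation) with the null-aware CSSR
reconstruction and emission attachment, returning everything an analysis
needs: the mixture, the partition, the symbol sequence and the final machine.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

from .cssr import (
    CssrConfig,
    SuffixCounts,
    attach_emissions,
    count_windows,
    determinize,
    infer_causal_states,
    prune_transitions,
    remove_transients,
    suggest_max_length,
)
from .discretize import (
    MixtureModel,
    Partition,
    SymbolSequence,
    build_partition,
    equalize_partition,
    fit_mixture,
    rank_mixtures,
    symbolize,
)
from .errors import ConfigurationError, PartitionError
from .machine import CausalStateMachine, Trace

__all__ = ["PipelineConfig", "PipelineResult", "fit_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the trace-to-machine pipeline.

    Defaults follow common practice for sparse single-molecule spectra:
    permille partition quantile, 5% test level, mixture sizes up to four
    unless ``k_fixed`` pins the component count.
    """

    q: float = 0.001
    k_max: int = 4
    k_fixed: int | None = None
    alpha: float = 0.05
    max_length: int | None = None  # None: choose from the certain-data volume
    test: str = "chi2"
    prune_threshold: float = 0.0
    criterion: str = "aic"
    dt: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q < 0.5:
            raise ConfigurationError("q must be in (0, 0.5)")
        if self.criterion not in ("aic", "bic"):
            raise ConfigurationError("criterion must be 'aic' or 'bic'")
        CssrConfig(
            alpha=self.alpha,
            max_length=self.max_length if self.max_length is not None else 1,
            test=self.test,
            prune_threshold=self.prune_threshold,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


@dataclass
class PipelineResult:
    """Everything produced along the trace-to-machine pipeline."""

    mixture: MixtureModel
    partition: Partition
    symbols: SymbolSequence
    counts: SuffixCounts
    max_length: int
    machine: CausalStateMachine
    config: PipelineConfig
    timings: dict[str, float] = field(default_factory=dict)


def fit_pipeline(trace: Trace, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Infer a Gaussian-observed causal-state machine from a raw trace.

    Steps: select a Gaussian mixture (AIC over ``1..k_max`` or fixed K),
    build and equalise the certain/uncertain partition at tail quantile ``q``,
    symbolise, count null-free windows, run the adapted CSSR at significance
    ``alpha`` and history depth ``max_length`` (chosen from the certain-data
    volume if unset), determinise, drop transients, optionally prune spurious
    low-probability edges, and attach the fitted emissions.
    """
    timings: dict[str, float] = {}

    # Information criteria can overfit the mixture (extra, heavily overlapping
    # components); such fits admit no certain/uncertain partition.  When the
    # preferred mixture has none, fall back to the next-best candidate by the
    # criterion — the same recourse as constraining the component count by hand.
    t0 = time.perf_counter()
    if config.k_fixed is not None:
        candidates = [fit_mixture(trace.values, config.k_fixed, seed=config.seed)]
    else:
        candidates = rank_mixtures(
            trace.values, k_max=config.k_max, seed=config.seed, criterion=config.criterion
        )
    mixture = partition = None
    for cand in candidates:
        try:
            partition = equalize_partition(build_partition(cand, q=config.q), cand)
            mixture = cand
            break
        except PartitionError as exc:
            log.warning("K=%d mixture admits no partition (%s)", cand.k, exc)
    if mixture is None or partition is None:
        raise PartitionError(
            "no fitted mixture admits a valid certain/uncertain partition"
        )
    timings["mixture"] = time.perf_counter() - t0
    log.info("selected K=%d mixture (aic=%.1f)", mixture.k, mixture.aic)

    t0 = time.perf_counter()
    symbols = symbolize(trace, partition)
    timings["discretize"] = time.perf_counter() - t0
    log.info(
        "symbolised %d points, %d certain (%.1f%%)",
        len(symbols),
        symbols.n_certain,
        100 * symbols.n_certain / max(len(symbols), 1),
    )

    t0 = time.perf_counter()
    L = config.max_length
    if L is None:
        L = suggest_max_length(symbols.n_certain, mixture.k, config.alpha)
        log.info("chose max history length %d", L)
    counts = count_windows(symbols, max_length=L)
    cssr_cfg = CssrConfig(
        alpha=config.alpha,
        max_length=L,
        test=config.test,
        prune_threshold=config.prune_threshold,
        seed=config.seed,
    )
    states = infer_causal_states(counts, cssr_cfg)
    machine = remove_transients(determinize(states, counts))
    if config.prune_threshold > 0:
        machine = prune_transitions(machine, config.prune_threshold)
    machine = attach_emissions(machine, mixture)
    timings["cssr"] = time.perf_counter() - t0
    log.info("inferred %d-state machine", machine.n_states)

    return PipelineResult(
        mixture=mixture,
        partition=partition,
        symbols=symbols,
        counts=counts,
        max_length=L,
        machine=machine,
        config=config,
        timings=timings,
    )
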