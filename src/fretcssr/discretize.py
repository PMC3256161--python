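"""Mixture-based symbolisation of noisy, discretely-clustered signals.

The observable (e.g. a FRET efficiency) clusters around a handful of discrete
levels, each well approximated by a Gaussian.  The pipeline here:

1. fit Gaussian mixtures with ``k = 1..k_max`` components (EM, multiple
   restarts) and select ``K`` by AIC (BIC optionally);
2. place ``2K`` partition boundaries where each component's tail probability
   reaches a small quantile ``q`` (default one permille);
3. label the region inside exactly one component's quantile interval as that
   component's *certain* region; overlaps and extreme tails are *uncertain*;
4. equalise the per-component probability mass kept in the certain regions by
   shrinking the wider regions toward their means — without this, components
   would be censored at different rates and the relative frequencies of
   subsequences (hence the inferred transition probabilities) would be biased;
5. map each sample to its region's symbol, with a null symbol ``U`` for the
   uncertain regions.

Symbols are integers ``0..K-1`` in ascending order of component mean;
:data:`NULL` (= -1) marks uncertainty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import ConfigurationError, DegenerateFitError, PartitionError
from .machine import GaussianComponent, Trace

__all__ = [
    "NULL",
    "MixtureModel",
    "Partition",
    "SymbolSequence",
    "fit_mixture",
    "select_mixture",
    "build_partition",
    "equalize_partition",
    "symbolize",
]

NULL: int = -1
"""Null symbol: the observation cannot be confidently assigned to one level."""

SD_FLOOR = 1e-4

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixtureModel:
    """A fitted K-component Gaussian mixture, components sorted by mean."""

    components: tuple[GaussianComponent, ...]
    loglik: float
    n_params: int
    aic: float
    bic: float | None = None

    @property
    def k(self) -> int:
        return len(self.components)

    def component(self, i: int) -> GaussianComponent:
        return self.components[i]


@dataclass(frozen=True)
class Partition:
    """Certain/uncertain partition of the signal axis.

    ``boundaries`` are the ``2K`` sorted endpoints of the K disjoint certain
    intervals; ``region_labels`` has one entry per region (``2K + 1`` of them,
    alternating ``NULL, 0, NULL, 1, ..., K-1, NULL``).  ``kept_fraction[i]`` is
    the probability mass of component ``i`` inside its certain region.
    """

    boundaries: tuple[float, ...]
    region_labels: tuple[int, ...]
    kept_fraction: tuple[float, ...]
    q: float

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if np.any(np.diff(b) < 0):
            raise PartitionError("partition boundaries must be sorted")
        if len(self.region_labels) != len(self.boundaries) + 1:
            raise PartitionError("need exactly one label per region")

    def certain_interval(self, i: int) -> tuple[float, float]:
        """The certain region ``[lo, hi]`` of component ``i``."""
        j = self.region_labels.index(i)
        return self.boundaries[j - 1], self.boundaries[j]


@dataclass(frozen=True)
class SymbolSequence:
    """Per-bin symbols over ``{0..K-1} U {NULL}`` with the trace's ``dt``."""

    symbols: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", np.asarray(self.symbols, dtype=int))

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_certain(self) -> int:
        return int((self.symbols != NULL).sum())

    def to_string(self, aliases: str | None = None) -> str:
        """Single-character rendering; null is ``'U'``.

        ``aliases`` optionally maps symbol ``i`` to ``aliases[i]`` (e.g. "LH").
        """
        chars = []
        for s in self.symbols:
            if s == NULL:
                chars.append("U")
            elif aliases is not None:
                chars.append(aliases[s])
            else:
                chars.append(str(s))
        return "".join(chars)


# ---------------------------------------------------------------------------
# mixture fitting


def fit_mixture(values: np.ndarray, k: int, seed: int = 0) -> MixtureModel:
    """Maximum-likelihood EM fit of a ``k``-component Gaussian mixture.

    Best of five restarts, deterministic given ``seed``.  A fit whose smallest
    standard deviation collapses below ``SD_FLOOR`` is degenerate and raises.
    """
    values = np.asarray(values, dtype=float)
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if len(values) < 3 * k:
        raise ConfigurationError(f"need at least {3 * k} points to fit k={k}")
    X = values.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=5,
        reg_covar=1e-10,
        random_state=seed,
        max_iter=500,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(X)
    sds = np.sqrt(gm.covariances_.ravel())
    if np.any(sds < SD_FLOOR):
        raise DegenerateFitError(
            f"mixture fit for k={k} collapsed (sd < {SD_FLOOR}) on all restarts"
        )
    order = np.argsort(gm.means_.ravel())
    comps = tuple(
        GaussianComponent(
            weight=float(gm.weights_[i]), mean=float(gm.means_[i, 0]), sd=float(sds[i])
        )
        for i in order
    )
    loglik = float(gm.score(X) * len(values))
    n_params = 3 * k - 1
    return MixtureModel(
        components=comps,
        loglik=loglik,
        n_params=n_params,
        aic=2 * n_params - 2 * loglik,
        bic=n_params * float(np.log(len(values))) - 2 * loglik,
    )


def rank_mixtures(
    values: np.ndarray, k_max: int = 4, seed: int = 0, criterion: str = "aic"
) -> list[MixtureModel]:
    """Fit ``k = 1..k_max`` and return the fits in ascending AIC (or BIC) order.

    Ties go to the smaller ``k``; sizes that fail to fit are skipped with a
    logged warning.
    """
    if k_max < 1:
        raise ConfigurationError("k_max must be >= 1")
    fits: list[MixtureModel] = []
    for k in range(1, k_max + 1):
        try:
            fits.append(fit_mixture(values, k, seed=seed))
        except (DegenerateFitError, ConfigurationError) as exc:
            log.warning("skipping k=%d: %s", k, exc)
    if not fits:
        raise DegenerateFitError("no mixture size could be fitted")
    key = (lambda f: (f.aic, f.k)) if criterion == "aic" else (lambda f: (f.bic, f.k))
    return sorted(fits, key=key)


def select_mixture(
    values: np.ndarray,
    k_max: int = 4,
    seed: int = 0,
    criterion: str = "aic",
    k_fixed: int | None = None,
) -> MixtureModel:
    """Fit ``k = 1..k_max`` and keep the fit with the lowest AIC (or BIC).

    Ties go to the smaller ``k``.  ``k_fixed`` bypasses selection entirely —
    useful when a drifting spectrum misleads the criterion but the number of
    levels is known.
    """
    if k_fixed is not None:
        return fit_mixture(values, k_fixed, seed=seed)
    return rank_mixtures(values, k_max=k_max, seed=seed, criterion=criterion)[0]


# ---------------------------------------------------------------------------
# partitioning


def build_partition(mixture: MixtureModel, q: float = 0.001) -> Partition:
    """Partition the signal axis at each component's ``q``/``1-q`` quantiles.

    A region is certain for component ``i`` iff it lies inside component
    ``i``'s quantile interval and no other component's; overlaps and the two
    unbounded tails are uncertain.  Components whose quantile interval nests
    entirely inside another's admit no valid partition.
    """
    if not 0 < q < 0.5:
        raise ConfigurationError(f"q must be in (0, 0.5), got {q}")
    comps = mixture.components
    z = norm.ppf(1 - q)
    lo = np.array([c.mean - z * c.sd for c in comps])
    hi = np.array([c.mean + z * c.sd for c in comps])

    for i in range(len(comps)):
        for j in range(len(comps)):
            if i != j and lo[j] <= lo[i] and hi[i] <= hi[j]:
                raise PartitionError(
                    f"component {i}'s quantile interval [{lo[i]:.4g}, {hi[i]:.4g}] nests "
                    f"inside component {j}'s [{lo[j]:.4g}, {hi[j]:.4g}]; "
                    "no valid partition exists"
                )

    # certain region of i: its own interval clipped by the neighbours' intervals
    bounds = []
    kept = []
    for i, c in enumerate(comps):
        left = lo[i] if i == 0 else max(lo[i], hi[i - 1])
        right = hi[i] if i == len(comps) - 1 else min(hi[i], lo[i + 1])
        if left >= right:
            raise PartitionError(
                f"component {i}'s certain region is empty (levels too close "
                "relative to their variances)"
            )
        bounds.extend([left, right])
        kept.append(_mass(c, left, right))

    labels = [NULL]
    for i in range(len(comps)):
        labels.extend([i, NULL])
    return Partition(
        boundaries=tuple(bounds),
        region_labels=tuple(labels),
        kept_fraction=tuple(kept),
        q=q,
    )


def _mass(c: GaussianComponent, lo: float, hi: float) -> float:
    return float(norm.cdf(hi, c.mean, c.sd) - norm.cdf(lo, c.mean, c.sd))


def equalize_partition(partition: Partition, mixture: MixtureModel) -> Partition:
    """Equalise per-component kept mass at the pre-adjustment minimum.

    Discarding different fractions of different components would skew the
    relative frequencies of subsequences in the symbolised data and bias the
    inferred transition probabilities; trimming every component to the same
    kept fraction preserves the original ratios.  Each component's excess mass
    is removed by moving its certain-region edges toward the mean, split in
    proportion to the mass already excluded on each side.
    """
    comps = mixture.components
    if len(partition.kept_fraction) != len(comps):
        raise ConfigurationError("partition and mixture component counts differ")
    target = min(partition.kept_fraction)
    bounds = list(partition.boundaries)
    kept = []
    for i, c in enumerate(comps):
        left, right = bounds[2 * i], bounds[2 * i + 1]
        f = _mass(c, left, right)
        excess = f - target
        if excess > 1e-15:
            excl_left = float(norm.cdf(left, c.mean, c.sd))
            excl_right = float(1.0 - norm.cdf(right, c.mean, c.sd))
            total_excl = excl_left + excl_right
            w_left = excl_left / total_excl if total_excl > 0 else 0.5
            new_left = float(norm.ppf(excl_left + excess * w_left, c.mean, c.sd))
            new_right = float(norm.ppf(1.0 - (excl_right + excess * (1 - w_left)), c.mean, c.sd))
            bounds[2 * i], bounds[2 * i + 1] = new_left, new_right
            kept.append(_mass(c, new_left, new_right))
        else:
            kept.append(f)
    return replace(
        partition, boundaries=tuple(bounds), kept_fraction=tuple(kept)
    )


def symbolize(trace: Trace | np.ndarray, partition: Partition) -> SymbolSequence:
    """Map each sample to its region's symbol; uncertain regions give NULL.

    Values landing exactly on a boundary are conservatively null (a
    measure-zero event for continuous data).
    """
    if isinstance(trace, Trace):
        values, dt = trace.values, trace.dt
    else:
        values, dt = np.asarray(trace, dtype=float), 1.0
    b = np.asarray(partition.boundaries)
    left = np.searchsorted(b, values, side="left")
    right = np.searchsorted(b, values, side="right")
    labels = np.asarray(partition.region_labels)
    symbols = labels[right]
    symbols[left != right] = NULL  # exactly on a boundary
    return SymbolSequence(symbols=symbols, dt=dt)
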