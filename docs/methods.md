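# Methods

## The model class

A machine here is a unifilar, symbol-emitting hidden Markov model: a finite
set of states; transitions labelled with a symbol from an alphabet of size
`K`; for each state the outgoing probabilities sum to one; and the pair
(state, symbol) determines the successor uniquely (unifilarity, also called
determinism). Each symbol optionally carries a Gaussian density
`N(μ_a, σ_a²)`, making the machine a generative model of a continuous trace:
at every time bin a transition is drawn from the current state, the symbol's
Gaussian is sampled for the observation, and the state advances. The hidden
path is reported as the state *after* each emission, which, under the
convention that a transition emits its destination's level, aligns state runs
with observable dwell periods.

Unifilar machines are exactly the form produced by causal-state
reconstruction: causal states are equivalence classes of past observation
windows ("histories", as symbol suffixes) sharing the same conditional
distribution of futures, and the minimal such partition is a sufficient
statistic for prediction. All analyses assume stationarity — transition
probabilities and emission parameters constant in time — and the initial
state law for both simulation and likelihoods is the stationary distribution
(the left fixed point of the state-to-state matrix), so no burn-in is needed.

Likelihoods use a scaled forward recursion over per-symbol transition
matrices (log-space normalisation each step; finite for traces of 10⁶+
samples). Decoding uses Viterbi with ties broken toward the lowest state
index. The model distance between a generating and an inferred machine on a
trace of length `T` is `D = [log P(O|λ_gen) − log P(O|λ_inf)] / T`, in nats
per sample (natural logarithms throughout; the statistical complexity — the
Shannon entropy of the stationary state distribution — is reported in bits).
`D` is evaluated on the same observation sequence used for inference. Because
the inferred machine's parameters are maximum-likelihood fits to that very
sequence, `D` can legitimately be slightly *negative* — the inferred model
beats the generator by roughly (number of fitted parameters)/2 nats in total,
i.e. a few thousandths of a nat per sample at `T = 1500`. Either sign, small
magnitude means the machines are statistically interchangeable on data of
this size.

## Discretisation with an explicit null symbol

* **Mixture fit.** 1-D Gaussian mixtures for `k = 1..k_max` (default 4) via
  EM (scikit-learn, 5 restarts, deterministic per seed, covariance floor
  `sd ≥ 10⁻⁴`; a fit collapsing below the floor is an error). Model size is
  chosen by AIC (`2(3k−1) − 2 log L`; BIC available). Information criteria
  can overfit — an extra, heavily overlapping component admits no valid
  partition — in which case the pipeline falls back to the next-best size by
  the criterion, the same recourse as constraining `K` by hand for a known
  number of levels (`k_fixed`).
* **Partition.** Each component claims the interval between its `q` and
  `1−q` normal quantiles (default `q = 0.001`, i.e. boundaries at
  `μ ± 3.09 σ`). A region is *certain* for component `i` iff it lies in
  component `i`'s interval and no other's; overlaps and the two unbounded
  tails are *uncertain*. A component whose interval nests inside another's
  (levels extremely close, or very unequal variances) admits no partition and
  is an error naming the components.
* **Equalisation.** The kept mass `∫ certain region` generally differs across
  components; censoring levels at different rates would bias the relative
  frequencies of symbol subsequences and hence every estimated transition
  probability. Each component's kept mass is therefore reduced to the
  pre-adjustment minimum by moving its certain edges toward the mean, the
  excess split in proportion to the mass already excluded on each side. This
  is solved in closed form with the normal quantile function (equivalent to
  root-finding on the CDF, exact to far below the 10⁻¹⁰ mass tolerance).
* **Symbolisation.** Each sample maps to its region's symbol, `0..K−1` in
  ascending-mean order, or the null symbol for uncertain regions. Values
  exactly on a boundary (measure-zero) are conservatively null. Note that
  changing `q` moves the outer tail boundaries and the overlap clips in
  opposite directions, so refinement is not monotone in the certain set; what
  always holds — and is tested — is that no change of `q` relabels one
  component's symbol as another's.

## Null-aware CSSR

Subsequence statistics come only from windows of consecutive certain symbols:
counts for length-`ℓ` histories use windows of `ℓ+1` certain symbols, and any
window touching a null is discarded whole. Splicing the flanks of a null
together would fabricate transitions across uncertain gaps; whole-window
discarding, combined with the equalised partition, censors every subsequence
at the same rate, which is what keeps relative frequencies unbiased. A
sequence with no two adjacent certain symbols cannot be modelled
("insufficient certain data").

State splitting starts from one state holding the empty history. For each
length `ℓ < L_max`, every history in every state is extended one symbol into
the past; the child's next-symbol distribution is tested against its parent
state's pooled distribution (two-sample chi-squared homogeneity; cells with
pooled expectation below 1 merged; Yates' continuity correction applies at
one degree of freedom — without it, low-count contexts split off on ~2σ
fluctuations). A rejected child joins the existing state with the highest
p-value above `α` (default 0.05), or founds a new state; assignments are
re-swept to a fixed point at each length. History enumeration is by length
then lexicographic order, fixing all tie-breaks; unobserved histories are
never instantiated. `L_max` defaults to the largest `L` with at least 25
expected occurrences per length-`L` history (`n_certain / K^L ≥ 25`), the
floor below which the test has little power.

Determinisation then splits states whose member histories disagree on the
successor state under some symbol (successor = state of the longest
instantiated suffix of `h·a`); histories with no observed continuation cast
no vote and follow the first voter group. Transition probabilities are pooled
continuation frequencies over each state's *maximal* member histories — a
history's windows are a subset of the union of its children's, so pooling
nested histories would double-count windows, inflate variance, and overstate
the binomial sample sizes attached to the estimates. Finally the machine is
restricted to its unique terminal strongly-connected component (short-history
seed states are transient); transitions below a user threshold can be pruned
(off by default — far-tail misassignments appear as conspicuously
low-probability edges and are easy to identify), and symbol `i` is bound to
mixture component `i` so the machine becomes a generative model of the raw
trace, directly comparable to a generator through the model distance.

## Kinetics

Rates are per-bin transition probabilities divided by the sampling interval
(`rate = p / Δt`, in s⁻¹; valid while `p ≪ 1`), reported for inter-state
transitions only. Rates pooled over traces are combined by taking logs,
averaging, and exponentiating (geometric mean with log-space sd), since rate
estimates spread multiplicatively. Dwell times come from run-length encoding
a decoded state path; the first and last runs are censored and excluded from
the exponential maximum-likelihood fit (`rate = 1/mean`; histogram and fitted
curve returned for overlay plots; at least 5 uncensored dwells required).
Because observations are time-binned, bins containing a transition tend to
fall in the uncertain region and be discarded, so probability- and
dwell-derived rates are both biased slightly low at coarse sampling; at stay
probability ≥ 0.8 and a few thousand samples the two estimators agree within
~15%.

The stationarity check splits the symbolised record in half and compares the
next-symbol distribution of every length-1 history between halves; any
rejection at `α` fails the trace (the typical culprit being a level drifting
across the partition, for which no model exists — such traces are rejected,
not repaired). The marginal symbol frequencies of the halves are reported for
inspection but excluded from the verdict: marginals of a persistent chain are
strongly autocorrelated, and a count-based test on them rejects ~19% of
perfectly stationary replicates at `α = 0.05` (measured), whereas
conditioning on the previous symbol restores calibration. This diagnostic is
a reconstruction of intent — a split-half homogeneity test plus dwell
exponentiality plots — not a transcription of a published procedure.

## Built-in study conditions

The simulator defaults encode the two standard validation setups:

* **Two-state system** — emission means 0.3 and 0.7, sd 0.1, stay probability
  0.9 per state, 1500 samples. With `q = 0.001` about 82% of bins are
  certain; the pipeline recovers the two-state architecture and transition
  probabilities within binomial error, and the generator-vs-inferred model
  distance is of order 10⁻³ nats/sample.
* **Degenerate four-state system** — emission means 0.1/0.5/0.9, sd 0.09,
  5000 samples; states A and D both emit the 0.1 level with self-transition
  probabilities 0.95 and 0.60. Because both degenerate states self-loop on
  the same symbol, a run of that symbol never fully identifies the hidden
  state (the symbol process is non-synchronizable), and ambiguous 0-run
  contexts are mixtures of A and D. The free transition probabilities
  (B→A 0.30, B self 0.58, B→C 0.12, C self 0.80, C→D 0.20, D→B 0.40) were
  chosen by a power analysis so that the minority state D is rare enough
  (π_D/π_A ≈ 0.05) for the mixture contexts to sit within test noise of the
  A-state, while the C→D flux keeps the context that reveals D — a 0
  following a 2 — sampled ~40 times per trace. Under these conditions the
  majority of seeded runs recover exactly four states, more than the three
  observable levels. The exact generator edge set is not recoverable at
  history depth 2 (the D self-loop's continuation is absorbed by the
  dominant 0-run context); the architecture claim validated is the state
  count.

## What the simulations do and do not show

The generator emits i.i.d. Gaussian noise about fixed levels with
memoryless switching — no level drift, no camera time-averaging over
transitions, no photophysics (blinking/bleaching), and no heavy-tailed or
skewed noise. Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions; on real spectra the
known additional effects (drift, coarse time binning) bias rates low and can
defeat the discretisation entirely, which is why the stationarity check and
the partition-failure errors exist. Drifting traces are detected and
rejected, not corrected.

## Numerical choices

Probability rows are validated to 10⁻⁶; stationary distributions solve the
fixed point by least squares with a normalisation row (residual below 10⁻⁹);
forward/Viterbi run in log space; EM uses `reg_covar = 10⁻¹⁰` so the `k = 1`
fit matches the closed-form MLE to ~10⁻⁶; machine JSON serialisation is
lossless and byte-stable, making full pipeline runs reproducible
(seed + input ⇒ identical machine file). Test problem sizes (traces of
500–5000 samples, 20–50 seeded replicates) are chosen to hold Monte-Carlo
noise well below the tested tolerances while keeping the suite quick on a
single CPU.

## Non-goals

FRET efficiency computation from raw donor/acceptor intensities, drift
correction, non-Gaussian emission families, continuous-time (rate-matrix)
models, Baum–Welch refinement, and Bayesian/variational HMM inference are out
of scope.
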