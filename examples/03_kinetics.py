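"""Physical kinetics from an inferred machine and its decoded state path.

Per-bin transition probabilities divide by the sampling interval (41 ms here)
to give first-order rates in 1/s; rates pooled over several traces average
geometrically.  The Viterbi-decoded most probable state path yields dwell
times whose exponential MLE is an independent estimate of the same escape
rates — the two should agree for well-sampled memoryless kinetics.
"""

from fretcssr import (
    PipelineConfig,
    aggregate_rates,
    dwell_times,
    fit_exponential_dwell,
    fit_pipeline,
    simulate_trace,
    transition_rates,
    viterbi_path,
)
from fretcssr.models import two_state_machine

DT = 0.041  # 41 ms per point

gen = two_state_machine(stay=0.9)
per_trace: dict[str, list[float]] = {}
for seed in (1, 2, 3):
    trace, _, _ = simulate_trace(gen, 3000, seed=seed, dt=DT)
    res = fit_pipeline(trace, PipelineConfig(max_length=2, seed=seed))
    for r in transition_rates(res.machine, dt=DT):
        label = f"level {res.machine.emissions[r.symbol].mean:.1f} entry"
        per_trace.setdefault(label, []).append(r.rate)

print(f"switching rates over 3 traces (true rate {0.1 / DT:.2f}/s):")
for summary in aggregate_rates(per_trace):
    print(
        f"  {summary.transition}: geometric mean {summary.geometric_mean_rate:.2f}/s "
        f"(log-sd {summary.log_sd:.2f}, n={summary.n_traces})"
    )

trace, _, _ = simulate_trace(gen, 5000, seed=7, dt=DT)
path = viterbi_path(gen, trace)
for state, dwell in dwell_times(path, dt=DT).items():
    rate, _edges, _freq, _curve = fit_exponential_dwell(dwell)
    print(
        f"  state {state}: {len(dwell.durations)} dwells, "
        f"mean {1 / rate:.2f} s, escape rate {rate:.2f}/s"
    )
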