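"""Detect a drifting trace before trying to model it.

The whole reconstruction assumes stationary transition statistics; a FRET
level drifting across the partition produces symbol statistics that differ
between the two halves of the record, and no meaningful machine exists for
such data.  The check compares the next-symbol distribution of each length-1
history between the halves; any rejection at the 5% level fails the trace.
"""

import numpy as np

from fretcssr import (
    GaussianComponent,
    PipelineConfig,
    Trace,
    build_partition,
    equalize_partition,
    fit_pipeline,
    simulate_trace,
    stationarity_check,
    symbolize,
)
from fretcssr.discretize import MixtureModel
from fretcssr.models import two_state_machine

# stationary trace: should pass
trace, _, _ = simulate_trace(two_state_machine(), 2000, seed=5)
res = fit_pipeline(trace, PipelineConfig(max_length=1, seed=5))
report = stationarity_check(res.symbols)
print(f"stationary two-state trace: {report.status}")
for label, p in report.comparisons:
    print(f"  {label}: p = {p:.3f}")

# drifting trace: occupancy slides from the low to the high level
rng = np.random.default_rng(6)
n = 2000
p_high = np.linspace(0.1, 0.9, n)
levels = np.where(rng.random(n) < p_high, 0.7, 0.3)
values = rng.normal(levels, 0.1)
mix = MixtureModel(
    components=(GaussianComponent(0.5, 0.3, 0.1), GaussianComponent(0.5, 0.7, 0.1)),
    loglik=0.0,
    n_params=5,
    aic=0.0,
)
part = equalize_partition(build_partition(mix, 0.001), mix)
report = stationarity_check(symbolize(Trace(values), part))
print(f"drifting trace: {report.status} (expected: fail)")
for label, p in report.comparisons:
    print(f"  {label}: p = {p:.4f}")
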