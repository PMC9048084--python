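"""Train the GRU detector on one training quad and watch its output.

Uses a reduced search budget so the example runs in about a minute; the
full benchmark uses deeper training.  The trained network's output y stays
below 0 on an unseen error-free delivery and crosses 0 early on an unseen
error delivery (y > 0 signifies an error).
"""

import numpy as np

from portalwatch import (
    DeliverySpec,
    ErrorSpec,
    ObjectiveSpec,
    SearchConfig,
    TrainingCase,
    forward,
    metric_stream,
    random_search,
    simulate_delivery,
)
from portalwatch.simulate import FULL_ERROR_CASES, PARTIAL_ERROR_CASES

def stream_for(pid, error, seed):
    spec = DeliverySpec(patient_id=pid, error=error, seed=seed)
    return metric_stream(simulate_delivery(spec), patient_id=pid, error=error)

print("simulating training deliveries (a minute or two)...")
cases = []
seed = 0
for pid in ("P2", "P3"):
    for error in (ErrorSpec.none(), *FULL_ERROR_CASES):
        cases.append(TrainingCase.from_stream(stream_for(pid, error, seed := seed + 1)))
for pid in ("P5", "P6"):
    for error in (ErrorSpec.none(), *PARTIAL_ERROR_CASES):
        cases.append(TrainingCase.from_stream(stream_for(pid, error, seed := seed + 1)))

spec = ObjectiveSpec()
search = SearchConfig(iterations=1500, restarts=2, target_objective=4.0, seed=5,
                      step_decay=0.7, decay_patience=40, min_step=3e-3)
weights, trace = random_search(cases, spec, search)
print(f"objective: {trace[0]:.2f} -> {trace[-1]:.3f} over {len(trace) - 1} evaluations")

for error in (ErrorSpec.none(), ErrorSpec("mlc_retraction", 6)):
    stream = stream_for("P1", error, 777)
    y = forward(stream, weights, spec.input_scale)
    crossed = np.flatnonzero(y > 0)
    when = f"y>0 from internal window {crossed[0]+1}" if crossed.size else "y stays below 0"
    print(f"{error.label:20s} y_max {y.max():+.2f}  ({when})")
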