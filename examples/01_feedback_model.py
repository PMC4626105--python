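"""The delayed-feedback model: how the Ca²⁺-buffer delay reshapes recovery.

Builds the slow-cell flash-response kernel x_s(t) = A_s·t³·e^(-t/τ), runs
the feedback loop x_o(t) = H·[x_s(t) - G·x_o(t-Δ)] at three buffer delays
and classifies each recovery. The printed labels show the progression a
growing Ca²⁺-buffering capacity produces: a plain scaled-down response
(single), a shouldered dual-component recovery, and damped oscillations —
while the rising phase before t = Δ stays identical to the unregulated one.
"""

import numpy as np

from conekinetics import (
    FeedbackParams,
    PoissonParams,
    TimeGrid,
    classify_recovery,
    feedback_response,
    oscillation_metrics,
    poisson_peak,
    poisson_response,
)

grid = TimeGrid(0.0, 1e-3, 1000)           # 1 s at 1 kHz
kernel = PoissonParams(A_s=5200.0, tau=0.052)

t_peak, v_peak = poisson_peak(kernel)
print(f"unregulated kernel: peak {v_peak:.3f} at t = 3*tau = {t_peak:.3f} s")

xs = poisson_response(kernel, grid)
for delta in (0.0, 0.06, 0.1):
    xo = feedback_response(kernel, FeedbackParams(G=0.6, delta=delta), grid)
    c = classify_recovery(xo)
    line = (f"G=0.6, delta={delta:5.3f} s -> {c.label:11s} "
            f"(peak {c.peak_value:.3f} at {c.peak_time:.3f} s)")
    if c.label == "oscillatory":
        period, damping = oscillation_metrics(c)
        line += f", ringing period {period:.3f} s, damping ratio {damping:.2f}"
    # the delay preserves the fast onset: identical to x_s before t = delta
    d = round(delta / grid.dt)
    if d:
        assert np.array_equal(xo.values[:d], xs.values[:d])
        line += "; onset identical to unregulated response"
    print(line)

print("\nThe delay converts feedback compression into a reshaped recovery:")
print("larger Ca²⁺ buffering (larger delta) -> dual components, then ringing.")
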