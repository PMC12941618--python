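"""Confidence-guided diffusion on a toy class-score vector.

Shows the three core operations: forward corruption with noise scaled by
(1 - confidence), exact algebraic inversion of that corruption, and the
textbook reduction at zero confidence.
"""

import numpy as np

from cgad import build_schedule, estimate_clean, forward_diffuse

sched = build_schedule(T=200, beta_start=1e-4, beta_end=0.1)
print(f"schedule: T={sched.T}, abar_1={sched.alpha_bar[0]:.4f}, "
      f"abar_T={sched.alpha_bar[-1]:.2e}")

rng = np.random.default_rng(0)
y0 = np.array([1.0, 0.0, 0.0])          # one-hot clean target, K = 3
eps = rng.standard_normal(3)
guidance = np.array([0.3, -0.1, 0.05])  # prior-branch sum

for c in (0.25, 0.8, 1.0):
    y_t = forward_diffuse(y0, t=100, c=c, eps=eps, guidance=guidance, schedule=sched)
    noise_norm = np.linalg.norm(
        y_t - np.sqrt(sched.abar(100)) * y0 - (1 - sched.abar(100)) * guidance
    )
    rec = estimate_clean(y_t, 100, c, eps, guidance, sched)
    print(f"c={c:4.2f}  injected-noise norm={noise_norm:6.3f}  "
          f"round-trip error={np.abs(rec - y0).max():.2e}")
# The noise norm shrinks as confidence rises (zero at c = 1), while the
# estimator returns the clean vector to machine precision at every c.
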