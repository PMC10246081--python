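"""From sinusoid-plus-jitter time series to connectivity.

Simulates BOLD-like signals where each region is a common-frequency sinusoid
with its own phase and jitter, then shows that the Pearson correlation of two
regions approaches j_c * j_d * cos(theta_c - theta_d) -- the identity the
angle-basis model is built on -- and computes the phase-locking value for
comparison.
"""

import numpy as np

from fcbasis import generate_sine_signals, pearson_fc, plv

phases = np.array([0.0, 0.9, 2.2])
jitters = np.array([1.0, 0.8, 0.6])
ts = generate_sine_signals(phases, jitters, omega=1.0, n_samples=20000,
                           dt=2 * np.pi / 100, seed=0)
fc = pearson_fc(ts).values
plv_mat = plv(ts)

print("pair   empirical_corr   j_c*j_d*cos(dtheta)   PLV")
for c in range(3):
    for d in range(c + 1, 3):
        pred = jitters[c] * jitters[d] * np.cos(phases[c] - phases[d])
        print(f"({c},{d})    {fc[c, d]:+.3f}           {pred:+.3f}"
              f"            {plv_mat[c, d]:.3f}")
# The empirical correlations track the closed form within Monte-Carlo error;
# PLV stays near 1 for high-jitter pairs (phase locking) and drops with noise.
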