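"""Virtual photometer: how bilirubin and hemolysis shape the two channels.

Evaluates the noise-free forward model on a mildly icteric sample at
increasing degrees of hemolysis, then shows one simulated (noisy, two-read
averaged) strip test.
"""

import numpy as np

from bilicomp import default_params, reflectance, simulate_measurement

params = default_params().with_(noise_rel_sd=0.0)
c_bil = 9.67  # mg/dL, a clinically relevant neonatal bilirubin level

print(f"Sample at {c_bil} mg/dL bilirubin, increasing free hemoglobin:")
print(f"{'Hb [g/dL]':>10} {'R465':>8} {'R590':>8}")
for c_hb in (0.06, 0.29, 0.50, 0.75, 0.99):
    r465 = reflectance(params, c_bil, c_hb, 465)
    r590 = reflectance(params, c_bil, c_hb, 590)
    print(f"{c_hb:>10.2f} {r465:>8.2f} {r590:>8.2f}")
print(
    "Both channels darken with hemolysis; the 590 nm drop is a pure\n"
    "hemoglobin signal (bilirubin-blind channel), which is what the\n"
    "compensation algorithm exploits.\n"
)

noisy = default_params()
m = simulate_measurement(noisy, c_bil, 0.50, np.random.default_rng(42),
                         sample_id="B2H3")
print(f"One simulated strip test of {m.sample_id}: "
      f"r465 = {m.r465:.3f}, r590 = {m.r590:.3f}")
print("Each channel is the average of two 1%-relative-noise reads, as the "
      "instrument measures.")
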