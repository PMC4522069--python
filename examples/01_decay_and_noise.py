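"""Echo schedules, the monoexponential decay model, and Rician noise.

Builds the three sequence schedules, evaluates the noiseless decay of a
myocardium-like pixel, and shows how the Rician noise floor lifts the
expected magnitude above the true amplitude at low SNR.
"""

import numpy as np

import t2mapping as t2

for name in ("MESE", "GraSE", "T2prep"):
    sched = t2.build_schedule(name)
    print(f"{name:7s} times (ms): {np.round(sched.times_array, 1)}")

params = t2.DecayParams(s0=100.0, t2=50.3)
grase = t2.build_schedule("GraSE")
signal = t2.decay_signal(params, grase)
print(f"\nnoiseless GraSE decay at T2 = {params.t2} ms:")
print(np.round(signal, 2))
# each value is S0*exp(-TE/T2); the first echo (TE = 15 ms) retains ~74%
# of the amplitude, the last (TE = 76.6 ms) ~22%.

print("\nexpected magnitude vs true amplitude (sigma = 2):")
for nu in (0.0, 2.0, 6.0, 20.0):
    print(f"  true {nu:5.1f} -> observed mean {t2.rician_mean(max(nu, 0), 2.0):6.2f}")
# at amplitude 0 the mean is sigma*sqrt(pi/2) ~ 2.51 (the noise floor);
# by amplitude 20 (SNR 10) the bias is already below 0.5%.

noisy = t2.add_rician_noise(np.full(10_000, 6.0), sigma=2.0, seed=1)
print(f"\nMonte-Carlo mean at true amplitude 6: {noisy.mean():.3f} "
      f"(closed form {t2.rician_mean(6.0, 2.0):.3f})")
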