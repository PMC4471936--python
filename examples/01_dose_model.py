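"""Evaluate the radiation-damage model at a few resolutions.

Prints the critical exposure Ne(k), the optimal exposure (2.5x Ne) and
the amplitude surviving a 25 e-/A^2 exposure at each resolution.  High
resolution fades much faster: the optimal exposure at 4 A is a fraction
of that at 20 A.
"""

from doseweight import attenuation_factor, critical_exposure, optimal_exposure

print(f"{'res (A)':>8} {'k (1/A)':>8} {'Ne':>7} {'optimal':>8} "
      f"{'q(25 e/A^2)':>12}")
for resolution in (20.0, 10.0, 8.0, 4.0, 3.0):
    k = 1.0 / resolution
    ne = critical_exposure(k)
    opt = optimal_exposure(k)
    q = attenuation_factor(k, 25.0)
    print(f"{resolution:8.1f} {k:8.3f} {ne:7.2f} {opt:8.2f} {q:12.3f}")

print()
print("Ne and the optimal exposure are in e-/A^2; q is the fraction of")
print("the Fourier amplitude surviving 25 e-/A^2 at that resolution.")
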