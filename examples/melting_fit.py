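"""Two-state thermal-unfolding fit of a CD melting curve.

Simulates a continuous-heating melt (20-80 C) with linear native and
unfolded baselines plus 1% noise, fits the six-parameter two-state model
and reports the midpoint and van't Hoff enthalpy.
"""

from relaxkit.melting import fit_melting, fraction_unfolded
from relaxkit.simulate import gen_melting

curve, truth = gen_melting(Tm=332.8, dH=80.9, noise=0.01, seed=1)
fit = fit_melting(curve)

print(f"fitted Tm: {fit.Tm:.2f} K = {fit.Tm_celsius:.2f} C "
      f"(generated at {truth.Tm:.2f} K)")
print(f"fitted dH_unfold: {fit.dH_unfold:.1f} kcal/mol "
      f"(generated at {truth.dH_unfold:.1f})")
print(f"native baseline: {fit.native_baseline}")
print(f"unfolded baseline: {fit.unfolded_baseline}")
f_u = fraction_unfolded(fit.Tm + 5.0, fit.Tm, fit.dH_unfold)
print(f"unfolded fraction 5 K above the midpoint: {f_u:.2f}")
print(
    "\nTm is where half the molecules are unfolded; dH sets how sharp the\n"
    "transition is (larger enthalpy = steeper sigmoid)."
)
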