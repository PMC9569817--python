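"""Model-free analysis of a synthetic 15N relaxation dataset.

Generates 40 residues of R1/R2/NOE data at 14.1 T from known order
parameters (tau_m = 9.6 ns tumbling, 3% noise), re-estimates the tumbling
time from filtered R2/R1 ratios, fits models 1-5 per residue with
statistical selection, and compares the recovered order parameters with the
ground truth.
"""

import numpy as np

from relaxkit.modelfree import fit_dataset
from relaxkit.simulate import gen_relaxation

data, truth = gen_relaxation(n_residues=40, noise_frac=0.03, seed=1)
result = fit_dataset(data, seed=1)

print(f"estimated tau_m: {result.diffusion.tau_m:.2f} ns (generated at 9.60 ns)")
print("residues per selected model:", result.model_counts())

errors = [abs(f.params.S2 - t.S2) for f, t in zip(result.fits, truth)]
print(f"median |S2_fit - S2_true|: {np.median(errors):.4f}")

print("\nfirst five residues:")
print("  res  model  S2_fit  S2_true  Rex_fit  Rex_true")
for fit, mf in list(zip(result.fits, truth))[:5]:
    print(
        f"  {fit.residue.index:>3}  {fit.params.model_id:>5}  "
        f"{fit.params.S2:6.3f}  {mf.S2:7.3f}  "
        f"{fit.params.Rex_app:7.2f}  {mf.Rex_app:8.2f}"
    )
print(
    "\nS2 near 1 means a rigid N-H bond vector; Rex > 0 flags microsecond-\n"
    "to-millisecond exchange contributions to transverse relaxation."
)
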