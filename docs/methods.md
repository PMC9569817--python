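# Methods

This note records the models implemented in relaxkit, the assumptions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Units and conventions

Temperatures kelvin, magnetic field tesla, rates s⁻¹, chemical shifts ppm,
coordinates Å, τ_m ns, τ_e ps. Residue indices are 1-based PDB-style
numbering; prolines and unassigned residues are simply absent from tables
and are never imputed. Tabular I/O is TSV with a header row and
`# key=value` metadata comments; floats are written at full precision and
parsed with Python's correctly-rounded parser so that read(write(x)) == x
bit-for-bit.

## Chemical-shift perturbation

Δδ = √[(Δδ_HN)² + (w₁·Δδ_N)²], w₁ = 0.154 — the nitrogen weight that
equalizes the typical amide ¹H and ¹⁵N shift dispersions. Two classifiers:
an absolute cutoff (default 0.25 ppm) and mean + 0.5·SD of the profile.
Both use strict inequality, so a constant profile flags nothing. The mean
and SD are computed over the residues shared by both tables; residues
present in only one table are reported as missing.

## Model-free analysis

Spectral density (extended Lipari–Szabo):

J(ω) = (2/5) Σ_k A_k [ S²τ_k/(1+(ωτ_k)²) + (S_f²−S²)τ′_k/(1+(ωτ′_k)²) ],
1/τ′_k = 1/τ_k + 1/τ_e.

Isotropic tumbling has one term (A = 1, τ = τ_m); axially symmetric
tumbling three, with amplitudes ((3cos²θ−1)²/4, 3sin²θcos²θ, (3/4)sin⁴θ)
and times (6D⊥)⁻¹, (5D⊥+D∥)⁻¹, (2D⊥+4D∥)⁻¹, θ the angle between the N–H
bond and the unique axis. Rates follow the standard dipolar + CSA
expressions with r_NH = 1.02 Å and Δσ = −172 ppm; ω_N is computed from
γ_N and B₀ rather than hard-coded (≈ 60.87 MHz at 14.1 T). R_ex,app adds
directly to R₂.

**Diffusion estimation.** Residues with NOE < 0.65 (flexible) or R₂/R₁
beyond 1 SD of the 10%-trimmed mean (exchange-broadened) are excluded;
both cutoffs are arguments. Isotropic τ_m is the Brent root of the
rigid-limit ratio against the mean filtered ratio (the rigid ratio is
exactly S²-independent when τ_e = 0, which is why the filter works).
The axially symmetric mode fits (τ_m, D∥/D⊥, axis) to the per-residue
ratios by bounded least squares from three axis starts. True N–H vectors
cannot be derived from a Cα-only trace, so the API accepts explicit
per-residue orientations; when only a Cα structure is given they are
approximated by the local chain direction Cα(i−1)→Cα(i+1). This is a
geometric stand-in adequate for exercising the anisotropic machinery, not
a replacement for real amide vectors.

**Fitting.** Bounded weighted least squares (scipy `least_squares`, trf)
of the three observables per model; bounds S², S_f², S_s² ∈ [0,1],
τ_e ∈ [0, τ_m], R_ex ∈ [0, 50] s⁻¹; five starts (three deterministic, the
rest seeded) guard against the τ_e/S² trade-off. Parameter errors by
seeded Monte-Carlo refitting of the observable errors (200 draws by
default).

**Model selection.** With only three observables per residue the nested
F-test has an F(1,1) reference whose 95% point is ≈161 — it essentially
never fires — and the AICc small-sample correction divides by
n−k−1 ≤ 0. Selection therefore follows the classic goodness-of-fit
cascade: keep model 1 while its χ² is consistent with 2 degrees of
freedom at α = 0.05; otherwise take the adequate two-parameter model
(2 or 3) with the lower χ²; only if neither fits do the exactly-determined
models 4 and 5 enter, decided by lower χ² with ties going to model 4. On
synthetic data this selects model 1 for noise-free rigid residues and an
R_ex-containing model for 100% of replicates carrying R_ex = 4 s⁻¹ at 2%
noise.

## CPMG relaxation dispersion

Two-state A↔B exchange with k_ex = k_AB + k_BA, p_B < 0.5,
k_AB = p_B·k_ex. R₂eff(ν_CPMG) uses the Carver–Richards closed form with
equal intrinsic rates in the two states; ¹⁵N Δδ is converted to rad/s at
the given field. Evaluation is overflow-safe: for large η₊ the acosh is
taken in the log domain. Only single-quantum ¹⁵N data are modelled; the
optional ¹H Δω argument exists for interface compatibility and rejects
nonzero values.

The cross-check is a numerically exact Bloch–McConnell propagator over the
τ–180–τ pulse train (ν_CPMG = 1/(4τ), ideal pulses as complex
conjugation, free precession by matrix exponential). Its default output is
the decay rate of the slowest mode of the echo propagator — the quantity
the closed form describes — and with equal intrinsic rates the two agree
to ~1e-12, which is what the oracle test asserts. An `intensity` mode
instead propagates equilibrium magnetization through the finite 40-ms
constant-time train; it differs from the asymptotic rate by transient
amplitude effects of a few percent at the lowest ν_CPMG, and requires a
whole number of echoes. Note that in deep slow exchange (k_ex ≪ Δω with a
substantial p_B) the exact R₂eff(ν_CPMG) is not monotone — both routes
show the same small oscillations — so the monotonicity property is only
asserted over the CPMG-detectable regime.

**Fits.** Individual profiles: weighted least squares over
(log k_ex, p_B, Δδ, R₂⁰) with a 3×2 multistart grid over k_ex decades
{10², 10³, 10⁴} and p_B {0.01, 0.05}. Flat profiles leave p_B·Δδ
unidentifiable and are flagged (degenerate) instead of reported with
spurious precision. Global cluster fits share (k_ex, p_B) per temperature
and Δδ per residue; every per-profile R₂⁰ enters additively and is
profiled out in closed form at each iteration, so the optimizer sees only
2·n_T + n_residues parameters. Only |Δδ| is reported — the sign is not
identifiable from CPMG data alone. R_ex is estimated as
R₂eff(ν_min) − R₂eff(ν_max), and profiles with R_ex > 15 Hz can be
flagged as strong-exchange sites.

**Thermodynamics.** K(T) = p_B/(1−p_B) (= k_AB/k_BA); ln K vs 1/T by
least squares gives ΔH = −R·slope and ΔS = R·intercept; ΔG(T) =
−RT·ln(k_AB/k_BA) is computed at every temperature regardless. The
regression needs ≥ 3 temperatures. Regressing on the populations rather
than the rate ratio is a choice without consequence — the two are
algebraically identical.

## Thermal unfolding

K(T) = exp[−(ΔH/R)(1/T − 1/T_m)] with ΔC_p = 0 by default (a fixed ΔC_p
can be supplied, adding the Gibbs–Helmholtz terms); f_U = K/(1+K);
observed signal = (1−f_U)(a_N + b_N·T) + f_U(a_U + b_U·T). Six fitted
parameters. Initialization: baselines from the outer sixths of the curve,
T_m from the steepest point of a lightly smoothed derivative, ΔH at
85 kcal/mol; two T_m starts. The fit is invariant to linear rescaling of
the signal axis. Preconditions and flags: the signal change must exceed
5× the point-to-point noise (otherwise "no transition"), and a T_m at the
range boundary is flagged as unbracketed.

## Trajectory analytics

**RMSF.** Frames after burn-in (default: first 10% — the first 100 ns of
a 1 μs run) are superposed onto the mean structure by Kabsch SVD, the mean
re-computed and the alignment repeated once (align → re-average → align),
then RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩. Isotropic per-coordinate jitter σ gives
RMSF ≈ σ√3 up to the ~6 rigid-body degrees of freedom absorbed by the
superposition.

**Windowed residue averaging.** Centered moving average over sequence
neighbours (default window 3); the window shrinks at chain ends and a gap
in residue numbering breaks it.

**Portal openness.** Mean of the four Cα–Cα distances across the D–E
strand gap (pairs 59–73, 60–72, 61–71, 62–70 by default); a closed/open
two-conformer system appears as a bimodal distribution of this series.

**Correlated-motion clustering.** Cα positions are averaged over
non-overlapping 250-frame windows (5 ns at 20 ps/frame) to suppress fast
motions; all pairwise distances d_ij(w) are formed per window. Two
co-movement summaries are exposed: `variance` (C_ij = 1 − var_w(d_ij)
normalized by the largest pair variance — rigid pairs score 1) and
`correlation` (C_ij = Pearson correlation between residues' distance-
alteration vectors to all residues, flattened over windows). Rows of C are
clustered by k-means (k-means++ init, 20 restarts, fixed seed, lowest
inertia). On planted-block data both modes recover the partition exactly
at the default trajectory length; the variance mode is the default.
Zero-variance (static) geometries are reported with a warning rather than
an error.

## Synthetic data

Generators are seeded (`numpy` Generator; identical seed ⇒ identical
output) and always return their ground truth alongside the data; tests use
the truth only for scoring. Noise is Gaussian and relative to the clean
value unless stated. Defaults are the study conditions: 14.1 T; 283 K
relaxation with τ_m = 9.6 ns and S² ~ U[0.75, 0.98] (20% of residues with
R_ex = 4 s⁻¹, 30% with τ_e ~ U[20, 100] ps, 3% noise); dispersion on the
19-point ν_CPMG grid (25–883 Hz, T_CP = 40 ms) at {283, 287, 291} K with
duplicate-replicate noise — two noisy copies per point, mean reported,
half-range as the error floored at 2% — and reference kinetics
k_ex = 871/1159/1546 s⁻¹, p_B = 3.1/3.5/4.1%; melting on a 20–80 °C grid;
trajectories of 50000 frames at 20 ps/frame (1 μs).

Planted block motion is a stationary low-pass-filtered Gaussian process
(boxcar over 2×250 frames, RMS amplitude 3 Å): a literal integrated
random walk was rejected because independent unit-root series exhibit
large spurious cross-correlations (observed inter-block ρ up to 0.64)
that destroy planted-partition recovery regardless of noise — a property
of random walks, not of the clustering.

What the generators do **not** emulate: spectral overlap and missing
assignments, field-dependent or temperature-dependent intrinsic rates,
anisotropic tumbling in the relaxation generator, correlated noise between
observables, baseline curvature in melts, and solvent/side-chain degrees
of freedom in trajectories. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to every pathology of real data.

## Problem sizes

The recovery studies run at sizes chosen to exercise the estimators while
staying desk-sized: 100 synthetic residues (model-free), a 10-residue ×
3-temperature dispersion cluster, 100 melting replicates, 20 clustering
seeds, and a 100-draw closed-form/propagator comparison. Experimentally
derived quantities that depend on the actual protein data (per-variant
rate averages, individual-residue exchange parameters, CD midpoints) are
covered by these parameter-recovery and consistency checks rather than by
numeric reproduction.

## Known limitations

- Fully asymmetric rotational diffusion is not implemented (isotropic and
  axially symmetric only).
- Single-quantum ¹⁵N dispersion only; no multiple-quantum ¹H Δω, no
  off-resonance R₁ρ, no B₁-inhomogeneity model, no three-state exchange.
- The Carver–Richards form assumes equal intrinsic R₂ in the two states.
- Model-free selection from three observables at one field is inherently
  weakly powered; multi-field data would sharpen it but is out of scope.
- ΔC_p is fixed, not fitted; strongly curved melt baselines will bias ΔH.
- The co-movement matrix is a heuristic summary; residues moving together
  only part of the time are assigned to their dominant block.
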