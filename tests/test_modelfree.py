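"""Model-free forward model, diffusion estimation, fitting and selection.

The forward-model checks compare against a literal, independent
transcription of the Lorentzian-sum spectral density and the dipolar/CSA
rate expressions written directly in this file.
"""

import numpy as np
import pytest

from relaxkit.constants import DEFAULT_CONSTANTS, HBAR, MU0_OVER_4PI
from relaxkit.datatypes import (
    RelaxationDataset,
    RelaxationRecord,
    ResidueId,
    TrajectoryData,
)
from relaxkit.modelfree import (
    DiffusionModel,
    MFParams,
    estimate_diffusion,
    fit_residue,
    forward_rates,
    select_model,
    spectral_density,
)

B0 = 14.1


# --- independent oracle -----------------------------------------------------

def oracle_J(omega, s2, tau_e_ps, tau_m_ns, sf2=1.0):
    """Straight transcription of the extended Lorentzian-sum spectral density
    for isotropic tumbling."""
    tau_m = tau_m_ns * 1e-9
    tau_e = tau_e_ps * 1e-12
    j = s2 * tau_m / (1.0 + (omega * tau_m) ** 2)
    if tau_e > 0 and sf2 > s2:
        tau_p = 1.0 / (1.0 / tau_m + 1.0 / tau_e)
        j += (sf2 - s2) * tau_p / (1.0 + (omega * tau_p) ** 2)
    return 0.4 * j


def oracle_rates(s2, tau_e_ps, rex, tau_m_ns, sf2=1.0):
    c = DEFAULT_CONSTANTS
    wh = c.gamma_H * B0
    wn = c.gamma_N * B0
    r = c.r_NH * 1e-10
    d2 = (MU0_OVER_4PI * HBAR * c.gamma_H * c.gamma_N / r**3) ** 2
    c2 = (c.delta_sigma * 1e-6 * wn) ** 2 / 3.0

    def J(w):
        return oracle_J(abs(w), s2, tau_e_ps, tau_m_ns, sf2)

    r1 = d2 / 4.0 * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn)) + c2 * J(wn)
    r2 = (
        d2 / 8.0 * (4 * J(0) + J(wh - wn) + 3 * J(wn) + 6 * J(wh) + 6 * J(wh + wn))
        + c2 / 6.0 * (4 * J(0) + 3 * J(wn))
        + rex
    )
    noe = 1.0 + (c.gamma_H / c.gamma_N) * d2 / 4.0 * (6 * J(wh + wn) - J(wh - wn)) / r1
    return r1, r2, noe


# --- spectral density -------------------------------------------------------

def test_rigid_limit_j_zero(iso_diff):
    """S2 = 1 at zero frequency gives J(0) = (2/5) tau_m."""
    j0 = spectral_density(0.0, MFParams(S2=1.0), iso_diff)
    assert j0 == pytest.approx(0.4 * 9.6e-9, rel=1e-12)


def test_spectral_density_monotone_non_increasing(iso_diff, rng):
    omegas = np.sort(rng.uniform(0.0, 1e10, 200))
    for _ in range(20):
        mf = MFParams(
            S2=rng.uniform(0.3, 1.0),
            tau_e=rng.uniform(0.0, 500.0),
        )
        j = spectral_density(omegas, mf, iso_diff)
        assert np.all(np.diff(j) <= 1e-30)


def test_negative_frequency_rejected(iso_diff):
    with pytest.raises(ValueError):
        spectral_density(-1.0, MFParams(S2=0.9), iso_diff)


def test_forward_model_matches_independent_oracle(iso_diff, rng):
    """spectral_density and forward_rates agree with the literal
    transcription to 1e-12 relative over random parameter draws."""
    omega = 2 * np.pi * 60.8e6
    for _ in range(300):
        s2 = rng.uniform(0.2, 1.0)
        tau_e = rng.uniform(0.0, 800.0)
        rex = rng.uniform(0.0, 10.0)
        mf = MFParams(S2=s2, tau_e=tau_e, Rex_app=rex, model_id=4)
        assert spectral_density(omega, mf, iso_diff) == pytest.approx(
            oracle_J(omega, s2, tau_e, 9.6), rel=1e-12
        )
        got = forward_rates(mf, iso_diff, field_B0=B0)
        want = oracle_rates(s2, tau_e, rex, 9.6)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=1e-12)


def test_extended_model_oracle_agreement(iso_diff, rng):
    for _ in range(50):
        sf2 = rng.uniform(0.6, 1.0)
        ss2 = rng.uniform(0.5, 1.0)
        tau_e = rng.uniform(10.0, 1000.0)
        mf = MFParams(S2=sf2 * ss2, Sf2=sf2, tau_e=tau_e, model_id=5)
        got = forward_rates(mf, iso_diff, field_B0=B0)
        want = oracle_rates(sf2 * ss2, tau_e, 0.0, 9.6, sf2=sf2)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=1e-12)


def test_rex_adds_exactly_to_r2_only(iso_diff):
    base = forward_rates(MFParams(S2=0.9, tau_e=50.0, model_id=2), iso_diff)
    with_rex = forward_rates(
        MFParams(S2=0.9, tau_e=50.0, Rex_app=5.0, model_id=4), iso_diff
    )
    assert with_rex[1] - base[1] == pytest.approx(5.0, abs=1e-12)
    assert with_rex[0] == base[0]
    assert with_rex[2] == base[2]


def test_rigid_limit_independent_of_tau_e(iso_diff):
    a = forward_rates(MFParams(S2=1.0, tau_e=0.0), iso_diff)
    b = forward_rates(MFParams(S2=1.0, tau_e=500.0, model_id=2), iso_diff)
    assert a == b


def test_study_conditions_reproduce_typical_backbone_rates(iso_diff):
    """S2 ~ 0.92 and tau_m ~ 9.6 ns at 14.1 T give rates in the observed
    backbone ranges (R1 ~ 1.4 s^-1, R2 ~ 14 s^-1, NOE ~ 0.80)."""
    r1, r2, noe = forward_rates(MFParams(S2=0.92), iso_diff, field_B0=B0)
    assert 1.2 <= r1 <= 1.6
    assert 12.7 <= r2 <= 15.3
    assert 0.74 <= noe <= 0.86


def test_model5_s2_is_product_of_amplitudes():
    mf = MFParams(S2=0.72, Sf2=0.9, tau_e=100.0, model_id=5)
    assert mf.Ss2 == pytest.approx(0.8)
    assert mf.S2 == pytest.approx(mf.Sf2 * mf.Ss2)


# --- diffusion estimation ---------------------------------------------------

def _noise_free_dataset(tau_m=9.6, n=20, seed=0):
    rng = np.random.default_rng(seed)
    diff = DiffusionModel(kind="isotropic", tau_m=tau_m)
    records = []
    for i in range(n):
        s2 = rng.uniform(0.8, 0.95)
        r1, r2, noe = forward_rates(MFParams(S2=s2), diff, field_B0=B0)
        records.append(
            RelaxationRecord(
                ResidueId(i + 1), r1, 0.02 * r1, r2, 0.02 * r2, noe, 0.02
            )
        )
    return RelaxationDataset(records=records, field_B0=B0, temperature=283.0)


def test_isotropic_tau_m_recovered_from_noise_free_data():
    data = _noise_free_dataset(tau_m=9.6)
    diff = estimate_diffusion(data, mode="isotropic")
    assert diff.tau_m == pytest.approx(9.6, rel=0.01)


def test_diffusion_estimate_order_invariant():
    data = _noise_free_dataset()
    shuffled = RelaxationDataset(
        records=list(reversed(data.records)), field_B0=B0, temperature=283.0
    )
    a = estimate_diffusion(data, mode="isotropic")
    b = estimate_diffusion(shuffled, mode="isotropic")
    assert a.tau_m == pytest.approx(b.tau_m, rel=1e-9)


def test_axial_fit_of_isotropic_data_finds_unity_anisotropy(rng):
    data = _noise_free_dataset(n=15)
    orientations = {
        i + 1: (lambda v: v / np.linalg.norm(v))(rng.normal(size=3))
        for i in range(15)
    }
    diff = estimate_diffusion(
        data, mode="axially_symmetric", orientations=orientations
    )
    assert 0.95 <= diff.Dratio <= 1.05


def test_too_few_residues_rejected():
    data = _noise_free_dataset(n=3)
    with pytest.raises(ValueError, match="pass the diffusion filter"):
        estimate_diffusion(data, mode="isotropic")


# --- per-residue fitting and selection --------------------------------------

def test_model1_noise_free_round_trip(rigid_record, iso_diff):
    fit = fit_residue(rigid_record, iso_diff, model_id=1)
    assert fit.params.S2 == pytest.approx(0.85, abs=1e-6)
    assert fit.chisq == pytest.approx(0.0, abs=1e-10)


def test_misspecified_model_has_large_chisq(iso_diff):
    """Data carrying Rex = 4 fit with model 1 leaves chi-square >> dof."""
    r1, r2, noe = forward_rates(
        MFParams(S2=0.9, Rex_app=4.0, model_id=3), iso_diff
    )
    rec = RelaxationRecord(ResidueId(2), r1, 0.02 * r1, r2, 0.02 * r2, noe, 0.016)
    fit1 = fit_residue(rec, iso_diff, model_id=1)
    fit3 = fit_residue(rec, iso_diff, model_id=3)
    assert fit1.chisq > 20 * fit1.dof
    assert fit3.chisq == pytest.approx(0.0, abs=1e-8)
    assert fit3.params.Rex_app == pytest.approx(4.0, abs=0.01)


def test_zero_error_rejected(iso_diff, rigid_record):
    bad = RelaxationRecord(
        ResidueId(1), rigid_record.R1, 0.0, rigid_record.R2, 0.1,
        rigid_record.NOE, 0.01,
    )
    with pytest.raises(ValueError, match="strictly positive"):
        fit_residue(bad, iso_diff, model_id=1)


def test_parsimony_on_noise_free_model1_data(rigid_record, iso_diff):
    assert select_model(rigid_record, iso_diff).params.model_id == 1


def test_monte_carlo_errors_scale_with_observable_noise(rigid_record, iso_diff):
    """MC parameter errors are positive, reproducible for a fixed seed, and
    roughly commensurate with the 1% observable errors."""
    from relaxkit.modelfree import mc_parameter_errors

    a = mc_parameter_errors(rigid_record, iso_diff, model_id=1, n_draws=30, seed=3)
    b = mc_parameter_errors(rigid_record, iso_diff, model_id=1, n_draws=30, seed=3)
    assert a == b
    assert 0.001 < a["S2"] < 0.05
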