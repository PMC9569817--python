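import math

import numpy as np
import pytest

from relaxkit.constants import DEFAULT_CONSTANTS
from relaxkit.datatypes import DispersionDataset, DispersionProfile, ResidueId
from relaxkit.dispersion import (
    NU_CPMG_GRID,
    ExchangeParams,
    bloch_mcconnell_r2eff,
    exchange_thermo,
    fit_global,
    fit_individual,
    flag_strong_exchange,
    ppm_to_rad,
    r2eff_two_state,
    rex_from_profile,
)
from relaxkit.simulate import gen_dispersion, table_2a_cluster_params

B0 = 14.1


def test_no_exchange_returns_intrinsic_rate():
    p = ExchangeParams(kex=500.0, pB=0.03, dw=0.0, R20=11.0)
    r2 = r2eff_two_state(NU_CPMG_GRID, p, B0)
    np.testing.assert_allclose(r2, 11.0, rtol=1e-9)


def test_fast_exchange_low_frequency_limit():
    """For kex >> dw the low-nu plateau is R20 + pA pB dw^2 / kex."""
    p = ExchangeParams(kex=1e4, pB=0.03, dw=2.0, R20=10.0)
    dw_rad = ppm_to_rad(2.0, B0)
    expected = 10.0 + p.pB * (1 - p.pB) * dw_rad**2 / p.kex
    assert r2eff_two_state(25.0, p, B0) == pytest.approx(expected, rel=0.02)


def test_monotone_non_increasing_in_nu(rng):
    """R2eff decreases with refocusing frequency across the measurable
    exchange regime.  (In very slow exchange with large shift differences
    the exact two-site solution genuinely oscillates -- the echo-propagator
    cross-check confirms the closed form there -- so draws stay in the
    CPMG-detectable window.)"""
    nu = np.linspace(20.0, 2000.0, 120)
    for _ in range(50):
        dw = rng.uniform(0.1, 4.0)
        dw_rad = ppm_to_rad(dw, B0)
        p = ExchangeParams(
            kex=dw_rad * 10 ** rng.uniform(-0.2, 1.3),
            pB=rng.uniform(0.002, 0.1),
            dw=dw,
            R20=rng.uniform(3.0, 30.0),
        )
        r2 = r2eff_two_state(nu, p, B0)
        assert np.all(np.diff(r2) <= 1e-8)
        assert r2[-1] >= p.R20 - 1e-6


def test_high_frequency_limit_approaches_r20():
    p = ExchangeParams(kex=871.0, pB=0.031, dw=3.0, R20=12.0)
    assert r2eff_two_state(5e4, p, B0) == pytest.approx(12.0, abs=0.05)


def test_closed_form_matches_propagator_on_random_draws(rng):
    """Spot agreement with the Bloch-McConnell echo-propagator decay rate
    (the full 100-draw sweep lives in the acceptance suite)."""
    lattice = np.arange(2, 71) * 12.5
    for _ in range(20):
        p = ExchangeParams(
            kex=10 ** rng.uniform(1.5, 4.2),
            pB=rng.uniform(0.005, 0.15),
            dw=rng.uniform(0.3, 4.0),
            R20=rng.uniform(5.0, 25.0),
        )
        nus = rng.choice(lattice, size=4, replace=False)
        cr = r2eff_two_state(nus, p, B0)
        bm = bloch_mcconnell_r2eff(nus, p, B0)
        np.testing.assert_allclose(cr, bm, rtol=5e-3)


def test_intensity_propagator_close_to_eigenvalue_decay():
    p = ExchangeParams(kex=871.0, pB=0.031, dw=2.0, R20=10.0)
    nus = np.array([100.0, 400.0, 800.0])  # whole echo counts in 40 ms
    eig = bloch_mcconnell_r2eff(nus, p, B0)
    inten = bloch_mcconnell_r2eff(nus, p, B0, method="intensity")
    np.testing.assert_allclose(eig, inten, rtol=0.03)


def test_multiple_quantum_proton_shift_rejected():
    p = ExchangeParams(kex=500.0, pB=0.03, dw=1.0, R20=10.0)
    with pytest.raises(NotImplementedError):
        r2eff_two_state(100.0, p, B0, dw_H=1.0)


# --- Rex estimation ---------------------------------------------------------

def test_rex_flat_profile_is_zero():
    prof = DispersionProfile(
        NU_CPMG_GRID, np.full(19, 12.0), np.full(19, 0.2)
    )
    assert rex_from_profile(prof) == 0.0


def test_rex_is_edge_difference_of_synthesized_profile():
    p = ExchangeParams(kex=871.0, pB=0.031, dw=2.5, R20=12.0)
    r2 = r2eff_two_state(NU_CPMG_GRID, p, B0)
    prof = DispersionProfile(NU_CPMG_GRID, r2, np.full(19, 0.1))
    expected = r2eff_two_state(25.0, p, B0) - r2eff_two_state(883.0, p, B0)
    assert rex_from_profile(prof) == pytest.approx(expected, abs=1e-12)


def test_strong_exchange_flagging_rule():
    """Profiles with Rex above 15 Hz are flagged, the rest are not."""
    strong = ExchangeParams(kex=400.0, pB=0.05, dw=4.0, R20=12.0)
    weak = ExchangeParams(kex=871.0, pB=0.01, dw=1.0, R20=12.0)
    profiles = {}
    for i, p in enumerate((strong, weak), start=1):
        r2 = r2eff_two_state(NU_CPMG_GRID, p, B0)
        profiles[(ResidueId(i), 283.0)] = DispersionProfile(
            NU_CPMG_GRID, r2, np.full(19, 0.1)
        )
    data = DispersionDataset(profiles=profiles)
    flagged = flag_strong_exchange(data)
    assert (ResidueId(1), 283.0) in flagged
    assert (ResidueId(2), 283.0) not in flagged
    # sanity: the strong profile really exceeds the threshold
    assert rex_from_profile(profiles[(ResidueId(1), 283.0)]) > 15.0


# --- fitting ----------------------------------------------------------------

def test_individual_fit_noiseless_round_trip():
    """Slow-exchange parameters of Gly22 magnitude recovered within 1%."""
    truth = ExchangeParams(kex=364.0, pB=0.008, dw=2.5, R20=12.0)
    clean = r2eff_two_state(NU_CPMG_GRID, truth, B0)
    prof = DispersionProfile(NU_CPMG_GRID, clean, 0.02 * clean)
    fit = fit_individual(prof, B0)
    assert fit.params.kex == pytest.approx(truth.kex, rel=0.01)
    assert fit.params.pB == pytest.approx(truth.pB, rel=0.01)
    assert fit.params.dw == pytest.approx(truth.dw, rel=0.01)
    assert not fit.degenerate


def test_individual_fit_accuracy_under_duplicate_noise():
    """Across seeded 2% duplicate-noise replicates the median relative error
    of the recovered exchange rate stays within 10%."""
    errors = []
    for seed in range(60):
        data, truth = gen_dispersion(
            {283.0: (871.0, 0.031)}, dw_list=[2.5], noise_frac=0.02, seed=seed
        )
        prof = data.profiles[next(iter(data.profiles))]
        fit = fit_individual(prof, B0)
        errors.append(abs(fit.params.kex / 871.0 - 1.0))
    assert float(np.median(errors)) <= 0.10


def test_individual_fit_flags_flat_profile_degeneracy():
    prof = DispersionProfile(
        NU_CPMG_GRID, np.full(19, 12.0), np.full(19, 0.2)
    )
    with pytest.warns(RuntimeWarning, match="unidentifiable"):
        fit = fit_individual(prof, B0)
    assert fit.degenerate


def test_individual_fit_needs_enough_points():
    prof = DispersionProfile(
        np.array([25.0, 883.0]), np.array([15.0, 12.0]), np.array([0.1, 0.1])
    )
    with pytest.raises(ValueError, match=">= 6"):
        fit_individual(prof, B0)


def _single_residue_dataset(truth, temp=283.0):
    clean = r2eff_two_state(NU_CPMG_GRID, truth, B0)
    prof = DispersionProfile(NU_CPMG_GRID, clean, 0.02 * clean)
    return DispersionDataset(profiles={(ResidueId(1), temp): prof})


def test_global_fit_single_residue_reduces_to_individual():
    truth = ExchangeParams(kex=871.0, pB=0.031, dw=2.0, R20=12.0)
    data = _single_residue_dataset(truth)
    fit = fit_global(data, [ResidueId(1)], [283.0])
    assert fit.kex[283.0] == pytest.approx(truth.kex, rel=0.01)
    assert fit.pB[283.0] == pytest.approx(truth.pB, rel=0.01)
    assert fit.dw[ResidueId(1)] == pytest.approx(truth.dw, rel=0.01)
    assert fit.R20[(ResidueId(1), 283.0)] == pytest.approx(truth.R20, rel=0.01)


def test_global_fit_order_invariance():
    rng = np.random.default_rng(5)
    data, _ = gen_dispersion(
        {283.0: (871.0, 0.031)}, dw_list=rng.uniform(1.5, 3.5, 4), seed=9
    )
    residues = data.residues
    a = fit_global(data, residues, [283.0])
    b = fit_global(data, list(reversed(residues)), [283.0])
    assert a.kex[283.0] == pytest.approx(b.kex[283.0], rel=1e-6)
    for rid in residues:
        assert a.dw[rid] == pytest.approx(b.dw[rid], rel=1e-6)


def test_global_fit_missing_profile_rejected():
    truth = ExchangeParams(kex=871.0, pB=0.031, dw=2.0, R20=12.0)
    data = _single_residue_dataset(truth)
    with pytest.raises(ValueError, match="no profile"):
        fit_global(data, [ResidueId(1)], [283.0, 291.0])


# --- thermodynamics ---------------------------------------------------------

def test_vant_hoff_of_printed_populations():
    """The study's excited-state populations give dH ~ 5.9 kcal/mol and
    dS ~ 14 cal/mol/K by direct regression."""
    thermo = exchange_thermo(
        kex={283.0: 871.0, 287.0: 1159.0, 291.0: 1546.0},
        pB={283.0: 0.031, 287.0: 0.035, 291.0: 0.041},
    )
    assert thermo.dH == pytest.approx(5.93, abs=0.05)
    assert thermo.dS == pytest.approx(14.1, abs=0.2)


def test_rate_decomposition_matches_rounding():
    thermo = exchange_thermo(
        kex={283.0: 871.0, 287.0: 1159.0, 291.0: 1546.0},
        pB={283.0: 0.031, 287.0: 0.035, 291.0: 0.041},
    )
    assert round(thermo.kAB[283.0]) == 27
    assert round(thermo.kAB[287.0]) == 41
    assert round(thermo.kAB[291.0]) == 63
    assert round(thermo.kBA[283.0]) == 844


def test_temperature_independent_equilibrium_gives_zero_enthalpy():
    thermo = exchange_thermo(
        kex={283.0: 500.0, 287.0: 700.0, 291.0: 900.0},
        pB={283.0: 0.03, 287.0: 0.03, 291.0: 0.03},
    )
    assert thermo.dH == pytest.approx(0.0, abs=1e-9)


def test_thermodynamic_consistency():
    """dH - T dS reproduces -RT ln K within the regression residual."""
    thermo = exchange_thermo(
        kex={283.0: 871.0, 287.0: 1159.0, 291.0: 1546.0},
        pB={283.0: 0.031, 287.0: 0.035, 291.0: 0.041},
    )
    for t, dg in thermo.dG_at.items():
        assert thermo.dH - t * thermo.dS * 1e-3 == pytest.approx(dg, abs=0.02)


def test_too_few_temperatures_rejected():
    with pytest.raises(ValueError, match=">= 3"):
        exchange_thermo(kex={283.0: 871.0}, pB={283.0: 0.031})
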