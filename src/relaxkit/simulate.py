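"""Ground-truth synthetic-data generators for every pipeline stage.

Each generator draws from a seeded ``numpy`` Generator, runs the package's
own forward models, adds the stated noise, and returns the dataset together
with a ground-truth record (always emitted, used downstream only for
scoring, never for fitting).  Identical seeds give identical output.

Defaults mirror the study conditions: 14.1 T, 283 K (relaxation),
{283, 287, 291} K (dispersion), the 19-point nu_CPMG grid with T_CP = 40 ms
and duplicate-derived errors, tumbling at tau_m = 9.6 ns with order
parameters around 0.9, and 5 ns (250-frame) windows for slow correlated
motions.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import DEFAULT_CONSTANTS, DEFAULT_FIELD_B0, PhysicalConstants
from .datatypes import (
    DispersionDataset,
    DispersionProfile,
    MeltingCurve,
    RelaxationDataset,
    RelaxationRecord,
    ResidueId,
    TrajectoryData,
)
from .dispersion import NU_CPMG_GRID, DEFAULT_T_CP, ExchangeParams, r2eff_two_state
from .melting import UnfoldFit, two_state_signal
from .modelfree import DiffusionModel, MFParams, forward_rates

DEFAULT_TEMPERATURES = (283.0, 287.0, 291.0)


def gen_relaxation(
    n_residues: int = 100,
    S2_range: Tuple[float, float] = (0.75, 0.98),
    tau_m: float = 9.6,
    noise_frac: float = 0.03,
    seed: int = 0,
    rex_fraction: float = 0.2,
    rex_value: float = 4.0,
    tau_e_fraction: float = 0.3,
    tau_e_range: Tuple[float, float] = (20.0, 100.0),
    field_B0: float = DEFAULT_FIELD_B0,
    temperature: float = 283.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Tuple[RelaxationDataset, List[MFParams]]:
    """Synthetic 15N relaxation dataset from known motional parameters.

    Per-residue order parameters are uniform over ``S2_range``; a fraction
    ``rex_fraction`` of residues carries an exchange term ``rex_value`` and
    a (disjointly drawn) fraction ``tau_e_fraction`` an internal correlation
    time from ``tau_e_range`` (ps).  Observables get relative Gaussian noise
    of ``noise_frac`` and the same value as the reported error.

    Returns the dataset and the per-residue ground-truth parameters.
    """
    if not (0.0 < noise_frac < 0.2):
        raise ValueError("noise_frac must lie in (0, 0.2)")
    if not (0.0 < S2_range[0] <= S2_range[1] <= 1.0):
        raise ValueError("invalid S2 range")
    rng = np.random.default_rng(seed)
    diff = DiffusionModel(kind="isotropic", tau_m=tau_m)
    truth: List[MFParams] = []
    records: List[RelaxationRecord] = []
    roles = rng.uniform(size=n_residues)
    for i in range(n_residues):
        s2 = float(rng.uniform(*S2_range))
        rex = rex_value if roles[i] < rex_fraction else 0.0
        has_tau = rex_fraction <= roles[i] < rex_fraction + tau_e_fraction
        tau_e = float(rng.uniform(*tau_e_range)) if has_tau else 0.0
        if rex > 0 and tau_e > 0:
            model_id = 4
        elif rex > 0:
            model_id = 3
        elif tau_e > 0:
            model_id = 2
        else:
            model_id = 1
        mf = MFParams(S2=s2, tau_e=tau_e, Rex_app=rex, model_id=model_id)
        truth.append(mf)
        r1, r2, noe = forward_rates(mf, diff, constants, field_B0)
        r1_err, r2_err = noise_frac * r1, noise_frac * r2
        noe_err = noise_frac * abs(noe)
        records.append(
            RelaxationRecord(
                ResidueId(i + 1),
                R1=float(max(rng.normal(r1, r1_err), 1e-3)),
                R1_err=r1_err,
                R2=float(max(rng.normal(r2, r2_err), 1e-3)),
                R2_err=r2_err,
                NOE=float(rng.normal(noe, noe_err)),
                NOE_err=noe_err,
            )
        )
    data = RelaxationDataset(
        records=records, field_B0=field_B0, temperature=temperature
    )
    return data, truth


def gen_dispersion(
    cluster_params: Dict[float, Tuple[float, float]],
    dw_list: Sequence[float],
    R20: float = 12.0,
    grid: Optional[np.ndarray] = None,
    noise_frac: float = 0.02,
    seed: int = 0,
    T_CP: float = DEFAULT_T_CP,
    field_B0: float = DEFAULT_FIELD_B0,
    duplicate_errors: bool = True,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Tuple[DispersionDataset, Dict]:
    """Synthetic CPMG dispersion dataset for a global-fit cluster.

    ``cluster_params`` maps temperature (K) to the shared (kex, pB);
    ``dw_list`` gives one 15N shift difference (ppm) per residue, shared
    across temperatures.  Each point is measured in two noisy replicates
    (relative Gaussian noise ``noise_frac``); the reported value is their
    mean and the reported error the half-range, floored at
    ``noise_frac * value`` -- emulating duplicate spectra.  Setting
    ``duplicate_errors=False`` records single noisy values with errors
    ``noise_frac * value`` instead.

    Returns the dataset and a truth dict with the generating parameters.
    """
    nu = NU_CPMG_GRID.copy() if grid is None else np.asarray(grid, dtype=float)
    if np.any(nu <= 0) or len(np.unique(nu)) != len(nu):
        raise ValueError("invalid nu_CPMG grid")
    rng = np.random.default_rng(seed)
    profiles: Dict[Tuple[ResidueId, float], DispersionProfile] = {}
    residues = [ResidueId(i + 1) for i in range(len(dw_list))]
    for temp in sorted(cluster_params):
        kex, pb = cluster_params[temp]
        for rid, dw in zip(residues, dw_list):
            params = ExchangeParams(kex=kex, pB=pb, dw=dw, R20=R20)
            clean = r2eff_two_state(nu, params, field_B0, constants=constants)
            scale = noise_frac * clean
            if duplicate_errors:
                rep1 = rng.normal(clean, scale)
                rep2 = rng.normal(clean, scale)
                value = 0.5 * (rep1 + rep2)
                err = np.maximum(0.5 * np.abs(rep1 - rep2), noise_frac * clean)
            else:
                value = rng.normal(clean, scale)
                err = scale
            profiles[(rid, temp)] = DispersionProfile(
                nu_cpmg=nu.copy(), r2eff=value, error=err
            )
    truth = {
        "kex": {t: cluster_params[t][0] for t in cluster_params},
        "pB": {t: cluster_params[t][1] for t in cluster_params},
        "dw": {rid.index: float(d) for rid, d in zip(residues, dw_list)},
        "R20": R20,
        "noise_frac": noise_frac,
        "seed": seed,
    }
    data = DispersionDataset(profiles=profiles, T_CP=T_CP, field_B0=field_B0)
    return data, truth


def table_2a_cluster_params() -> Dict[float, Tuple[float, float]]:
    """The reference two-state exchange conditions used throughout the
    synthetic dispersion fixtures: a single A<->B process accelerating from
    871 s^-1 / 3.1% at 283 K to 1546 s^-1 / 4.1% at 291 K."""
    return {283.0: (871.0, 0.031), 287.0: (1159.0, 0.035), 291.0: (1546.0, 0.041)}


def gen_melting(
    Tm: float = 333.0,
    dH: float = 85.0,
    native_baseline: Tuple[float, float] = (-5.0, -0.01),
    unfolded_baseline: Tuple[float, float] = (-25.0, 0.02),
    noise: float = 0.0,
    seed: int = 0,
    temp_range: Tuple[float, float] = (293.15, 353.15),
    n_points: int = 61,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Tuple[MeltingCurve, UnfoldFit]:
    """Synthetic two-state melting curve with linear baselines.

    ``noise`` is the Gaussian signal noise as a fraction of the total signal
    span.  The default 20-80 C grid matches a continuous-heating melt.
    Returns the curve and the generating parameters as an UnfoldFit.
    """
    if not (temp_range[0] < Tm < temp_range[1]):
        raise ValueError("Tm must lie inside the generated temperature range")
    rng = np.random.default_rng(seed)
    truth = UnfoldFit(
        Tm=Tm,
        dH_unfold=dH,
        native_baseline=native_baseline,
        unfolded_baseline=unfolded_baseline,
        chisq=0.0,
    )
    temps = np.linspace(temp_range[0], temp_range[1], n_points)
    signal = two_state_signal(temps, truth, constants)
    if noise > 0:
        signal = signal + rng.normal(0.0, noise * float(np.ptp(signal)), n_points)
    return MeltingCurve(temperature=temps, signal=signal, label="synthetic"), truth


def _backbone_curve(n_residues: int) -> np.ndarray:
    """Residues laid out on a gentle helix-like space curve, 3.8 A apart."""
    t = np.arange(n_residues) * 0.6
    raw = np.stack(
        [5.0 * np.cos(t), 5.0 * np.sin(t), 1.5 * t], axis=1
    )
    steps = np.linalg.norm(np.diff(raw, axis=0), axis=1)
    raw[1:] = raw[0] + np.cumsum(
        (np.diff(raw, axis=0).T * (3.8 / steps)).T, axis=0
    )
    return raw


def _slow_displacement(
    rng: np.random.Generator, n_frames: int, amplitude: float, timescale_frames: int
) -> np.ndarray:
    """A stationary 3-D displacement series varying on > ``timescale_frames``.

    White Gaussian noise low-pass filtered with a boxcar of the stated
    timescale; stationarity keeps independently drawn block displacements
    uncorrelated over a long run (an integrated random walk would show the
    classic spurious correlation between independent unit-root series).
    Scaled so the total RMS displacement equals ``amplitude``.
    """
    if amplitude == 0.0:
        return np.zeros((n_frames, 3))
    noise = rng.normal(0.0, 1.0, size=(n_frames + timescale_frames, 3))
    kernel = np.ones(timescale_frames) / timescale_frames
    smooth = np.stack(
        [
            np.convolve(noise[:, d], kernel, mode="valid")[:n_frames]
            for d in range(3)
        ],
        axis=1,
    )
    smooth -= smooth.mean(axis=0)
    rms = math.sqrt((smooth**2).sum(axis=1).mean()) or 1.0
    return amplitude * smooth / rms


def gen_trajectory(
    n_residues: int = 60,
    block_labels: Optional[Sequence[int]] = None,
    n_frames: int = 50000,
    dt: float = 0.02,
    block_motion_amp: float = 3.0,
    jitter: float = 0.3,
    seed: int = 0,
    window_frames: int = 250,
) -> Tuple[TrajectoryData, np.ndarray]:
    """Trajectory with planted co-moving residue blocks.

    Residues sit on a backbone-like curve; each block receives an
    independent slow rigid-body displacement (a random walk low-pass
    filtered to vary on timescales longer than ``window_frames`` frames,
    i.e. > 5 ns at the default 20 ps/frame) of peak amplitude
    ``block_motion_amp`` Angstrom, plus fast per-coordinate Gaussian jitter
    of SD ``jitter``.  Returns the trajectory and the planted labels.
    """
    if block_labels is None:
        block_labels = np.repeat(np.arange(3), math.ceil(n_residues / 3))[:n_residues]
    labels = np.asarray(block_labels, dtype=int)
    if len(labels) != n_residues:
        raise ValueError("block_labels length must equal n_residues")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 distinct blocks")
    rng = np.random.default_rng(seed)
    base = _backbone_curve(n_residues)
    coords = np.broadcast_to(base, (n_frames, n_residues, 3)).copy()
    for block in np.unique(labels):
        displacement = _slow_displacement(
            rng, n_frames, block_motion_amp, 2 * window_frames
        )
        coords[:, labels == block, :] += displacement[:, None, :]
    if jitter > 0:
        coords += rng.normal(0.0, jitter, size=coords.shape)
    traj = TrajectoryData(coords=coords, dt=dt)
    return traj, labels


def gen_portal_trajectory(
    closed_distance: float = 7.5,
    open_distance: float = 10.0,
    open_fraction: float = 0.3,
    n_frames: int = 2000,
    dt: float = 0.02,
    dwell_frames: int = 200,
    jitter: float = 0.15,
    seed: int = 0,
    n_residues: int = 80,
) -> Tuple[TrajectoryData, np.ndarray]:
    """Two-conformer trajectory with distinct closed/open portal distances.

    The four D-E strand C-alpha pairs sit at ``closed_distance`` or
    ``open_distance`` Angstrom depending on a two-state dwell process
    (geometric dwell times of mean ``dwell_frames``); the rest of the chain
    is static apart from Gaussian jitter.  Returns the trajectory and the
    per-frame conformer flags (1 = open).
    """
    rng = np.random.default_rng(seed)
    base = _backbone_curve(n_residues)
    state = np.empty(n_frames, dtype=int)
    current = 0
    i = 0
    while i < n_frames:
        dwell = max(1, int(rng.geometric(1.0 / dwell_frames)))
        state[i: i + dwell] = current
        i += dwell
        # occupancy steered toward open_fraction
        current = int(rng.uniform() < open_fraction)
    coords = np.broadcast_to(base, (n_frames, n_residues, 3)).copy()
    from .trajectory import DE_PAIRS  # local import to avoid a cycle

    target = np.where(state == 1, open_distance, closed_distance)
    for i_res, j_res in DE_PAIRS:
        a, b = i_res - 1, j_res - 1
        direction = base[b] - base[a]
        direction = direction / np.linalg.norm(direction)
        coords[:, b, :] = base[a] + direction[None, :] * target[:, None]
    if jitter > 0:
        coords += rng.normal(0.0, jitter, size=coords.shape)
    traj = TrajectoryData(coords=coords, dt=dt)
    return traj, state
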