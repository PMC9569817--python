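"""Trajectory analytics: RMSF, windowed residue averaging, the portal
openness distance, and correlated-motion clustering.

All operations act on a plain C-alpha trajectory (frames x residues x 3).
The portal-openness observable is the mean of four C-alpha pair distances
across the gap between beta-strands D and E, the route by which ligands are
thought to enter the binding cavity.  Correlated-motion clustering averages
out fast motions over multi-frame windows, summarizes how rigidly each
residue pair moves together through its windowed distance series, and
k-means-partitions the residues into co-moving blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .datatypes import ResidueId, TrajectoryData

#: C-alpha pairs spanning the D-E strand gap (sequence positions).
DE_PAIRS: Tuple[Tuple[int, int], ...] = ((59, 73), (60, 72), (61, 71), (62, 70))

#: Frames per averaging window: 5 ns at 20 ps/frame.
DEFAULT_WINDOW_FRAMES = 250

#: Burn-in fraction: the first 100 ns of a 1 us run.
DEFAULT_BURN_IN_FRACTION = 0.1


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Angstrom)."""

    values: Dict[ResidueId, float]
    burn_in_frames: int

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()))


@dataclass
class ClusterAssignment:
    """Residue -> cluster labels from correlated-motion clustering."""

    labels: Dict[ResidueId, int]  # cluster ids 1..k
    k: int
    inertia: float

    def as_array(self) -> np.ndarray:
        return np.array(list(self.labels.values()))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    Both are (n, 3); returns the transformed mobile coordinates.
    """
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    a = mobile - mob_center
    b = reference - ref_center
    u, _, vt = np.linalg.svd(a.T @ b)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rotation = u @ d @ vt
    return a @ rotation + ref_center


def _burn_in_count(traj: TrajectoryData, burn_in: Optional[float]) -> int:
    frac = DEFAULT_BURN_IN_FRACTION if burn_in is None else burn_in
    return int(round(frac * traj.n_frames))


def rmsf(traj: TrajectoryData, burn_in: Optional[float] = None) -> RMSFProfile:
    """Per-residue RMSF around the average structure after superposition.

    Each post-burn-in frame is superposed (Kabsch) onto the mean structure;
    the mean is then re-computed from the aligned frames and the alignment
    repeated once more before taking fluctuations, so the reference is
    self-consistent.

    Parameters
    ----------
    burn_in : float, optional
        Fraction of leading frames to discard; defaults to 0.1 (the first
        100 ns of a 1 us trajectory).
    """
    skip = _burn_in_count(traj, burn_in)
    frames = traj.coords[skip:]
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames after burn-in")
    reference = frames.mean(axis=0)
    for _ in range(2):  # align -> re-average -> align
        aligned = np.array([kabsch_superpose(f, reference) for f in frames])
        reference = aligned.mean(axis=0)
    deviations = aligned - reference
    per_residue = np.sqrt((deviations**2).sum(axis=2).mean(axis=0))
    return RMSFProfile(
        values={rid: float(v) for rid, v in zip(traj.residue_ids, per_residue)},
        burn_in_frames=skip,
    )


def windowed_average(
    values: Dict[ResidueId, float], window: int = 3
) -> Dict[ResidueId, float]:
    """Centered moving average of a per-residue series over sequence windows.

    The window shrinks at chain ends, and gaps in residue numbering break
    it: only residues at consecutive sequence positions enter an average.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    by_index = {rid.index: v for rid, v in values.items()}
    out: Dict[ResidueId, float] = {}
    for rid in values:
        left = []  # walk outward until a numbering gap breaks the window
        for step in range(1, half + 1):
            if rid.index - step in by_index and len(left) == step - 1:
                left.append(by_index[rid.index - step])
            else:
                break
        right = []
        for step in range(1, half + 1):
            if rid.index + step in by_index and len(right) == step - 1:
                right.append(by_index[rid.index + step])
            else:
                break
        out[rid] = float(np.mean([by_index[rid.index]] + left + right))
    return out


def de_distance_series(
    traj: TrajectoryData, pairs: Sequence[Tuple[int, int]] = DE_PAIRS
) -> np.ndarray:
    """Per-frame portal openness: mean of the strand-gap C-alpha distances.

    Raises ``KeyError`` naming any residue absent from the trajectory.
    """
    index_pairs = []
    for i, j in pairs:
        index_pairs.append((traj.index_of(i), traj.index_of(j)))
    dists = np.stack(
        [
            np.linalg.norm(traj.coords[:, a, :] - traj.coords[:, b, :], axis=1)
            for a, b in index_pairs
        ],
        axis=1,
    )
    return dists.mean(axis=1)


def _windowed_positions(
    traj: TrajectoryData, window_frames: int, burn_in: Optional[float]
) -> np.ndarray:
    skip = _burn_in_count(traj, burn_in)
    frames = traj.coords[skip:]
    n_windows = frames.shape[0] // window_frames
    if n_windows < 10:
        raise ValueError(
            f"only {n_windows} windows of {window_frames} frames after burn-in "
            "(need >= 10)"
        )
    trimmed = frames[: n_windows * window_frames]
    return trimmed.reshape(n_windows, window_frames, traj.n_residues, 3).mean(axis=1)


def _pair_distance_series(positions: np.ndarray) -> np.ndarray:
    """(windows, residues, residues) matrix of pairwise C-alpha distances."""
    diff = positions[:, :, None, :] - positions[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def comovement_matrix(
    traj: TrajectoryData,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
    burn_in: Optional[float] = None,
    mode: str = "variance",
) -> np.ndarray:
    """Residue x residue co-movement matrix from windowed distance series.

    mode='variance' (default): C_ij = 1 - var(d_ij) / max_kl var(d_kl); a
    pair whose distance barely fluctuates relative to the most variable
    pair moves together rigidly.  mode='correlation': C_ij is the Pearson
    correlation between residue i's and residue j's distance-alteration
    vectors (each residue's deviations of its distances to all residues
    from their window means, flattened over windows).
    """
    if mode not in ("variance", "correlation"):
        raise ValueError(f"unknown co-movement mode {mode!r}")
    positions = _windowed_positions(traj, window_frames, burn_in)
    dists = _pair_distance_series(positions)  # (W, R, R)
    if mode == "variance":
        var = dists.var(axis=0)
        top = var.max()
        if top <= 1e-12:  # static geometry up to float rounding
            warnings.warn(
                "no distance variance between windows; co-movement structure "
                "is undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            return np.ones_like(var)
        return 1.0 - var / top
    alterations = dists - dists.mean(axis=0)  # (W, R, R)
    n_res = alterations.shape[1]
    features = alterations.transpose(1, 0, 2).reshape(n_res, -1)
    sd = features.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} residue(s) with zero distance variance; their "
            "correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        sd[zero] = 1.0
    standardized = (features - features.mean(axis=1, keepdims=True)) / sd
    corr = standardized @ standardized.T / features.shape[1]
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def correlated_clusters(
    traj: TrajectoryData,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
    k: int = 4,
    seed: int = 0,
    burn_in: Optional[float] = None,
    mode: str = "variance",
    n_init: int = 20,
) -> ClusterAssignment:
    """Partition residues into co-moving blocks.

    Window-averaged C-alpha positions give per-pair distance series; rows
    of the co-movement matrix (see :func:`comovement_matrix`) are clustered
    with k-means (k-means++ init, ``n_init`` restarts, fixed seed; lowest
    inertia wins).  Labels are reported per residue as cluster ids 1..k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    matrix = comovement_matrix(traj, window_frames, burn_in, mode)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(matrix)
    return ClusterAssignment(
        labels={
            rid: int(lab) + 1 for rid, lab in zip(traj.residue_ids, labels)
        },
        k=k,
        inertia=float(km.inertia_),
    )
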