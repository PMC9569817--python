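"""Shared domain containers for the relaxation/dispersion/trajectory pipeline.

All containers are light dataclasses around numpy arrays or plain dicts.
Temperatures are kelvin internally; magnetic fields are tesla; rates s^-1;
chemical shifts ppm; coordinates Angstrom; times as stated per field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True, order=True)
class ResidueId:
    """A 1-based sequence position plus an amino-acid code.

    Prolines and unassigned residues may simply be absent from any table;
    nothing assumes a contiguous index range.
    """

    index: int
    name: str = "X"

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")

    def __str__(self) -> str:  # e.g. "Q51"
        return f"{self.name}{self.index}"


@dataclass
class ShiftTable:
    """Per-residue backbone amide 1H/15N chemical shifts for one variant."""

    entries: Dict[ResidueId, Tuple[float, float]]  # residue -> (delta_HN, delta_N) ppm
    label: str = ""

    def __post_init__(self) -> None:
        for rid, (hn, n) in self.entries.items():
            if not (np.isfinite(hn) and np.isfinite(n)):
                raise ValueError(f"non-finite shift for {rid}")

    def by_index(self) -> Dict[int, Tuple[float, float]]:
        return {rid.index: v for rid, v in self.entries.items()}

    @property
    def residues(self) -> List[ResidueId]:
        return list(self.entries)


@dataclass
class RelaxationRecord:
    """One residue's 15N R1, R2 and {1H}-15N NOE with errors."""

    residue: ResidueId
    R1: float
    R1_err: float
    R2: float
    R2_err: float
    NOE: float
    NOE_err: float


@dataclass
class RelaxationDataset:
    """Per-residue 15N relaxation rates at a stated field and temperature."""

    records: List[RelaxationRecord]
    field_B0: float
    temperature: float
    noe_max: float = 1.1  # sanity bound for steady-state NOE

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.R1 <= 0 or rec.R2 <= 0:
                raise ValueError(f"non-positive rate for {rec.residue}")
            if min(rec.R1_err, rec.R2_err, rec.NOE_err) < 0:
                raise ValueError(f"negative error for {rec.residue}")
            if rec.NOE > self.noe_max:
                raise ValueError(
                    f"NOE {rec.NOE} for {rec.residue} exceeds sanity bound {self.noe_max}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def residues(self) -> List[ResidueId]:
        return [r.residue for r in self.records]


@dataclass
class DispersionProfile:
    """One residue's R2eff(nu_CPMG) profile at one temperature."""

    nu_cpmg: np.ndarray  # Hz, strictly positive, unique
    r2eff: np.ndarray  # s^-1
    error: np.ndarray  # s^-1

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("nu_CPMG values must be strictly positive")
        if len(np.unique(self.nu_cpmg)) != len(self.nu_cpmg):
            raise ValueError("duplicate nu_CPMG values in profile")


@dataclass
class DispersionDataset:
    """R2eff profiles over nu_CPMG for residues x temperatures."""

    profiles: Dict[Tuple[ResidueId, float], DispersionProfile]
    T_CP: float = 0.040  # constant-time CPMG delay, seconds
    field_B0: float = 14.1

    def __post_init__(self) -> None:
        if self.T_CP <= 0:
            raise ValueError("T_CP must be positive")

    @property
    def temperatures(self) -> List[float]:
        return sorted({t for (_, t) in self.profiles})

    @property
    def residues(self) -> List[ResidueId]:
        seen: Dict[ResidueId, None] = {}
        for rid, _ in self.profiles:
            seen.setdefault(rid)
        return list(seen)


@dataclass
class MeltingCurve:
    """A thermal-melt trace: CD signal (or structure fraction) vs temperature."""

    temperature: np.ndarray  # kelvin, strictly increasing
    signal: np.ndarray  # arbitrary units
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if len(self.temperature) < 8:
            raise ValueError("need >= 8 points for a melting fit")


@dataclass
class TrajectoryData:
    """Frames x residues x 3 C-alpha coordinates with a frame time step."""

    coords: np.ndarray  # (n_frames, n_residues, 3), Angstrom
    dt: float  # ns per frame
    residue_ids: List[ResidueId] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, residues, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.residue_ids:
            self.residue_ids = [
                ResidueId(i + 1) for i in range(self.coords.shape[1])
            ]
        if len(self.residue_ids) != self.coords.shape[1]:
            raise ValueError("residue_ids length must match coords")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def index_of(self, residue_index: int) -> int:
        for k, rid in enumerate(self.residue_ids):
            if rid.index == residue_index:
                return k
        raise KeyError(f"residue {residue_index} not in trajectory")
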