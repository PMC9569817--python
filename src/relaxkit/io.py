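"""Readers and writers for the pipeline's tabular and structural formats.

All tabular I/O is tab-separated text with a mandatory header row; comment
lines start with ``#``.  Metadata (field, temperature, T_CP, label) travels
in ``# key=value`` comment lines so a written file round-trips to an
identical dataset.  Temperatures are kelvin internally; melting tables may
instead carry a ``temperature_C`` column which is converted on read.
"""

from __future__ import annotations

import io as _io
import os
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd

from .datatypes import (
    DispersionDataset,
    DispersionProfile,
    MeltingCurve,
    RelaxationDataset,
    RelaxationRecord,
    ResidueId,
    ShiftTable,
    TrajectoryData,
)

SCHEMAS = ("shift", "relaxation", "dispersion", "melting")

_COLUMNS = {
    "shift": ["index", "name", "delta_HN", "delta_N"],
    "relaxation": ["index", "name", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"],
    "dispersion": ["index", "name", "temperature", "nu_cpmg", "R2eff", "R2eff_err"],
    "melting": ["temperature", "signal"],
}

CELSIUS_OFFSET = 273.15


def _read_meta_and_table(path: str) -> Tuple[Dict[str, str], pd.DataFrame, List[int]]:
    """Parse '# key=value' comments and the TSV body.

    Returns metadata, the dataframe (all columns as strings), and the
    1-based file line number of each data row.
    """
    meta: Dict[str, str] = {}
    body_lines: List[str] = []
    line_numbers: List[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                payload = stripped.lstrip("#").strip()
                if "=" in payload:
                    key, _, value = payload.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            body_lines.append(line.rstrip("\n"))
            line_numbers.append(lineno)
    if not body_lines:
        raise ValueError(f"{path}: no header row found")
    frame = pd.read_csv(
        _io.StringIO("\n".join(body_lines)), sep="\t", dtype=str
    )
    return meta, frame, line_numbers[1:]


def _numeric(frame: pd.DataFrame, columns: List[str], line_numbers: List[int], path: str) -> pd.DataFrame:
    out = frame.copy()
    bad_rows: set = set()
    for col in columns:
        parsed = []
        # python's float() is correctly rounded; pandas' fast parser is not
        for i, raw in enumerate(out[col].tolist()):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(raw))
            except (TypeError, ValueError):
                bad_rows.add(i)
                parsed.append(np.nan)
        out[col] = parsed
    if bad_rows:
        lines = sorted({line_numbers[i] for i in bad_rows})
        raise ValueError(f"{path}: non-numeric values on line(s) {lines}")
    return out


def read_table(
    path: str, schema: str
) -> Union[ShiftTable, RelaxationDataset, DispersionDataset, MeltingCurve]:
    """Read a typed dataset from a TSV file.

    Parameters
    ----------
    path : str
        File to read.
    schema : {'shift', 'relaxation', 'dispersion', 'melting'}
        Which dataset type the file holds.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    meta, frame, line_numbers = _read_meta_and_table(path)

    required = list(_COLUMNS[schema])
    if schema == "melting" and "temperature" not in frame.columns:
        required = ["temperature_C", "signal"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    numeric_cols = [c for c in required if c != "name"]
    frame = _numeric(frame, numeric_cols, line_numbers, path)

    if schema == "shift":
        entries: Dict[ResidueId, Tuple[float, float]] = {}
        for _, row in frame.iterrows():
            rid = ResidueId(int(row["index"]), str(row["name"]))
            if rid in entries:
                raise ValueError(f"{path}: duplicate residue {rid}")
            entries[rid] = (float(row["delta_HN"]), float(row["delta_N"]))
        return ShiftTable(entries=entries, label=meta.get("label", ""))

    if schema == "relaxation":
        records: List[RelaxationRecord] = []
        seen = set()
        for _, row in frame.iterrows():
            rid = ResidueId(int(row["index"]), str(row["name"]))
            if rid in seen:
                raise ValueError(f"{path}: duplicate residue {rid}")
            seen.add(rid)
            records.append(
                RelaxationRecord(
                    rid,
                    float(row["R1"]), float(row["R1_err"]),
                    float(row["R2"]), float(row["R2_err"]),
                    float(row["NOE"]), float(row["NOE_err"]),
                )
            )
        return RelaxationDataset(
            records=records,
            field_B0=float(meta.get("field_B0", 14.1)),
            temperature=float(meta.get("temperature", 283.0)),
        )

    if schema == "dispersion":
        groups: Dict[Tuple[ResidueId, float], List[Tuple[float, float, float]]] = {}
        for _, row in frame.iterrows():
            rid = ResidueId(int(row["index"]), str(row["name"]))
            key = (rid, float(row["temperature"]))
            nu = float(row["nu_cpmg"])
            rows = groups.setdefault(key, [])
            if any(abs(nu - existing[0]) < 1e-12 for existing in rows):
                raise ValueError(
                    f"{path}: duplicate (residue, temperature, nu_cpmg) key "
                    f"({rid}, {key[1]} K, {nu} Hz)"
                )
            rows.append((nu, float(row["R2eff"]), float(row["R2eff_err"])))
        profiles = {
            key: DispersionProfile(
                nu_cpmg=np.array([r[0] for r in rows]),
                r2eff=np.array([r[1] for r in rows]),
                error=np.array([r[2] for r in rows]),
            )
            for key, rows in groups.items()
        }
        return DispersionDataset(
            profiles=profiles,
            T_CP=float(meta.get("T_CP", 0.040)),
            field_B0=float(meta.get("field_B0", 14.1)),
        )

    # melting
    temps = frame[required[0]].to_numpy(dtype=float)
    if required[0] == "temperature_C":
        temps = temps + CELSIUS_OFFSET
    return MeltingCurve(
        temperature=temps,
        signal=frame["signal"].to_numpy(dtype=float),
        label=meta.get("label", ""),
    )


def _r(value) -> str:
    """Full-precision decimal text for a float (or numpy scalar)."""
    return repr(float(value))


def write_table(dataset, path: str) -> None:
    """Write a typed dataset to TSV, preserving residue order and metadata."""
    lines: List[str] = []
    if isinstance(dataset, ShiftTable):
        if dataset.label:
            lines.append(f"# label={dataset.label}")
        lines.append("\t".join(_COLUMNS["shift"]))
        for rid, (hn, n) in dataset.entries.items():
            lines.append(f"{rid.index}\t{rid.name}\t{_r(hn)}\t{_r(n)}")
    elif isinstance(dataset, RelaxationDataset):
        lines.append(f"# field_B0={_r(dataset.field_B0)}")
        lines.append(f"# temperature={_r(dataset.temperature)}")
        lines.append("\t".join(_COLUMNS["relaxation"]))
        for rec in dataset.records:
            lines.append(
                f"{rec.residue.index}\t{rec.residue.name}\t{_r(rec.R1)}\t{_r(rec.R1_err)}"
                f"\t{_r(rec.R2)}\t{_r(rec.R2_err)}\t{_r(rec.NOE)}\t{_r(rec.NOE_err)}"
            )
    elif isinstance(dataset, DispersionDataset):
        lines.append(f"# T_CP={_r(dataset.T_CP)}")
        lines.append(f"# field_B0={_r(dataset.field_B0)}")
        lines.append("\t".join(_COLUMNS["dispersion"]))
        for (rid, temp), prof in dataset.profiles.items():
            for nu, r2, err in zip(prof.nu_cpmg, prof.r2eff, prof.error):
                lines.append(
                    f"{rid.index}\t{rid.name}\t{_r(temp)}\t{_r(nu)}\t{_r(r2)}\t{_r(err)}"
                )
    elif isinstance(dataset, MeltingCurve):
        if dataset.label:
            lines.append(f"# label={dataset.label}")
        lines.append("\t".join(_COLUMNS["melting"]))
        for t, s in zip(dataset.temperature, dataset.signal):
            lines.append(f"{_r(t)}\t{_r(s)}")
    else:
        raise TypeError(f"cannot write dataset of type {type(dataset).__name__}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_calpha(path: str, dt: float = 1.0) -> TrajectoryData:
    """Read a C-alpha trajectory from a (multi-model) PDB or plain XYZ table.

    PDB ``MODEL`` records become frames; a single-model file yields one
    frame.  The XYZ dialect is one frame per blank-line-separated block with
    columns ``index x y z``.  All frames must share one residue set.

    Parameters
    ----------
    path : str
        Input file; format sniffed from content (``ATOM``/``MODEL`` records
        vs. numeric columns).
    dt : float
        Frame spacing in ns to attach to the trajectory.
    """
    with open(path) as fh:
        head = fh.read(4096)
    if "ATOM" in head or "MODEL" in head or path.lower().endswith(".pdb"):
        return _read_calpha_pdb(path, dt)
    return _read_calpha_xyz(path, dt)


def _read_calpha_pdb(path: str, dt: float) -> TrajectoryData:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", path)
    frames: List[Dict[int, np.ndarray]] = []
    names: Dict[int, str] = {}
    for model in structure:
        frame: Dict[int, np.ndarray] = {}
        for chain in model:
            for residue in chain:
                if "CA" in residue:
                    idx = residue.id[1]
                    frame[idx] = residue["CA"].coord.astype(float)
                    names[idx] = residue.get_resname()
        frames.append(frame)
    return _assemble_frames(frames, names, dt, path)


def _read_calpha_xyz(path: str, dt: float) -> TrajectoryData:
    frames: List[Dict[int, np.ndarray]] = []
    current: Dict[int, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            if not stripped:
                if current:
                    frames.append(current)
                    current = {}
                continue
            parts = stripped.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'index x y z'")
            try:
                idx = int(parts[0])
                xyz = np.array([float(p) for p in parts[1:]], dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if idx in current:
                raise ValueError(f"{path}:{lineno}: duplicate residue {idx} in frame")
            current[idx] = xyz
    if current:
        frames.append(current)
    return _assemble_frames(frames, {}, dt, path)


def _assemble_frames(
    frames: List[Dict[int, np.ndarray]], names: Dict[int, str], dt: float, path: str
) -> TrajectoryData:
    if not frames or not frames[0]:
        raise ValueError(f"{path}: no C-alpha atoms found")
    reference = sorted(frames[0])
    for k, frame in enumerate(frames):
        if sorted(frame) != reference:
            missing = sorted(set(reference) ^ set(frame))
            raise ValueError(
                f"{path}: frame {k + 1} has an inconsistent residue set "
                f"(difference: {missing})"
            )
    coords = np.array([[frame[i] for i in reference] for frame in frames])
    residue_ids = [ResidueId(i, names.get(i, "X")) for i in reference]
    return TrajectoryData(coords=coords, dt=dt, residue_ids=residue_ids)
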