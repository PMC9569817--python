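"""Combined 1H/15N chemical-shift-perturbation (CSP) profiles.

The combined perturbation for a residue is

    dd = sqrt( (dd_HN)^2 + (w1 * dd_N)^2 )

with w1 = 0.154 by default, the nitrogen weight derived from the relative
chemical-shift dispersions of amide 1H and 15N in the BMRB.  Residues are
flagged as perturbed either by an absolute cutoff or relative to the
profile's mean and standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np

from .datatypes import ResidueId, ShiftTable

DEFAULT_W1 = 0.154


@dataclass
class CSPProfile:
    """Per-residue combined shift perturbations plus summary statistics."""

    values: Dict[ResidueId, float]
    w1: float
    mean: float
    sd: float
    missing_in_a: List[ResidueId] = field(default_factory=list)
    missing_in_b: List[ResidueId] = field(default_factory=list)


def combined_shift_difference(
    a: ShiftTable, b: ShiftTable, w1: float = DEFAULT_W1
) -> CSPProfile:
    """Combined amide shift difference between two variants, residue by residue.

    Residues present in only one table are reported in ``missing_in_a`` /
    ``missing_in_b`` (those absent from `a` / from `b`), never imputed as
    zero.  Mean and SD are computed over the shared residues only.

    Raises
    ------
    ValueError
        If the two tables share no residue.
    """
    a_ix = a.by_index()
    b_ix = b.by_index()
    shared = [rid for rid in a.residues if rid.index in b_ix]
    if not shared:
        raise ValueError("shift tables share no residues")
    values: Dict[ResidueId, float] = {}
    for rid in shared:
        hn_a, n_a = a_ix[rid.index]
        hn_b, n_b = b_ix[rid.index]
        values[rid] = math.hypot(hn_a - hn_b, w1 * (n_a - n_b))
    arr = np.array(list(values.values()))
    shared_idx = {rid.index for rid in shared}
    missing_in_b = [rid for rid in a.residues if rid.index not in shared_idx]
    missing_in_a = [rid for rid in b.residues if rid.index not in shared_idx]
    return CSPProfile(
        values=values,
        w1=w1,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        missing_in_a=missing_in_a,
        missing_in_b=missing_in_b,
    )


def classify_perturbed(
    profile: CSPProfile,
    absolute_cut: float = 0.25,
    sd_factor: float = 0.5,
) -> Tuple[Set[ResidueId], Set[ResidueId]]:
    """Split a CSP profile into notably perturbed residue sets.

    Returns ``(above_absolute, above_mean_plus_half_sd)``: residues with a
    perturbation strictly greater than ``absolute_cut`` ppm, and residues
    strictly exceeding ``mean + sd_factor * sd``.  Ties at either threshold
    are excluded.  The two sets may overlap.
    """
    if not profile.values:
        raise ValueError("empty CSP profile")
    relative_cut = profile.mean + sd_factor * profile.sd
    above_absolute = {r for r, v in profile.values.items() if v > absolute_cut}
    above_relative = {r for r, v in profile.values.items() if v > relative_cut}
    return above_absolute, above_relative
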