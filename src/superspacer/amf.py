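"""Atomic modulation function (AMF) approximations.

In (3+1)D superspace every atomic parameter is governed by a periodic
function of the superspace coordinate x4.  A commensurate N-cell supercell
samples each AMF at the N values of t realized by its basic cells, so the
AMFs can be approximated by recording, per family member, the displacement
of the folded coordinates from the family average at that cell's t.  The
same machinery covers occupancy modulation (a family member simply missing
from some cells — the AMF has a discontinuity there) and the animation-frame
ordering used to visualise the modulation as a movie over one period of t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoResetError, SuperspacerError
from .partition import (AverageStructure, ChainFamily, SupercellModel,
                        SuperspaceOrdering)

__all__ = [
    "AMFSeries",
    "SawtoothReset",
    "FrameSequence",
    "displacement_series",
    "occupancy_series",
    "detect_sawtooth_reset",
    "compare_series",
    "export_frames",
]

AXES = ("x1", "x2", "x3")


@dataclass
class AMFSeries:
    """Sampled AMF of one subject along one axis: displacement vs t.

    ``t`` is sorted ascending in [0, 1); ``values`` are displacements from
    the family average in basic-cell fractional units (``values_ang`` in
    Angstrom via cell-edge scaling); ``present`` flags cells in which the
    subject exists — values at absent samples are NaN.
    """

    subject: str
    axis: str
    t: np.ndarray
    values: np.ndarray
    values_ang: np.ndarray
    present: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.values_ang = np.asarray(self.values_ang, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        order = np.argsort(self.t, kind="stable")
        for name in ("t", "values", "values_ang", "present"):
            setattr(self, name, getattr(self, name)[order])

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "d_frac": self.values,
            "d_ang": self.values_ang, "present": self.present.astype(int),
        })


@dataclass
class SawtoothReset:
    """Location of the discontinuous reset of a sawtooth-like AMF."""

    t: float
    magnitude: float
    contrast: float
    low_contrast: bool


@dataclass
class FrameSequence:
    """Basic-cell snapshots in superspace order, for animation.

    One frame per basic cell, ordered by t (cyclic: the frame after the last
    is the first).  ``arrows[k]`` maps family label -> COM displacement of
    that family's chain from the previous frame (fractional, basic cell).
    """

    frames: list[SupercellModel]
    t_values: list[float]
    cells: list[tuple[int, int, int]]
    arrows: list[dict[str, np.ndarray]]

    def __len__(self) -> int:
        return len(self.frames)


def _member_offsets(
    folded: SupercellModel,
    family: ChainFamily,
    average: AverageStructure,
    selector: str,
) -> dict[tuple[int, int, int], np.ndarray]:
    """Per-cell displacement of the family member from the family average.

    selector "com": displacement of the member COM from the average COM over
    the member's own atom set (so partially-present members compare like with
    like).  selector "all": mean per-atom displacement — identical to "com"
    on the common atom set, kept as the explicit atom-wise route.
    """
    avg = average.tables[family.label]
    offsets = {}
    for cell, chain in family.members.items():
        member = folded.atoms[folded.atoms["chain"] == chain]
        keyed = member.set_index(["resseq", "atom"])[["x1", "x2", "x3"]]
        common = keyed.index.intersection(avg.index)
        if len(common) == 0:
            raise SuperspacerError(
                f"chain {chain!r} shares no atoms with the {family.label} average"
            )
        delta = keyed.loc[common].to_numpy() - avg.loc[common, ["x1", "x2", "x3"]].to_numpy()
        offsets[cell] = delta.mean(axis=0) if selector in ("com", "all") else delta
    return offsets


def displacement_series(
    folded: SupercellModel,
    family: ChainFamily,
    average: AverageStructure,
    ordering: SuperspaceOrdering,
    selector: str = "com",
) -> dict[str, AMFSeries]:
    """Displacement-from-average AMF samples of one family, one series per axis.

    Each member cell contributes one sample at that cell's t; values are in
    basic-cell fractional units and Angstrom.  Displacement series average
    to zero over the members by construction.
    """
    if selector not in ("com", "all"):
        raise ValueError("selector must be 'com' or 'all'")
    if not family.members:
        raise SuperspacerError(f"family {family.label} has no members")
    offsets = _member_offsets(folded, family, average, selector)
    lengths = np.array(folded.cell.lengths)
    cells = sorted(offsets)
    t = np.array([float(ordering.t_of(c)) for c in cells])
    delta = np.array([offsets[c] for c in cells])
    out = {}
    for i, axis in enumerate(AXES):
        out[axis] = AMFSeries(
            subject=f"{family.label} ({selector})", axis=axis, t=t,
            values=delta[:, i], values_ang=delta[:, i] * lengths[i],
            present=np.ones(len(t), dtype=bool),
        )
    return out


def occupancy_series(
    folded: SupercellModel,
    family: ChainFamily,
    average: AverageStructure,
    ordering: SuperspaceOrdering,
    selector: str = "com",
) -> dict[str, AMFSeries]:
    """AMF samples over *all* basic cells with presence flags.

    Cells in which the family has no member get present=False and NaN
    displacement — the discontinuity by which superspace represents an
    occupancy modulation.
    """
    offsets = _member_offsets(folded, family, average, selector)
    lengths = np.array(folded.cell.lengths)
    cells = list(ordering.cells)
    t = np.array([float(ordering.t_of(c)) for c in cells])
    present = np.array([c in offsets for c in cells])
    delta = np.array([offsets.get(c, np.full(3, np.nan)) for c in cells])
    out = {}
    for i, axis in enumerate(AXES):
        out[axis] = AMFSeries(
            subject=f"{family.label} ({selector})", axis=axis, t=t,
            values=delta[:, i], values_ang=delta[:, i] * lengths[i],
            present=present,
        )
    return out


def detect_sawtooth_reset(series: AMFSeries, contrast_floor: float = 2.0) -> SawtoothReset:
    """Locate the reset of a sawtooth-like AMF.

    A sawtooth rises linearly then resets discontinuously; on the sampled
    series the reset is the largest negative jump between consecutive samples
    on the cyclic t domain.  The reported t is the cyclic midpoint of the
    bracketing sample pair (discrete sampling cannot localize it further).
    ``contrast`` is the jump magnitude over the mean magnitude of the other
    steps; smooth waveforms (e.g. a sinusoid's descending flank) are flagged
    ``low_contrast`` below ``contrast_floor``.
    """
    mask = series.present
    t, v = series.t[mask], series.values[mask]
    if len(t) < 3:
        raise ValueError("need at least 3 present samples")
    t_next = np.roll(t, -1)
    jumps = np.roll(v, -1) - v
    if jumps.min() >= 0:
        raise NoResetError("no reset found: series has no negative cyclic jump")
    k = int(jumps.argmin())
    gap = (t_next[k] - t[k]) % 1.0
    t_reset = (t[k] + gap / 2.0) % 1.0
    magnitude = -float(jumps[k])
    others = np.abs(np.delete(jumps, k))
    contrast = magnitude / others.mean() if others.mean() > 0 else np.inf
    return SawtoothReset(t=float(t_reset), magnitude=magnitude,
                         contrast=float(contrast),
                         low_contrast=contrast < contrast_floor)


def _cyclic_interp(t_query: np.ndarray, t_data: np.ndarray, v_data: np.ndarray) -> np.ndarray:
    """Linear interpolation on the cyclic unit t domain."""
    order = np.argsort(t_data)
    td, vd = t_data[order], v_data[order]
    td_ext = np.concatenate([[td[-1] - 1.0], td, [td[0] + 1.0]])
    vd_ext = np.concatenate([[vd[-1]], vd, [vd[0]]])
    return np.interp(t_query % 1.0, td_ext, vd_ext)


def compare_series(a: AMFSeries, b: AMFSeries, transform: str = "identity",
                   use_ang: bool = False) -> float:
    """RMS difference between two AMF series, optionally mirrored in t.

    ``transform`` "mirror_t" evaluates b at (1 - t) mod 1 before differencing
    — the comparison behind mirror-related chain pairs.  Series on different
    t grids are compared by cyclic linear interpolation of b at a's sample
    points; the RMS runs over a's present samples.
    """
    if transform not in ("identity", "mirror_t"):
        raise ValueError("transform must be 'identity' or 'mirror_t'")
    attr = "values_ang" if use_ang else "values"
    ta, va = a.t[a.present], getattr(a, attr)[a.present]
    tb, vb = b.t[b.present], getattr(b, attr)[b.present]
    if len(ta) == 0 or len(tb) == 0:
        raise SuperspacerError("disjoint supports: a series has no present samples")
    t_query = (1.0 - ta) % 1.0 if transform == "mirror_t" else ta
    vb_at_a = _cyclic_interp(t_query, tb, vb)
    return float(np.sqrt(np.mean((va - vb_at_a) ** 2)))


def export_frames(
    folded: SupercellModel,
    assignment: Mapping[str, tuple[int, int, int]],
    families: Sequence[ChainFamily],
    ordering: SuperspaceOrdering,
) -> FrameSequence:
    """Arrange the folded basic cells as animation frames in superspace order.

    Each frame holds the folded coordinates of the chains assigned to one
    basic cell; frames are ordered by t and cyclic.  Arrows record, per
    family, the COM displacement of its chain from the previous frame (the
    previous frame of the first is the last).
    """
    cell_chains: dict[tuple[int, int, int], list[str]] = {}
    for chain, cell in assignment.items():
        cell_chains.setdefault(cell, []).append(chain)
    frames, coms = [], []
    for cell in ordering.cells:
        chains = cell_chains.get(cell, [])
        atoms = folded.atoms[folded.atoms["chain"].isin(chains)].copy()
        frames.append(SupercellModel(cell=folded.cell, atoms=atoms))
        com_by_family = {}
        for fam in families:
            chain = fam.members.get(cell)
            if chain is not None:
                com_by_family[fam.label] = folded.chain_com(chain)
        coms.append(com_by_family)
    arrows = []
    n = len(frames)
    for k in range(n):
        prev = coms[(k - 1) % n]
        arrows.append({
            label: com - prev[label]
            for label, com in coms[k].items() if label in prev
        })
    return FrameSequence(
        frames=frames,
        t_values=[float(t) for t in ordering.t_values],
        cells=list(ordering.cells),
        arrows=arrows,
    )
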