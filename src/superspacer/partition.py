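"""Supercell decomposition and superspace ordering.

A commensurate supercell holds N copies of a basic cell whose contents vary
from cell to cell under the modulation.  This module partitions a supercell
model into basic cells, folds all cells onto the first one, groups chains
into tNCS families across cells, averages family members into an average
structure, and computes the superspace coordinate

    x4 = q . (x_avg + n) = q . x_avg + t,    t = frac(q . n)

whose fractional part orders the basic cells along one period of the atomic
modulation functions (the "superorder").  All ordering arithmetic is exact
(rational); floats appear only in atom-level coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import AmbiguousChainMatchError, SuperspacerError
from .qvector import RationalQ

__all__ = [
    "CellParameters",
    "SupercellModel",
    "ChainFamily",
    "AverageStructure",
    "SuperspaceOrdering",
    "assign_cells",
    "fold_to_basic",
    "unfold_from_basic",
    "build_families",
    "average_structure",
    "compute_x4",
    "superorder",
]

ATOM_COLUMNS = ["chain", "resseq", "resname", "atom", "element",
                "x1", "x2", "x3", "occ", "bfac"]


@dataclass(frozen=True)
class CellParameters:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must be in (0, 180) degrees")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass
class SupercellModel:
    """Coordinate model: cell parameters plus a flat atom table.

    ``atoms`` columns: chain, resseq, resname, atom, element, x1, x2, x3
    (fractional), occ, bfac.  Chain ids label whole chains; fractional
    coordinates of a deposited model are wrapped to [0, 1) at read time,
    while folded models may spill slightly outside when a chain extends
    past its basic-cell boundary.
    """

    cell: CellParameters
    atoms: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns {missing}")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def chain_coords(self, chain: str) -> np.ndarray:
        return self.atoms.loc[self.atoms["chain"] == chain, ["x1", "x2", "x3"]].to_numpy()

    def chain_com(self, chain: str) -> np.ndarray:
        """Unweighted mean fractional position of all atoms of one chain."""
        return self.chain_coords(chain).mean(axis=0)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class ChainFamily:
    """Chains related by the modulation across basic cells (prime notation).

    ``label`` is the reference chain id with a prime (e.g. "B'"); ``members``
    maps each basic-cell index vector to the chain id occupying it there.  A
    family may be absent from some cells (occupancy modulation).
    """

    label: str
    reference: str
    members: dict[tuple[int, int, int], str]

    @property
    def chain_ids(self) -> list[str]:
        return [self.members[c] for c in sorted(self.members)]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AverageStructure:
    """Per-family mean folded positions with presence counts.

    ``tables[label]`` is indexed by (resseq, atom) with columns x1, x2, x3
    (mean folded fractional position over the members in which the atom is
    present), presence (member count) and resname/element carried through.
    """

    tables: dict[str, pd.DataFrame]
    n_members: dict[str, int]

    def com(self, label: str) -> np.ndarray:
        return self.tables[label][["x1", "x2", "x3"]].to_numpy().mean(axis=0)


@dataclass
class SuperspaceOrdering:
    """Basic cells sorted by the fractional superspace coordinate t.

    ``cells`` are 0-based index vectors in ascending-t order; ``t_values``
    are the exact fractional t of each (rational when q and origin are).
    1-based flat indices follow the natural enumeration of the cell grid
    (last axis fastest), so a purely-x3 supercell numbers its cells 1..N
    along x3.
    """

    cells: list[tuple[int, int, int]]
    t_values: list[Fraction]
    denominators: tuple[int, int, int]

    def __post_init__(self):
        self._t_by_cell = dict(zip(self.cells, self.t_values))

    @property
    def indices_1based(self) -> list[int]:
        d1, d2, d3 = self.denominators
        return [n1 * d2 * d3 + n2 * d3 + n3 + 1 for (n1, n2, n3) in self.cells]

    def t_of(self, cell: tuple[int, int, int]) -> Fraction:
        return self._t_by_cell[cell]

    def __len__(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": self.indices_1based,
            "cell": [str(c) for c in self.cells],
            "t": [str(t) for t in self.t_values],
            "t_float": [float(t) for t in self.t_values],
        })


def assign_cells(model: SupercellModel, q: RationalQ,
                 eps: float = 1e-9) -> dict[str, tuple[int, int, int]]:
    """Assign each chain to a basic cell by its center of mass.

    The cell index along axis i is floor(com_i * D_i) with D_i the number of
    basic cells along that axis; whole chains are never split.  A center of
    mass sitting on a cell boundary (within ``eps`` of it) goes to the lower
    cell with a warning.
    """
    dens = q.denominators
    assignment: dict[str, tuple[int, int, int]] = {}
    for chain in model.chains:
        com = model.chain_com(chain)
        idx = []
        for i, d in enumerate(dens):
            s = com[i] * d
            r = round(s)
            if abs(s - r) < eps and r >= 1 and r <= d:
                warnings.warn(
                    f"chain {chain!r} COM on a cell boundary along x{i + 1}; "
                    "assigned to the lower cell"
                )
                n = r - 1
            else:
                n = math.floor(s)
            idx.append(min(max(n, 0), d - 1))
        assignment[chain] = tuple(idx)
    return assignment


def fold_to_basic(model: SupercellModel, assignment: Mapping[str, tuple[int, int, int]],
                  q: RationalQ) -> SupercellModel:
    """Translate every basic cell onto the first one.

    Folded fractional coordinates are x_basic = x_super * D - n per axis;
    basic-cell lengths are the supercell lengths divided by the denominators,
    angles unchanged.  Coordinates are deliberately not re-wrapped so chains
    extending past a cell face stay contiguous.
    """
    dens = np.array(q.denominators, dtype=float)
    atoms = model.atoms.copy()
    shift = np.array([assignment[ch] for ch in atoms["chain"]], dtype=float)
    xyz = atoms[["x1", "x2", "x3"]].to_numpy() * dens - shift
    atoms[["x1", "x2", "x3"]] = xyz
    cell = model.cell
    basic = CellParameters(cell.a / dens[0], cell.b / dens[1], cell.c / dens[2],
                           cell.alpha, cell.beta, cell.gamma)
    return SupercellModel(cell=basic, atoms=atoms)


def unfold_from_basic(folded: SupercellModel, assignment: Mapping[str, tuple[int, int, int]],
                      q: RationalQ, supercell: CellParameters) -> SupercellModel:
    """Inverse of :func:`fold_to_basic`: x_super = (x_basic + n) / D."""
    dens = np.array(q.denominators, dtype=float)
    atoms = folded.atoms.copy()
    shift = np.array([assignment[ch] for ch in atoms["chain"]], dtype=float)
    atoms[["x1", "x2", "x3"]] = (atoms[["x1", "x2", "x3"]].to_numpy() + shift) / dens
    return SupercellModel(cell=supercell, atoms=atoms)


def _com_table(model: SupercellModel, chains: Sequence[str]) -> np.ndarray:
    return np.array([model.chain_com(ch) for ch in chains])


def build_families(
    folded: SupercellModel,
    assignment: Mapping[str, tuple[int, int, int]],
    chain_map: Mapping[str, Sequence[str]] | None = None,
    match_tolerance: float = 10.0,
) -> list[ChainFamily]:
    """Group chains across basic cells into tNCS families.

    Without an explicit ``chain_map`` (family label -> member chain ids),
    chains in each cell are matched one-to-one to the reference cell's chains
    by folded center-of-mass distance (optimal assignment); matches beyond
    ``match_tolerance`` (Angstrom) fail, and two chains of one cell within
    tolerance of the same reference chain raise
    :class:`AmbiguousChainMatchError` asking for an explicit map.
    """
    cells: dict[tuple[int, int, int], list[str]] = {}
    for chain, cell in assignment.items():
        cells.setdefault(cell, []).append(chain)

    if chain_map is not None:
        families = []
        for label, member_ids in chain_map.items():
            members = {assignment[ch]: ch for ch in member_ids}
            families.append(ChainFamily(label=label, reference=member_ids[0],
                                        members=members))
        return families

    lengths = np.array(folded.cell.lengths)
    ref_cell = min(cells)
    ref_chains = sorted(cells[ref_cell])
    ref_coms = _com_table(folded, ref_chains)

    families = [ChainFamily(label=f"{ch}'", reference=ch, members={ref_cell: ch})
                for ch in ref_chains]
    for cell in sorted(c for c in cells if c != ref_cell):
        member_chains = cells[cell]
        coms = _com_table(folded, member_chains)
        # Distances in Angstrom via cell-edge scaling of fractional offsets.
        diff = (coms[:, None, :] - ref_coms[None, :, :]) * lengths
        dist = np.linalg.norm(diff, axis=2)
        for j, ref in enumerate(ref_chains):
            close = [member_chains[i] for i in np.nonzero(dist[:, j] < match_tolerance)[0]]
            if len(close) > 1:
                raise AmbiguousChainMatchError(ref, close)
        rows, cols = linear_sum_assignment(dist)
        for i, j in zip(rows, cols):
            if dist[i, j] > match_tolerance:
                raise SuperspacerError(
                    f"chain {member_chains[i]!r} in cell {cell} has no reference "
                    f"match within {match_tolerance} A (closest: "
                    f"{ref_chains[j]!r} at {dist[i, j]:.1f} A)"
                )
            families[j].members[cell] = member_chains[i]
    return families


def average_structure(folded: SupercellModel, families: Sequence[ChainFamily]) -> AverageStructure:
    """Mean folded position of every atom over the family members where present.

    Atom correspondence across members is by (residue number, atom name);
    the presence count supports occupancy-modulated species that are absent
    from some basic cells.
    """
    if not families:
        raise ValueError("no families supplied")
    tables: dict[str, pd.DataFrame] = {}
    n_members: dict[str, int] = {}
    atoms = folded.atoms
    for fam in families:
        member_atoms = atoms[atoms["chain"].isin(fam.chain_ids)]
        grouped = member_atoms.groupby(["resseq", "atom"], sort=True)
        tab = grouped.agg(
            x1=("x1", "mean"), x2=("x2", "mean"), x3=("x3", "mean"),
            presence=("chain", "size"),
            resname=("resname", "first"), element=("element", "first"),
        )
        tables[fam.label] = tab
        n_members[fam.label] = len(fam)
    return AverageStructure(tables=tables, n_members=n_members)


def compute_x4(x_avg: Sequence[float], q: RationalQ,
               n: Sequence[int] = (0, 0, 0)) -> tuple[float, float]:
    """Superspace coordinate of an average position in basic cell n.

    x4 = sum_i sigma_i * (x_avg_i + n_i); the fractional part is taken with
    floor (not truncation) so negative x4 lands correctly in [0, 1).
    """
    x4 = sum(float(s) * (float(x) + int(ni))
             for s, x, ni in zip(q.components, x_avg, n))
    return x4, x4 - math.floor(x4)


def superorder(q: RationalQ,
               origin: Sequence[Fraction | int | float] = (0, 0, 0)) -> SuperspaceOrdering:
    """Order the basic cells of the supercell by fractional x4.

    Enumerates every basic-cell index vector, computes
    t = frac(sum_i sigma_i * (origin_i + n_i)) exactly, and sorts ascending
    (ties broken by ascending cell index, stable).  The default origin is the
    basic-cell corner (0, 0, 0).  Works for q with any number of nonzero
    components, e.g. a two-axis 5 x 7 supercell of 35 cells.
    """
    dens = q.denominators
    origin = [Fraction(o) for o in origin]
    entries = []
    for n in product(*(range(d) for d in dens)):
        t = sum((s * (o + ni) for s, o, ni in zip(q.components, origin, n)),
                start=Fraction(0)) % 1
        entries.append((t, n))
    entries.sort(key=lambda e: (e[0], e[1]))
    return SuperspaceOrdering(
        cells=[n for _, n in entries],
        t_values=[t for t, _ in entries],
        denominators=dens,
    )
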