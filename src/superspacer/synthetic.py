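"""Synthetic modulated-supercell generator with known ground truth.

Builds a basic cell of pseudo-random C-alpha trace chains, expands it to a
commensurate supercell by displacing each chain rigidly according to a
prescribed atomic modulation function (sinusoid, sawtooth or constant per
axis, optionally with an occupancy window in t), and simulates the 00l
diffraction systematics of the result with point scatterers.  Every output
carries a :class:`SyntheticTruth` record so the partitioning, family
matching, ordering, AMF sampling, q estimation and tNCS detection stages can
all be verified against construction.

The default exemplars emulate the geometry of the two deposited Hyp-1-ANS
superstructures: a sevenfold supercell with q = (0, 0, 3/7) and a ninefold
supercell with q = (0, 0, 4/9), each with four chains per basic-cell ASU
(PDB entries 4n3e and 6sjj).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ModelBuildError
from .partition import ATOM_COLUMNS, CellParameters, SupercellModel
from .qvector import IntensityProfile, RationalQ
from .tncs import ReflectionSet

__all__ = [
    "AxisModulation",
    "AMFSpec",
    "SyntheticTruth",
    "make_basic_cell",
    "make_modulated_supercell",
    "simulate_intensities",
    "make_sevenfold_example",
    "make_ninefold_example",
    "HYP1_BASIC_CELL",
]

# Basic cell of the sevenfold Hyp-1-ANS superstructure (supercell c = 298.56 A / 7).
HYP1_BASIC_CELL = CellParameters(146.29, 146.29, 42.65, 90.0, 90.0, 90.0)

_CHAIN_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class AxisModulation:
    """Displacive AMF of one family along one axis.

    waveform: "sinusoid" -> A*sin(2*pi*(x4 + phase));
              "sawtooth" -> A*(2*frac(x4 + phase - reset) - 1), resetting
              from +A to -A at x4 = reset - phase (mod 1);
              "constant" -> 0.
    Amplitude is in basic-cell fractional units and must stay small
    relative to the cell.
    """

    waveform: str = "constant"
    amplitude: float = 0.0
    phase: float = 0.0
    reset: float = 0.5

    def __post_init__(self):
        if self.waveform not in ("sinusoid", "sawtooth", "constant"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if not 0 <= self.amplitude <= 0.05:
            raise ValueError("amplitude must be in [0, 0.05] fractional units")
        if not 0 <= self.phase < 1:
            raise ValueError("phase must be in [0, 1)")

    def __call__(self, x4: float) -> float:
        if self.waveform == "constant" or self.amplitude == 0:
            return 0.0
        s = (x4 + self.phase) % 1.0
        if self.waveform == "sinusoid":
            return self.amplitude * math.sin(2.0 * math.pi * s)
        frac = (s - self.reset) % 1.0
        return self.amplitude * (2.0 * frac - 1.0)


@dataclass
class AMFSpec:
    """Per-family modulation recipe.

    ``displacive[chain]`` gives an :class:`AxisModulation` triple (x1, x2, x3)
    for that reference chain; ``occupancy[chain]`` optionally restricts the
    family to cells whose t lies in [t0, t1) (cyclically if t0 > t1).
    Families not listed are unmodulated.
    """

    displacive: dict[str, tuple[AxisModulation, AxisModulation, AxisModulation]] = field(
        default_factory=dict)
    occupancy: dict[str, tuple[float, float]] = field(default_factory=dict)

    def modulation(self, chain: str) -> tuple[AxisModulation, ...]:
        return self.displacive.get(chain, (AxisModulation(),) * 3)

    def occupied(self, chain: str, t: float) -> bool:
        window = self.occupancy.get(chain)
        if window is None:
            return True
        t0, t1 = window
        t = t % 1.0
        return (t0 <= t < t1) if t0 <= t1 else (t >= t0 or t < t1)


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for a generated supercell.

    ``chains`` is indexed by supercell chain id with the source family
    (reference chain of the basic cell), 0-based cell index, exact t, and
    the applied rigid displacement (basic-cell fractional units).
    """

    q: RationalQ
    seed: int | None
    basic_cell: CellParameters
    spec: AMFSpec
    chains: pd.DataFrame  # chain, family, n1, n2, n3, t, u1, u2, u3

    def cell_of(self, chain: str) -> tuple[int, int, int]:
        row = self.chains.loc[self.chains["chain"] == chain].iloc[0]
        return (int(row["n1"]), int(row["n2"]), int(row["n3"]))

    def family_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, row in self.chains.sort_values(["n1", "n2", "n3"]).iterrows():
            out.setdefault(str(row["family"]), []).append(str(row["chain"]))
        return out


def make_basic_cell(
    n_families: int = 4,
    n_residues: int = 20,
    cell: CellParameters = HYP1_BASIC_CELL,
    seed: int = 0,
    min_separation: float = 15.0,
) -> SupercellModel:
    """Build a single basic cell of pseudo-random C-alpha trace chains.

    Chain centers of mass are dart-thrown in the central region of the cell
    with a minimum Cartesian separation (``min_separation``, Angstrom);
    each chain is a 3.8 A-step random walk re-centered on its COM.  Fully
    deterministic for a given seed.
    """
    if n_families < 1 or n_residues < 3:
        raise ValueError("need n_families >= 1 and n_residues >= 3")
    rng = np.random.default_rng(seed)
    lengths = np.array(cell.lengths)
    coms: list[np.ndarray] = []
    for _ in range(n_families):
        for _attempt in range(2000):
            cand = rng.uniform(0.25, 0.75, size=3)
            if all(np.linalg.norm((cand - c) * lengths) >= min_separation for c in coms):
                coms.append(cand)
                break
        else:
            raise ModelBuildError(
                f"could not place {n_families} chains {min_separation} A apart "
                f"in a {cell.lengths} cell"
            )
    records = []
    for fam_idx, com in enumerate(coms):
        chain_id = _CHAIN_POOL[fam_idx]
        steps = rng.normal(size=(n_residues - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        walk = np.vstack([np.zeros(3), np.cumsum(3.8 * steps, axis=0)])
        walk -= walk.mean(axis=0)
        frac = com + walk / lengths
        for res_i, pos in enumerate(frac, start=1):
            records.append((chain_id, res_i, "ALA", "CA", "C",
                            pos[0], pos[1], pos[2], 1.0, 20.0))
    atoms = pd.DataFrame.from_records(records, columns=ATOM_COLUMNS)
    return SupercellModel(cell=cell, atoms=atoms)


def make_modulated_supercell(
    basic: SupercellModel,
    q: RationalQ,
    spec: AMFSpec | None = None,
    seed: int | None = None,
) -> tuple[SupercellModel, SyntheticTruth]:
    """Expand a basic cell into a modulated commensurate supercell.

    For every basic cell n and family, the AMF is evaluated at
    x4 = q . com + t(n) (corner-origin t = frac(q . n)) and all atoms of the
    family's chain are displaced rigidly by the result; occupancy windows
    drop the chain from cells whose t falls outside.  Supercell axes are the
    basic axes times the q denominators and chains get fresh unique ids.
    A displacement that would push a chain COM across its cell boundary
    raises, keeping the assignment recoverable downstream.
    """
    spec = spec if spec is not None else AMFSpec()
    dens = q.denominators
    n_cells = dens[0] * dens[1] * dens[2]
    ref_chains = basic.chains
    if n_cells * len(ref_chains) > len(_CHAIN_POOL):
        raise ModelBuildError("too many chains for unique single-character ids")

    sigma = np.array([float(s) for s in q.components])
    records, truth_rows = [], []
    for cell_rank, n in enumerate(product(*(range(d) for d in dens))):
        t_exact = sum((s * ni for s, ni in zip(q.components, n)), start=Fraction(0)) % 1
        t = float(t_exact)
        for fam_idx, ref in enumerate(ref_chains):
            if not spec.occupied(ref, t):
                continue
            new_id = _CHAIN_POOL[cell_rank * len(ref_chains) + fam_idx]
            chain_atoms = basic.atoms[basic.atoms["chain"] == ref]
            com = chain_atoms[["x1", "x2", "x3"]].to_numpy().mean(axis=0)
            x4 = float(sigma @ com) + t
            u = np.array([m(x4) for m in spec.modulation(ref)])
            displaced_com = com + u
            if np.any(displaced_com < 0) or np.any(displaced_com >= 1):
                raise ModelBuildError(
                    f"modulation pushes chain {ref!r} COM out of its basic cell "
                    f"in cell {n}; reduce amplitudes"
                )
            xyz = chain_atoms[["x1", "x2", "x3"]].to_numpy() + u
            xyz_super = (xyz + np.array(n)) / np.array(dens, dtype=float)
            for (_, row), pos in zip(chain_atoms.iterrows(), xyz_super):
                records.append((new_id, row["resseq"], row["resname"], row["atom"],
                                row["element"], pos[0], pos[1], pos[2],
                                row["occ"], row["bfac"]))
            truth_rows.append((new_id, ref, *n, t, *u))

    atoms = pd.DataFrame.from_records(records, columns=ATOM_COLUMNS)
    b = basic.cell
    supercell = CellParameters(b.a * dens[0], b.b * dens[1], b.c * dens[2],
                               b.alpha, b.beta, b.gamma)
    model = SupercellModel(cell=supercell, atoms=atoms)
    truth = SyntheticTruth(
        q=q, seed=seed, basic_cell=b, spec=spec,
        chains=pd.DataFrame(truth_rows,
                            columns=["chain", "family", "n1", "n2", "n3",
                                     "t", "u1", "u2", "u3"]),
    )
    return model, truth


def simulate_intensities(
    model: SupercellModel,
    index_range: Iterable[int] = range(0, 127),
) -> tuple[ReflectionSet, IntensityProfile]:
    """Point-scatterer 00l diffraction of a supercell model.

    F(00l) = sum over atoms of occ * exp(-B * s^2 / 4) * exp(2*pi*i*l*x3)
    with unit scattering factors, s = l/c the scattering-vector length of the
    00l reflection, and B the atomic displacement parameter — real intensity
    data decays with resolution, and omitting the Debye-Waller factor would
    leave unphysical series-termination ripple in Patterson syntheses.
    Intensities are |F|^2.  The profile (mean intensity per l — one 00l
    reflection per l here) carries the main/satellite systematics the
    q-vector and tNCS diagnostics read.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    ls = np.array(sorted(set(int(l) for l in index_range)))
    x3 = model.atoms["x3"].to_numpy()
    occ = model.atoms["occ"].to_numpy()
    bfac = model.atoms["bfac"].to_numpy()
    s2 = (ls / model.cell.c) ** 2
    dw = np.exp(-0.25 * np.outer(s2, bfac))
    phase = 2.0 * np.pi * np.outer(ls, x3)
    F = (occ * dw * np.exp(1j * phase)).sum(axis=1)
    I = np.abs(F) ** 2
    refl = ReflectionSet(h=np.zeros_like(ls), k=np.zeros_like(ls), l=ls,
                         values=I, kind="I")
    return refl, IntensityProfile(indices=ls, intensities=I, axis="l")


def _default_spec(chains: Sequence[str]) -> AMFSpec:
    """Exemplar modulation: mirror-paired sinusoids in x1/x2, sawtooth in x3.

    Emulates the qualitative features of the Hyp-1-ANS superstructures:
    transverse sinusoidal AMFs forming mirror pairs between families, and a
    sawtooth along the stacking axis whose reset position differs per family
    (two families resetting together, one lagging, one ahead).
    """
    displacive = {}
    resets = [0.5, 0.5, 0.25, 0.75]
    for i, ch in enumerate(chains):
        pair = i % 2
        sign_phase = 0.0 if i < 2 else 0.5  # mirror partner: half-period shift
        displacive[ch] = (
            AxisModulation("sinusoid", 0.012, (0.15 * pair + sign_phase) % 1.0),
            AxisModulation("sinusoid", 0.008, (0.40 * pair + sign_phase) % 1.0),
            AxisModulation("sawtooth", 0.010, 0.0, resets[i % 4]),
        )
    return AMFSpec(displacive=displacive)


def make_sevenfold_example(
    seed: int = 1,
    n_families: int = 4,
    n_residues: int = 20,
    spec: AMFSpec | None = None,
) -> tuple[SupercellModel, SyntheticTruth]:
    """Sevenfold exemplar: q = (0, 0, 3/7), four chains per basic-cell ASU.

    Emulates the supercell geometry of PDB entry 4n3e (28 chains, supercell
    c = 7 x 42.65 A = 298.55 A).
    """
    basic = make_basic_cell(n_families, n_residues, HYP1_BASIC_CELL, seed=seed)
    q = RationalQ(Fraction(0), Fraction(0), Fraction(3, 7))
    spec = spec if spec is not None else _default_spec(basic.chains)
    return make_modulated_supercell(basic, q, spec, seed=seed)


def make_ninefold_example(
    seed: int = 1,
    n_families: int = 4,
    n_residues: int = 20,
    spec: AMFSpec | None = None,
) -> tuple[SupercellModel, SyntheticTruth]:
    """Ninefold exemplar: q = (0, 0, 4/9), four chains per basic-cell ASU.

    Emulates the supercell geometry of PDB entry 6sjj (36 chains in a
    ninefold stack of the same basic cell family arrangement).
    """
    basic = make_basic_cell(n_families, n_residues, HYP1_BASIC_CELL, seed=seed)
    q = RationalQ(Fraction(0), Fraction(0), Fraction(4, 9))
    spec = spec if spec is not None else _default_spec(basic.chains)
    return make_modulated_supercell(basic, q, spec, seed=seed)
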