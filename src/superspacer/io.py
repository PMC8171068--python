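"""Coordinate and reflection file I/O (PDB, mmCIF, structure-factor mmCIF, MTZ).

All parsing goes through gemmi; this module only converts between gemmi's
containers and the package's flat atom/reflection tables.  Fractional
coordinates are wrapped to [0, 1) at read time; altloc conflicts keep the
highest-occupancy conformer; negative measured intensities are clamped to
zero with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .amf import AMFSeries, FrameSequence
from .errors import FormatError
from .partition import ATOM_COLUMNS, CellParameters, SupercellModel
from .qvector import IntensityProfile
from .tncs import ReflectionSet

__all__ = [
    "read_coordinates",
    "write_pdb",
    "write_mmcif",
    "write_frames_pdb",
    "read_reflections",
    "write_sf_mmcif",
    "write_profile_tsv",
    "write_series_tsv",
]


def _cell_from_gemmi(cell: gemmi.UnitCell) -> CellParameters:
    return CellParameters(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


def read_coordinates(path: str | Path) -> SupercellModel:
    """Read a PDB or mmCIF coordinate file into a :class:`SupercellModel`.

    Requires cell parameters (CRYST1 / _cell); rejects multi-model files;
    keeps the highest-occupancy conformer at altloc'd positions.  Orthogonal
    Angstrom coordinates are fractionalized through the cell and wrapped to
    [0, 1).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path.name}: no models")
    if len(st) > 1:
        raise FormatError(
            f"{path.name}: {len(st)} models; supercell input must be single-model"
        )
    cell = st.cell
    if cell.a <= 1.0 or cell.b <= 1.0 or cell.c <= 1.0:
        raise FormatError(f"{path.name}: missing or degenerate cell parameters")
    records = []
    for chain in st[0]:
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                f = cell.fractionalize(atom.pos)
                records.append((chain.name, res.seqid.num, res.name, atom.name,
                                atom.element.name,
                                f.x % 1.0, f.y % 1.0, f.z % 1.0,
                                atom.occ, atom.b_iso))
    if not records:
        raise FormatError(f"{path.name}: no atoms")
    atoms = pd.DataFrame.from_records(records, columns=ATOM_COLUMNS)
    return SupercellModel(cell=_cell_from_gemmi(cell), atoms=atoms)


def _to_gemmi_structure(models: Sequence[SupercellModel], name: str = "superspacer") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    cell = models[0].cell
    st.cell = gemmi.UnitCell(*cell.lengths, *cell.angles)
    st.spacegroup_hm = "P 1"
    for k, model in enumerate(models, start=1):
        gm = gemmi.Model(str(k))
        for chain_id in model.chains:
            ch = gemmi.Chain(str(chain_id))
            sub = model.atoms[model.atoms["chain"] == chain_id]
            for resseq, res_atoms in sub.groupby("resseq", sort=True):
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(int(resseq), " ")
                res.name = str(res_atoms["resname"].iloc[0])
                res.het_flag = "A"
                for _, row in res_atoms.iterrows():
                    at = gemmi.Atom()
                    at.name = str(row["atom"])
                    at.element = gemmi.Element(str(row["element"]))
                    frac = gemmi.Fractional(row["x1"], row["x2"], row["x3"])
                    at.pos = st.cell.orthogonalize(frac)
                    at.occ = float(row["occ"])
                    at.b_iso = float(row["bfac"])
                    res.add_atom(at)
                ch.add_residue(res)
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: SupercellModel, path: str | Path) -> None:
    _to_gemmi_structure([model]).write_pdb(str(path))


def write_mmcif(model: SupercellModel, path: str | Path) -> None:
    _to_gemmi_structure([model]).make_mmcif_document().write_file(str(path))


def write_frames_pdb(frames: FrameSequence, path: str | Path) -> None:
    """Write an animation as a multi-model PDB, one model per superspace frame."""
    _to_gemmi_structure(frames.frames, name="frames").write_pdb(str(path))


def _reflections_from_arrays(h, k, l, values, kind, source: str) -> ReflectionSet:
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        warnings.warn(f"{source}: negative {kind} values clamped to 0")
        values = np.clip(values, 0.0, None)
    hkl = np.stack([h, k, l], axis=1)
    uniq, counts = np.unique(hkl, axis=0, return_counts=True)
    if np.any(counts > 1):
        dup = tuple(int(x) for x in uniq[counts > 1][0])
        raise FormatError(f"{source}: duplicate reflection {dup}")
    return ReflectionSet(h=h, k=k, l=l, values=values, kind=kind)


def read_reflections(path: str | Path) -> ReflectionSet:
    """Read reflections from structure-factor mmCIF (or MTZ).

    Uses the _refln loop's intensity_meas column when present, otherwise
    F_meas(_au) squared to intensities.  Duplicate (h, k, l) rows and files
    with neither column are errors.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtz":
        mtz = gemmi.read_mtz_file(str(path))
        arr = np.array(mtz, copy=False)
        cols = [c.label for c in mtz.columns]
        hkl = {lab: arr[:, cols.index(lab)].astype(int) for lab in ("H", "K", "L")}
        for label, kind in (("I", "I"), ("IMEAN", "I"), ("F", "F"), ("FP", "F")):
            if label in cols:
                return _reflections_from_arrays(
                    hkl["H"], hkl["K"], hkl["L"],
                    arr[:, cols.index(label)], kind, path.name)
        raise FormatError(f"{path.name}: no I/IMEAN/F/FP column")
    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    block = None
    for blk in doc:
        if blk.find_values("_refln.index_h"):
            block = blk
            break
    if block is None:
        raise FormatError(f"{path.name}: no _refln loop")

    def column(tag: str) -> np.ndarray | None:
        vals = block.find_values(f"_refln.{tag}")
        if not vals:
            return None
        return np.array([gemmi.cif.as_number(v) for v in vals])

    h = column("index_h").astype(int)
    k = column("index_k").astype(int)
    l = column("index_l").astype(int)
    inten = column("intensity_meas")
    if inten is not None:
        return _reflections_from_arrays(h, k, l, inten, "I", path.name)
    for tag in ("F_meas_au", "F_meas"):
        famp = column(tag)
        if famp is not None:
            return _reflections_from_arrays(h, k, l, famp, "F", path.name)
    raise FormatError(f"{path.name}: neither intensity_meas nor F_meas present")


def write_sf_mmcif(refl: ReflectionSet, path: str | Path) -> None:
    """Write reflections as a minimal structure-factor mmCIF _refln loop."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("reflections")
    tag = "intensity_meas" if refl.kind == "I" else "F_meas_au"
    loop = block.init_loop("_refln.", ["index_h", "index_k", "index_l", tag])
    for h, k, l, v in zip(refl.h, refl.k, refl.l, refl.values):
        loop.add_row([str(int(h)), str(int(k)), str(int(l)), f"{v:.6g}"])
    doc.write_file(str(path))


def write_profile_tsv(profile: IntensityProfile, path: str | Path) -> None:
    pd.DataFrame({profile.axis: profile.indices, "mean_I": profile.intensities}) \
        .to_csv(path, sep="\t", index=False)


def write_series_tsv(series_by_axis: dict[str, AMFSeries], path: str | Path) -> None:
    """One TSV for a family's three-axis AMF series: t, per-axis d in frac and A."""
    axes = sorted(series_by_axis)
    base = series_by_axis[axes[0]]
    out = {"t": base.t}
    for ax in axes:
        s = series_by_axis[ax]
        out[f"d_{ax}_frac"] = s.values
        out[f"d_{ax}_ang"] = s.values_ang
    out["present"] = base.present.astype(int)
    pd.DataFrame(out).to_csv(path, sep="\t", index=False, float_format="%.8g")
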