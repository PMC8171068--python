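"""Model/Results interface over the superspace pipeline.

:class:`SuperspaceModel` bundles a supercell coordinate model with a
modulation wavevector; :meth:`SuperspaceModel.fit` runs the decomposition —
cell assignment, folding, family matching, averaging, superspace ordering,
AMF sampling — and returns a :class:`SuperspaceResults` carrying every
intermediate product, diagnostics (sawtooth resets, mirror-pair RMS) and a
``summary()`` table.  The fit is a deterministic geometric decomposition;
"residuals" are the AMF displacement samples themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import amf as _amf
from . import io as _io
from . import partition as _partition
from .errors import NoResetError
from .qvector import DecimalQ, RationalQ, count_basic_cells, rationalize_q

__all__ = ["SuperspaceModel", "SuperspaceResults"]


class SuperspaceModel:
    """A supercell coordinate model paired with its modulation wavevector.

    Parameters
    ----------
    supercell : SupercellModel
        Atoms and cell of the deposited (or synthetic) supercell.
    q : RationalQ, DecimalQ or sequence of three numbers
        The modulation wavevector.  Decimal input is rationalized with
        ``tolerance`` and ``max_denominator``.
    chain_map : mapping, optional
        Explicit family label -> ordered member chain ids, overriding
        COM-distance matching.
    match_tolerance : float
        Family-matching COM tolerance in Angstrom.
    """

    def __init__(
        self,
        supercell: _partition.SupercellModel,
        q: RationalQ | DecimalQ | Sequence[float],
        chain_map: Mapping[str, Sequence[str]] | None = None,
        match_tolerance: float = 10.0,
        tolerance: float = 1e-3,
        max_denominator: int = 50,
    ):
        self.supercell = supercell
        if not isinstance(q, RationalQ):
            q = rationalize_q(q if isinstance(q, DecimalQ) else DecimalQ(*q),
                              tolerance, max_denominator)
        self.q = q
        self.chain_map = dict(chain_map) if chain_map else None
        self.match_tolerance = match_tolerance

    @classmethod
    def from_file(cls, path: str | Path, q, **kwargs) -> "SuperspaceModel":
        """Build from a PDB/mmCIF file (see :func:`superspacer.io.read_coordinates`)."""
        return cls(_io.read_coordinates(path), q, **kwargs)

    def fit(self, selector: str = "com") -> "SuperspaceResults":
        """Run the full supercell -> superspace decomposition."""
        assignment = _partition.assign_cells(self.supercell, self.q)
        folded = _partition.fold_to_basic(self.supercell, assignment, self.q)
        families = _partition.build_families(
            folded, assignment, chain_map=self.chain_map,
            match_tolerance=self.match_tolerance)
        average = _partition.average_structure(folded, families)
        ordering = _partition.superorder(self.q)
        series = {f.label: _amf.occupancy_series(folded, f, average, ordering, selector)
                  for f in families}
        frames = _amf.export_frames(folded, assignment, families, ordering)
        return SuperspaceResults(
            model=self, assignment=assignment, folded=folded,
            families=families, average=average, ordering=ordering,
            series=series, frames=frames,
        )


@dataclass
class SuperspaceResults:
    """Products of the superspace decomposition of one supercell."""

    model: SuperspaceModel
    assignment: dict[str, tuple[int, int, int]]
    folded: _partition.SupercellModel
    families: list[_partition.ChainFamily]
    average: _partition.AverageStructure
    ordering: _partition.SuperspaceOrdering
    series: dict[str, dict[str, _amf.AMFSeries]]
    frames: _amf.FrameSequence

    @property
    def q(self) -> RationalQ:
        return self.model.q

    @property
    def n_basic_cells(self) -> int:
        return count_basic_cells(self.q)

    @property
    def basic_cell(self) -> _partition.CellParameters:
        return self.folded.cell

    def sawtooth_resets(self, axis: str = "x3") -> dict[str, _amf.SawtoothReset | None]:
        """Per-family sawtooth reset along one axis (None where no reset exists)."""
        out = {}
        for label, per_axis in self.series.items():
            try:
                out[label] = _amf.detect_sawtooth_reset(per_axis[axis])
            except (NoResetError, ValueError):
                out[label] = None
        return out

    def mirror_rms(self, family_a: str, family_b: str, axis: str = "x1") -> float:
        """RMS difference of two family AMFs under the t -> 1 - t mirror."""
        return _amf.compare_series(self.series[family_a][axis],
                                   self.series[family_b][axis],
                                   transform="mirror_t")

    def summary(self) -> str:
        """Human-readable account: cells, ordering, families, AMF diagnostics."""
        q = self.q
        sc = self.model.supercell.cell
        bc = self.basic_cell
        lines = [
            "Superspace decomposition",
            "=" * 64,
            f"q vector:            {q}",
            f"basic cells:         {self.n_basic_cells} "
            f"({' x '.join(str(d) for d in q.denominators)})",
            f"supercell (A):       {sc.a:.2f} {sc.b:.2f} {sc.c:.2f}",
            f"basic cell (A):      {bc.a:.2f} {bc.b:.2f} {bc.c:.2f}",
            f"chains:              {len(self.model.supercell.chains)}",
            f"families:            {len(self.families)} "
            f"({', '.join(f.label for f in self.families)})",
            "",
            "Superspace order (1-based cell index : t)",
            "  " + "  ".join(f"{i}:{t}" for i, t in
                             zip(self.ordering.indices_1based, self.ordering.t_values)),
            "",
            "Families",
        ]
        for fam in self.families:
            lines.append(f"  {fam.label:6s} members {len(fam)}/{self.n_basic_cells}: "
                         + " ".join(fam.chain_ids))
        resets = self.sawtooth_resets()
        lines += ["", "Sawtooth resets along x3 (t, jump in fractional units)"]
        for label, r in resets.items():
            if r is None:
                lines.append(f"  {label:6s} no reset")
            else:
                flag = "  (low contrast)" if r.low_contrast else ""
                lines.append(f"  {label:6s} t = {r.t:.4f}, jump = {r.magnitude:.5f}{flag}")
        return "\n".join(lines)

    def export(self, outdir: str | Path) -> None:
        """Write series TSVs, the superorder table and the frame PDB to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ordering.to_frame().to_csv(outdir / "superorder.tsv", sep="\t", index=False)
        for label, per_axis in self.series.items():
            safe = label.replace("'", "p")
            _io.write_series_tsv(per_axis, outdir / f"amf_{safe}.tsv")
        _io.write_frames_pdb(self.frames, outdir / "frames.pdb")
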