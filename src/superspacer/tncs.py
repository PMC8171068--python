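"""Translational NCS diagnostics via a one-dimensional Patterson section.

Translational noncrystallographic symmetry (tNCS) — near-identical copies of
a molecule repeated by a fractional lattice translation — produces strong
non-origin peaks in the Patterson map at multiples of the repeat vector.  For
an N-fold supercell stacked along c the signature is a peak every 1/N along
the w Patterson direction.  A 1D section P(w) at (u, v) = (0, 0) carries the
whole diagnostic: every reflection (h, k, l) contributes cos(2*pi*l*w) there,
so the section is a cosine series over l weighted by intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import find_peaks

from .errors import NoTncsError

__all__ = ["ReflectionSet", "PattersonSection", "patterson_section", "detect_tncs_spacing"]


@dataclass
class ReflectionSet:
    """Reflections as parallel arrays of Miller indices and amplitudes or intensities.

    ``kind`` is "I" (intensities) or "F" (amplitudes, squared to intensities
    on use).  Duplicate (h, k, l) triples are rejected.
    """

    h: np.ndarray
    k: np.ndarray
    l: np.ndarray
    values: np.ndarray
    kind: str = "I"

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=int)
        self.k = np.asarray(self.k, dtype=int)
        self.l = np.asarray(self.l, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("I", "F"):
            raise ValueError("kind must be 'I' or 'F'")
        if not (self.h.shape == self.k.shape == self.l.shape == self.values.shape):
            raise ValueError("h, k, l, values must have equal shapes")
        if np.any(self.values < 0):
            raise ValueError("amplitudes/intensities must be non-negative")
        hkl = np.stack([self.h, self.k, self.l], axis=1)
        uniq = np.unique(hkl, axis=0)
        if len(uniq) != len(hkl):
            seen, dup = set(), None
            for t in map(tuple, hkl):
                if t in seen:
                    dup = t
                    break
                seen.add(t)
            raise ValueError(f"duplicate reflection {dup}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def intensities(self) -> np.ndarray:
        return self.values**2 if self.kind == "F" else self.values


@dataclass
class PattersonSection:
    """P(w) on a uniform grid of fractional w in [0, 1), origin-normalized to 1."""

    w: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.w)


def patterson_section(refl: ReflectionSet, n_grid: int = 512) -> PattersonSection:
    """Cosine Patterson synthesis along w at (u, v) = (0, 0).

    P(w) = sum over reflections of I(hkl) * cos(2*pi*l*w); any h, k collapse
    onto the l-cosine on this section.  The result is normalized so P(0) = 1.
    P is centrosymmetric (P(w) = P(1 - w)) because the synthesis is a pure
    cosine series.
    """
    if len(refl) == 0:
        raise ValueError("empty reflection set")
    inten = refl.intensities
    if not np.any(inten > 0):
        raise ValueError("all intensities are zero; Patterson section undefined")
    w = np.arange(n_grid) / n_grid
    values = np.cos(2.0 * np.pi * np.outer(w, refl.l)) @ inten
    return PattersonSection(w=w, values=values / values[0])


def detect_tncs_spacing(
    sec: PattersonSection,
    peak_threshold: float = 0.2,
    max_denominator: int = 24,
    rel_strength: float = 0.5,
) -> tuple[Fraction, np.ndarray]:
    """Detect the tNCS repeat 1/N from non-origin Patterson peaks.

    Local maxima of the section with origin-normalized height >=
    ``peak_threshold`` are located away from the origin; maxima weaker than
    ``rel_strength`` of the strongest non-origin peak are discarded (tNCS
    repeat peaks are near-origin-height, while truncation ripple and minor
    interatomic vectors are not).  The mean nearest-neighbour spacing of the
    survivors is computed (including the gaps to w = 0 and w = 1, which the
    origin peak occupies) and snapped to the nearest 1/N with
    N <= ``max_denominator``.  Returns (1/N, peak positions).
    """
    if not 0 < peak_threshold < 1:
        raise ValueError("peak_threshold must be in (0, 1)")
    pk, props = find_peaks(sec.values, height=peak_threshold)
    if len(pk) == 0:
        raise NoTncsError(
            f"no tNCS detected: no non-origin peaks above {peak_threshold}"
        )
    heights = props["peak_heights"]
    keep = heights >= rel_strength * heights.max()
    positions = sec.w[pk[keep]]
    # Nearest-neighbour gaps, treating the origin peak at w = 0 (== 1) as a peak.
    augmented = np.concatenate([[0.0], np.sort(positions), [1.0]])
    spacing = float(np.diff(augmented).mean())
    denominators = np.arange(1, max_denominator + 1)
    N = int(denominators[np.argmin(np.abs(1.0 / denominators - spacing))])
    return Fraction(1, N), positions
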