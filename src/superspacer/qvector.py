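"""Modulation wavevector (q) handling.

A commensurately modulated crystal diffracts with strong *main* reflections
and weaker *satellite* reflections.  The q vector gives the reciprocal-space
offset of a first-order satellite from its main reflection, in units of the
basic-cell reciprocal lattice.  When every component sigma_n of q is rational
(sigma_n = p_n / N_n in lowest terms) the structure is commensurate and can be
described by a supercell of prod(N_n) basic cells, N_n of them along axis n.

This module represents q in decimal and rational form, rationalizes a decimal
q to within a tolerance, estimates q from the systematics of average
reflection intensities along one reciprocal axis, and reindexes supercell
reflection indices l into superspace (h3, h4) labels, where h3 counts main
reflections and h4 is the satellite order.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .errors import NoModulationError, RationalizationError

__all__ = [
    "DecimalQ",
    "RationalQ",
    "IntensityProfile",
    "SuperspaceIndex",
    "rationalize_q",
    "rationalize_component",
    "count_basic_cells",
    "cells_along_dimension",
    "estimate_q_from_profile",
    "reindex_reflection",
]


@dataclass(frozen=True)
class DecimalQ:
    """Modulation wavevector with real components, reduced modulo 1."""

    sigma1: float
    sigma2: float
    sigma3: float

    def __post_init__(self):
        for name in ("sigma1", "sigma2", "sigma3"):
            v = float(getattr(self, name)) % 1.0
            object.__setattr__(self, name, v)

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.sigma1, self.sigma2, self.sigma3)


@dataclass(frozen=True)
class RationalQ:
    """Rational modulation wavevector; each component a Fraction in [0, 1).

    The supercell implied by q has ``denominator`` basic cells along each
    axis and their product in total.
    """

    sigma1: Fraction
    sigma2: Fraction
    sigma3: Fraction

    def __post_init__(self):
        for name in ("sigma1", "sigma2", "sigma3"):
            v = Fraction(getattr(self, name)) % 1
            object.__setattr__(self, name, v)

    @classmethod
    def from_tuples(cls, *pairs: tuple[int, int]) -> "RationalQ":
        if len(pairs) != 3:
            raise ValueError("need three (numerator, denominator) pairs")
        return cls(*(Fraction(p, q) for p, q in pairs))

    @property
    def components(self) -> tuple[Fraction, Fraction, Fraction]:
        return (self.sigma1, self.sigma2, self.sigma3)

    @property
    def denominators(self) -> tuple[int, int, int]:
        return tuple(c.denominator for c in self.components)

    @property
    def numerators(self) -> tuple[int, int, int]:
        return tuple(c.numerator for c in self.components)

    def to_decimal(self) -> DecimalQ:
        return DecimalQ(*(float(c) for c in self.components))

    def __str__(self) -> str:
        return "(" + ", ".join(str(c) for c in self.components) + ")"


@dataclass(frozen=True)
class SuperspaceIndex:
    """Superspace label of one reflection: main index h3 and satellite order h4."""

    h3: int
    h4: int


@dataclass
class IntensityProfile:
    """Average reflection intensity as a function of one reciprocal index.

    ``indices`` must be strictly increasing integers; ``intensities`` are the
    mean observed intensities at those index values (non-negative).
    """

    indices: np.ndarray
    intensities: np.ndarray
    axis: str = "l"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.indices.shape != self.intensities.shape or self.indices.ndim != 1:
            raise ValueError("indices and intensities must be 1D and equal length")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("indices must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)


def rationalize_component(sigma: float, tolerance: float, max_denominator: int) -> Fraction:
    """Smallest-denominator fraction p/N with N <= max_denominator and |p/N - sigma| <= tolerance.

    Scanning denominators in ascending order and taking the nearest numerator
    guarantees the minimal-denominator solution; the returned Fraction is in
    lowest terms and reduced modulo 1.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if max_denominator < 1:
        raise ValueError("max_denominator must be >= 1")
    sigma = float(sigma) % 1.0
    for den in range(1, max_denominator + 1):
        num = round(sigma * den)
        if abs(num / den - sigma) <= tolerance:
            return Fraction(num, den) % 1
    raise RationalizationError(
        f"sigma={sigma!r} is irrational within bounds: no p/N with N <= "
        f"{max_denominator} lies within {tolerance} (effectively incommensurate)"
    )


def rationalize_q(q: DecimalQ | Sequence[float], tolerance: float = 1e-3,
                  max_denominator: int = 50) -> RationalQ:
    """Rationalize a decimal q vector component-wise to within a tolerance."""
    if not isinstance(q, DecimalQ):
        q = DecimalQ(*q)
    return RationalQ(*(rationalize_component(s, tolerance, max_denominator)
                       for s in q.components))


def count_basic_cells(q: RationalQ) -> int:
    """Total number of basic cells in the supercell: the product of the denominators."""
    d1, d2, d3 = q.denominators
    return d1 * d2 * d3


def cells_along_dimension(q: RationalQ, dim: int) -> int:
    """Number of basic cells along axis ``dim`` (1, 2 or 3): that component's denominator."""
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    return q.denominators[dim - 1]


def _class_means(indices: np.ndarray, intensities: np.ndarray, period: int) -> np.ndarray:
    """Mean intensity of each residue class of the index modulo ``period``."""
    means = np.empty(period)
    residues = indices % period
    for r in range(period):
        sel = residues == r
        means[r] = intensities[sel].mean() if sel.any() else np.nan
    return means


def estimate_q_from_profile(
    profile: IntensityProfile,
    max_denominator: int = 50,
    contrast_ratio: float = 3.0,
    satellite_floor: float = 1e-6,
) -> tuple[DecimalQ, RationalQ]:
    """Estimate the modulation wavevector from an intensity-vs-index profile.

    The main-reflection period N is the candidate for which one residue class
    of the index (mod N) dominates the others most strongly (mean intensity of
    the best class over the mean of the rest >= ``contrast_ratio``).  The
    first-order satellite offset m is the strongest non-main class, folded to
    min(m, N - m); the estimate is sigma = m/N on the profiled axis.  On
    average mains must outshine first-order satellites, which must outshine
    higher orders — profiles violating that, or with no satellite class above
    ``satellite_floor`` of the main intensity, raise :class:`NoModulationError`.
    """
    idx, inten = profile.indices, profile.intensities
    span = idx.max() - idx.min() + 1
    best = None  # (score, N, class_means)
    for period in range(2, max_denominator + 1):
        if span < 2 * period:
            break  # need at least two full periods of indices
        means = _class_means(idx, inten, period)
        if np.isnan(means).any():
            continue
        main = means.max()
        rest = np.delete(means, means.argmax())
        rest_mean = rest.mean()
        score = main / rest_mean if rest_mean > 0 else np.inf
        if score >= contrast_ratio and (best is None or score > best[0]):
            best = (score, period, means)
    if best is None:
        raise NoModulationError(
            "no modulation detected: no residue class of the index dominates "
            f"by a factor of {contrast_ratio}"
        )
    _, period, means = best
    r_main = int(means.argmax())
    main_mean = means[r_main]

    others = [(r, means[r]) for r in range(period) if r != r_main]
    r_sat, sat_mean = max(others, key=lambda t: t[1])
    if sat_mean <= satellite_floor * main_mean:
        raise NoModulationError(
            "no modulation detected: reflections repeat with a single dominant "
            f"class every {period} indices but no satellite class rises above "
            "the floor (pure translational repeat)"
        )
    m = (r_sat - r_main) % period
    m = min(m, period - m)

    # Hierarchy check: mains >= first order >= second order (on average).
    second = {(r_main + 2 * m) % period, (r_main - 2 * m) % period} - {r_main, r_sat}
    if second:
        second_mean = np.mean([means[r] for r in second])
        if not (main_mean >= sat_mean >= second_mean):
            raise NoModulationError(
                "intensity hierarchy main >= first-order >= second-order "
                "satellites does not hold; profile is not consistent with a "
                "single-q modulation"
            )
    sigma = Fraction(m, period)
    rational = RationalQ(Fraction(0), Fraction(0), sigma)
    return rational.to_decimal(), rational


def reindex_reflection(l: int, q3: Fraction) -> SuperspaceIndex:
    """Superspace label (h3, h4) of a supercell reflection index l.

    With sigma3 = p/N in lowest terms, l = h3*N + h4*p has a one-parameter
    family of integer solutions; the one with minimal |h4| is returned (a tie
    between +h4 and -h4 is broken toward the positive satellite order).
    """
    q3 = Fraction(q3)
    p, N = q3.numerator, q3.denominator
    if p == 0:
        return SuperspaceIndex(h3=int(l), h4=0)
    # h4 must satisfy h4*p ≡ l (mod N); p invertible since gcd(p, N) = 1.
    h4_mod = (int(l) * pow(p, -1, N)) % N
    candidates = (h4_mod, h4_mod - N)
    h4 = min(candidates, key=lambda h: (abs(h), -h))
    h3 = (int(l) - h4 * p) // N
    return SuperspaceIndex(h3=h3, h4=h4)
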