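"""Supercell partitioning, folding, family matching and superspace ordering."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from superspacer import (CellParameters, RationalQ, SupercellModel,
                         assign_cells, build_families, compute_x4,
                         fold_to_basic, superorder, unfold_from_basic)
from superspacer.partition import ATOM_COLUMNS

Q37 = RationalQ.from_tuples((0, 1), (0, 1), (3, 7))
Q49 = RationalQ.from_tuples((0, 1), (0, 1), (4, 9))


def _bruteforce_order_1d(p, N):
    """Sort cells 0..N-1 by frac(p*n/N); report 1-based indices."""
    return [n + 1 for n in sorted(range(N), key=lambda n: (p * n % N, n))]


@pytest.mark.parametrize("p, N", [(p, N) for N in range(1, 13) for p in range(N)
                                  if math.gcd(p, N) == 1 or (p, N) == (0, 1)])
def test_superorder_matches_bruteforce_for_all_axial_q(p, N):
    q = RationalQ(Fraction(0), Fraction(0), Fraction(p, N))
    ordering = superorder(q)
    assert ordering.indices_1based == _bruteforce_order_1d(p, N)
    assert ordering.t_values == [Fraction(k, N) for k in range(N)]


@pytest.mark.parametrize("q, expected", [
    (Q37, [1, 6, 4, 2, 7, 5, 3]),
    (Q49, [1, 8, 6, 4, 2, 9, 7, 5, 3]),
    (RationalQ.from_tuples((0, 1), (0, 1), (1, 2)), [1, 2]),
])
def test_superorder_reference_reorderings(q, expected):
    assert superorder(q).indices_1based == expected


def test_superorder_two_axis_supercell():
    """A 5 x 7 two-axis supercell: 35 cells, every t = k/35 exactly once."""
    q = RationalQ.from_tuples((1, 5), (0, 1), (2, 7))
    ordering = superorder(q)
    assert len(ordering) == 35
    assert sorted(ordering.cells) == sorted(
        (n1, 0, n3) for n1 in range(5) for n3 in range(7))
    assert ordering.t_values == [Fraction(k, 35) for k in range(35)]


def test_superorder_non_coprime_directions_degenerate():
    q = RationalQ.from_tuples((1, 2), (0, 1), (1, 2))
    ordering = superorder(q)
    assert len(ordering) == 4
    assert sorted(ordering.t_values) == [Fraction(0), Fraction(0),
                                         Fraction(1, 2), Fraction(1, 2)]


@pytest.mark.parametrize("x_avg, n, expected_frac", [
    ((0, 0, 0), (0, 0, 0), 0.0),
    ((0, 0, 0), (0, 0, 5), 1.0 / 7.0),
    ((0, 0, -0.1), (0, 0, 0), 1.0 - 3.0 / 70.0),
])
def test_x4_fractional_part_uses_floor(x_avg, n, expected_frac):
    _, frac = compute_x4(x_avg, Q37, n)
    assert frac == pytest.approx(expected_frac, abs=1e-12)


def test_x4_invariant_under_superspace_translation():
    """Shifting x_avg by an integer and n by its negative leaves frac(x4) fixed."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        x = rng.uniform(-1, 2, size=3)
        n = rng.integers(0, 7, size=3)
        m = rng.integers(-3, 4, size=3)
        _, f1 = compute_x4(x, Q37, tuple(n))
        _, f2 = compute_x4(x + m, Q37, tuple(n - m))
        assert f1 == pytest.approx(f2, abs=1e-9)


def _toy_model(coms_x3, cell_c=298.56):
    """One-atom 'chains' at given supercell x3 positions."""
    rows = [(f"C{i}", 1, "ALA", "CA", "C", 0.4, 0.4, x3, 1.0, 20.0)
            for i, x3 in enumerate(coms_x3)]
    cell = CellParameters(146.29, 146.29, cell_c)
    return SupercellModel(cell=cell, atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS))


def test_cell_assignment_by_center_of_mass():
    model = _toy_model([0.5])
    assert assign_cells(model, Q37)["C0"] == (0, 0, 3)  # floor(0.5 * 7)
    q0 = RationalQ.from_tuples((0, 1), (0, 1), (0, 1))
    assert assign_cells(model, q0)["C0"] == (0, 0, 0)


def test_boundary_center_of_mass_goes_to_lower_cell_with_warning():
    model = _toy_model([3.0 / 7.0])
    with pytest.warns(UserWarning, match="boundary"):
        assert assign_cells(model, Q37)["C0"] == (0, 0, 2)


def test_fold_divides_cell_and_roundtrips():
    model = _toy_model([0.5], cell_c=298.56)
    assignment = assign_cells(model, Q37)
    folded = fold_to_basic(model, assignment, Q37)
    assert folded.cell.c == pytest.approx(42.65, abs=5e-3)  # 298.56 / 7
    assert folded.atoms["x3"].iloc[0] == pytest.approx(0.5)  # 3.5 - 3
    back = unfold_from_basic(folded, assignment, Q37, model.cell)
    assert np.max(np.abs(back.atoms[["x1", "x2", "x3"]].to_numpy()
                         - model.atoms[["x1", "x2", "x3"]].to_numpy())) < 1e-12


def test_ninefold_supercell_axis_division():
    model = _toy_model([0.5], cell_c=385.4)
    folded = fold_to_basic(model, assign_cells(model, Q49), Q49)
    assert folded.cell.c == pytest.approx(385.4 / 9, abs=1e-9)
    assert round(folded.cell.c, 2) == 42.82


def test_family_recovery_on_synthetic_supercell(sevenfold, sevenfold_fit):
    """COM matching reproduces the generator's families and cell assignments."""
    _, truth = sevenfold
    res = sevenfold_fit
    for _, row in truth.chains.iterrows():
        assert res.assignment[row["chain"]] == (row["n1"], row["n2"], row["n3"])
    expected = truth.family_members()
    by_ref = {f.reference: sorted(f.chain_ids) for f in res.families}
    assert {r: sorted(m) for r, m in expected.items()} == by_ref
    assert all(len(f) == 7 for f in res.families)


def test_families_invariant_under_chain_relabeling(sevenfold):
    """Scrambling chain ids must not change the recovered family structure."""
    model, truth = sevenfold
    rng = np.random.default_rng(3)
    old = model.chains
    new = list(rng.permutation(old))
    mapping = dict(zip(old, new))
    shuffled = SupercellModel(cell=model.cell,
                              atoms=model.atoms.assign(
                                  chain=model.atoms["chain"].map(mapping)))
    q = truth.q
    assignment = assign_cells(shuffled, q)
    families = build_families(fold_to_basic(shuffled, assignment, q), assignment)
    got = {frozenset(f.chain_ids) for f in families}
    expected = {frozenset(mapping[c] for c in members)
                for members in truth.family_members().values()}
    assert got == expected


def test_single_cell_model_gives_singleton_families():
    model = _toy_model([0.3, 0.5], cell_c=42.65)
    q0 = RationalQ.from_tuples((0, 1), (0, 1), (0, 1))
    assignment = assign_cells(model, q0)
    families = build_families(fold_to_basic(model, assignment, q0), assignment)
    assert [len(f) for f in families] == [1, 1]


def test_explicit_chain_map_overrides_matching(sevenfold):
    model, truth = sevenfold
    q = truth.q
    assignment = assign_cells(model, q)
    folded = fold_to_basic(model, assignment, q)
    chain_map = {f"{ref}'": members for ref, members in truth.family_members().items()}
    families = build_families(folded, assignment, chain_map=chain_map)
    assert {f.label: f.chain_ids for f in families} == {
        lab: list(m) for lab, m in chain_map.items()}


def test_average_structure_means_and_presence(sevenfold, sevenfold_fit):
    model, truth = sevenfold
    res = sevenfold_fit
    avg = res.average
    for fam in res.families:
        tab = avg.tables[fam.label]
        assert (tab["presence"] == 7).all()
        # mean of member-minus-average displacements is zero per atom
        member_atoms = res.folded.atoms[res.folded.atoms["chain"].isin(fam.chain_ids)]
        keyed = member_atoms.set_index(["resseq", "atom"])
        for col in ("x1", "x2", "x3"):
            resid = keyed[col] - tab[col].reindex(keyed.index)
            assert abs(resid.groupby(level=[0, 1]).mean()).max() < 1e-12
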