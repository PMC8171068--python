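"""AMF sampling, sawtooth/occupancy diagnostics, series comparison and frames."""

from fractions import Fraction

import numpy as np
import pytest

from superspacer import (AMFSeries, AMFSpec, AxisModulation, NoResetError,
                         RationalQ, SuperspaceModel, compare_series,
                         detect_sawtooth_reset, make_basic_cell,
                         make_modulated_supercell)

Q37 = RationalQ(Fraction(0), Fraction(0), Fraction(3, 7))


def _fit(model, q=Q37):
    return SuperspaceModel(model, q).fit()


@pytest.fixture(scope="module")
def sinusoid_fit():
    """Single-family sinusoid along x1: closed-form AMF is recoverable."""
    basic = make_basic_cell(n_families=1, n_residues=10, seed=5)
    amp, phase = 0.02, 0.30
    spec = AMFSpec(displacive={
        "A": (AxisModulation("sinusoid", amp, phase),
              AxisModulation(), AxisModulation())})
    model, truth = make_modulated_supercell(basic, Q37, spec)
    return basic, amp, phase, model, truth, _fit(model)


def test_sinusoid_amf_recovered_at_sample_points(sinusoid_fit):
    """Recovered displacements equal A*sin(2*pi*(q.x_com + t + phase)) exactly.

    A sinusoid sampled at the N equispaced t values sums to zero, so the
    family average coincides with the unmodulated position and the sampled
    series reproduces the generating AMF to machine precision.
    """
    basic, amp, phase, model, truth, res = sinusoid_fit
    com = basic.atoms[["x1", "x2", "x3"]].to_numpy().mean(axis=0)
    x4_base = float(Q37.sigma3) * com[2]
    series = res.series["A'"]["x1"]
    expected = amp * np.sin(2 * np.pi * ((x4_base + series.t + phase) % 1.0))
    assert np.max(np.abs(series.values - expected)) < 1e-10
    # average position equals the unmodulated chain position
    avg_com = res.average.com("A'")
    assert np.max(np.abs(avg_com - com)) < 1e-12


def test_unmodulated_model_yields_identically_zero_series():
    basic = make_basic_cell(n_families=2, n_residues=8, seed=2)
    model, _ = make_modulated_supercell(basic, Q37, AMFSpec())
    res = _fit(model)
    for per_axis in res.series.values():
        for s in per_axis.values():
            assert np.max(np.abs(s.values)) < 1e-12


def test_displacement_series_are_zero_mean(sevenfold_fit):
    for per_axis in sevenfold_fit.series.values():
        for s in per_axis.values():
            assert abs(np.nanmean(s.values[s.present])) < 1e-10


def test_occupancy_window_presence_pattern():
    """A family present only for t < 0.5 shows exactly that presence mask."""
    basic = make_basic_cell(n_families=2, n_residues=8, seed=4)
    spec = AMFSpec(occupancy={"B": (0.0, 0.5)})
    model, truth = make_modulated_supercell(basic, Q37, spec)
    res = _fit(model)
    sb = res.series["B'"]["x1"]
    assert list(sb.present) == [t < 0.5 for t in sb.t]
    assert np.isnan(sb.values[~sb.present]).all()
    assert res.series["A'"]["x1"].present.all()
    # 3/7: t values {k/7}, those below 0.5 are 0, 1/7, 2/7, 3/7
    assert sb.present.sum() == 4


def test_sawtooth_reset_located_between_bracketing_samples():
    basic = make_basic_cell(n_families=1, n_residues=8, seed=6)
    reset = 0.6
    spec = AMFSpec(displacive={
        "A": (AxisModulation(), AxisModulation(),
              AxisModulation("sawtooth", 0.02, 0.0, reset))})
    model, _ = make_modulated_supercell(basic, Q37, spec)
    res = _fit(model)
    series = res.series["A'"]["x3"]
    com = basic.atoms[["x1", "x2", "x3"]].to_numpy().mean(axis=0)
    # generator resets at x4 = reset, i.e. t_reset = reset - q.x_com (mod 1)
    t_reset = (reset - float(Q37.sigma3) * com[2]) % 1.0
    found = detect_sawtooth_reset(series)
    assert not found.low_contrast
    ts = np.sort(series.t)
    below = ts[ts < t_reset].max() if (ts < t_reset).any() else ts.max() - 1.0
    above = ts[ts > t_reset].min() if (ts > t_reset).any() else ts.min() + 1.0
    assert below < (found.t if found.t > below else found.t + 1.0) < above
    assert found.magnitude == pytest.approx(2 * 0.02 * (1 - 1 / 7), rel=0.2)


def test_sinusoid_reset_is_flagged_low_contrast(sinusoid_fit):
    *_, res = sinusoid_fit
    found = detect_sawtooth_reset(res.series["A'"]["x1"])
    assert found.low_contrast


def test_constant_series_has_no_reset():
    t = np.arange(7) / 7.0
    s = AMFSeries("c", "x1", t, np.zeros(7), np.zeros(7), np.ones(7, bool))
    with pytest.raises(NoResetError):
        detect_sawtooth_reset(s)


def _series(t, v):
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    return AMFSeries("s", "x1", t, v, v, np.ones(len(t), bool))


def test_compare_series_identity_and_offset():
    t = np.arange(7) / 7.0
    v = np.sin(2 * np.pi * t)
    a = _series(t, v)
    assert compare_series(a, a, "identity") == 0.0
    b = _series(t, v + 0.25)
    assert compare_series(a, b, "identity") == pytest.approx(0.25, abs=1e-12)


def test_compare_series_exact_mirrors_match_under_mirror_t():
    t = np.arange(9) / 9.0
    f = np.sin(2 * np.pi * t) + 0.3 * np.cos(4 * np.pi * t)
    a = _series(t, f)
    mirrored = _series(t, np.interp((1.0 - t) % 1.0, t, f, period=1.0))
    assert compare_series(a, mirrored, "mirror_t") < 1e-12
    assert compare_series(a, mirrored, "identity") > 0.1


def test_compare_series_interpolates_across_different_grids():
    t7 = np.arange(7) / 7.0
    t9 = np.arange(9) / 9.0
    a = _series(t7, np.sin(2 * np.pi * t7))
    b = _series(t9, np.sin(2 * np.pi * t9))
    # same underlying waveform sampled differently: small interpolation residual
    assert compare_series(a, b, "identity") < 0.05


def test_frames_follow_superorder_and_close_the_cycle(sevenfold_fit):
    res = sevenfold_fit
    frames = res.frames
    assert frames.cells == res.ordering.cells
    assert [round(t, 9) for t in frames.t_values] == \
        [round(float(t), 9) for t in res.ordering.t_values]
    labels = {f.label for f in res.families}
    totals = {lab: np.zeros(3) for lab in labels}
    for arrows in frames.arrows:
        assert set(arrows) == labels
        for lab, vec in arrows.items():
            totals[lab] += vec
    for vec in totals.values():
        assert np.max(np.abs(vec)) < 1e-10


def test_unmodulated_frames_have_zero_arrows():
    basic = make_basic_cell(n_families=2, n_residues=6, seed=8)
    model, _ = make_modulated_supercell(basic, Q37, AMFSpec())
    res = _fit(model)
    for arrows in res.frames.arrows:
        for vec in arrows.values():
            assert np.max(np.abs(vec)) < 1e-12


def test_single_cell_model_gives_single_frame():
    basic = make_basic_cell(n_families=2, n_residues=6, seed=9)
    q0 = RationalQ(Fraction(0), Fraction(0), Fraction(0))
    model, _ = make_modulated_supercell(basic, q0, AMFSpec())
    res = _fit(model, q0)
    assert len(res.frames) == 1


def test_mirror_paired_families_match_under_mirror_t():
    """Two families given exactly mirrored sinusoids compare to ~0 under t -> 1-t."""
    basic = make_basic_cell(n_families=2, n_residues=8, seed=10)
    coms = {ch: basic.atoms[basic.atoms["chain"] == ch][["x1", "x2", "x3"]]
            .to_numpy().mean(axis=0) for ch in basic.chains}
    amp = 0.015
    # family A: u_A = A*sin(2*pi*(alpha_A + t)); a mirror partner needs
    # u_B(-t) = u_A(t), which for a sine holds when alpha_B = 1/2 - alpha_A
    qc = float(Q37.sigma3)
    phase_a = 0.1
    phase_b = (0.5 - (qc * coms["A"][2] + phase_a) - qc * coms["B"][2]) % 1.0
    spec = AMFSpec(displacive={
        "A": (AxisModulation("sinusoid", amp, phase_a), AxisModulation(), AxisModulation()),
        "B": (AxisModulation("sinusoid", amp, phase_b), AxisModulation(), AxisModulation()),
    })
    model, _ = make_modulated_supercell(basic, Q37, spec)
    res = _fit(model)
    rms = compare_series(res.series["A'"]["x1"], res.series["B'"]["x1"], "mirror_t")
    assert rms < 1e-10
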