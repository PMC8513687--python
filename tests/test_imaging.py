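"""Frame assembly, adhesion metrics and detachment kinetics."""

import numpy as np
import pytest

import quadcell as qc
from quadcell.errors import CoverageError, ModalityError, ValidationError
from quadcell.imaging import IMPEDANCE, OPACITY


def _full_scan(geometry, value=1.0e6):
    scans = []
    for r in range(geometry.rows):
        for c in range(geometry.cols - 1):
            scans.append(qc.PairScan("horizontal",
                                     (geometry.pixel_id(r, c), geometry.pixel_id(r, c + 1)),
                                     value))
    for r in range(geometry.rows - 1):
        for c in range(geometry.cols):
            scans.append(qc.PairScan("vertical",
                                     (geometry.pixel_id(r, c), geometry.pixel_id(r + 1, c)),
                                     value))
    return scans


# ----------------------------------------------------------------- opacity

def test_opacity_assembly_constant(small_geometry):
    sites = np.full(small_geometry.n_optical_sites, 7.0)
    site_frame, pixel_frame = qc.assemble_opacity_frame(sites, small_geometry)
    assert site_frame.values.shape == (12, 12)
    assert pixel_frame.values.shape == (6, 6)
    assert np.all(site_frame.values == 7.0) and np.all(pixel_frame.values == 7.0)


def test_opacity_assembly_wrong_count(small_geometry):
    with pytest.raises(ValidationError):
        qc.assemble_opacity_frame(np.ones(small_geometry.n_optical_sites - 1),
                                  small_geometry)


def test_opacity_pixel_is_mean_of_its_four_sites(small_geometry):
    sites = np.arange(small_geometry.n_optical_sites, dtype=float)
    site_frame, pixel_frame = qc.assemble_opacity_frame(sites, small_geometry)
    # pixel 0 owns sites 0..3; its 2x2 subgrid sits at site-frame rows 0-1
    assert pixel_frame.values[0, 0] == pytest.approx(np.mean(sites[:4]))
    assert np.array_equal(site_frame.values[:2, :2], sites[:4].reshape(2, 2))
    # checkerboard within each pixel: pixel mean is the average of its sites
    checker = np.tile([10.0, 20.0, 30.0, 40.0], small_geometry.n_pixels)
    _, pf = qc.assemble_opacity_frame(checker, small_geometry)
    assert np.all(pf.values == 25.0)


# --------------------------------------------------------------- impedance

def test_full_scan_pair_count():
    assert qc.full_pair_scan_count(qc.DEFAULT_GEOMETRY) == 1984  # 2 * 32 * 31


def test_impedance_assembly_constant(small_geometry):
    scans = _full_scan(small_geometry, 2.0e5)
    assert len(scans) == qc.full_pair_scan_count(small_geometry)
    frame = qc.assemble_impedance_frame(scans, small_geometry)
    assert np.all(frame.values == 2.0e5)


def test_single_differing_pair_is_local(small_geometry):
    scans = _full_scan(small_geometry, 1.0e5)
    scans[0] = qc.PairScan("horizontal", scans[0].pair_index, 5.0e5)
    frame = qc.assemble_impedance_frame(scans, small_geometry)
    changed = np.flatnonzero(frame.values.ravel() != 1.0e5)
    assert set(changed) == set(scans[0].pair_index)


def test_non_adjacent_pair_rejected(small_geometry):
    scans = _full_scan(small_geometry)
    scans.append(qc.PairScan("horizontal", (0, 2), 1.0e5))
    with pytest.raises(ValidationError):
        qc.assemble_impedance_frame(scans, small_geometry)


def test_incomplete_coverage_rejected(small_geometry):
    scans = _full_scan(small_geometry)[:3]
    with pytest.raises(CoverageError):
        qc.assemble_impedance_frame(scans, small_geometry)


def test_assembly_linearity(small_geometry):
    rng = np.random.default_rng(0)
    z1 = rng.uniform(1e5, 1e6, qc.full_pair_scan_count(small_geometry))
    z2 = rng.uniform(1e5, 1e6, z1.size)
    base = _full_scan(small_geometry)
    s1 = [qc.PairScan(s.orientation, s.pair_index, z) for s, z in zip(base, z1)]
    s2 = [qc.PairScan(s.orientation, s.pair_index, z) for s, z in zip(base, z2)]
    s12 = [qc.PairScan(s.orientation, s.pair_index, 2 * a + 3 * b)
           for s, a, b in zip(base, z1, z2)]
    f1 = qc.assemble_impedance_frame(s1, small_geometry).values
    f2 = qc.assemble_impedance_frame(s2, small_geometry).values
    f12 = qc.assemble_impedance_frame(s12, small_geometry).values
    assert np.allclose(f12, 2 * f1 + 3 * f2)


# ---------------------------------------------------------------- adhesion

def test_attached_fraction_extremes(small_geometry):
    base = 2.0e5
    at_base = qc.Frame(IMPEDANCE, np.full((6, 6), base))
    assert qc.adhesion_metrics(at_base, base, 0.5).attached_fraction == 0.0
    at_plateau = qc.Frame(IMPEDANCE, np.full((6, 6), 1.1e6))
    m = qc.adhesion_metrics(at_plateau, base, 0.5)
    assert m.attached_fraction == 1.0
    assert m.mean_attached_impedance_ohm == pytest.approx(1.1e6)


def test_front_radius_matches_generated_disc():
    geom = qc.ArrayGeometry(rows=16, cols=16, pitch_um=58.0)
    radius = 300.0
    params = qc.TimelapseParams(
        aggregates=(qc.AggregateParams(centre_rc=(8, 8), seed_time_h=0.0,
                                       initial_radius_um=radius,
                                       growth_rate_um_per_h=0.0),),
        impedance_base_ohm=2e5, impedance_plateau_ohm=1.1e6,
        adhesion_tau_h=1.0,
    )
    _, im = qc.synth_timelapse(params, geom, np.array([0.0, 24.0]))
    centre_um = tuple(geom.pixel_centres_um()[geom.pixel_id(8, 8)])
    m = qc.adhesion_metrics(im.frame(1), 2e5, 0.5, [centre_um], geom)
    assert m.front_radius_um[0] == pytest.approx(radius, abs=geom.pitch_um)


def test_opacity_frame_rejected_for_adhesion():
    with pytest.raises(ModalityError):
        qc.adhesion_metrics(qc.Frame(OPACITY, np.ones((4, 4))), 1.0, 0.5)


# -------------------------------------------------------------- detachment

def _decay_series(rates, boundaries_min, base=2e5, excess0=8e5):
    t_min = np.arange(0.0, 21.0, 1.0)
    bounds = [0.0] + boundaries_min + [np.inf]
    z = []
    for t in t_min:
        acc = 0.0
        for k, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            acc += rates[k] * max(0.0, min(t, hi) - lo)
        z.append(base + excess0 * np.exp(-acc))
    frames = np.array(z)[:, None, None] * np.ones((1, 4, 4))
    return qc.FrameSeries(IMPEDANCE, frames, t_min / 60.0)


def test_half_time_matches_closed_form():
    k = 0.08
    series = _decay_series([k], [])
    fit = qc.detachment_kinetics(series, baseline_ohm=2e5)
    assert fit.half_times_min[0] == pytest.approx(np.log(2) / k, rel=0.05)


def test_constant_series_flags_infinite_half_time():
    frames = np.full((5, 4, 4), 9e5)
    series = qc.FrameSeries(IMPEDANCE, frames, np.arange(5.0) / 60.0)
    with pytest.warns(UserWarning):
        fit = qc.detachment_kinetics(series, baseline_ohm=2e5)
    assert fit.half_times_min[0] == np.inf


def test_two_phase_series_second_phase_faster():
    """Slow room-temperature decay then fast 37 C decay: the fitted phase-2
    half-time is shorter."""
    series = _decay_series([0.01, 0.2], [11.0])
    fit = qc.detachment_kinetics(series, baseline_ohm=2e5,
                                 phase_boundaries_min=[11.0])
    assert fit.half_times_min[1] < fit.half_times_min[0]
    assert fit.rates_per_min[0] == pytest.approx(0.01, rel=0.05)
    assert fit.rates_per_min[1] == pytest.approx(0.2, rel=0.05)
    assert 0.0 < fit.final_fraction < 1.0
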