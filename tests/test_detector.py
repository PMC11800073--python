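"""Detector distortions: response matrix, cross-talk, Poisson, pileup, binning."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcct.detector import (
    DetectorConfigError,
    DetectorModel,
    ThresholdSet,
    add_poisson_noise,
    apply_charge_splitting,
    apply_pulse_pileup,
    build_charge_splitting_response,
    counts_in_bins,
    default_branch_probabilities,
    pileup_event_mc,
)
from pcct.sinogram import SpectralSinogram

GRID = np.arange(12.0, 121.0)


def fine_sino(data):
    return SpectralSinogram(data=data, channel_kind="fine-keV", channel_edges=GRID)


def model_with(response=None, **kw):
    if response is None:
        response = build_charge_splitting_response(GRID)
    return DetectorModel(energy_grid=GRID, response=response, **kw)


# ----------------------------------------------------------------- response

def test_pure_full_detection_with_zero_blur_is_identity():
    n = GRID.size
    zeros = np.zeros(n)
    branches = (zeros, np.ones(n), zeros, zeros)
    r = build_charge_splitting_response(GRID, branches, energy_blur_sigma_kev=0.0)
    assert np.array_equal(r, np.eye(n))


def test_uniform_penetration_scales_column_sums():
    n = GRID.size
    p_pen = np.full(n, 0.2)
    branches = (p_pen, 1 - p_pen, np.zeros(n), np.zeros(n))
    r = build_charge_splitting_response(GRID, branches, energy_blur_sigma_kev=0.0)
    assert np.allclose(r.sum(axis=0), 0.8, atol=1e-12)


def test_default_response_columns_sum_to_one_minus_penetration():
    r = build_charge_splitting_response(GRID)
    p_pen, *_ = default_branch_probabilities(GRID)
    # direct column-summation oracle; escape mass below the grid floor is lost
    sums = r.sum(axis=0)
    assert np.all(sums <= 1 - p_pen + 1e-12)
    high = GRID >= 45  # fluorescence-shifted mass stays on the grid here
    assert np.allclose(sums[high], (1 - p_pen)[high], atol=1e-9)


def test_bad_branch_probabilities_raise():
    n = GRID.size
    branches = (np.full(n, 0.5), np.full(n, 0.6), np.zeros(n), np.zeros(n))
    with pytest.raises(DetectorConfigError):
        build_charge_splitting_response(GRID, branches)


# ---------------------------------------------------------------- crosstalk

def test_identity_response_zero_crosstalk_is_identity():
    model = model_with(response=np.eye(GRID.size), crosstalk_fraction=0.0)
    rng = np.random.default_rng(0)
    sino = fine_sino(rng.random((2, 5, 6, GRID.size)))
    out = apply_charge_splitting(sino, model)
    assert np.allclose(out.data, sino.data, atol=1e-12)


def test_uniform_image_interior_unchanged_by_crosstalk():
    model = model_with(response=np.eye(GRID.size), crosstalk_fraction=0.3)
    sino = fine_sino(np.full((1, 7, 7, GRID.size), 50.0))
    out = apply_charge_splitting(sino, model)
    assert np.allclose(out.data[0, 2:-2, 2:-2], 50.0, atol=1e-9)


def test_impulse_crosstalk_matches_hand_redistribution():
    model = model_with(response=np.eye(GRID.size), crosstalk_fraction=0.2)
    data = np.zeros((1, 5, 5, GRID.size))
    data[0, 2, 2, 40] = 1.0
    out = apply_charge_splitting(fine_sino(data), model).data[..., 40]
    assert out[0, 2, 2] == pytest.approx(0.8)
    for r, c in ((1, 2), (3, 2), (2, 1), (2, 3)):
        assert out[0, r, c] == pytest.approx(0.05)
    assert out.sum() == pytest.approx(1.0)


def test_crosstalk_conserves_total_counts_globally():
    model = model_with(response=np.eye(GRID.size), crosstalk_fraction=0.25)
    rng = np.random.default_rng(1)
    sino = fine_sino(rng.random((2, 6, 4, GRID.size)))
    out = apply_charge_splitting(sino, model)
    assert out.data.sum() == pytest.approx(sino.data.sum(), rel=1e-12)


# ------------------------------------------------------------------ Poisson

def test_poisson_zero_expectation_gives_zero_and_seed_determinism():
    sino = fine_sino(np.zeros((1, 3, 3, GRID.size)))
    assert add_poisson_noise(sino, 0).data.sum() == 0
    lam = fine_sino(np.full((2, 4, 4, GRID.size), 7.0))
    a = add_poisson_noise(lam, 42).data
    b = add_poisson_noise(lam, 42).data
    assert np.array_equal(a, b)


def test_poisson_moments():
    n_cells = 100_000
    lam_value = 100.0
    data = np.full((1, 1, n_cells // GRID.size + 1, GRID.size), lam_value)
    draw = add_poisson_noise(fine_sino(data), 3).data.ravel()[:n_cells]
    se_mean = np.sqrt(lam_value / n_cells)
    assert abs(draw.mean() - lam_value) < 3 * se_mean
    se_var = lam_value * np.sqrt(2.0 / n_cells)  # var of sample variance ~ 2*lam^2/n
    assert abs(draw.var() - lam_value) < 3 * se_var


def test_negative_expectation_is_rejected():
    sino = fine_sino(np.zeros((1, 1, 1, GRID.size)))
    sino.data = sino.data - 1.0  # bypass constructor validation deliberately
    with pytest.raises(ValueError):
        add_poisson_noise(sino, 0)


# ------------------------------------------------------------------- pileup

def test_zero_dead_time_is_identity_for_both_modes():
    rng = np.random.default_rng(0)
    sino = fine_sino(rng.integers(0, 20, (1, 2, 2, GRID.size)).astype(float))
    model = model_with(dead_time_s=0.0)
    for mode in ("analytic", "event_mc"):
        out = apply_pulse_pileup(sino, model, mode=mode, seed=0)
        assert np.array_equal(out.data, sino.data)


def test_event_mc_recovers_paralyzable_count_law():
    rng = np.random.default_rng(7)
    tau, exposure = 1e-9, 1e-3
    n_events = 200_000
    ntau = n_events / exposure * tau  # 0.2
    counts = np.zeros(GRID.size)
    counts[48] = n_events
    recorded = pileup_event_mc(counts, GRID, tau, exposure, rng)
    expected = n_events * np.exp(-ntau)
    assert recorded.sum() == pytest.approx(expected, rel=0.01)


def test_monochromatic_pileup_shifts_mass_upward_only():
    rng = np.random.default_rng(1)
    counts = np.zeros(GRID.size)
    counts[48] = 50_000  # 60 keV
    recorded = pileup_event_mc(counts, GRID, 5e-9, 1e-3, rng)  # heavy pileup
    below = recorded[GRID < 60.0].sum()
    above = recorded[GRID > 60.0].sum()
    assert below == 0.0
    assert above > 0.0


def test_recorded_total_non_increasing_in_dead_time():
    totals = []
    for tau in (0.0, 1e-9, 3e-9, 1e-8):
        rng = np.random.default_rng(11)
        counts = np.zeros(GRID.size)
        counts[30] = 50_000
        totals.append(pileup_event_mc(counts, GRID, tau, 1e-3, rng).sum())
    assert all(a >= b for a, b in zip(totals, totals[1:]))


def test_analytic_mode_applies_recorded_rate_law_per_pixel():
    data = np.zeros((1, 1, 2, GRID.size))
    data[0, 0, 0, 40] = 200_000.0
    data[0, 0, 1, 40] = 400_000.0
    model = model_with(dead_time_s=1.25e-10, exposure_s=1e-3)
    out = apply_pulse_pileup(fine_sino(data), model, mode="analytic").data
    for pix in range(2):
        n = data[0, 0, pix].sum()
        assert out[0, 0, pix].sum() == pytest.approx(n * np.exp(-n / 1e-3 * 1.25e-10), rel=1e-9)


# ------------------------------------------------------------------ binning

def test_default_thresholds_give_nine_bins():
    sino = fine_sino(np.ones((1, 2, 2, GRID.size)))
    bins = counts_in_bins(sino, ThresholdSet())
    assert bins.n_channels == 9
    assert np.array_equal(bins.channel_edges, np.arange(20.0, 111.0, 10.0))


def test_two_thresholds_select_the_energy_window():
    data = np.zeros((1, 1, 1, GRID.size))
    data[..., (GRID >= 30) & (GRID < 60)] = 2.0
    data[..., GRID >= 60] = 5.0
    bins = counts_in_bins(fine_sino(data), ThresholdSet(np.array([30.0, 60.0])))
    in_window = 2.0 * ((GRID >= 30) & (GRID < 60)).sum()
    assert bins.data[0, 0, 0, 0] == pytest.approx(in_window)


def test_bins_sum_to_cat_difference_and_are_nonnegative(rng):
    data = rng.random((2, 3, 3, GRID.size)) * 10
    thresholds = ThresholdSet()
    bins = counts_in_bins(fine_sino(data), thresholds)
    cat_first = data[..., GRID >= thresholds.thresholds[0]].sum(axis=-1)
    cat_last = data[..., GRID >= thresholds.thresholds[-1]].sum(axis=-1)
    assert np.allclose(bins.data.sum(axis=-1), cat_first - cat_last, atol=1e-9)
    assert np.all(bins.data >= 0)


@settings(deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_binning_is_additive(seed):
    r = np.random.default_rng(seed)
    a = r.random((1, 2, 2, GRID.size)) * 5
    b = r.random((1, 2, 2, GRID.size)) * 5
    t = ThresholdSet()
    ab = counts_in_bins(fine_sino(a + b), t).data
    separate = counts_in_bins(fine_sino(a), t).data + counts_in_bins(fine_sino(b), t).data
    assert np.allclose(ab, separate, atol=1e-9)


def test_unsorted_thresholds_raise():
    with pytest.raises(DetectorConfigError):
        ThresholdSet(np.array([30.0, 20.0, 40.0]))
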