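"""TV denoising, guided filtering, guidance image and material decomposition."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcct.denoise import (
    BasisSet,
    GFParams,
    TVParams,
    basis_from_materials,
    build_guidance_image,
    denoise_stack,
    guided_filter,
    guided_filter_once,
    material_decompose,
    tv_denoise,
    tv_objective,
)
from pcct.materials import packaged_material
from pcct.recon import ReconVolume, fbp_slice, log_normalize
from pcct.sinogram import SpectralSinogram


def brute_force_guided_filter(p, guide, radius, eps):
    """Direct window-enumeration implementation of the local linear model."""
    h, w = p.shape
    a = np.zeros((h, w))
    b = np.zeros((h, w))
    for ky in range(h):
        for kx in range(w):
            ys = slice(max(0, ky - radius), min(h, ky + radius + 1))
            xs = slice(max(0, kx - radius), min(w, kx + radius + 1))
            iw, pw = guide[ys, xs].ravel(), p[ys, xs].ravel()
            cov = (iw * pw).mean() - iw.mean() * pw.mean()
            var = (iw * iw).mean() - iw.mean() ** 2
            a[ky, kx] = cov / (var + eps)
            b[ky, kx] = pw.mean() - a[ky, kx] * iw.mean()
    q = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            ys = slice(max(0, i - radius), min(h, i + radius + 1))
            xs = slice(max(0, j - radius), min(w, j + radius + 1))
            q[i, j] = (a[ys, xs] * guide[i, j] + b[ys, xs]).mean()
    return q


# ----------------------------------------------------------------------- TV

def test_zero_weight_returns_input():
    rng = np.random.default_rng(0)
    f = rng.random((12, 12))
    assert np.array_equal(tv_denoise(f, TVParams(lam=0.0)), f)


@pytest.mark.parametrize("data_term", ["L1", "L2"])
def test_tv_objective_decreases_from_noisy_start(data_term):
    rng = np.random.default_rng(1)
    f = np.zeros((16, 16))
    f[4:12, 4:12] = 1.0
    f += rng.normal(0, 0.2, f.shape)
    params = TVParams(lam=0.5, n_iter=0, data_term=data_term)
    objectives = []
    for n_iter in (1, 5, 10, 18, 40):
        p = TVParams(lam=0.5, n_iter=n_iter, data_term=data_term)
        objectives.append(tv_objective(tv_denoise(f, p), f, p))
    start = tv_objective(f, f, params)
    assert objectives[-1] < start
    assert all(a >= b - 1e-6 * start for a, b in zip(objectives, objectives[1:]))


def test_primal_dual_reaches_lp_optimum_on_small_instance():
    """Anisotropic TV-L1 is a linear program; HiGHS provides the oracle optimum."""
    from scipy import sparse
    from scipy.optimize import linprog

    rng = np.random.default_rng(2)
    f = np.zeros((16, 16))
    f[4:12, 4:12] = 1.0
    f[rng.random((16, 16)) < 0.08] = 3.0
    params = TVParams(lam=0.8, n_iter=3000, data_term="L1", tv_kind="anisotropic")
    ours = tv_objective(tv_denoise(f, params), f, params)

    n = 256
    dx = sparse.lil_matrix((n, n))
    dy = sparse.lil_matrix((n, n))
    for i in range(16):
        for j in range(16):
            k = i * 16 + j
            if j < 15:
                dx[k, k], dx[k, k + 1] = -1, 1
            if i < 15:
                dy[k, k], dy[k, k + 16] = -1, 1
    grad_op = sparse.vstack([dx.tocsr(), dy.tocsr()])
    c = np.concatenate([np.zeros(n), np.ones(n), params.lam * np.ones(2 * n)])
    eye = sparse.eye(n)
    z_n = sparse.csr_matrix((n, 2 * n))
    a_ub = sparse.vstack([
        sparse.hstack([eye, -eye, z_n]),
        sparse.hstack([-eye, -eye, z_n]),
        sparse.hstack([grad_op, sparse.csr_matrix((2 * n, n)), -sparse.eye(2 * n)]),
        sparse.hstack([-grad_op, sparse.csr_matrix((2 * n, n)), -sparse.eye(2 * n)]),
    ])
    b_ub = np.concatenate([f.ravel(), -f.ravel(), np.zeros(4 * n)])
    bounds = [(None, None)] * n + [(0, None)] * (3 * n)
    res = linprog(c, A_ub=a_ub.tocsr(), b_ub=b_ub, bounds=bounds, method="highs")
    assert res.status == 0
    assert ours <= res.fun + 1e-3


def test_invalid_step_sizes_rejected():
    with pytest.raises(ValueError):
        TVParams(tau=1.0, sigma=1.0)


# -------------------------------------------------------------- guided filter

def test_constant_input_is_a_fixed_point(rng):
    p = np.full((10, 10), 3.25)
    guide = rng.random((10, 10))
    q = guided_filter(p, guide, GFParams(radius=3, eps=1e-6, n_guide=4))
    assert np.allclose(q, 3.25, atol=1e-10)


@pytest.mark.parametrize("self_guided", [True, False])
def test_single_application_matches_window_enumeration_oracle(self_guided):
    rng = np.random.default_rng(3)
    p = rng.random((12, 12))
    guide = p if self_guided else rng.random((12, 12))
    params = GFParams(radius=2, eps=1e-3, n_guide=1)
    ours = guided_filter_once(p, guide, params)
    oracle = brute_force_guided_filter(p, guide, 2, 1e-3)
    assert np.abs(ours - oracle).max() < 1e-10


def test_large_eps_reduces_to_box_mean(rng):
    from pcct.denoise import _box_sum

    p = rng.random((14, 14))
    guide = rng.random((14, 14))
    q = guided_filter_once(p, guide, GFParams(radius=3, eps=1e12, n_guide=1))
    count = _box_sum(np.ones_like(p), 3)
    box_mean = _box_sum(_box_sum(p, 3) / count, 3) / count
    assert np.allclose(q, box_mean, atol=1e-8)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        guided_filter_once(np.zeros((4, 4)), np.zeros((5, 5)), GFParams())


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_guided_filter_preserves_constants_property(seed):
    r = np.random.default_rng(seed)
    c = float(r.uniform(-5, 5))
    guide = r.random((8, 8))
    q = guided_filter_once(np.full((8, 8), c), guide, GFParams(radius=2, eps=1e-4, n_guide=1))
    assert np.allclose(q, c, atol=1e-9)


# ------------------------------------------------------------ guidance image

def test_single_bin_guidance_equals_reconstructed_denoised_bin(tiny_dataset):
    ds = tiny_dataset
    one_bin = SpectralSinogram(
        ds.distorted.data[..., :1], "counts-in-bins",
        ds.thresholds.thresholds[:2], angles_deg=ds.geometry.angles_deg,
    )
    air = ds.air_distorted[..., :1]
    tv = TVParams(n_iter=6)
    rows = [16]
    guidance = build_guidance_image(
        one_bin, air, ds.geometry, tv_params=tv, output_size=32, rows=rows
    )
    line = log_normalize(one_bin, air)
    direct = tv_denoise(
        fbp_slice(line.data[:, 16, :, 0], ds.geometry, "ramp", 32), tv
    )
    assert np.allclose(guidance[0], direct, atol=1e-12)


def test_virtual_integrating_bin_has_lowest_noise(tiny_dataset):
    ds = tiny_dataset
    rows = [16]
    no_tv = TVParams(lam=0.0)  # isolate the counts-summation effect
    guidance = build_guidance_image(
        ds.distorted, ds.air_distorted, ds.geometry, tv_params=no_tv,
        output_size=32, rows=rows,
    )
    # flat interior patch away from structures
    roi = (slice(4, 10), slice(12, 20))
    guide_noise = guidance[0][roi].std()
    line = log_normalize(ds.distorted, ds.air_distorted)
    for b in range(ds.distorted.n_channels):
        img = fbp_slice(line.data[:, 16, :, b], ds.geometry, "ramp", 32)
        assert guide_noise < img[roi].std()


# -------------------------------------------------------------- denoise_stack

def test_denoise_stack_near_identity_limit():
    rng = np.random.default_rng(4)
    clean = np.zeros((2, 1, 20, 20))
    clean[:, :, 6:14, 6:14] = rng.random((2, 1, 8, 8)) * 0.1 + 0.2
    vol = ReconVolume(clean, 0.11, np.array([20.0, 30.0, 40.0]))
    guidance = clean[0]  # aligned guidance equal to bin 0
    tv = TVParams(lam=1e-9, n_iter=4)
    gf = GFParams(radius=2, eps=1e-12, n_guide=1)
    out = denoise_stack(vol, guidance, tv, gf)
    deviation = np.abs(out.data[0] - clean[0]).max()
    assert deviation < 1e-6  # self-guided exact reproduction
    assert np.abs(out.data - clean).max() < 0.2  # bounded perturbation overall


# ------------------------------------------------------- material decompose

def two_material_basis():
    edges = np.arange(20.0, 111.0, 10.0)
    return basis_from_materials(
        [packaged_material("soft_tissue"), packaged_material("cortical_bone")], edges
    )


def test_basis_column_recovers_unit_weight():
    basis = two_material_basis()
    mu = basis.matrix[:, 0]
    vol = ReconVolume(
        np.tile(mu[:, None, None, None], (1, 1, 2, 2)), 0.11, np.arange(20.0, 111.0, 10.0)
    )
    maps = material_decompose(vol, basis)
    assert np.allclose(maps[0], 1.0, atol=1e-10)
    assert np.allclose(maps[1], 0.0, atol=1e-10)


def test_random_mixture_round_trip(rng):
    basis = two_material_basis()
    truth = rng.random((2, 1, 3, 3))
    data = np.einsum("bk,k...->b...", basis.matrix, truth)
    vol = ReconVolume(data, 0.11, np.arange(20.0, 111.0, 10.0))
    maps = material_decompose(vol, basis)
    assert np.allclose(maps, truth, atol=1e-8)
    recomposed = np.einsum("bk,k...->b...", basis.matrix, maps)
    assert np.allclose(recomposed, data, atol=1e-8)


def test_nonnegative_solve_clips_negative_components(rng):
    basis = two_material_basis()
    data = np.einsum("bk,k...->b...", basis.matrix, np.array([[[[0.5]]], [[[0.0]]]]))
    data = data - 0.05  # push toward a slightly negative bone weight
    vol = ReconVolume(data, 0.11, np.arange(20.0, 111.0, 10.0))
    maps = material_decompose(vol, basis, nonneg=True)
    assert np.all(maps >= 0)


def test_rank_deficient_basis_rejected():
    with pytest.raises(ValueError):
        BasisSet(names=["a", "b"], matrix=np.ones((9, 2)))
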