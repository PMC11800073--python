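"""Residual WGAN-ViT: architectures, losses, patches and inference."""
import numpy as np
import pytest

from pcct.gan import (
    LossWeights,
    NetConfig,
    ViT,
    build_discriminator,
    build_generator,
    correct_projections,
    discriminator_loss,
    extract_patch_pairs,
    generator_loss,
    load_checkpoint,
    save_checkpoint,
    split_train_val,
    vit_features,
)
from pcct.nn import Tensor, no_grad, set_training
from pcct.nn import autograd as ag
from pcct.sinogram import SpectralSinogram

CFG = NetConfig.compact()


def batch(shape, seed=0, scale=0.1, offset=0.3):
    return Tensor(
        np.random.default_rng(seed).normal(size=shape).astype(np.float32) * scale + offset
    )


# ------------------------------------------------------------ architectures

def test_generator_preserves_shape_and_is_identity_at_zero_weights():
    gen = build_generator(CFG)
    for p in gen.parameters():
        p.data = np.zeros_like(p.data)
    x = batch((2, 9, 16, 16))
    with no_grad():
        out = gen(x)
    assert out.shape == (2, 9, 16, 16)
    assert np.array_equal(out.data, x.data)


def test_generator_is_fully_convolutional():
    gen = build_generator(CFG)
    with no_grad():
        out = gen(batch((1, 9, 64, 96)))
    assert out.shape == (1, 9, 64, 96)


def test_discriminator_emits_one_score_per_sample():
    disc = build_discriminator(CFG)
    x = batch((5, 9, 16, 16))
    with no_grad():
        scores = disc(x)
    assert scores.shape == (5, 1)
    # spatial size after four stride-2 blocks on 16x16 is 1x1
    assert disc.dense1.weight.shape[0] == CFG.disc_widths[-1]


def test_discriminator_scores_are_per_sample_independent():
    disc = build_discriminator(CFG)
    set_training(disc, False)  # frozen normalization statistics
    x = batch((3, 9, 16, 16), seed=1)
    doubled = Tensor(np.concatenate([x.data, x.data[:1]]))
    with no_grad():
        s1 = disc(x)
        s2 = disc(doubled)
    # float32 GEMM blocking differs with batch size; tolerance is rounding-level
    assert s2.data[3, 0] == pytest.approx(s2.data[0, 0], abs=1e-5)
    assert np.allclose(s1.data, s2.data[:3], atol=1e-5)


def test_discriminator_rejects_indivisible_input_size():
    with pytest.raises(ValueError):
        build_discriminator(NetConfig.compact(patch_size=24))


# ---------------------------------------------------------------------- ViT

def test_vit_token_arithmetic_and_class_token():
    vit = ViT(CFG)
    with no_grad():
        tokens = vit(batch((2, 9, 16, 16)))
    assert tokens.shape == (2, 16, CFG.vit_dim)  # (16/4)^2 spatial tokens
    vit_cls = ViT(NetConfig.compact(vit_class_token=True))
    with no_grad():
        tokens = vit_cls(batch((2, 9, 16, 16)))
    assert tokens.shape == (2, 17, CFG.vit_dim)


def test_identical_inputs_have_zero_feature_distance():
    vit = ViT(CFG)
    x = batch((2, 9, 16, 16), seed=3)
    with no_grad():
        fa = vit_features(x, vit)
        fb = vit_features(Tensor(x.data.copy()), vit)
    assert np.array_equal(fa.data, fb.data)


def test_attention_reaches_every_token():
    vit = ViT(CFG)
    x = batch((1, 9, 16, 16), seed=4)
    perturbed = x.data.copy()
    perturbed[0, :, :4, :4] += 0.5  # one 4x4 token patch
    with no_grad():
        fa = vit_features(x, vit).data
        fb = vit_features(Tensor(perturbed), vit).data
    per_token_change = np.abs(fa - fb).max(axis=-1)[0]
    assert np.all(per_token_change > 0)


def test_vit_rejects_indivisible_spatial_size():
    vit = ViT(CFG)
    with pytest.raises(ValueError):
        vit(batch((1, 9, 18, 18)))


# -------------------------------------------------------------------- losses

class ConstantCritic:
    def __init__(self, value):
        self.value = value

    def __call__(self, t):
        return Tensor(np.full((t.shape[0], 1), self.value, np.float32))


class LinearCritic:
    """D(x) = <w, x> with a fixed weight tensor."""

    def __init__(self, w):
        self.w = Tensor(w, requires_grad=True)

    def __call__(self, t):
        prod = t * ag.reshape(self.w, (1,) + self.w.shape)
        return ag.reshape(ag.sum_(prod, axis=(1, 2, 3)), (t.shape[0], 1))


def test_constant_critic_gives_exactly_lambda_gp():
    gen = build_generator(CFG)
    p = batch((4, 9, 16, 16), seed=5)
    m = batch((4, 9, 16, 16), seed=6)
    loss = discriminator_loss(ConstantCritic(2.5), gen, p, m, lambda_gp=10.0, rng=0)
    assert loss.item() == pytest.approx(10.0, abs=1e-12)


def test_linear_critic_matches_closed_form():
    rng = np.random.default_rng(7)
    w = rng.normal(size=(9, 16, 16)).astype(np.float32)
    p = batch((3, 9, 16, 16), seed=8)
    fake = batch((3, 9, 16, 16), seed=9)
    critic = LinearCritic(w)
    lam = 10.0
    loss = discriminator_loss(critic, None, p, p, lam, rng=1, fake=fake)
    wnorm = np.linalg.norm(w.astype(np.float64))
    expected = (
        float(np.tensordot(fake.data, w, 3).mean())
        - float(np.tensordot(p.data, w, 3).mean())
        + lam * (wnorm - 1.0) ** 2
    )
    assert loss.item() == pytest.approx(expected, rel=1e-6)


def test_matched_pairs_and_zero_penalty_weight_give_zero_loss():
    gen = build_generator(CFG)
    for par in gen.parameters():
        par.data = np.zeros_like(par.data)  # identity generator
    p = batch((3, 9, 16, 16), seed=10)
    loss = discriminator_loss(ConstantCritic(0.0), gen, p, p, lambda_gp=0.0, rng=2)
    assert loss.item() == 0.0


def test_perfect_generator_with_zero_critic_has_zero_loss():
    gen = build_generator(CFG)
    vit = ViT(CFG)
    p = batch((3, 9, 16, 16), seed=11)
    loss = generator_loss(ConstantCritic(0.0), gen, p, p, LossWeights(), vit, fake=p)
    assert loss.item() == 0.0


def test_generator_loss_terms_match_independent_oracle():
    vit = ViT(CFG)
    p = batch((3, 9, 16, 16), seed=12)
    fake = batch((3, 9, 16, 16), seed=13)
    critic = ConstantCritic(1.5)
    weights = LossWeights(lambda1=1000.0, lambda2=1000.0, lambda3=10.0, eps_rmae=1e-4)
    loss = generator_loss(critic, None, p, None, weights, vit, fake=fake)
    # straight-line reimplementation of every term
    g, t = fake.data.astype(np.float64), p.data.astype(np.float64)
    with no_grad():
        fg = vit(fake).data.astype(np.float64)
        fp = vit(p).data.astype(np.float64)
    expected = (
        -1.5
        + 1000.0 * np.mean((g - t) ** 2)
        + 1000.0 * np.mean(np.abs((g - t) / (t + 1e-4)))
        + 10.0 * np.mean((fg - fp) ** 2)
    )
    assert loss.item() == pytest.approx(expected, rel=1e-5)


@pytest.mark.parametrize("active", ["adv", "mse", "rmae", "perceptual"])
def test_single_term_ablations(active):
    vit = ViT(CFG)
    p = batch((2, 9, 16, 16), seed=14)
    fake = batch((2, 9, 16, 16), seed=15)
    critic = ConstantCritic(2.0)
    kw = dict(lambda1=0.0, lambda2=0.0, lambda3=0.0)
    g, t = fake.data.astype(np.float64), p.data.astype(np.float64)
    if active == "adv":
        expected = -2.0
    elif active == "mse":
        kw["lambda1"] = 7.0
        expected = -2.0 + 7.0 * np.mean((g - t) ** 2)
    elif active == "rmae":
        kw["lambda2"] = 3.0
        expected = -2.0 + 3.0 * np.mean(np.abs((g - t) / (t + 1e-4)))
    else:
        kw["lambda3"] = 2.0
        with no_grad():
            fg, fp = vit(fake).data, vit(p).data
        expected = -2.0 + 2.0 * np.mean((fg.astype(np.float64) - fp.astype(np.float64)) ** 2)
    loss = generator_loss(critic, None, p, None, LossWeights(**kw), vit, fake=fake)
    assert loss.item() == pytest.approx(expected, rel=1e-5)


# ----------------------------------------------------- patches and inference

def _paired_sinograms(seed=0, shape=(5, 24, 32, 9)):
    rng = np.random.default_rng(seed)
    edges = np.arange(20.0, 20.0 + 10.0 * (shape[-1] + 1), 10.0)
    dist = SpectralSinogram(rng.random(shape) * 1000, "counts-in-bins", edges)
    ideal = SpectralSinogram(rng.random(shape) * 1000, "counts-in-bins", edges)
    return dist, ideal


def test_patch_pairs_reread_at_anchor_bit_exact():
    dist, ideal = _paired_sinograms()
    pairs = extract_patch_pairs(dist, ideal, 50, patch_size=16, seed=1,
                                normalization_constant=1000.0)
    norm = np.float32(1000.0)
    for i in (0, 17, 49):
        a, r, c = pairs.anchors[i]
        src = dist.data[a, r : r + 16, c : c + 16].transpose(2, 0, 1)
        assert np.array_equal(pairs.distorted[i], src.astype(np.float32) / norm)
        src_i = ideal.data[a, r : r + 16, c : c + 16].transpose(2, 0, 1)
        assert np.array_equal(pairs.ideal[i], src_i.astype(np.float32) / norm)


def test_zero_patches_and_oversized_patch():
    dist, ideal = _paired_sinograms()
    assert len(extract_patch_pairs(dist, ideal, 0)) == 0
    with pytest.raises(ValueError):
        extract_patch_pairs(dist, ideal, 1, patch_size=64)


def test_split_partition_is_disjoint_and_exhaustive():
    dist, ideal = _paired_sinograms(seed=2)
    pairs = extract_patch_pairs(dist, ideal, 101, seed=3)
    train, val = split_train_val(pairs, 0.7)
    assert len(train) + len(val) == 101
    stacked = np.concatenate([train.anchors, val.anchors])
    assert np.array_equal(stacked, pairs.anchors)
    train_all, val_none = split_train_val(pairs, 1.0)
    assert len(train_all) == 101 and len(val_none) == 0


def test_identity_generator_inference_round_trip():
    gen = build_generator(CFG)
    for p in gen.parameters():
        p.data = np.zeros_like(p.data)
    dist, _ = _paired_sinograms(seed=4)
    out = correct_projections(gen, dist, normalization_constant=1000.0)
    assert np.allclose(out.data, dist.data, rtol=1e-5, atol=1e-2)


def test_whole_projection_matches_tile_interiors():
    cfg = NetConfig.compact(seed=77)
    gen = build_generator(cfg)
    # non-trivial weights: perturb the zero head so the net is not the identity
    rng = np.random.default_rng(5)
    gen.head.weight.data = rng.normal(0, 0.05, gen.head.weight.shape).astype(np.float32)
    x = rng.normal(size=(1, 9, 32, 64)).astype(np.float32)
    with no_grad():
        whole = gen(Tensor(x)).data
        left = gen(Tensor(x[:, :, :, :56])).data
        right = gen(Tensor(x[:, :, :, 8:])).data
    # interior columns far from every tile seam agree with the one-shot result
    averaged = (left[..., 24:40] + right[..., 16:32]) / 2
    assert np.allclose(whole[..., 24:40], averaged, atol=1e-4)


def test_checkpoint_round_trip(tmp_path):
    cfg = NetConfig.compact(seed=21)
    gen = build_generator(cfg)
    path = tmp_path / "gen.npz"
    save_checkpoint(path, gen, cfg, normalization_constant=123.0)
    loaded, loaded_cfg, norm = load_checkpoint(path)
    assert norm == 123.0
    assert loaded_cfg == cfg
    x = batch((1, 9, 16, 16), seed=22)
    with no_grad():
        assert np.array_equal(gen(x).data, loaded(x).data)
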