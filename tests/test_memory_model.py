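import numpy as np
import pytest

from mapseg.mask_gen import rasterize_template, ContourSpec
from mapseg.memory_model import (
    ArchConfig,
    FeaturePyramid,
    MapSegNet,
    MemoryBank,
    best_difference_map,
    build_memory,
    count_parameters,
    extract_features,
    head_inputs,
    load_checkpoint,
    save_checkpoint,
    spatial_attention,
    stack_head_inputs,
)
from mapseg.nn.core import no_grad
from mapseg.simpo import SimpoConfig, patch_synthesis


@pytest.fixture(scope="module")
def net():
    return MapSegNet(ArchConfig(input_size=64))


@pytest.fixture(scope="module")
def small_bank(net, mucosa_images_64):
    return build_memory(mucosa_images_64, 3, seed=0, encoder=net.encoder)


@pytest.fixture(scope="module")
def mucosa_images_64():
    from mapseg.fixtures import MucosaSpec, generate_mucosa

    return [generate_mucosa(MucosaSpec(size=64, seed=40 + i)) for i in range(5)]


def toy_bank(arrays):
    """Build a MemoryBank whose three scales are the same toy tensors."""
    stack = np.stack(arrays).astype(np.float32)
    return MemoryBank(m1=stack, m2=stack, m3=stack, indices=np.arange(len(arrays)))


class TestEncoder:
    def test_pyramid_shapes_for_256(self):
        net = MapSegNet()
        img = np.zeros((256, 256, 3), np.uint8)
        pyr = extract_features(img, net.encoder)
        assert pyr.f1.shape == (64, 64, 64)
        assert pyr.f2.shape == (128, 32, 32)
        assert pyr.f3.shape == (256, 16, 16)
        assert np.isfinite(pyr.f1).all()

    def test_deterministic(self, net, mucosa_images_64):
        a = extract_features(mucosa_images_64[0], net.encoder)
        b = extract_features(mucosa_images_64[0], net.encoder)
        assert (a.f3 == b.f3).all()

    def test_wrong_size_rejected(self, net):
        with pytest.raises(ValueError):
            extract_features(np.zeros((100, 100, 3), np.uint8), net.encoder)


class TestMemoryBank:
    def test_selection_without_replacement(self, net, mucosa_images_64):
        bank = build_memory(mucosa_images_64, 3, seed=1, encoder=net.encoder)
        assert bank.n == 3
        assert len(set(bank.indices.tolist())) == 3

    def test_too_many_requested(self, net, mucosa_images_64):
        with pytest.raises(ValueError):
            build_memory(mucosa_images_64, 99, seed=0, encoder=net.encoder)

    def test_seeded_selection_stable(self, net, mucosa_images_64):
        a = build_memory(mucosa_images_64, 2, seed=5, encoder=net.encoder)
        b = build_memory(mucosa_images_64, 2, seed=5, encoder=net.encoder)
        assert (a.indices == b.indices).all()


class TestDifferenceMaps:
    def test_zero_discrepancy_for_memory_item(self, net, small_bank, mucosa_images_64):
        member = mucosa_images_64[small_bank.indices[1]]
        diff = best_difference_map(extract_features(member, net.encoder), small_bank)
        assert diff.selected[0] == 1 or diff.total[0] == 0.0
        assert all(t == pytest.approx(0.0, abs=1e-6) for t in diff.total)

    def test_argmin_matches_brute_force_toy(self, rng):
        items = [rng.normal(size=(1, 2, 2)) for _ in range(3)]
        bank = toy_bank(items)
        feat = rng.normal(size=(1, 2, 2)).astype(np.float32)
        pyr = FeaturePyramid(f1=feat, f2=feat, f3=feat)
        diff = best_difference_map(pyr, bank)
        sums = [(np.stack(items)[k].astype(np.float32) - feat) ** 2 for k in range(3)]
        brute = int(np.argmin([s.sum() for s in sums]))
        assert diff.selected == (brute, brute, brute)
        assert np.allclose(diff.di_star[0], sums[brute])
        assert (diff.di_star[0] >= 0).all()

    def test_bank_permutation_invariance(self, net, small_bank, mucosa_images_64):
        pyr = extract_features(mucosa_images_64[4], net.encoder)
        d1 = best_difference_map(pyr, small_bank)
        perm = MemoryBank(
            m1=small_bank.m1[::-1].copy(), m2=small_bank.m2[::-1].copy(),
            m3=small_bank.m3[::-1].copy(), indices=small_bank.indices[::-1].copy(),
        )
        d2 = best_difference_map(pyr, perm)
        for a, b in zip(d1.di_star, d2.di_star):
            assert np.allclose(a, b)


class TestSpatialAttention:
    def test_channel_mean_constant_maps(self):
        d3 = np.stack([np.full((4, 4), 0.2), np.full((4, 4), 0.4)])
        d2 = np.ones((1, 8, 8))
        d1 = np.ones((1, 16, 16))
        from mapseg.memory_model import DifferenceMaps

        att = spatial_attention(DifferenceMaps((d1, d2, d3), (0, 0, 0), (0, 0, 0)))
        assert np.allclose(att.m3, 0.3)

    @pytest.mark.parametrize("c1,c2,c3", [(1.0, 1.0, 1.0), (0.5, 2.0, 0.25)])
    def test_constant_cascade_closed_form(self, c1, c2, c3):
        from mapseg.memory_model import DifferenceMaps

        att = spatial_attention(
            DifferenceMaps(
                (np.full((2, 16, 16), c1), np.full((2, 8, 8), c2), np.full((2, 4, 4), c3)),
                (0, 0, 0), (0, 0, 0),
            )
        )
        assert np.allclose(att.m1, c1 * c2 * c3, atol=1e-6)
        assert np.allclose(att.m2, c2 * c3, atol=1e-6)

    def test_zero_propagation(self):
        from mapseg.memory_model import DifferenceMaps

        att = spatial_attention(
            DifferenceMaps(
                (np.zeros((2, 16, 16)), np.zeros((2, 8, 8)), np.zeros((2, 4, 4))),
                (0, 0, 0), (0, 0, 0),
            )
        )
        assert not att.m1.any() and not att.m2.any() and not att.m3.any()


class TestLesionSensitivity:
    def test_lesion_increases_min_discrepancy(self, net, small_bank, mucosa_images_64,
                                              templates_64):
        member = mucosa_images_64[small_bank.indices[0]]
        clean_total = best_difference_map(
            extract_features(member, net.encoder), small_bank
        ).total
        lesion = patch_synthesis(
            member, templates_64[0], np.random.default_rng(3), SimpoConfig()
        )
        lesion_total = best_difference_map(
            extract_features(lesion.image, net.encoder), small_bank
        ).total
        for c, l in zip(clean_total, lesion_total):
            assert l > c

    def test_attention_localizes_lesion(self, net, small_bank, mucosa_images_64,
                                        templates_64):
        member = mucosa_images_64[small_bank.indices[0]]
        lesion = patch_synthesis(
            member, templates_64[1], np.random.default_rng(5), SimpoConfig()
        )
        _, attn = head_inputs(lesion.image, small_bank, net.encoder)
        m1 = attn[0][0]
        from skimage.transform import resize

        mask16 = resize(lesion.mask.astype(float), m1.shape, order=0) > 0.5
        assert m1[mask16].mean() > m1[~mask16].mean()


class TestForward:
    def test_output_contract(self, net, small_bank, mucosa_images_64):
        prob = net.eval().forward(np.stack(mucosa_images_64[:2]), small_bank)
        assert prob.shape == (2, 64, 64)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_eval_determinism(self, net, small_bank, mucosa_images_64):
        a = net.eval().forward(np.stack(mucosa_images_64[:1]), small_bank)
        b = net.eval().forward(np.stack(mucosa_images_64[:1]), small_bank)
        assert (a == b).all()

    def test_memory_item_zeroes_attention_stage(self, net, small_bank, mucosa_images_64):
        member = mucosa_images_64[small_bank.indices[2]]
        ci, attn = head_inputs(member, small_bank, net.encoder)
        assert all(np.abs(a).max() == pytest.approx(0.0, abs=1e-8) for a in attn)


class TestParameterCounts:
    def test_reference_counts(self):
        total, trainable = count_parameters(MapSegNet())
        assert round(total / 1e6, 2) == 19.05
        assert round(trainable / 1e6, 2) == 16.27
        assert total - trainable == 2_782_784  # frozen ResNet18 stem+stages 1-3


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, net, small_bank):
        path = tmp_path / "ck.npz"
        save_checkpoint(path, net, small_bank, extra={"epoch": 3})
        model, bank, extra = load_checkpoint(path)
        assert int(extra["epoch"]) == 3
        assert bank.n == small_bank.n
        a = dict(net.named_parameters())
        b = dict(model.named_parameters())
        assert all(np.allclose(a[k].data, b[k].data) for k in a)
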