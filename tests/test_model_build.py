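"""Basic-model construction and the four coarsening rules vs brute-force oracles."""
import numpy as np
import pytest

from trabfe.model_build import (build_basic_model, coarsen, coarsen_fl,
                                coarsen_fs, coarsen_ft, coarsen_h)
from trabfe.phantoms import make_solid_block

from .conftest import random_stack


# ---------------------------------------------------------------- oracles
def oracle_basic(slices):
    """Voxel layer k = elementwise AND of slices k and k+1."""
    n = len(slices)
    return np.array([slices[k] & slices[k + 1] for k in range(n - 1)], bool)


def oracle_h(occ, k):
    """Exhaustive per-cuberrille fill count, full nominal denominator."""
    nz, ny, nx = occ.shape
    oz, oy, ox = -(-nz // k), -(-ny // k), -(-nx // k)
    out = np.zeros((oz, oy, ox), bool)
    for z in range(oz):
        for y in range(oy):
            for x in range(ox):
                block = occ[z * k:(z + 1) * k, y * k:(y + 1) * k,
                            x * k:(x + 1) * k]
                out[z, y, x] = block.sum() * 2 > k**3
    return out


def oracle_layered(slices, m, offset):
    """AND of slice pairs (k*m, k*m + offset) for extent-limited layers."""
    n = len(slices)
    layers = []
    for k in range((n - 1) // m):
        second = k * m + offset
        if second > n - 1:
            break
        layers.append(slices[k * m] & slices[second])
    return np.array(layers, bool)


# ---------------------------------------------------------------- basic model
class TestBasicModel:
    def test_two_solid_slices_one_solid_layer(self):
        model = build_basic_model(make_solid_block((5, 5, 2)))
        assert model.shape == (1, 5, 5)
        assert model.occupancy.all()

    def test_bone_in_one_slice_only_gives_empty_voxel(self):
        """The AND rule: bone must appear in both bounding slices."""
        from trabfe.io_stack import ImageStack

        slices = np.zeros((2, 4, 4), np.uint8)
        slices[0, 1, 1] = 1
        model = build_basic_model(ImageStack(slices, 36.0, 36.0))
        assert not model.occupancy.any()

    def test_matches_and_oracle(self):
        stack = random_stack((6, 10, 10), seed=3)
        model = build_basic_model(stack)
        expected = oracle_basic(stack.slices.astype(bool))
        assert np.array_equal(model.occupancy, expected)

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            build_basic_model(make_solid_block((4, 4, 1)))

    def test_anisotropic_base_rejected(self):
        stack = random_stack((4, 4, 4), seed=0, slice_increment=72.0)
        with pytest.raises(ValueError):
            build_basic_model(stack)


# ---------------------------------------------------------------- H method
class TestHexahedral:
    def test_majority_rule_5_of_8(self):
        occ = np.zeros((2, 2, 2), bool)
        occ.ravel()[:5] = True
        model = build_basic_model(make_solid_block((2, 2, 3)))
        model.occupancy = occ
        out = coarsen_h(model, 72.0)
        assert out.occupancy.all()  # 5/8 = 62.5% > 50%

    def test_exactly_half_is_empty(self):
        """50% fill does not satisfy the strict >50% rule."""
        occ = np.zeros((2, 2, 2), bool)
        occ.ravel()[:4] = True
        model = build_basic_model(make_solid_block((2, 2, 3)))
        model.occupancy = occ
        out = coarsen_h(model, 72.0)
        assert not out.occupancy.any()

    def test_solid_identity(self):
        model = build_basic_model(make_solid_block((4, 4, 5)))
        out = coarsen_h(model, 72.0)
        assert out.shape == (2, 2, 2)
        assert out.occupancy.all()
        assert out.dx == out.dy == out.dz == 72.0

    @pytest.mark.parametrize("s", [72.0, 108.0, 144.0])
    def test_matches_counting_oracle(self, s):
        stack = random_stack((13, 12, 12), seed=9)
        model = build_basic_model(stack)
        out = coarsen_h(model, s)
        assert np.array_equal(out.occupancy, oracle_h(model.occupancy, int(s // 36)))

    def test_invalid_s_rejected(self):
        model = build_basic_model(make_solid_block((4, 4, 5)))
        with pytest.raises(ValueError):
            coarsen_h(model, 100.0)  # not a multiple of 36
        with pytest.raises(ValueError):
            coarsen_h(model, 360.0)  # outside 72-288 with enforcement on
        coarsen_h(model, 36.0 * 10, enforce_range=False)  # override allowed


# ---------------------------------------------------------------- layered methods
class TestLayeredMethods:
    @pytest.mark.parametrize("fn,d", [(coarsen_fl, 108.0), (coarsen_fs, 144.0),
                                      (coarsen_ft, 216.0)])
    def test_solid_stays_solid(self, fn, d):
        out = fn(make_solid_block((5, 5, 31)), d)
        assert out.occupancy.all()
        assert out.shape[0] == 30 // int(d // 36)

    def test_fl_matches_pair_oracle(self):
        stack = random_stack((31, 10, 10), seed=17)
        out = coarsen_fl(stack, 108.0)
        expected = oracle_layered(stack.slices.astype(bool), 3, 3)
        assert np.array_equal(out.occupancy, expected)
        assert out.dz == 108.0

    def test_fs_matches_pair_oracle(self):
        stack = random_stack((31, 10, 10), seed=17)
        out = coarsen_fs(stack, 144.0)
        expected = oracle_layered(stack.slices.astype(bool), 4, 1)
        assert np.array_equal(out.occupancy, expected)

    def test_ft_matches_pair_oracle(self):
        stack = random_stack((31, 10, 10), seed=17)
        out = coarsen_ft(stack, 216.0)
        expected = oracle_layered(stack.slices.astype(bool), 6, 2)
        assert np.array_equal(out.occupancy, expected)

    def test_first_slice_empty_gives_empty_voxel(self):
        """AND-rule methods never create bone absent from the first slice."""
        stack = random_stack((9, 8, 8), seed=4)
        for fn, d in ((coarsen_fl, 144.0), (coarsen_fs, 144.0),
                      (coarsen_ft, 144.0)):
            out = fn(stack, d)
            for k in range(out.shape[0]):
                first = stack.slices[k * 4].astype(bool)
                assert not (out.occupancy[k] & ~first).any()

    def test_ft_equals_fl_at_72(self):
        """At d = 72 both rules pair slices 72 µm apart at the same anchors."""
        stack = random_stack((21, 9, 9), seed=23)
        a = coarsen_ft(stack, 72.0)
        b = coarsen_fl(stack, 72.0)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_fs_at_base_increment_reproduces_basic(self):
        """Degenerate d = 36 µm identity used as an internal consistency check."""
        stack = random_stack((9, 8, 8), seed=31)
        out = coarsen_fs(stack, 36.0, enforce_range=False)
        basic = build_basic_model(stack)
        assert np.array_equal(out.occupancy, basic.occupancy)

    def test_too_few_slices_rejected(self):
        stack = random_stack((4, 6, 6), seed=1)
        with pytest.raises(ValueError):
            coarsen_fl(stack, 144.0)  # needs m+1 = 5 slices

    def test_ft_odd_multiple_rejected(self):
        stack = random_stack((21, 6, 6), seed=1)
        with pytest.raises(ValueError):
            coarsen_ft(stack, 108.0)  # not a multiple of 72

    def test_bone_volume_never_exceeds_source(self):
        stack = random_stack((25, 8, 8), seed=40, p=0.6)
        total = stack.bone_pixel_count()
        for method in ("FL", "FS", "FT"):
            model = coarsen(stack, method, 144.0)
            assert model.bone_voxel_count() <= total
            # each layer equals the AND of its two source slices exactly
            m = 4
            offset = {"FL": m, "FS": 1, "FT": 2}[method]
            for k in range(model.shape[0]):
                pair = (stack.slices[k * m] & stack.slices[k * m + offset]).astype(bool)
                assert np.array_equal(model.occupancy[k], pair)


def test_dispatch_and_unknown_method():
    stack = make_solid_block((4, 4, 9))
    assert coarsen(stack, "H", 72.0).method == "H"
    with pytest.raises(ValueError):
        coarsen(stack, "XX", 72.0)
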