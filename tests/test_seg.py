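"""Segmentation codec: bit packing, encoding, filtering, reconstruction."""

import numpy as np
import pytest

from dcmforge import seg, sop
from dcmforge.coding import codes
from dcmforge.errors import FramingError, SegmentOverlapError
from dcmforge.seg import (
    AlgorithmIdentification,
    AlgorithmType,
    FractionalType,
    SegmentDescription,
    SegmentationParams,
    SegmentationType,
    encode_segmentation,
    find_segments,
    pack_bits,
    quantize_fraction,
    reconstruct_mask,
    unpack_bits,
)

ALG = AlgorithmIdentification("fixture-alg", "1.0", {"threshold": 0.5})


def desc(n, label=None, ptype=None, tracking=None):
    return SegmentDescription(
        n, label or f"segment-{n}",
        property_category=codes.SCT.Tissue,
        property_type=ptype or codes.SCT.Tissue,
        algorithm_type=AlgorithmType.AUTOMATIC,
        algorithm_identification=ALG,
        tracking_id=tracking and tracking[0],
        tracking_uid=tracking and tracking[1],
    )


def _bit_oracle(planes):
    """Independent bit-level packing oracle: per-pixel loop."""
    flat = np.asarray(planes).ravel()
    out = bytearray((len(flat) + 7) // 8)
    for i, bit in enumerate(flat):
        if bit:
            out[i // 8] |= 1 << (i % 8)
    if len(out) % 2:
        out.append(0)
    return bytes(out)


class TestBitPacking:
    def test_bit_order_example(self):
        frame = np.array([1, 0, 0, 0, 0, 0, 0, 1], bool).reshape(1, 1, 8)
        assert pack_bits(frame) == b"\x81\x00"  # 0x81 + even padding

    def test_all_zero_3x3(self):
        packed = pack_bits(np.zeros((1, 3, 3), bool))
        assert packed == b"\x00\x00"

    def test_roundtrip_random_stack(self, rng):
        planes = rng.random((5, 7, 3)) > 0.5
        assert np.array_equal(unpack_bits(pack_bits(planes), 5, 7, 3), planes)

    def test_matches_bit_oracle(self, rng):
        for shape in [(1, 4, 4), (3, 5, 7), (2, 16, 16), (4, 3, 3)]:
            planes = rng.random(shape) > 0.4
            assert pack_bits(planes) == _bit_oracle(planes)

    def test_frames_not_byte_aligned(self):
        """9-bit frames pack continuously across frame boundaries."""
        planes = np.ones((2, 3, 3), bool)
        packed = pack_bits(planes)
        assert len(packed) == 4  # ceil(18/8)=3, padded to 4
        assert packed == _bit_oracle(planes)

    def test_length_mismatch_rejected(self):
        with pytest.raises(FramingError):
            unpack_bits(b"\x00" * 5, 2, 3, 3)

    def test_non_boolean_rejected(self):
        with pytest.raises(TypeError):
            pack_bits(np.zeros((1, 2, 2), np.uint8))


class TestQuantization:
    def test_half_rounds_up(self):
        # round-half-up: 0.5 * 255 = 127.5 -> 128
        assert quantize_fraction(np.array([0.5]), 255)[0] == 128

    @pytest.mark.parametrize("p,expected", [(0.0, 0), (1.0, 255),
                                            (0.25, 64), (0.75, 191)])
    def test_examples(self, p, expected):
        assert quantize_fraction(np.array([p]), 255)[0] == expected


class TestEncode:
    def test_label_map_frame_counting(self, ct_series):
        label_map = np.zeros((3, 16, 16), np.int64)
        label_map[0, 1:3, 1:3] = 1
        label_map[0, 8:10, 8:10] = 2
        ds = encode_segmentation(label_map, ct_series, [desc(1), desc(2)])
        assert int(ds.NumberOfFrames) == 2  # one frame per non-empty segment

    def test_binary_packed_length(self, ct_series):
        mask = np.zeros((3, 16, 16), bool)
        mask[0, 0, 0] = True
        ds = encode_segmentation(mask[:1], ct_series[:1], [desc(1)])
        assert len(ds.PixelData) == 32  # ceil(16*16/8)

    def test_fractional_stored_values(self, ct_series):
        pm = np.full((1, 16, 16), 0.5)
        params = SegmentationParams(SegmentationType.FRACTIONAL,
                                    FractionalType.PROBABILITY)
        ds = encode_segmentation(pm, ct_series[:1], [desc(1)], params)
        stored = np.frombuffer(ds.PixelData[:256], np.uint8)
        assert (stored == 128).all()

    def test_float_with_binary_type_rejected(self, ct_series):
        with pytest.raises(TypeError):
            encode_segmentation(np.zeros((1, 16, 16)) + 0.5, ct_series[:1],
                                [desc(1)])

    def test_out_of_range_float_rejected(self, ct_series):
        params = SegmentationParams(SegmentationType.FRACTIONAL,
                                    FractionalType.PROBABILITY)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            encode_segmentation(np.full((1, 16, 16), 1.5), ct_series[:1],
                                [desc(1)], params)

    def test_label_exceeding_descriptions_rejected(self, ct_series):
        label_map = np.full((1, 16, 16), 3, np.int64)
        with pytest.raises(ValueError, match="label map"):
            encode_segmentation(label_map, ct_series[:1], [desc(1), desc(2)])

    def test_all_empty_with_omission_instructs_disabling(self, ct_series):
        with pytest.raises(ValueError, match="omit_empty_frames"):
            encode_segmentation(np.zeros((1, 16, 16), bool), ct_series[:1],
                                [desc(1)])

    def test_all_empty_without_omission_encodes_background(self, ct_series):
        params = SegmentationParams(omit_empty_frames=False)
        ds = encode_segmentation(np.zeros((3, 16, 16), bool), ct_series,
                                 [desc(1)], params)
        assert int(ds.NumberOfFrames) == 3

    def test_validates_at_construction(self, ct_series):
        mask = np.zeros((3, 16, 16), bool)
        mask[1, 5, 5] = True
        ds = encode_segmentation(mask, ct_series, [desc(1)])
        assert sop.validate_sop(ds, "segmentation").is_valid


class TestFindSegments:
    @pytest.fixture()
    def three_segment_seg(self, ct_series):
        mask = np.zeros((3, 16, 16, 3), bool)
        mask[0, 1, 1, 0] = mask[1, 2, 2, 1] = mask[2, 3, 3, 2] = True
        descriptions = [
            desc(1, label="tumor", ptype=codes.SCT.Tumor,
                 tracking=("T1", "2.25.111")),
            desc(2, label="normal", ptype=codes.SCT.Normal),
            desc(3, label="nodule", ptype=codes.SCT.Nodule),
        ]
        return encode_segmentation(mask, ct_series, descriptions)

    def test_no_filters_returns_all(self, three_segment_seg):
        assert find_segments(three_segment_seg) == [1, 2, 3]

    def test_property_type_tumor(self, three_segment_seg):
        assert find_segments(three_segment_seg,
                             property_type=codes.SCT.Tumor) == [1]

    def test_label_filter(self, three_segment_seg):
        assert find_segments(three_segment_seg, label="normal") == [2]

    def test_tracking_uid_filter(self, three_segment_seg):
        assert find_segments(three_segment_seg,
                             tracking_uid="2.25.111") == [1]

    def test_unused_label_empty(self, three_segment_seg):
        assert find_segments(three_segment_seg, label="does-not-exist") == []

    def test_conjunctive_filters(self, three_segment_seg):
        assert find_segments(three_segment_seg, label="tumor",
                             property_type=codes.SCT.Normal) == []


class TestReconstruct:
    def test_binary_roundtrip_exact(self, ct_series, rng, roundtrip):
        mask = rng.random((3, 16, 16, 2)) > 0.7
        ds = roundtrip(encode_segmentation(mask, ct_series,
                                           [desc(1), desc(2)]))
        keys = [str(s.SOPInstanceUID) for s in ct_series]
        rec = reconstruct_mask(ds, keys, [1, 2])
        assert np.array_equal(rec, mask)

    def test_omitted_background_frame_returns_zeros(self, ct_series):
        mask = np.zeros((3, 16, 16), bool)
        mask[0, 1:4, 1:4] = True
        mask[2, 5:9, 5:9] = True  # frame 1 entirely background -> omitted
        ds = encode_segmentation(mask, ct_series, [desc(1)])
        assert int(ds.NumberOfFrames) == 2
        keys = [str(s.SOPInstanceUID) for s in ct_series]
        rec = reconstruct_mask(ds, keys, [1])
        assert not rec[1].any()
        assert np.array_equal(rec[..., 0], mask)

    def test_query_order_respected(self, ct_series, rng):
        mask = rng.random((3, 16, 16)) > 0.5
        ds = encode_segmentation(mask, ct_series, [desc(1)])
        keys = [str(s.SOPInstanceUID) for s in ct_series]
        rec = reconstruct_mask(ds, keys[::-1], [1])
        assert np.array_equal(rec[..., 0], mask[::-1])

    def test_storage_order_invariance(self, ct_series, rng):
        """Shuffling stored frames (with their index entries) is a no-op."""
        mask = rng.random((3, 16, 16, 2)) > 0.6
        ds = encode_segmentation(mask, ct_series, [desc(1), desc(2)])
        keys = [str(s.SOPInstanceUID) for s in ct_series]
        baseline = reconstruct_mask(ds, keys, [1, 2])

        n = int(ds.NumberOfFrames)
        planes = unpack_bits(bytes(ds.PixelData), n, 16, 16)
        perm = rng.permutation(n)
        ds.PixelData = pack_bits(planes[perm])
        items = list(ds.PerFrameFunctionalGroupsSequence)
        ds.PerFrameFunctionalGroupsSequence = [items[i] for i in perm]
        assert np.array_equal(reconstruct_mask(ds, keys, [1, 2]), baseline)

    def test_unknown_segment_rejected(self, ct_series):
        mask = np.ones((1, 16, 16), bool)
        ds = encode_segmentation(mask, ct_series[:1], [desc(1)])
        with pytest.raises(LookupError):
            reconstruct_mask(ds, [str(ct_series[0].SOPInstanceUID)], [5])

    def test_unreferenced_source_frame_rejected(self, ct_series):
        mask = np.ones((1, 16, 16), bool)
        ds = encode_segmentation(mask, ct_series[:1], [desc(1)])
        with pytest.raises(LookupError, match="not referenced"):
            reconstruct_mask(ds, ["1.2.3.4"], [1])

    def test_combine_overlap_rejected_then_resolved(self, ct_series):
        mask = np.zeros((1, 16, 16, 2), bool)
        mask[0, 2:5, 2:5, 0] = True
        mask[0, 4, 4, 1] = True  # one-pixel overlap
        ds = encode_segmentation(mask, ct_series[:1], [desc(1), desc(2)])
        key = [str(ct_series[0].SOPInstanceUID)]
        with pytest.raises(SegmentOverlapError):
            reconstruct_mask(ds, key, combine=True)
        label_map = reconstruct_mask(ds, key, combine=True,
                                     allow_overlap=True)
        assert label_map[0, 4, 4] == 2  # highest segment number wins

    def test_combine_matches_label_map_oracle(self, ct_series, rng):
        """Brute-force per-pixel oracle on small disjoint masks."""
        for _ in range(10):
            mask = np.zeros((3, 16, 16, 3), bool)
            # assign each foreground pixel to exactly one segment
            owner = rng.integers(0, 4, size=(3, 4, 4))
            for s in range(1, 4):
                mask[:, :4, :4, s - 1] = owner == s
            ds = encode_segmentation(
                mask, ct_series, [desc(1), desc(2), desc(3)],
                SegmentationParams(omit_empty_frames=False))
            keys = [str(s.SOPInstanceUID) for s in ct_series]
            label_map = reconstruct_mask(ds, keys, combine=True)
            # oracle: per-pixel argmax of membership, 0 when none
            expected = np.zeros((3, 16, 16), np.int64)
            for s in range(1, 4):
                expected[mask[..., s - 1]] = s
            assert np.array_equal(label_map, expected)

    def test_fractional_roundtrip_within_quantization_bound(
            self, ct_series, rng, roundtrip):
        pm = rng.random((3, 16, 16))
        params = SegmentationParams(SegmentationType.FRACTIONAL,
                                    FractionalType.PROBABILITY)
        ds = roundtrip(encode_segmentation(pm, ct_series, [desc(1)], params))
        keys = [str(s.SOPInstanceUID) for s in ct_series]
        rec = reconstruct_mask(ds, keys, [1], rescale_fractional=True)
        assert np.abs(rec[..., 0] - pm).max() <= 1 / 510 + 1e-12

    def test_fractional_returns_stored_integers_by_default(self, ct_series):
        pm = np.full((1, 16, 16), 0.25)
        params = SegmentationParams(SegmentationType.FRACTIONAL,
                                    FractionalType.PROBABILITY)
        ds = encode_segmentation(pm, ct_series[:1], [desc(1)], params)
        rec = reconstruct_mask(ds, [str(ct_series[0].SOPInstanceUID)], [1])
        assert rec.dtype == np.uint8
        assert (rec[rec > 0] == 64).all()


class TestTiledSources:
    def test_sm_seg_roundtrip_by_frame_number(self, sm_image, rng):
        n = int(sm_image.NumberOfFrames)
        mask = rng.random((n, 32, 32)) > 0.8
        ds = encode_segmentation(mask, [sm_image], [desc(1)])
        rec = reconstruct_mask(ds, list(range(1, n + 1)), [1])
        assert np.array_equal(rec[..., 0], mask)

    def test_varying_orientation_rejected(self, ct_series):
        import copy

        twisted = [copy.deepcopy(ds) for ds in ct_series]
        twisted[1].ImageOrientationPatient = [0.0, 1.0, 0.0, -1.0, 0.0, 0.0]
        with pytest.raises(ValueError, match="orientation"):
            encode_segmentation(np.ones((3, 16, 16), bool), twisted,
                                [desc(1)])


class TestDescriptions:
    def test_nonconsecutive_numbers_rejected(self, ct_series):
        with pytest.raises(ValueError, match="consecutive"):
            encode_segmentation(np.ones((1, 16, 16), bool), ct_series[:1],
                                [desc(2)])

    def test_algorithm_required_unless_manual(self):
        with pytest.raises(ValueError, match="algorithm_identification"):
            SegmentDescription(1, "x", codes.SCT.Tissue, codes.SCT.Tumor,
                               algorithm_type=AlgorithmType.AUTOMATIC)
        SegmentDescription(1, "x", codes.SCT.Tissue, codes.SCT.Tumor,
                           algorithm_type=AlgorithmType.MANUAL)

    def test_description_roundtrip(self, ct_series, roundtrip):
        d = desc(1, label="tumor", ptype=codes.SCT.Tumor,
                 tracking=("T1", "2.25.42"))
        mask = np.ones((1, 16, 16), bool)
        ds = roundtrip(encode_segmentation(mask, ct_series[:1], [d]))
        back = seg.read_segment_descriptions(ds)[0]
        assert back == d
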