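"""Tomogram containers, TIFF+sidecar I/O, projections and sections."""

import json

import numpy as np
import pytest
import tifffile
from hypothesis import given
from hypothesis import strategies as st

from rifiber.errors import FormatError, MetadataError, ValidationError
from rifiber.tomo import (
    RITomogram,
    Section2D,
    TimeLapseSeries,
    extract_axial_section,
    max_intensity_projection,
    read_tomogram,
    write_tomogram,
)


def make_tomo(values, **kw):
    kw.setdefault("voxel_size", (0.5, 0.2, 0.2))
    kw.setdefault("medium_ri", 1.337)
    return RITomogram(values=values, **kw)


class TestContainers:
    def test_rejects_out_of_gate_values(self):
        with pytest.raises(ValidationError):
            make_tomo(np.full((2, 2, 2), 1.9, dtype=np.float32))
        with pytest.raises(ValidationError):
            make_tomo(np.full((2, 2, 2), np.nan))

    def test_rejects_nonpositive_voxels(self):
        with pytest.raises(ValidationError):
            make_tomo(np.full((2, 2, 2), 1.35), voxel_size=(0.5, 0.0, 0.2))

    def test_series_requires_strictly_increasing_times(self):
        frames = [
            make_tomo(np.full((2, 2, 2), 1.34), time_min=t) for t in (0.0, 5.0, 5.0)
        ]
        with pytest.raises(ValidationError):
            TimeLapseSeries(frames=frames)

    def test_series_requires_shared_geometry(self):
        a = make_tomo(np.full((2, 2, 2), 1.34), time_min=0.0)
        b = make_tomo(np.full((2, 3, 2), 1.34), time_min=5.0)
        with pytest.raises(ValidationError):
            TimeLapseSeries(frames=[a, b])


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        tomo = make_tomo(
            np.linspace(1.33, 1.36, 64, dtype=np.float32).reshape(4, 4, 4),
            time_min=12.5,
            label="roundtrip",
        )
        path = write_tomogram(tomo, tmp_path / "v.tiff")
        back = read_tomogram(path)
        assert np.array_equal(back.values, tomo.values)
        assert back.voxel_size == tomo.voxel_size
        assert back.medium_ri == tomo.medium_ri
        assert back.time_min == tomo.time_min
        assert back.label == tomo.label

    @given(
        shape=st.tuples(
            st.integers(1, 4), st.integers(1, 5), st.integers(1, 5)
        ),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_property(self, shape, seed):
        import tempfile
        from pathlib import Path

        rng = np.random.default_rng(seed)
        vals = (1.30 + 0.1 * rng.random(shape)).astype(np.float32)
        tomo = make_tomo(vals)
        with tempfile.TemporaryDirectory() as d:
            back = read_tomogram(write_tomogram(tomo, Path(d) / "v.tiff"))
        assert np.array_equal(back.values, tomo.values)

    def test_deterministic_encoding(self, tmp_path):
        tomo = make_tomo(np.full((4, 4, 4), 1.35, dtype=np.float32))
        p1 = write_tomogram(tomo, tmp_path / "a.tiff")
        p2 = write_tomogram(tomo, tmp_path / "b.tiff")
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_volume_rejected_before_write(self, tmp_path):
        tomo = make_tomo(np.full((2, 2, 2), 1.35, dtype=np.float32))
        tomo.values[0, 0, 0] = 2.5  # violate the gate after construction
        with pytest.raises(ValidationError):
            write_tomogram(tomo, tmp_path / "bad.tiff")
        assert not (tmp_path / "bad.tiff").exists()


class TestReadErrors:
    def test_missing_sidecar_is_metadata_error(self, tmp_path):
        tifffile.imwrite(tmp_path / "x.tiff", np.zeros((2, 3, 3), np.float32),
                         photometric="minisblack")
        with pytest.raises(MetadataError):
            read_tomogram(tmp_path / "x.tiff")

    def test_missing_voxel_size_is_metadata_error(self, tmp_path):
        tifffile.imwrite(tmp_path / "x.tiff", np.full((2, 3, 3), 1.34, np.float32))
        with pytest.raises(MetadataError, match="voxel_size"):
            read_tomogram(tmp_path / "x.tiff", meta={"medium_ri": 1.337})

    def test_integer_stack_affine_decode(self, tmp_path):
        # hand-decoded: 1.30 + 1e-4 * {100, 200, 300}
        arr = np.array([[[100, 200, 300]]], dtype=np.uint16)
        tifffile.imwrite(tmp_path / "i.tiff", arr)
        meta = {
            "voxel_size_um": [0.5, 0.2, 0.2],
            "medium_ri": 1.337,
            "scale": 1e-4,
            "offset": 1.30,
        }
        tomo = read_tomogram(tmp_path / "i.tiff", meta=meta)
        np.testing.assert_allclose(tomo.values[0, 0], [1.31, 1.32, 1.33], atol=1e-6)

    def test_integer_stack_without_scale_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "i.tiff", np.full((1, 2, 2), 7, np.uint16))
        with pytest.raises(MetadataError, match="scale"):
            read_tomogram(
                tmp_path / "i.tiff",
                meta={"voxel_size_um": [0.5, 0.2, 0.2], "medium_ri": 1.337},
            )

    def test_mixed_dtype_pages_are_format_error(self, tmp_path):
        with tifffile.TiffWriter(tmp_path / "m.tiff") as tw:
            tw.write(np.zeros((3, 3), np.float32))
            tw.write(np.zeros((3, 3), np.uint16))
        with pytest.raises(FormatError, match="mixed"):
            read_tomogram(
                tmp_path / "m.tiff",
                meta={"voxel_size_um": [0.5, 0.2, 0.2], "medium_ri": 1.337},
            )


class TestProjections:
    def test_mip_locates_single_bright_voxel(self):
        vals = np.full((8, 6, 7), 1.337, np.float32)
        vals[5, 2, 3] = 1.36
        mip = max_intensity_projection(make_tomo(vals))
        assert np.unravel_index(mip.argmax(), mip.shape) == (2, 3)
        # every MIP pixel equals its column maximum exactly
        np.testing.assert_array_equal(mip, vals.max(axis=0))

    def test_constant_volume_gives_constant_mip(self):
        mip = max_intensity_projection(make_tomo(np.full((3, 4, 4), 1.35, np.float32)))
        assert np.all(mip == np.float32(1.35))

    def test_depth_color_ties_break_toward_smaller_z(self):
        vals = np.full((8, 4, 4), 1.337, np.float32)
        vals[1, 2, 2] = 1.36
        vals[6, 2, 2] = 1.36  # equal maxima at z=1 and z=6
        rgb = max_intensity_projection(make_tomo(vals), depth_colored=True)
        import matplotlib

        expected_hue = matplotlib.colormaps["viridis"](1 / 7)[:3]
        np.testing.assert_allclose(rgb[2, 2], expected_hue, atol=1e-6)

    def test_depth_color_bounded(self):
        rng = np.random.default_rng(1)
        vals = (1.33 + 0.02 * rng.random((5, 8, 8))).astype(np.float32)
        rgb = max_intensity_projection(make_tomo(vals), depth_colored=True)
        assert rgb.shape == (8, 8, 3)
        assert rgb.min() >= 0 and rgb.max() <= 1


class TestSections:
    def test_max_contrast_picks_unique_maximizer(self):
        vals = np.full((10, 5, 5), 1.337, np.float32)
        vals[7] += 0.01
        sec = extract_axial_section(make_tomo(vals), "max_contrast")
        assert sec.z_index == 7
        assert sec.slice_thickness == 0.5
        assert sec.pixel_size == (0.2, 0.2)

    def test_max_contrast_dominates_all_other_slices(self):
        rng = np.random.default_rng(3)
        vals = (1.33 + 0.02 * rng.random((6, 16, 16))).astype(np.float32)
        tomo = make_tomo(vals)
        sec = extract_axial_section(tomo, "max_contrast")
        energies = np.clip(vals - 1.337, 0, None).sum(axis=(1, 2))
        assert energies[sec.z_index] == energies.max()

    def test_fixed_index_and_bounds(self):
        tomo = make_tomo(np.full((10, 4, 4), 1.34, np.float32))
        assert extract_axial_section(tomo, 3).z_index == 3
        with pytest.raises(ValidationError):
            extract_axial_section(tomo, 12)

    def test_section_validation(self):
        with pytest.raises(ValidationError):
            Section2D(
                values=np.full((4, 4), 2.0, np.float32),
                pixel_size=(0.2, 0.2),
                slice_thickness=0.5,
                z_index=0,
                medium_ri=1.337,
            )
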