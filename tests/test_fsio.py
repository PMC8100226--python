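"""File-format round trips and agreement with an independent reader."""

import gzip

import numpy as np
import nibabel as nib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfglm import fsio
from surfglm.fsio import (
    FormatError,
    MghImage,
    SurfaceMesh,
    load_stack,
    parse_map_filename,
    read_mgh,
    read_surface,
    write_mgh,
    write_surface,
)
from surfglm.synthetic import SimulationConfig, make_icosphere, simulate_dataset


class TestMgh:
    def test_roundtrip_identity(self, tmp_path):
        vals = np.linspace(-3, 3, 17, dtype=np.float32)
        write_mgh(MghImage.from_map(vals), tmp_path / "x.mgh")
        back = read_mgh(tmp_path / "x.mgh")
        assert back.data.shape == (17, 1, 1, 1)
        np.testing.assert_array_equal(back.vertex_values, vals)

    def test_footerless_file_length_is_header_plus_payload(self, tmp_path):
        img = MghImage(np.zeros((2, 1, 1, 1), dtype=np.float32), footer=None)
        write_mgh(img, tmp_path / "two.mgh")
        assert (tmp_path / "two.mgh").stat().st_size == 284 + 2 * 4

    def test_zero_map_roundtrip(self, tmp_path):
        write_mgh(MghImage.from_map(np.zeros(10, dtype=np.float32)), tmp_path / "z.mgh")
        assert np.all(read_mgh(tmp_path / "z.mgh").vertex_values == 0)

    def test_mgz_is_gzipped_mgh(self, tmp_path):
        img = MghImage.from_map(np.arange(5, dtype=np.float32))
        write_mgh(img, tmp_path / "a.mgh")
        write_mgh(img, tmp_path / "a.mgz")
        assert gzip.decompress((tmp_path / "a.mgz").read_bytes()) == (tmp_path / "a.mgh").read_bytes()

    @settings(max_examples=40, deadline=None)
    @given(
        w=st.integers(1, 40),
        h=st.integers(1, 3),
        d=st.integers(1, 3),
        f=st.integers(1, 3),
        seed=st.integers(0, 2**31 - 1),
        footer=st.booleans(),
    )
    def test_roundtrip_bit_exact_property(self, tmp_path_factory, w, h, d, f, seed, footer):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((w, h, d, f)).astype(np.float32)
        img = MghImage(data, footer=(1.5, 90.0, 2.5, 3.5) if footer else None)
        path = tmp_path_factory.mktemp("mgh") / "p.mgh"
        write_mgh(img, path)
        back = read_mgh(path)
        np.testing.assert_array_equal(back.data, data)
        assert back.data.dtype == np.float32
        if footer:
            assert back.footer == (1.5, 90.0, 2.5, 3.5)

    @pytest.mark.parametrize("code,npdtype", [(0, np.uint8), (1, np.int32), (4, np.int16)])
    def test_integer_dtypes_roundtrip(self, tmp_path, code, npdtype):
        data = np.arange(24, dtype=npdtype).reshape(4, 3, 2, 1)
        write_mgh(MghImage(data, dtype_code=code), tmp_path / "i.mgh")
        back = read_mgh(tmp_path / "i.mgh")
        np.testing.assert_array_equal(back.data, data)

    @pytest.mark.parametrize("suffix", [".mgh", ".mgz"])
    def test_independent_reader_agrees(self, tmp_path, suffix):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal(100).astype(np.float32)
        ours = tmp_path / f"ours{suffix}"
        write_mgh(MghImage.from_map(vals), ours)
        np.testing.assert_array_equal(np.asarray(nib.load(ours).dataobj).ravel(), vals)
        theirs = tmp_path / f"theirs{suffix}"
        nib.save(nib.MGHImage(vals.reshape(-1, 1, 1), np.eye(4)), theirs)
        np.testing.assert_array_equal(read_mgh(theirs).vertex_values, vals)

    def test_bad_version_rejected(self, tmp_path):
        path = tmp_path / "bad.mgh"
        write_mgh(MghImage.from_map(np.ones(3, dtype=np.float32)), path)
        raw = bytearray(path.read_bytes())
        raw[:4] = (2).to_bytes(4, "big")
        path.write_bytes(bytes(raw))
        with pytest.raises(FormatError, match="version"):
            read_mgh(path)

    def test_truncated_payload_rejected(self, tmp_path):
        path = tmp_path / "trunc.mgh"
        write_mgh(MghImage(np.ones((50, 1, 1, 1), dtype=np.float32), footer=None), path)
        path.write_bytes(path.read_bytes()[:-8])
        with pytest.raises(FormatError, match="truncated"):
            read_mgh(path)

    def test_unsupported_dtype_code(self):
        with pytest.raises(FormatError):
            MghImage(np.zeros((1, 1, 1, 1)), dtype_code=2)


class TestMapFilename:
    def test_custom_measure_name_parses(self):
        parts = parse_map_filename("lh.radialdistance.fwhm10.fsaverage.mgh")
        assert parts == {"hemi": "lh", "measure": "radialdistance", "fwhm": 10, "target": "fsaverage"}

    def test_dotted_measure_parses(self):
        parts = parse_map_filename("rh.w-g.pct.fwhm5.fsaverage.mgh")
        assert parts["measure"] == "w-g.pct"
        assert parts["fwhm"] == 5

    def test_thickness_resolves_standard_name(self):
        assert fsio.map_filename("lh", "thickness", 10, "fsaverage") == "lh.thickness.fwhm10.fsaverage.mgh"


class TestSurface:
    def test_icosahedron_roundtrip(self, tmp_path, ico0):
        write_surface(ico0, tmp_path / "lh.white")
        back = read_surface(tmp_path / "lh.white")
        assert back.n_vertices == 12 and back.n_faces == 20
        assert all(len(a) == 5 for a in back.adjacency)

    def test_unit_edge_icosahedron_area(self):
        # circumradius of a unit-edge icosahedron
        r = 0.25 * np.sqrt(10 + 2 * np.sqrt(5))
        mesh = make_icosphere(0, r)
        assert mesh.total_area == pytest.approx(5 * np.sqrt(3), rel=1e-9)
        assert mesh.vertex_area.sum() == pytest.approx(mesh.total_area, rel=1e-9)

    def test_single_triangle_adjacency(self):
        mesh = SurfaceMesh(coords=np.eye(3), faces=np.array([[0, 1, 2]]))
        assert all(len(a) == 2 for a in mesh.adjacency)
        for u in range(3):
            for v in mesh.adjacency[u]:
                assert u in mesh.adjacency[v]

    def test_independent_reader_agrees(self, tmp_path, ico2):
        write_surface(ico2, tmp_path / "lh.white")
        coords, faces = nib.freesurfer.read_geometry(tmp_path / "lh.white")
        np.testing.assert_allclose(coords, ico2.coords, atol=1e-4)
        np.testing.assert_array_equal(faces, ico2.faces)
        nib.freesurfer.write_geometry(tmp_path / "rh.white", ico2.coords, ico2.faces)
        back = read_surface(tmp_path / "rh.white")
        np.testing.assert_allclose(back.coords, ico2.coords, atol=1e-4)
        np.testing.assert_array_equal(back.faces, ico2.faces)

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "junk").write_bytes(b"\x00\x01\x02" + b"x" * 50)
        with pytest.raises(FormatError, match="magic"):
            read_surface(tmp_path / "junk")

    def test_face_index_out_of_range_rejected(self, tmp_path, ico0):
        write_surface(ico0, tmp_path / "lh.white")
        raw = bytearray((tmp_path / "lh.white").read_bytes())
        raw[-4:] = (99).to_bytes(4, "big")  # corrupt last face index
        (tmp_path / "bad.white").write_bytes(bytes(raw))
        with pytest.raises(FormatError, match="face index"):
            read_surface(tmp_path / "bad.white")

    def test_vertex_area_conserved_on_random_icospheres(self):
        for s, r in [(1, 10.0), (2, 50.0), (3, 80.0)]:
            mesh = make_icosphere(s, r)
            assert mesh.vertex_area.sum() == pytest.approx(mesh.triangle_area.sum(), rel=1e-9)


class TestLoadStack:
    def test_row_order_follows_ids(self, tmp_path):
        cfg = SimulationConfig(n_subjects=3, seed=3)
        simulate_dataset(cfg, tmp_path)
        ids = ["sub0002", "sub0003", "sub0001"]
        stack = load_stack(tmp_path, ids, "lh", "thickness", 10, "fsaverage")
        assert stack.data.shape == (3, 162)
        assert stack.ids == ids
        direct = read_mgh(tmp_path / "sub0002" / "surf" / "lh.thickness.fwhm10.fsaverage.mgh")
        np.testing.assert_allclose(stack.data[0], direct.vertex_values)

    def test_missing_subject_named(self, tmp_path):
        cfg = SimulationConfig(n_subjects=2, seed=3)
        simulate_dataset(cfg, tmp_path)
        with pytest.raises(FileNotFoundError, match="ghost"):
            load_stack(tmp_path, ["sub0001", "ghost"], "lh", "thickness", 10, "fsaverage")

    def test_vertex_count_mismatch_rejected(self, tmp_path):
        cfg = SimulationConfig(n_subjects=2, seed=3)
        simulate_dataset(cfg, tmp_path)
        bad = tmp_path / "sub0002" / "surf" / "lh.thickness.fwhm10.fsaverage.mgh"
        write_mgh(MghImage.from_map(np.ones(50, dtype=np.float32)), bad)
        with pytest.raises(FormatError, match="vertex count"):
            load_stack(tmp_path, ["sub0001", "sub0002"], "lh", "thickness", 10, "fsaverage")

    def test_mgz_accepted_transparently(self, tmp_path):
        cfg = SimulationConfig(n_subjects=2, seed=3)
        simulate_dataset(cfg, tmp_path)
        p = tmp_path / "sub0002" / "surf" / "lh.thickness.fwhm10.fsaverage.mgh"
        img = read_mgh(p)
        p.unlink()
        write_mgh(img, p.with_suffix(".mgz"))
        stack = load_stack(tmp_path, ["sub0001", "sub0002"], "lh", "thickness", 10, "fsaverage")
        assert stack.data.shape == (2, 162)

    def test_memmap_backing_above_budget(self, tmp_path):
        cfg = SimulationConfig(n_subjects=3, seed=3)
        simulate_dataset(cfg, tmp_path)
        ids = ["sub0001", "sub0002", "sub0003"]
        small = load_stack(tmp_path, ids, "lh", "thickness", 10, "fsaverage", mem_budget_bytes=100)
        big = load_stack(tmp_path, ids, "lh", "thickness", 10, "fsaverage")
        assert isinstance(small.data, np.memmap)
        assert not isinstance(big.data, np.memmap)
        np.testing.assert_array_equal(np.asarray(small.data), big.data)
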