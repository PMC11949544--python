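"""Network assembly, delays, fragmentation, annulment, coupled simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromass.brain_network import (
    Atlas,
    ConnectivityMatrix,
    Region,
    annul_region_connections,
    build_delay_matrix,
    build_network,
    fragment_region,
    region_seed,
    simulate_network,
)
from neuromass.nmm_core import simulate_column
from neuromass.synthetic_scenarios import make_synthetic_connectivity


class TestDelayMatrix:
    def test_known_distance(self, toy_atlas):
        a = Atlas((Region("lh.a", "lh", (0.0, 0.0, 0.0)), Region("lh.b", "lh", (75.0, 0.0, 0.0))))
        d = build_delay_matrix(a, velocity=7.5)
        assert d[0, 1] == pytest.approx(0.010)  # 75 mm at 7.5 m/s = 10 ms
        assert d[0, 0] == 0.0

    def test_identical_centroids_zero_delay(self):
        a = Atlas((Region("lh.a", "lh", (1.0, 2.0, 3.0)), Region("lh.b", "lh", (1.0, 2.0, 3.0))))
        assert np.all(build_delay_matrix(a) == 0.0)

    def test_matches_elementwise_recomputation(self, rng):
        pts = rng.normal(0, 40, size=(5, 3))
        a = Atlas(tuple(Region(f"lh.r{i}", "lh", tuple(p)) for i, p in enumerate(pts)))
        d = build_delay_matrix(a, velocity=7.5)
        for i in range(5):
            for j in range(5):
                expect = np.linalg.norm(pts[i] - pts[j]) * 1e-3 / 7.5
                assert d[i, j] == pytest.approx(expect)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_symmetry_and_zero_diagonal(self, seed):
        pts = np.random.default_rng(seed).normal(0, 50, size=(6, 3))
        a = Atlas(tuple(Region(f"lh.r{i}", "lh", tuple(p)) for i, p in enumerate(pts)))
        d = build_delay_matrix(a)
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)

    def test_rejects_nonpositive_velocity(self, toy_atlas):
        with pytest.raises(ValueError):
            build_delay_matrix(toy_atlas, velocity=0.0)


class TestBuildNetwork:
    def test_default_head_has_67_masses_66_cortical(self, default_head):
        atlas, _, _ = default_head
        conn = make_synthetic_connectivity(atlas, seed=0)
        model = build_network(atlas, conn)
        assert model.n_masses == 67
        assert len(model.atlas.cortical_names) == 66

    def test_one_mass_per_region_and_thalamic_params(self, toy_atlas):
        conn = make_synthetic_connectivity(toy_atlas, seed=0)
        model = build_network(toy_atlas, conn)
        assert set(model.params) == set(toy_atlas.names)
        assert model.params["thalamus"].output_subpop == "TC"
        assert model.params["lh.a"].output_subpop == "PYR"

    def test_dimension_mismatch_rejected(self, toy_atlas):
        bad = ConnectivityMatrix(names=("lh.a", "lh.b"), weights=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            build_network(toy_atlas, bad)


class TestFragmentation:
    def test_single_part_is_identity_up_to_renaming(self, toy_atlas):
        conn = make_synthetic_connectivity(toy_atlas, density=1.0, seed=2)
        atlas2, conn2 = fragment_region(toy_atlas, conn, "lh.b", [1.0])
        i_old = conn.index("lh.b")
        i_new = conn2.index("lh.b#0")
        assert atlas2.get("lh.b#0").parent == "lh.b"
        keep_old = [i for i in range(len(conn.names)) if i != i_old]
        keep_new = [i for i in range(len(conn2.names)) if i != i_new]
        np.testing.assert_array_equal(
            conn2.weights[np.ix_(keep_new, keep_new)], conn.weights[np.ix_(keep_old, keep_old)]
        )
        np.testing.assert_array_equal(conn2.weights[i_new, keep_new], conn.weights[i_old, keep_old])

    def test_children_copy_parent_connectivity(self, toy_atlas):
        conn = make_synthetic_connectivity(toy_atlas, density=1.0, seed=2)
        atlas2, conn2 = fragment_region(toy_atlas, conn, "lh.a", [0.5, 0.25, 0.25])
        others = [n for n in conn.names if n != "lh.a"]
        for child in ("lh.a#0", "lh.a#1", "lh.a#2"):
            for other in others:
                assert conn2.weights[conn2.index(child), conn2.index(other)] == pytest.approx(
                    conn.weights[conn.index("lh.a"), conn.index(other)]
                )
        # all other rows/columns bit-identical
        for a in others:
            for b in others:
                assert conn2.weights[conn2.index(a), conn2.index(b)] == conn.weights[conn.index(a), conn.index(b)]

    def test_area_bookkeeping_sums_to_parent(self, toy_atlas):
        conn = make_synthetic_connectivity(toy_atlas, seed=2)
        atlas2, _ = fragment_region(toy_atlas, conn, "lh.a", [0.2, 0.3, 0.5])
        children = [r for r in atlas2.regions if r.parent == "lh.a"]
        assert sum(r.area for r in children) == pytest.approx(1.0)
        assert [r.area for r in children] == pytest.approx([0.2, 0.3, 0.5])

    def test_fragment_then_annul_child_zeroes_only_that_child(self, toy_atlas):
        conn = make_synthetic_connectivity(toy_atlas, density=1.0, seed=2)
        atlas2, conn2 = fragment_region(toy_atlas, conn, "lh.a", [0.5, 0.5])
        conn3 = annul_region_connections(conn2, "lh.a#1")
        k = conn3.index("lh.a#1")
        assert np.all(conn3.weights[k] == 0) and np.all(conn3.weights[:, k] == 0)
        keep = [i for i in range(len(conn2.names)) if i != k]
        np.testing.assert_array_equal(
            conn3.weights[np.ix_(keep, keep)], conn2.weights[np.ix_(keep, keep)]
        )

    def test_invalid_fractions_rejected(self, toy_atlas):
        conn = make_synthetic_connectivity(toy_atlas, seed=2)
        with pytest.raises(ValueError):
            fragment_region(toy_atlas, conn, "lh.a", [0.5, 0.4])
        with pytest.raises(KeyError):
            fragment_region(toy_atlas, conn, "nope", [1.0])


class TestAnnulment:
    def test_fully_connected_four_regions(self):
        names = ("lh.a", "lh.b", "rh.a", "rh.b")
        w = np.ones((4, 4)) - np.eye(4)
        conn = ConnectivityMatrix(names=names, weights=w)
        out = annul_region_connections(conn, "lh.b")
        assert int((out.weights != w).sum()) == 2 * (4 - 1)

    def test_already_isolated_region_unchanged(self):
        names = ("lh.a", "lh.b")
        conn = ConnectivityMatrix(names=names, weights=np.zeros((2, 2)))
        out = annul_region_connections(conn, "lh.a")
        np.testing.assert_array_equal(out.weights, conn.weights)

    def test_annulling_all_regions_gives_zero_matrix(self):
        names = ("lh.a", "lh.b", "rh.a")
        conn = ConnectivityMatrix(names=names, weights=np.ones((3, 3)) - np.eye(3))
        for n in names:
            conn = annul_region_connections(conn, n)
        assert np.all(conn.weights == 0)


class TestSimulateNetwork:
    def test_decoupled_limit_equals_isolated_columns_exactly(self, small_head):
        atlas, _, _, conn = small_head
        model = build_network(atlas, conn, global_coupling=0.0)
        traces = simulate_network(model, 3.0, seed=9)
        for i, name in enumerate(atlas.names):
            solo = simulate_column(model.params[name], 3.0, seed=region_seed(9, i)) \
                if name != "thalamus" else None
            if solo is not None:
                np.testing.assert_array_equal(traces.trace(name), solo.dipole_drive)

    def test_deterministic_under_seed(self, small_head):
        atlas, _, _, conn = small_head
        model = build_network(atlas, conn)
        a = simulate_network(model, 3.0, seed=4)
        b = simulate_network(model, 3.0, seed=4)
        np.testing.assert_array_equal(a.data, b.data)

    def test_spikes_only_in_and_near_ez(self, small_head):
        from neuromass.forward_model import EEGRecording
        from neuromass.ies_metrics import DetectorParams, detect_ies

        atlas, _, _, conn = small_head
        model = build_network(atlas, conn)
        ez = atlas.cortical_names[0]
        traces = simulate_network(model, 12.0, seed=2, ez_regions=[ez])

        def n_events(name):
            x = traces.trace(name)[int(2.0 / traces.dt) :]
            rec = EEGRecording([name], x[None, :], 1.0 / traces.dt, kind="bipolar")
            return len(detect_ies(rec, window=10.0, params=DetectorParams(min_amplitude=0.5)))

        assert n_events(ez) >= 20  # 2-3/s over 10 s
        background_counts = [n_events(n) for n in atlas.cortical_names[1:]]
        assert max(background_counts) < n_events(ez) / 2

    def test_all_background_network_has_no_spikewave(self, small_head):
        from neuromass.forward_model import EEGRecording
        from neuromass.ies_metrics import DetectorParams, detect_ies

        atlas, _, _, conn = small_head
        model = build_network(atlas, conn)
        traces = simulate_network(model, 12.0, seed=6)
        total = 0
        for name in atlas.cortical_names:
            x = traces.trace(name)[int(2.0 / traces.dt) :]
            rec = EEGRecording([name], x[None, :], 1.0 / traces.dt, kind="bipolar")
            total += len(detect_ies(rec, window=10.0, params=DetectorParams(min_amplitude=0.5)))
        assert total == 0

    def test_unknown_ez_region_rejected(self, small_head):
        atlas, _, _, conn = small_head
        model = build_network(atlas, conn)
        with pytest.raises(KeyError):
            simulate_network(model, 1.0, seed=0, ez_regions=["nonexistent"])


class TestTableIO:
    def test_atlas_round_trip(self, toy_atlas, tmp_path):
        toy_atlas.save(tmp_path / "atlas.tsv")
        from neuromass.brain_network import Atlas

        back = Atlas.load(tmp_path / "atlas.tsv")
        assert back.names == toy_atlas.names
        np.testing.assert_allclose(back.centroids, toy_atlas.centroids)
        assert back.get("thalamus").hemisphere == "sub"

    def test_connectivity_round_trip(self, toy_atlas, tmp_path):
        conn = make_synthetic_connectivity(toy_atlas, seed=1)
        conn.save(tmp_path / "c.tsv")
        back = ConnectivityMatrix.load(tmp_path / "c.tsv")
        assert back.names == conn.names
        np.testing.assert_allclose(back.weights, conn.weights, rtol=1e-12)


def test_numerical_blowup_reports_step_and_region():
    from neuromass.nmm_core import NumericalBlowupError
    from neuromass.presets import cortical_params
    from neuromass.nmm_core import simulate_column
    import numpy as np

    n = int(1.0 * 2048)
    bad = np.zeros(n)
    bad[100] = np.nan
    with pytest.raises(NumericalBlowupError) as err:
        simulate_column(cortical_params("background"), 1.0, seed=0,
                        external_inputs={"PYR": bad})
    assert err.value.step >= 100
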