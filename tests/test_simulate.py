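"""Tests of the synthetic-data generators against closed-form expectations."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from junctionkit import simulate


class TestJunctionNetwork:
    def test_two_cells_give_single_bisector_belt(self):
        geo = simulate.generate_junction_network(2, (10000, 10000), seed=0)
        assert len(geo.belts) == 1
        assert geo.total_belt_length_nm() > 0

    def test_same_seed_reproduces_geometry(self):
        a = simulate.generate_junction_network(9, (20000, 20000), seed=7)
        b = simulate.generate_junction_network(9, (20000, 20000), seed=7)
        assert len(a.belts) == len(b.belts)
        for ba, bb in zip(a.belts, b.belts):
            np.testing.assert_array_equal(ba, bb)

    def test_single_cell_cannot_form_junctions(self):
        with pytest.raises(ValueError, match="cannot form junctions"):
            simulate.generate_junction_network(1, (10000, 10000), seed=0)

    def test_vertices_inside_field(self, medium_geometry):
        w, h = medium_geometry.field_size_nm
        for belt in medium_geometry.belts:
            assert belt[:, 0].min() >= 0 and belt[:, 0].max() <= w
            assert belt[:, 1].min() >= 0 and belt[:, 1].max() <= h

    def test_total_length_matches_poisson_voronoi_theory(self):
        # Poisson-Voronoi tessellations have expected edge length per unit
        # area 2*sqrt(lambda); border clipping removes part of it, so the
        # Monte-Carlo mean over many fields should sit within 20%.
        side_um = 40.0
        n_cells = 25
        lam = n_cells / side_um**2
        theory_um = 2.0 * np.sqrt(lam) * side_um**2
        lengths = [
            simulate.generate_junction_network(
                n_cells, (side_um * 1000, side_um * 1000), seed=s
            ).total_belt_length_nm()
            / 1000.0
            for s in range(100)
        ]
        assert abs(np.mean(lengths) / theory_um - 1.0) < 0.20


class TestPlacement:
    def test_dispersed_molecules_lie_on_belts(self, small_geometry):
        params = simulate.ClusteringParams(mode="dispersed", linear_density_per_um=10)
        mol = simulate.place_fluorophores(small_geometry, params, seed=4)
        lines = [LineString(b) for b in small_geometry.belts]
        for p in mol.positions_nm:
            assert min(ln.distance(Point(p)) for ln in lines) < 1e-6
        assert (mol.cluster_id == -1).all()

    def test_expected_count_is_poisson_mean(self, small_geometry):
        # tiny density: expected count = belt_length_um * density
        density = 0.01
        expected = small_geometry.total_belt_length_nm() / 1000.0 * density
        params = simulate.ClusteringParams(mode="dispersed", linear_density_per_um=density)
        counts = [
            simulate.place_fluorophores(small_geometry, params, seed=s).n
            for s in range(1000)
        ]
        se = np.sqrt(expected / 1000)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_clustered_count_matches_same_expectation(self, small_geometry):
        density = 10.0
        expected = small_geometry.total_belt_length_nm() / 1000.0 * density
        params = simulate.ClusteringParams(
            mode="clustered", linear_density_per_um=density,
            mean_molecules_per_cluster=8,
        )
        counts = [
            simulate.place_fluorophores(small_geometry, params, seed=s).n
            for s in range(300)
        ]
        # compound Poisson: var = E[N] * (1 + mean_per_cluster)
        se = np.sqrt(expected * 9 / 300)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_within_cluster_pair_distance_is_rayleigh(self, medium_geometry):
        # two iid isotropic Gaussian(sigma) points differ by Rayleigh(sigma*sqrt2)
        # whose mean is sigma*sqrt(2)*sqrt(pi/2)
        from scipy.spatial.distance import pdist

        sigma = 20.0
        params = simulate.ClusteringParams(
            mode="clustered", linear_density_per_um=20,
            cluster_sigma_nm=sigma, mean_molecules_per_cluster=6,
        )
        dists = []
        for s in range(5):
            mol = simulate.place_fluorophores(medium_geometry, params, seed=s)
            for cid in np.unique(mol.cluster_id[mol.cluster_id >= 0]):
                pts = mol.positions_nm[mol.cluster_id == cid]
                if len(pts) >= 2:
                    dists.append(pdist(pts))
        mean = np.concatenate(dists).mean()
        assert abs(mean - sigma * np.sqrt(2) * np.sqrt(np.pi / 2)) < 0.05 * mean

    def test_clustered_mode_enriches_short_distances(self, small_geometry):
        # fraction of pairwise distances below 40 nm is strictly higher for
        # clustered than dispersed placements at equal expected count
        from scipy.spatial.distance import pdist

        wins = 0
        for s in range(20):
            frac = {}
            for mode in ("clustered", "dispersed"):
                params = simulate.ClusteringParams(
                    mode=mode, linear_density_per_um=15, cluster_sigma_nm=20,
                    mean_molecules_per_cluster=8,
                )
                mol = simulate.place_fluorophores(small_geometry, params, seed=100 + s)
                d = pdist(mol.positions_nm)
                frac[mode] = (d < 40).mean()
            wins += frac["clustered"] > frac["dispersed"]
        assert wins == 20

    def test_off_belt_fraction_places_background(self, small_geometry):
        params = simulate.ClusteringParams(
            mode="dispersed", linear_density_per_um=20, off_belt_fraction=0.5
        )
        mol = simulate.place_fluorophores(small_geometry, params, seed=9)
        lines = [LineString(b) for b in small_geometry.belts]
        d = np.array(
            [min(ln.distance(Point(p)) for ln in lines) for p in mol.positions_nm]
        )
        assert (d > 100).any()  # some molecules clearly off the belt

    def test_colocalized_channels_partner_structure(self, medium_geometry):
        params = simulate.ClusteringParams(mode="dispersed", linear_density_per_um=2)
        a, b = simulate.place_colocalized_channels(
            medium_geometry, params, coloc_fraction=0.4, seed=5
        )
        paired_a = np.flatnonzero(a.colocalized_partner >= 0)
        assert len(paired_a) == round(0.4 * a.n)
        # partner offsets are Gaussian sigma=20 -> essentially all within 90 nm
        pa = a.positions_nm[paired_a]
        pb = b.positions_nm[a.colocalized_partner[paired_a]]
        d = np.linalg.norm(pa - pb, axis=1)
        assert np.quantile(d, 0.95) < 90.0


class TestSMLMRender:
    def test_all_off_stack_is_baseline_plus_read_noise(self):
        mol = simulate.GroundTruthMolecules(
            np.array([[400.0, 400.0]]), "x", np.array([-1])
        )
        acq = simulate.AcquisitionParams(
            n_frames=50, on_probability=0.0, baseline_adu=100.0, read_noise_adu=5.0
        )
        stack = simulate.render_smlm_stack(mol, acq, seed=0, field_size_nm=(800, 800))
        assert abs(stack.mean() - 100.0) < 1.0

    def test_photon_conservation_without_noise(self):
        # one emitter at a pixel center, gain 1, no noise: each ON frame sums
        # to the photon budget (minus the <0.01% PSF tail outside the field)
        acq = simulate.AcquisitionParams(
            n_frames=40, on_probability=0.5, em_gain=1.0, photons_per_on_frame=2000,
            read_noise_adu=0.0, baseline_adu=0.0, shot_noise=False,
        )
        center = np.array([[10.5 * 80, 10.5 * 80]])
        mol = simulate.GroundTruthMolecules(center, "x", np.array([-1]))
        stack, on = simulate.render_smlm_stack(
            mol, acq, seed=1, field_size_nm=(21 * 80, 21 * 80), return_on_events=True
        )
        sums = stack.sum(axis=(1, 2)).astype(float)
        on = on[:, 0]
        assert np.allclose(sums[on], 2000, rtol=2e-3)
        assert (sums[~on] == 0).all()

    def test_on_event_count_binomial(self):
        rng = np.random.default_rng(12)
        pos = rng.uniform(100, 2400, size=(100, 2))
        mol = simulate.GroundTruthMolecules(pos, "x", np.full(100, -1))
        acq = simulate.AcquisitionParams(
            n_frames=2000, on_probability=0.005, read_noise_adu=0.0,
            baseline_adu=0.0, shot_noise=False,
        )
        _, on = simulate.render_smlm_stack(
            mol, acq, seed=3, field_size_nm=(2560, 2560), return_on_events=True
        )
        total = on.sum()
        expected = 100 * 0.005 * 2000
        sd = np.sqrt(expected * (1 - 0.005))
        assert abs(total - expected) < 4 * sd

    def test_render_deterministic_per_seed(self):
        mol = simulate.GroundTruthMolecules(
            np.array([[500.0, 700.0], [1500.0, 900.0]]), "x", np.array([-1, -1])
        )
        acq = simulate.AcquisitionParams(n_frames=20, on_probability=0.1)
        a = simulate.render_smlm_stack(mol, acq, seed=42, field_size_nm=(2000, 2000))
        b = simulate.render_smlm_stack(mol, acq, seed=42, field_size_nm=(2000, 2000))
        np.testing.assert_array_equal(a, b)


class TestWidefieldRender:
    def test_background_ordering_by_substrate(self, small_geometry):
        means = {}
        for sub in ("glass", "PC", "PE"):
            stack = simulate.render_widefield_if(
                small_geometry, belt_intensity=0.0, substrate=sub, n_slices=3,
                seed=1, noise=False,
            )
            means[sub] = stack.mean()
        assert means["glass"] < means["PC"] < means["PE"]

    def test_max_projection_peak_on_belt(self, small_geometry):
        stack = simulate.render_widefield_if(
            small_geometry, belt_intensity=800.0, substrate="glass", n_slices=5,
            seed=1, pixel_nm=160.0,
        )
        proj = stack.max(axis=0)
        mask = simulate.belt_mask(small_geometry, 160.0, halfwidth_nm=320.0)
        peak = np.unravel_index(np.argmax(proj), proj.shape)
        assert mask.mask[peak]

    def test_in_focus_belt_intensity_recovered(self, small_geometry):
        belt_intensity = 600.0
        stack = simulate.render_widefield_if(
            small_geometry, belt_intensity, substrate="glass", n_slices=5,
            seed=1, pixel_nm=160.0, noise=False, belt_width_px=0.0,
        )
        mask = simulate.belt_mask(small_geometry, 160.0, halfwidth_nm=0.0)
        in_focus = stack[2].astype(float)
        bg = simulate.SUBSTRATE_BACKGROUND_ADU["glass"]
        recovered = in_focus[mask.mask].mean() - bg
        assert abs(recovered - belt_intensity) < 0.05 * belt_intensity


class TestFunctionalGenerator:
    def test_zero_cv_is_noise_free(self):
        eff = simulate.EffectParams(replicate_cv=0.0)
        ds = simulate.generate_functional_dataset(eff, 4, seed=0)
        ter0 = ds.ter.query("condition=='control' and timepoint_h==0").raw_ohm
        assert ter0.nunique() == 1

    def test_blank_included_in_raw_resistance(self):
        eff = simulate.EffectParams(replicate_cv=0.0)
        ds = simulate.generate_functional_dataset(eff, 3, seed=0, substrate="PE")
        assert (ds.ter.blank_ohm == 121.0).all()
        assert (ds.ter.raw_ohm > 121.0).all()

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError, match="replicates"):
            simulate.generate_functional_dataset(simulate.EffectParams(), 2, seed=0)

    def test_dataset_deterministic_per_seed(self):
        eff = simulate.EffectParams()
        a = simulate.generate_functional_dataset(eff, 5, seed=11)
        b = simulate.generate_functional_dataset(eff, 5, seed=11)
        assert a.ter.equals(b.ter) and a.flux.equals(b.flux)


def test_ground_truth_csv_and_sidecar_roundtrip(tmp_path, small_geometry):
    import json

    import pandas as pd

    params = simulate.ClusteringParams(mode="dispersed", linear_density_per_um=5)
    mol = simulate.place_fluorophores(small_geometry, params, seed=1, channel="CLDN5")
    simulate.save_ground_truth_csv(tmp_path / "gt.csv", mol)
    df = pd.read_csv(tmp_path / "gt.csv")
    assert len(df) == mol.n and set(df.channel) == {"CLDN5"}
    simulate.write_parameter_sidecar(tmp_path / "params.json", clustering=params)
    payload = json.loads((tmp_path / "params.json").read_text())
    assert payload["clustering"]["linear_density_per_um"] == 5
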