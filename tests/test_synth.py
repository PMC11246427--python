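"""Synthetic tissue generator: placement, activation, rendering, myotube scenes."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from micropat import (
    ActivationModel,
    LigandChannel,
    NucleiChannel,
    PackingError,
    ReporterChannel,
    make_rows,
    make_square_array,
    pearson_fidelity,
    place_cells,
    render_scene,
    simulate_activation,
    simulate_dose_ladder,
    simulate_myotube_scene,
)
from micropat.myoquant import (
    local_orientation,
    orientation_histogram,
    orientation_order_parameter,
)

from conftest import disjoint_grid_cells


class TestPlaceCells:
    def test_mean_count_matches_density(self):
        # Poisson oracle: E[N] = density * area = 100 on 1 mm²
        counts = [
            len(place_cells(100, (1000, 1000), 0, seed=s)) for s in range(30)
        ]
        se = np.sqrt(100 / 30)
        assert abs(np.mean(counts) - 100) < 3 * se

    def test_zero_density_is_empty(self):
        assert len(place_cells(0, (1000, 1000), 0, seed=1)) == 0

    def test_min_spacing_honored(self):
        cells = place_cells(300, (1000, 1000), 25, seed=2)
        pts = cells[["x_um", "y_um"]].to_numpy()
        assert len(pts) > 100
        assert pdist(pts).min() >= 25

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            place_cells(5000, (1000, 1000), 40, seed=3)

    def test_deterministic(self):
        a = place_cells(200, (500, 500), 10, seed=9)
        b = place_cells(200, (500, 500), 10, seed=9)
        assert a.equals(b)


class TestActivationModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ActivationModel(p_max=0.5, p_basal=0.6)
        with pytest.raises(ValueError):
            ActivationModel(K_ug_ml=-1)
        with pytest.raises(ValueError):
            ActivationModel(h=0)

    def test_dose_response_endpoints(self):
        m = ActivationModel(p_max=0.8, K_ug_ml=30, h=2, p_basal=0.1)
        assert m.prob(0.0) == pytest.approx(0.1)
        assert m.prob(30.0) == pytest.approx(0.45)  # midpoint between basal and max
        assert m.prob(1e9) == pytest.approx(0.8, abs=1e-6)


class TestSimulateActivation:
    def test_no_leak_no_dose_means_no_activation(self):
        cells = place_cells(200, (500, 500), 0, seed=1)
        model = ActivationModel(p_basal=0.0)
        out = simulate_activation(
            cells, {"gfp": np.zeros((50, 50))}, {"mcherry": ("gfp", model)}, 10, seed=2
        )
        assert not out["active_mcherry"].any()

    def test_saturation_activates_all_on_pattern(self):
        cells = place_cells(300, (500, 500), 0, seed=4)
        model = ActivationModel(p_max=1.0, K_ug_ml=10, h=8, p_basal=0.0)
        dose = np.full((50, 50), 1000.0)
        out = simulate_activation(
            cells, {"gfp": dose}, {"rep": ("gfp", model)}, 10, seed=5
        )
        assert out["active_rep"].all()

    def test_half_saturation_binomial_oracle(self):
        # at c = K with p_basal = 0 the active fraction is p_max / 2
        n = 10_000
        cells = place_cells(n, (1000, 1000), 0, seed=6)
        n = len(cells)
        model = ActivationModel(p_max=0.8, K_ug_ml=50, h=2, p_basal=0.0)
        out = simulate_activation(
            cells, {"gfp": np.full((100, 100), 50.0)}, {"rep": ("gfp", model)}, 10, seed=7
        )
        p = 0.4
        se = np.sqrt(p * (1 - p) / n)
        assert abs(out["active_rep"].mean() - p) < 3 * se

    def test_impaired_mode_vetoes_double_active(self):
        cells = place_cells(500, (500, 500), 0, seed=8)
        model = ActivationModel(p_max=0.9, K_ug_ml=10, h=2, p_basal=0.05,
                                both_ligand_mode="impaired")
        dose = np.full((50, 50), 200.0)
        out = simulate_activation(
            cells,
            {"gfp": dose, "mch": dose},
            {"myo": ("gfp", model), "endo": ("mch", model)},
            10,
            seed=9,
        )
        assert not (out["active_myo"] & out["active_endo"]).any()

    def test_unknown_ligand_errors(self):
        cells = place_cells(10, (100, 100), 0, seed=1)
        with pytest.raises(KeyError, match="unknown ligand"):
            simulate_activation(
                cells, {"gfp": np.zeros((10, 10))},
                {"rep": ("nope", ActivationModel())}, 10,
            )


class TestRenderScene:
    def _scene(self, **kw):
        cells = disjoint_grid_cells(4, 50, 8, 2)  # 16 cells, 200x200 µm
        cells["active_rep"] = [True, False] * 8
        channels = {
            "nuclei": NucleiChannel(),
            "rep": ReporterChannel("rep", on_intensity=200, off_intensity=10),
        }
        return cells, render_scene(cells, channels, (200, 200), 2, seed=0, **kw)

    def test_noiseless_disjoint_cells_have_exact_intensities(self):
        cells, (img, truth) = self._scene()
        rep = img["rep"]
        for _, c in cells.iterrows():
            r, col = int(c.y_um / 2), int(c.x_um / 2)
            expect = 200.0 if c.active_rep else 10.0
            assert rep[r, col] == expect

    def test_bit_identical_for_fixed_seed(self):
        _, (img1, _) = self._scene(noise_sd=5.0, psf_sigma_um=2.0)
        _, (img2, _) = self._scene(noise_sd=5.0, psf_sigma_um=2.0)
        for name in img1.channel_names:
            assert np.array_equal(img1[name], img2[name])

    def test_ligand_channel_requires_matching_geometry(self):
        cells = disjoint_grid_cells(2, 50, 8, 2)
        cells["active_rep"] = True
        with pytest.raises(ValueError, match="dose map shape"):
            render_scene(
                cells, {"lig": LigandChannel(np.zeros((3, 3)))}, (100, 100), 2
            )

    def test_fidelity_strictly_decreases_with_psf_sigma(self):
        # optical-degradation regime: blur at or above one cell diameter (the
        # sub-cellular range is texture-dominated, where smoothing the
        # monolayer's cellular graininess can raise the correlation)
        pattern = make_square_array(200, 200, (1200, 1200), 4)
        cells = place_cells(1500, (1200, 1200), 15, radius_um=15, seed=11)
        model = ActivationModel(p_max=1.0, K_ug_ml=10, h=8, p_basal=0.0)
        cells = simulate_activation(
            cells, {"gfp": pattern.to_dose(100)}, {"rep": ("gfp", model)}, 4, seed=12
        )
        rs = []
        for sigma in (30.0, 60.0, 120.0):
            img, _ = render_scene(
                cells,
                {"rep": ReporterChannel("rep")},
                (1200, 1200), 4, psf_sigma_um=sigma, seed=13,
            )
            rs.append(pearson_fidelity(pattern, img["rep"]))
        assert rs[0] > rs[1] > rs[2]

    def test_fidelity_strictly_decreases_with_basal_leak(self):
        pattern = make_square_array(200, 200, (1200, 1200), 4)
        rs = []
        for p_basal in (0.0, 0.2, 0.4):
            model = ActivationModel(p_max=1.0, K_ug_ml=10, h=8, p_basal=p_basal)
            cells = place_cells(1500, (1200, 1200), 15, radius_um=15, seed=11)
            cells = simulate_activation(
                cells, {"gfp": pattern.to_dose(100)}, {"rep": ("gfp", model)}, 4, seed=12
            )
            img, _ = render_scene(
                cells, {"rep": ReporterChannel("rep")},
                (1200, 1200), 4, psf_sigma_um=30.0, seed=13,
            )
            rs.append(pearson_fidelity(pattern, img["rep"]))
        assert rs[0] > rs[1] > rs[2]


class TestDoseLadder:
    def test_counts_are_binomial_at_model_probability(self):
        model = ActivationModel(p_max=0.8, K_ug_ml=30, h=2, p_basal=0.0)
        df = simulate_dose_ladder([0, 10, 50, 100, 200], model, 5000, seed=1)
        p = model.prob(np.array([0, 10, 50, 100, 200], dtype=float))
        se = np.sqrt(p * (1 - p) / 5000)
        assert np.all(np.abs(df["percent_activation"].to_numpy() - p) <= 3 * se + 1e-12)


class TestMyotubeScene:
    def test_zero_fusion_gives_empty_actinin_and_zero_index(self):
        pattern = make_rows(200, 200, (800, 800), 4)
        img, truth = simulate_myotube_scene(pattern, 0.0, 2.0, off_pattern_fusion_prob=0.0,
                                            seed=1, psf_sigma_um=0)
        assert img["actinin"].max() == 0
        assert truth.params["true_myogenic_index_on"] == 0.0
        assert truth.params["n_myotubes"] == 0

    def test_perfect_alignment_limit_has_oop_near_one(self):
        pattern = make_rows(300, 100, (1200, 1200), 4)
        img, truth = simulate_myotube_scene(
            pattern, 0.9, np.inf, nuclei_density_per_mm2=600, seed=2, psf_sigma_um=0
        )
        assert all(a == 0.0 for a in truth.params["myotube_angles_deg"])
        field = local_orientation(img["actinin"], tensor_sigma=3)
        mask = img["actinin"] > 100
        hist = orientation_histogram(field, mask=mask)
        assert orientation_order_parameter(hist) > 0.9

    def test_truth_indices_reflect_fusion_probabilities(self):
        pattern = make_rows(400, 400, (1600, 1600), 4)
        img, truth = simulate_myotube_scene(
            pattern, 0.6, 4.0, off_pattern_fusion_prob=0.05,
            nuclei_density_per_mm2=500, seed=3, psf_sigma_um=0,
        )
        cells = truth.cells
        n_on = int(cells.on_pattern.sum())
        # grouping demotes singleton fusions, so realized truth sits below the
        # nominal rate but must stay within a few binomial SE of it
        se = np.sqrt(0.6 * 0.4 / n_on)
        assert truth.params["true_myogenic_index_on"] > 0.4
        assert truth.params["true_myogenic_index_on"] < 0.6 + 3 * se
        assert truth.params["true_myogenic_index_off"] < 0.15
        # every fused nucleus belongs to a myotube of >= 2 members
        fused = cells[cells.fused]
        assert (fused.myotube_id > 0).all()
        assert fused.groupby("myotube_id").size().min() >= 2

    def test_deterministic(self):
        pattern = make_rows(200, 200, (600, 600), 4)
        img1, t1 = simulate_myotube_scene(pattern, 0.5, 2.0, seed=5)
        img2, t2 = simulate_myotube_scene(pattern, 0.5, 2.0, seed=5)
        assert np.array_equal(img1["actinin"], img2["actinin"])
        assert t1.cells.equals(t2.cells)

    def test_invalid_fusion_prob_errors(self):
        pattern = make_rows(200, 200, (600, 600), 4)
        with pytest.raises(ValueError, match="fusion prob"):
            simulate_myotube_scene(pattern, 1.5, 2.0, seed=1)
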