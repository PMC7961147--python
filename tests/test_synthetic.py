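"""Generators: archetype populations, mask rendering, YAP coupling, mechanics curves."""

import math

import numpy as np
import pandas as pd
import pytest

from morphomech import mechanics, morphometry, synthetic


class TestGeneratePopulation:
    def test_counts_ranges_and_cluster_structure(self, default_population):
        pop = default_population
        assert len(pop) == 4 * 261
        for arch in synthetic.DEFAULT_ARCHETYPES:
            sub = pop[pop["group"] == arch.name]
            assert len(sub) == 261
            assert sub["cell_area_um2"].between(*arch.area_range).all()
            assert sub["cell_aspect"].between(*arch.aspect_ratio_range).all()
            assert sub["cell_solidity"].between(*arch.solidity_range).all()
            assert sub["cell_angle_deg"].abs().le(min(arch.angle_spread, 90)).all()
        # archetypes separate strongly in standardized descriptor space
        assert synthetic.archetype_separation(pop) >= 3.0

    def test_same_seed_gives_identical_tables(self):
        a = synthetic.generate_population(n_per_archetype=20, seed=7)
        b = synthetic.generate_population(n_per_archetype=20, seed=7)
        assert a.to_csv() == b.to_csv()

    def test_zero_width_ranges_give_identical_records(self):
        arch = synthetic.ArchetypeSpec(
            "fixed", (2000.0, 2000.0), (2.0, 2.0), 0.0, (0.8, 0.8), 0.2, 0
        )
        pop = synthetic.generate_population([arch], n_per_archetype=5, seed=0)
        feats = pop[synthetic.FEATURE_COLUMNS]
        assert (feats.nunique() == 1).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_population([], n_per_archetype=5)
        with pytest.raises(ValueError):
            synthetic.ArchetypeSpec("bad", (100.0, 50.0), (1.0, 2.0), 10.0, (0.5, 0.9), 0.2)
        with pytest.raises(ValueError):
            synthetic.ArchetypeSpec("bad", (100.0, 200.0), (0.5, 2.0), 10.0, (0.5, 0.9), 0.2)
        with pytest.raises(ValueError):
            synthetic.generate_population(n_per_archetype=0)


class TestRenderCellMask:
    DISK = {
        "cell_area_um2": 7000.0, "cell_aspect": 1.0, "cell_angle_deg": 0.0,
        "cell_solidity": 0.95, "nuc_area_um2": 1400.0, "nuc_aspect": 1.0,
        "nuc_angle_deg": 0.0, "lobes": 0,
    }

    def test_disk_is_circular(self):
        cell, nuc = synthetic.render_cell_mask(self.DISK, canvas=(256, 256))
        d = morphometry.extract_shape_descriptors(cell, nuc)
        assert d["cell_circularity"] >= 0.95
        assert d["cell_aspect"] == pytest.approx(1.0, abs=0.03)

    def test_rotated_ellipse_angle_and_area(self):
        rec = dict(self.DISK, cell_aspect=3.0, cell_angle_deg=30.0, nuc_aspect=2.0,
                   nuc_angle_deg=30.0)
        cell, nuc = synthetic.render_cell_mask(rec, canvas=(256, 256))
        d = morphometry.extract_shape_descriptors(cell, nuc)
        # oracle: second-moment orientation of the ideal ellipse is exactly 30 deg
        assert d["cell_angle_deg"] == pytest.approx(30.0, abs=2.0)
        assert d["cell_area_um2"] == pytest.approx(7000.0, rel=0.03)

    def test_nucleus_area_fraction_by_pixel_counting(self):
        cell, nuc = synthetic.render_cell_mask(self.DISK, canvas=(256, 256))
        ratio = nuc.sum() / cell.sum()
        assert 0.17 <= ratio <= 0.23  # nucleus_scale = 1400/7000 = 0.2
        assert np.all(cell[nuc > 0] == 1)  # strictly inside

    def test_shape_exceeding_canvas_errors(self):
        with pytest.raises(ValueError, match="canvas"):
            synthetic.render_cell_mask(self.DISK, canvas=(64, 64))


class TestAssignYap:
    def test_zero_noise_is_exactly_the_deterministic_transform(self, default_population):
        coupling = synthetic.CouplingSpec(noise_sd=0.0)
        table, _ = synthetic.assign_yap(default_population, coupling, seed=0)
        expected = np.maximum(
            synthetic.deterministic_yap(default_population, coupling), synthetic.YAP_FLOOR
        )
        np.testing.assert_allclose(table["yap_ratio"].to_numpy(), expected)

    def test_invalid_cue_rejected(self, default_population):
        with pytest.raises(ValueError, match="cue"):
            synthetic.assign_yap(default_population, cue=2)

    def test_cue_shift_moves_group_means(self):
        # oracle: group-mean difference over 10,000 draws per group; the
        # baseline is raised so the positivity floor never truncates the
        # shifted group and the additive shift is recovered exactly
        pop = synthetic.generate_population(n_per_archetype=2500, seed=3)
        coupling = synthetic.CouplingSpec(baseline=2.5)
        ctrl, _ = synthetic.assign_yap(pop, coupling, cue=0, seed=4)
        inhib, _ = synthetic.assign_yap(pop, coupling, cue=-1, seed=5)
        diff = ctrl["yap_ratio"].mean() - inhib["yap_ratio"].mean()
        sem = coupling.noise_sd / math.sqrt(len(pop))
        assert abs(diff - 0.60) <= 3 * sem * math.sqrt(2) + 1e-3

    def test_decoupled_offset_matches_invasive_calibration(self):
        pop = synthetic.generate_population(n_per_archetype=2000, seed=6)
        coupling = synthetic.CouplingSpec(noise_sd=0.0)
        base, _ = synthetic.assign_yap(pop, coupling, seed=7)
        dec, _ = synthetic.assign_yap(pop, coupling, decoupled=True, seed=7)
        offset = dec["yap_ratio"] - base["yap_ratio"]
        # clipping at the floor can only touch the far-left tail
        assert offset.mean() == pytest.approx(1.52, abs=0.05)
        assert offset.std() == pytest.approx(0.88, abs=0.05)

    def test_explainable_variance_reported_matches_empirical(self):
        pop = synthetic.generate_population(n_per_archetype=500, seed=8)
        coupling = synthetic.CouplingSpec()
        table, info = synthetic.assign_yap(pop, coupling, seed=9)
        det = synthetic.deterministic_yap(pop, coupling)
        resid = table["yap_ratio"].to_numpy() - det
        empirical = 1.0 - np.var(resid) / np.var(table["yap_ratio"])
        assert empirical == pytest.approx(info["explainable_variance"], abs=0.05)

    def test_noise_calibration_hits_target(self, default_population):
        coupling = synthetic.CouplingSpec()
        sd = synthetic.noise_sd_for_explainable_variance(default_population, coupling, 0.65)
        _, info = synthetic.assign_yap(
            default_population, synthetic.CouplingSpec(noise_sd=sd), seed=0
        )
        assert info["explainable_variance"] == pytest.approx(0.65, abs=1e-9)


class TestStressStrainGeneration:
    PARAMS = mechanics.FiberModelParams(
        A=0.1, B=40.0, k_matrix=2.0, sigma0=35.0, sigma_inf=10.0, alpha=20.0
    )

    def test_zero_noise_equals_forward_model(self):
        df = synthetic.generate_stress_strain(self.PARAMS, 0.09, 20, noise_cv=0.0)
        ref = mechanics.predict_stress(df["strain"].to_numpy(), self.PARAMS)
        np.testing.assert_allclose(df["stress_mpa"].to_numpy(), ref.stress_mpa)

    def test_matrix_only_limit_is_linear(self):
        p = mechanics.FiberModelParams(0.0, 40.0, 2.0, 35.0, 10.0, 20.0)
        df = synthetic.generate_stress_strain(p, 0.1, 11, noise_cv=0.0)
        np.testing.assert_allclose(df["stress_mpa"], 2.0 * df["strain"])

    def test_invalid_strain_max(self):
        with pytest.raises(ValueError):
            synthetic.generate_stress_strain(self.PARAMS, -0.1, 10)

    def test_noise_cv_scale(self):
        df = synthetic.generate_stress_strain(self.PARAMS, 0.09, 500, noise_cv=0.05, seed=1)
        clean = synthetic.generate_stress_strain(self.PARAMS, 0.09, 500, noise_cv=0.0)
        rel = (df["stress_mpa"] / clean["stress_mpa"] - 1).iloc[1:]
        assert rel.std() == pytest.approx(0.05, abs=0.01)


class TestInvasivenessDataset:
    def test_labels_and_decoupling_shift(self):
        with_dec = synthetic.generate_invasiveness_dataset(200, seed=0, decouple=True)
        no_dec = synthetic.generate_invasiveness_dataset(200, seed=0, decouple=False)
        assert with_dec["invasive"].sum() == 200
        inv_shift = (
            with_dec.loc[with_dec["invasive"], "yap_ratio"].mean()
            - no_dec.loc[no_dec["invasive"], "yap_ratio"].mean()
        )
        assert inv_shift == pytest.approx(1.52, abs=0.25)


def test_table_round_trip(tmp_path, coupled_table):
    table, _ = coupled_table
    path = tmp_path / "table.csv"
    synthetic.write_table(table, path)
    back = synthetic.read_table(path)
    assert list(back.columns) == synthetic.TABLE_COLUMNS
    np.testing.assert_allclose(
        back["yap_ratio"].to_numpy(), table["yap_ratio"].to_numpy()
    )
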