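"""Generator contracts: validation, coupling calibration, determinism, rendering."""

import numpy as np
import pandas as pd
import pytest

import morphoclone as mc
from morphoclone.synthetic import _BASE, assign_potencies


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs,field", [
        ({"n_clones": 0}, "n_clones"),
        ({"potency_range": (2, 5)}, "potency_range"),
        ({"cells_per_well_range": (0, 10)}, "cells_per_well_range"),
        ({"noise_sd": -1.0}, "noise_sd"),
        ({"growth_potency_r2_target": 1.5}, "growth_potency_r2_target"),
        ({"time_points": (5,)}, "time_points"),
        ({"n_fovs": 0}, "n_fovs"),
        ({"coupling": {("Nope", "SD", 6): 1.0}}, "descriptor"),
        ({"coupling": {("Length", "median", 6): 1.0}}, "mean|SD"),
        ({"coupling": {("Length", "SD", 7): 1.0}}, "time"),
        ({"coupling": {("Length", "SD", 6): float("nan")}}, "finite"),
    ])
    def test_invalid_spec_names_field(self, kwargs, field):
        with pytest.raises(mc.SpecValidationError, match=field):
            mc.SyntheticCohortSpec(**kwargs)


class TestPotencyAssignment:
    def test_round_robin_covers_range(self):
        rng = np.random.default_rng(0)
        pots = assign_potencies(15, (7, 13), rng)
        assert set(pots) == set(range(7, 14))
        # round-robin: counts differ by at most one
        counts = np.bincount(pots)[7:14]
        assert counts.max() - counts.min() <= 1

    def test_at_least_two_distinct_when_possible(self):
        rng = np.random.default_rng(1)
        assert len(set(assign_potencies(2, (7, 13), rng))) == 2


class TestCohortStructure:
    def test_default_study_conditions(self, small_cohort, small_spec):
        assert len(small_cohort) == 15
        pots = {c.potency for c in small_cohort}
        assert pots <= set(range(7, 14))
        assert len(pots) >= 2

    def test_counts_non_decreasing_and_growth_rate(self, small_cohort):
        for c in small_cohort:
            times = sorted(c.counts)
            counts = [c.counts[t] for t in times]
            assert all(b >= a for a, b in zip(counts, counts[1:]))
            assert c.growth_rate == pytest.approx(
                c.counts[times[-1]] / c.counts[times[0]])

    def test_cell_record_invariants(self, small_cells):
        assert (small_cells["Area"] > 0).all()
        assert (small_cells["Breadth"] <= small_cells["Length"] + 1e-9).all()
        assert ((small_cells["Roundness"] > 0)
                & (small_cells["Roundness"] <= 1.0 + 1e-9)).all()
        assert small_cells["Solidity"].between(0, 1).all()
        assert small_cells["Energy"].between(0, 1).all()
        assert small_cells["Correlation"].between(-1, 1).all()

    def test_determinism_bit_identical(self):
        spec = dict(n_clones=3, seed=11, cells_per_well_range=(300, 600),
                    n_fovs=8)
        a = mc.generate_cohort(mc.SyntheticCohortSpec(**spec))
        b = mc.generate_cohort(mc.SyntheticCohortSpec(**spec))
        for ca, cb in zip(a, b):
            pd.testing.assert_frame_equal(ca.cells, cb.cells)
            assert ca.potency == cb.potency


@pytest.fixture(scope="module")
def noiseless():
    spec = mc.SyntheticCohortSpec(
        n_clones=7, seed=3, noise_sd=0.0,
        cells_per_well_range=(300, 1000), n_fovs=8)
    return mc.generate_cohort(spec), spec


class TestCoupling:
    def test_noiseless_coupled_stats_exactly_affine(self, noiseless):
        clones, spec = noiseless
        for clone in clones:
            s = mc.summarize_population(clone.cells_at(6.0))
            for (desc, stat, t), coef in dict(spec.coupling).items():
                if t != 6:
                    continue
                base = _BASE[desc][stat]
                expected = base + coef * (clone.potency - 10)
                assert s[f"{desc}_{stat}"] == pytest.approx(expected, abs=1e-8)

    def test_monotone_in_coupling_sign(self, noiseless):
        clones, spec = noiseless
        by_pot = sorted(clones, key=lambda c: c.potency)
        stats = [mc.summarize_population(c.cells_at(6.0)) for c in by_pot]
        for (desc, stat, t), coef in dict(spec.coupling).items():
            if t != 6:
                continue
            vals = [s[f"{desc}_{stat}"] for s in stats]
            diffs = np.sign(np.diff(vals))
            assert (diffs == np.sign(coef)).all()

    def test_texture_sd_up_shape_sd_down_with_potency(self, noiseless):
        """High-potency clones: wider texture spread, tighter shape spread."""
        clones, _ = noiseless
        lo = min(clones, key=lambda c: c.potency)
        hi = max(clones, key=lambda c: c.potency)
        s_lo = mc.summarize_population(lo.cells_at(6.0))
        s_hi = mc.summarize_population(hi.cells_at(6.0))
        assert s_hi["Correlation_SD"] > s_lo["Correlation_SD"]
        assert s_hi["Energy_SD"] > s_lo["Energy_SD"]
        assert s_hi["Length_SD"] < s_lo["Length_SD"]
        assert s_hi["Compactness_SD"] < s_lo["Compactness_SD"]

    def test_growth_rate_r2_calibration(self):
        # the count ceiling must not clip growth, or realized fold-changes
        # decouple from the drawn growth rates
        spec = mc.SyntheticCohortSpec(n_clones=200, seed=7,
                                      cells_per_well_range=(300, 3000),
                                      n_fovs=4)
        clones = mc.generate_cohort(spec)
        labels = mc.cohort_labels(clones)
        r2 = mc.scalar_r2(labels["growth_rate"], labels["potency"])
        assert r2 == pytest.approx(spec.growth_potency_r2_target, abs=0.05)

    def test_proliferating_prevalence_increases_with_potency(self, small_cells,
                                                             small_labels):
        frac = small_cells.groupby("clone_id")["proliferating"].mean()
        merged = small_labels.set_index("clone_id").join(frac)
        r = np.corrcoef(merged["potency"], merged["proliferating"])[0, 1]
        assert r > 0.5


class TestRendering:
    def test_empty_fov_blank_frame(self, render_clone):
        # pick a FOV index beyond those the clone populates
        empty_fov = int(render_clone.cells["fov"].max()) + 1
        frame, mask = mc.render_frame(render_clone, 6.0, empty_fov)
        assert mask.n_labels == 0
        assert frame.intensity.std() < 5  # background only

    def test_fifty_nonoverlapping_cells_fifty_labels(self):
        spec = mc.SyntheticCohortSpec(
            n_clones=1, seed=2, cells_per_well_range=(50, 50),
            n_fovs=1, time_points=(6, 12))
        clone = mc.generate_cohort(spec)[0]
        assert len(clone.cells_at(6.0)) == 50
        big = mc.RenderSpec(image_size=(2000, 2000))
        frame, mask = mc.render_frame(clone, 6.0, 0, big)
        border = set(mask.source["border_labels"])
        present = set(np.unique(mask.labels)) - {0}
        # every generated cell is a mask label unless fully clipped away
        assert present | border == set(range(1, 51))

    def test_render_determinism(self, render_clone):
        f1, m1 = mc.render_frame(render_clone, 6.0, 1)
        f2, m2 = mc.render_frame(render_clone, 6.0, 1)
        np.testing.assert_array_equal(f1.intensity, f2.intensity)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_ground_truth_connected_components(self, rendered_pair):
        from skimage import measure
        _, gt = rendered_pair
        for lab in range(1, gt.n_labels + 1):
            region = gt.labels == lab
            if region.any():
                assert measure.label(region, connectivity=2).max() == 1

    def test_rendered_area_matches_table_within_10pct(self, render_clone,
                                                      rendered_pair):
        _, gt = rendered_pair
        table = render_clone.cells_at(6.0)
        table = table[table["fov"] == 0].set_index("cell_id")
        areas = gt.areas_px()
        border = set(gt.source["border_labels"])
        checked = 0
        for lab, cid in enumerate(gt.source["cell_ids"], start=1):
            if lab in border:
                continue
            expected = float(table.loc[cid, "area_px"])
            assert areas[lab - 1] == pytest.approx(expected, rel=0.10)
            checked += 1
        assert checked >= 5

    def test_round_cells_rendered_bright(self, render_clone):
        table = render_clone.cells_at(6.0)
        fovs_with_round = table.loc[table["proliferating"], "fov"].unique()
        if len(fovs_with_round) == 0:
            pytest.skip("no proliferating cell in this draw")
        fov = int(fovs_with_round[0])
        frame, gt = mc.render_frame(render_clone, 6.0, fov)
        sub = table[table["fov"] == fov].reset_index(drop=True)
        bg = np.median(frame.intensity[gt.labels == 0])
        for lab, cid in enumerate(gt.source["cell_ids"], start=1):
            row = sub.loc[sub["cell_id"] == cid].iloc[0]
            pix = frame.intensity[gt.labels == lab]
            if row["proliferating"] and pix.size:
                assert pix.mean() > bg + 50  # visually white and round

    def test_density_error_when_overcrowded(self):
        spec = mc.SyntheticCohortSpec(
            n_clones=1, seed=4, cells_per_well_range=(400, 400),
            n_fovs=1, time_points=(6, 12))
        clone = mc.generate_cohort(spec)[0]
        tiny = mc.RenderSpec(image_size=(256, 256), max_place_tries=20)
        with pytest.raises(mc.DensityError):
            mc.render_frame(clone, 6.0, 0, tiny)
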