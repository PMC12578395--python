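"""Determinism, planted structure, and contracts of the tissue generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import renimap.synthetic as rs
from renimap.errors import ConfigError, PlacementError
from renimap.stack import background_correct
from renimap.segmentation import dilate_voronoi, extract_mfi


def small_spec(**over):
    defaults = dict(image_shape=(400, 400), pixel_size=1.0, niche_specs=(),
                    n_glomeruli=1, n_tubules=2)
    defaults.update(over)
    return rs.default_spec(**defaults)


class TestGenerateBiopsy:
    def test_fixed_seed_bit_identical_tables(self):
        spec = small_spec()
        _, _, _, a, _ = rs.generate_biopsy(spec, 1)
        _, _, _, b, _ = rs.generate_biopsy(spec, 1)
        assert a.to_csv() == b.to_csv()

    def test_zero_noise_mfi_equals_class_template(self):
        tmpl = rs.templates_from_tree(classes=["CD4 T cell", "B cell"], noise_sd=0.0)
        spec = small_spec(class_templates=tmpl,
                          abundances={"CD4 T cell": 200, "B cell": 100})
        _, _, _, cells, _ = rs.generate_biopsy(spec, 2)
        for cls, grp in cells.groupby("true_class"):
            for m, (mean, _) in tmpl[cls].items():
                assert (grp[f"mfi_{m}"] == mean).all()

    def test_class_counts_follow_poisson_tolerance(self):
        # 100 cells/mm^2 on a 1 mm^2 field: within +-30 (3 sd) in >= 95% of seeds
        spec = small_spec(image_shape=(1000, 1000),
                          abundances={"CD4 T cell": 100.0},
                          n_glomeruli=0, n_tubules=0)
        inside = 0
        n_seeds = 15
        for seed in range(n_seeds):
            _, _, _, cells, _ = rs.generate_biopsy(spec, seed)
            inside += 70 <= len(cells) <= 130
        assert inside >= n_seeds - 1

    def test_no_centroid_inside_structures(self):
        spec = small_spec(n_glomeruli=2, n_tubules=3)
        _, tub, glom, cells, _ = rs.generate_biopsy(spec, 3)
        ys = cells["y"].to_numpy(int)
        xs = cells["x"].to_numpy(int)
        assert (tub[ys, xs] == 0).all()
        assert (glom[ys, xs] == 0).all()

    def test_cells_counted_once_and_in_bounds(self):
        spec = small_spec()
        nuclei, _, _, cells, truth = rs.generate_biopsy(spec, 4)
        assert cells["cell_id"].is_unique
        assert set(truth.cells["cell_id"]) == set(cells["cell_id"])
        assert cells["x"].between(0, 399).all()
        assert cells["y"].between(0, 399).all()
        assert cells["true_class"].value_counts().sum() == len(cells)

    def test_compartment_truth_uses_pipeline_priority(self):
        from renimap.compartments import (COMPARTMENTS, assign_compartment,
                                          build_compartment_masks)

        spec = small_spec(n_glomeruli=2, n_tubules=3,
                          periglomerular_enrichment=3.0)
        _, tub, glom, cells, _ = rs.generate_biopsy(spec, 6)
        comps = build_compartment_masks(tub, glom, spec.ring_width_um,
                                        spec.pixel_size)
        redo = assign_compartment(cells.drop(columns=["compartment"]), comps)
        assert (redo["compartment"] == cells["compartment"]).all()
        assert set(cells["compartment"]) <= set(COMPARTMENTS)

    def test_too_small_field_names_failing_structure(self):
        with pytest.raises(PlacementError) as err:
            rs.generate_biopsy(small_spec(image_shape=(30, 30)), 0)
        assert err.value.structure == "glomerulus"

    def test_invalid_niche_composition_rejected(self):
        with pytest.raises(ConfigError):
            rs.NicheSpec({"A": 0.6, "B": 0.5}).validate()


class TestSampleCohort:
    def test_zero_noise_single_factor_is_comonotone(self):
        model = rs.CohortModel(base={"a": 10.0, "b": 100.0},
                               loadings={"a": (1.0,), "b": (1.0,)},
                               noise_sd=0.0)
        spec = small_spec(cohort_models={"X": model})
        samples = rs.sample_cohort(spec, 10, "X", seed=0)
        mat = pd.DataFrame({s.biopsy_id: s.densities for s in samples}).T
        rho = sps.spearmanr(mat["a"], mat["b"]).statistic
        assert rho == pytest.approx(1.0)

    def test_orthogonal_blocks_within_exceeds_between(self):
        classes = list("abcdef")
        model = rs.CohortModel(
            base={c: 50.0 for c in classes},
            loadings={c: (1.0, 0.0) if c in "abc" else (0.0, 1.0)
                      for c in classes},
            noise_sd=0.3)
        spec = small_spec(cohort_models={"X": model})
        samples = rs.sample_cohort(spec, 25, "X", seed=1)
        mat = pd.DataFrame({s.biopsy_id: s.densities for s in samples}).T
        within, between = [], []
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                rho = sps.spearmanr(mat[a], mat[b]).statistic
                (within if (a in "abc") == (b in "abc") else between).append(rho)
        assert np.mean(within) > np.mean(between) + 0.3

    def test_zero_loadings_give_near_independent_abundances(self):
        classes = list("abcd")
        model = rs.CohortModel(base={c: 50.0 for c in classes},
                               loadings={c: (0.0,) for c in classes},
                               noise_sd=0.3)
        spec = small_spec(cohort_models={"X": model})
        samples = rs.sample_cohort(spec, 25, "X", seed=2)
        mat = pd.DataFrame({s.biopsy_id: s.densities for s in samples}).T
        rhos = [abs(sps.spearmanr(mat[a], mat[b]).statistic)
                for i, a in enumerate(classes) for b in classes[i + 1:]]
        assert np.mean(rhos) <= 0.3

    def test_fewer_than_three_biopsies_rejected(self):
        with pytest.raises(ConfigError):
            rs.sample_cohort(small_spec(), 2, "LuN", seed=0)


class TestRenderStack:
    def test_blank_correction_recovers_cell_values_exactly(self):
        tmpl = rs.templates_from_tree(classes=["CD4 T cell"], noise_sd=0.0)
        spec = small_spec(image_shape=(120, 120), class_templates=tmpl,
                          abundances={"CD4 T cell": 400.0},
                          n_glomeruli=0, n_tubules=0, body_dilation_px=2)
        nuclei, _, _, cells, _ = rs.generate_biopsy(spec, 7)
        assert len(cells) > 0
        stack = rs.render_stack(cells, spec, seed=8)
        corrected = background_correct(stack)
        bodies = dilate_voronoi(nuclei, spec.body_dilation_px)
        tab = extract_mfi(corrected, bodies).set_index("cell_id")
        sd = float(np.std(stack.blank_channels["blank"]))
        expect = cells.set_index("cell_id")["mfi_CD45"] / sd
        assert np.allclose(tab["mfi_CD45"], expect.loc[tab.index])

    def test_no_cells_channels_equal_background(self):
        spec = small_spec(image_shape=(50, 50), abundances={},
                          n_glomeruli=0, n_tubules=0)
        cells = pd.DataFrame({"cell_id": [], "x": [], "y": [], "mfi_CD45": []})
        stack = rs.render_stack(cells, spec, seed=0)
        assert np.array_equal(stack.channels["CD45"],
                              stack.blank_channels["blank"])


class TestPlaceTranscripts:
    def _layout(self):
        return pd.DataFrame({"niche_id": range(100), "niche_type": 0,
                             "x_um": np.linspace(50, 950, 100),
                             "y_um": 50.0, "radius_um": 20.0})

    def test_zero_rate_gene_absent(self):
        spec = small_spec(transcript_rates={0: {"CD14": 0.0, "CD3E": 5.0}})
        tr = rs.place_transcripts(self._layout(), spec, seed=0)
        assert (tr["gene"] != "CD14").all()

    def test_total_count_within_poisson_tolerance(self):
        # rate 20 per niche, 100 niches: within 3*sqrt(2000) of 2000
        spec = small_spec(transcript_rates={0: {"CD14": 20.0}})
        tr = rs.place_transcripts(self._layout(), spec, seed=1)
        assert abs(len(tr) - 2000) <= 3 * np.sqrt(2000)

    def test_coordinates_within_niche_footprint(self):
        spec = small_spec(transcript_rates={0: {"CD14": 20.0}})
        layout = self._layout()
        tr = rs.place_transcripts(layout, spec, seed=2)
        merged = tr.merge(layout, on="niche_id", suffixes=("", "_layout"))
        d = np.hypot(merged["x"] - merged["x_um"], merged["y"] - merged["y_um"])
        assert (d <= 20.0 + 1e-9).all()

    def test_same_seed_identical_table(self):
        spec = small_spec(transcript_rates={0: {"CD14": 5.0, "CD3E": 2.0}})
        a = rs.place_transcripts(self._layout(), spec, seed=3)
        b = rs.place_transcripts(self._layout(), spec, seed=3)
        assert a.equals(b)

    def test_niche_type_without_rates_rejected(self):
        spec = small_spec(transcript_rates={})
        with pytest.raises(ConfigError):
            rs.place_transcripts(self._layout(), spec, seed=0)


def test_templates_require_tree_leaves():
    with pytest.raises(ConfigError):
        rs.templates_from_tree(classes=["not a class"])
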