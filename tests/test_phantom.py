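import numpy as np
import pytest

from lesioneval import (
    ErrorInjectionConfig,
    FPSpec,
    build_compartment_map,
    extract_components,
    generate_cohort,
    inject_errors,
    sample_gt_cohort,
)
from lesioneval.phantom import (
    Compartment,
    PhantomConfigError,
    PhantomSpec,
    default_error_config,
    default_phantom_spec,
    sample_gt_case,
    verify_conservation,
)


def _spec_with(compartments, counts, **kwargs):
    defaults = dict(grid_shape=(20, 20, 20), voxel_spacing=(4.0, 4.0, 4.0),
                    radius_range_mm=(4.0, 8.0))
    defaults.update(kwargs)
    return PhantomSpec(
        compartments=compartments, lesions_per_compartment=counts, **defaults
    ).validate()


class TestCompartmentMap:
    def test_single_compartment_fills_grid(self):
        spec = _spec_with(
            [Compartment(1, "T", "right_lung_primary", ((0, 20), (0, 20), (0, 20)))],
            {1: 0},
        )
        cmap = build_compartment_map(spec)
        assert (cmap.voxels == 1).all()

    def test_zero_compartments_all_background(self):
        spec = _spec_with([], {})
        assert (build_compartment_map(spec).voxels == 0).all()

    def test_box_voxel_counts_are_analytic(self):
        boxes = [((0, 5), (0, 6), (0, 7)), ((10, 18), (10, 15), (10, 13))]
        spec = _spec_with(
            [
                Compartment(1, "T", "right_lung_primary", boxes[0]),
                Compartment(2, "M", "liver", boxes[1]),
            ],
            {},
        )
        cmap = build_compartment_map(spec)
        for cid, box in zip((1, 2), boxes):
            expected = np.prod([hi - lo for lo, hi in box])
            assert (cmap.voxels == cid).sum() == expected

    def test_overlapping_boxes_rejected(self):
        with pytest.raises(PhantomConfigError, match="overlap"):
            _spec_with(
                [
                    Compartment(1, "T", "a", ((0, 10), (0, 10), (0, 10))),
                    Compartment(2, "N", "b", ((5, 15), (5, 15), (5, 15))),
                ],
                {},
            )

    def test_radius_must_fit_smallest_box(self):
        with pytest.raises(PhantomConfigError, match="radius"):
            _spec_with(
                [Compartment(1, "T", "a", ((0, 3), (0, 20), (0, 20)))],
                {1: 1},
                radius_range_mm=(4.0, 12.0),
            )


class TestGtSampling:
    def test_same_seed_is_bit_identical(self, spec):
        a = sample_gt_cohort(spec, 3, seed=42)
        b = sample_gt_cohort(spec, 3, seed=42)
        for ca, cb in zip(a, b):
            assert ca.gt_mask.voxels.tobytes() == cb.gt_mask.voxels.tobytes()
            assert ca.lesion_table.equals(cb.lesion_table)

    def test_zero_counts_give_empty_masks(self, tiny_spec):
        tiny_spec.lesions_per_compartment = {1: 0, 2: 0, 3: 0}
        cases = sample_gt_cohort(tiny_spec, 2, seed=0)
        assert all((c.gt_mask.voxels == 0).all() for c in cases)

    def test_fixed_count_yields_exact_component_total(self):
        spec = _spec_with(
            [Compartment(1, "T", "right_lung_primary", ((0, 20), (0, 20), (0, 20)))],
            {1: 3},
            radius_range_mm=(4.0, 6.0),
        )
        cases = sample_gt_cohort(spec, 20, seed=5)
        total = sum(len(extract_components(c.gt_mask)) for c in cases)
        assert total == 60
        # lesion ids are instance labels: one component per instance
        for c in cases:
            assert sorted(np.unique(c.gt_mask.voxels))[1:] == [1, 2, 3]

    def test_lesion_table_matches_mask(self, tiny_spec):
        case = sample_gt_case(tiny_spec, np.random.default_rng(0), "P0")
        ids = set(np.unique(case.gt_mask.voxels)) - {0}
        assert set(case.lesion_table["lesion_id"]) == ids


class TestErrorInjection:
    def test_zero_error_is_identity(self, tiny_spec):
        case = sample_gt_case(tiny_spec, np.random.default_rng(1), "P0")
        pred, log, sidecar = inject_errors(case, ErrorInjectionConfig(), seed=1)
        assert np.array_equal(pred.voxels > 0, case.gt_mask.voxels > 0)
        assert all(e["op"] == "keep" for e in log)
        assert len(sidecar) == 0

    def test_full_fn_rate_empties_prediction(self, tiny_spec):
        case = sample_gt_case(tiny_spec, np.random.default_rng(2), "P0")
        pred, log, _ = inject_errors(case, ErrorInjectionConfig(fn_rate=1.0), seed=2)
        assert (pred.voxels == 0).all()
        assert all(e["op"] == "delete_fn" for e in log)

    def test_erosion_annihilation_logged_as_implicit_deletion(self):
        spec = _spec_with(
            [Compartment(1, "T", "right_lung_primary", ((0, 20), (0, 20), (0, 20)))],
            {1: 1},
            radius_range_mm=(4.0, 4.0),  # 7-voxel cross at 4 mm spacing
        )
        case = sample_gt_case(spec, np.random.default_rng(3), "P0")
        pred, log, _ = inject_errors(
            case, ErrorInjectionConfig(erode_voxels=2), seed=3
        )
        assert (pred.voxels == 0).all()
        assert [e["op"] for e in log] == ["implicit_deletion"]

    def test_deleted_fraction_matches_binomial_rate(self):
        spec = _spec_with(
            [Compartment(1, "T", "right_lung_primary", ((0, 20), (0, 20), (0, 20)))],
            {1: 3},
            radius_range_mm=(4.0, 6.0),
        )
        cfg = ErrorInjectionConfig(fn_rate=0.2)
        bundles = generate_cohort(spec, cfg, 80, seed=9)
        deleted = sum(
            1 for b in bundles for e in b.injection_log if e["op"] == "delete_fn"
        )
        total = sum(len(b.lesion_table) for b in bundles)
        rate = deleted / total
        se = np.sqrt(0.2 * 0.8 / total)
        assert abs(rate - 0.2) <= 3 * se

    def test_conservation_invariants(self, spec):
        bundles = generate_cohort(spec, default_error_config(), 15, seed=4)
        for b in bundles:
            verify_conservation(b)
            n_pred = len(extract_components(b.pred_mask))
            kept = sum(1 for e in b.injection_log if e["op"] == "keep")
            injected = sum(1 for e in b.injection_log if e["op"] == "inject_fp")
            merges = sum(1 for e in b.injection_log if e["op"] == "hilar_merge")
            # each merge fuses at least two components into one
            assert n_pred <= kept + injected
            if merges == 0:
                assert n_pred == kept + injected

    def test_injected_fp_sidecar_maps_to_components(self, tiny_spec):
        cfg = ErrorInjectionConfig(
            fp_specs=[FPSpec("M", "physiologic", "brown_adipose_tissue", 2)]
        )
        case = sample_gt_case(tiny_spec, np.random.default_rng(5), "P0")
        pred, log, sidecar = inject_errors(case, cfg, seed=5)
        injected = [e for e in log if e["op"] == "inject_fp"]
        assert len(sidecar) == len(injected)
        components = {l.lesion_id for l in extract_components(pred)}
        assert set(sidecar["lesion_id"]).issubset(components)

    def test_determinism_of_full_cohort(self, tiny_spec):
        cfg = default_error_config()
        a = generate_cohort(tiny_spec, cfg, 4, seed=11)
        b = generate_cohort(tiny_spec, cfg, 4, seed=11)
        for ba, bb in zip(a, b):
            assert ba.pred_mask.voxels.tobytes() == bb.pred_mask.voxels.tobytes()
            assert ba.injection_log == bb.injection_log

    def test_invalid_rates_rejected(self):
        with pytest.raises(PhantomConfigError):
            ErrorInjectionConfig(fn_rate=1.5).validate()
        with pytest.raises(PhantomConfigError):
            ErrorInjectionConfig(dilate_voxels=-1).validate()


def test_hilar_merge_bridges_primary_and_node(spec):
    cfg = ErrorInjectionConfig(hilar_merge_rate=1.0)
    # find a seed whose first patient has both a primary and a hilar node
    for i in range(20):
        bundles = generate_cohort(spec, cfg, 1, seed=100 + i)
        b = bundles[0]
        stations = set(b.lesion_table["station_or_organ"])
        if "ipsilateral_hilar" in stations:
            merges = [e for e in b.injection_log if e["op"] == "hilar_merge"]
            assert len(merges) == 1
            n_gt = len(b.lesion_table)
            n_pred = len(extract_components(b.pred_mask))
            assert n_pred < n_gt  # at least two components fused
            return
    pytest.fail("no cohort with a hilar node found")
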