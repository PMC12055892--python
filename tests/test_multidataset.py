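"""Shared-group matrices, secondary-dataset conversion, joint training."""

import numpy as np
import pytest

from simlabel.errors import DimensionError, ValidationError
from simlabel.grouping import (
    Grouping,
    build_matrix,
    compose_groupings,
    identity_grouping,
)
from simlabel.multidataset import (
    SharedGroupSpec,
    build_shared_matrices,
    convert_secondary,
    joint_train,
    load_shared_spec,
    save_shared_spec,
)
from simlabel.nn.model import build_reference_model
from simlabel.training import make_schedule, train

from conftest import tiny_scene_spec
from simlabel.experiments import default_shared_spec
from simlabel.synthetic import generate_samples, secondary_scene_spec


@pytest.fixture(scope="module")
def surgical_spec():
    """CholecSeg8k-style primary classes and robotic-dataset-style secondary
    classes mapped to biological / non-biological / primary-background."""
    primary = ("abdominal_wall", "fat", "gastrointestinal_tract", "liver",
               "gallbladder", "grasper", "l_hook", "background")
    secondary = ("kidney_parenchyma", "covered_kidney", "small_intestine",
                 "probe", "needle", "thread")
    p_map = {c: "biological" for c in primary[:5]}
    p_map |= {"grasper": "non_biological", "l_hook": "non_biological",
              "background": "cholecseg8k_background"}
    s_map = {c: "biological" for c in secondary[:3]}
    s_map |= {c: "non_biological" for c in secondary[3:]}
    return SharedGroupSpec(
        groups=("biological", "non_biological", "cholecseg8k_background"),
        primary_classes=primary, secondary_classes=secondary,
        primary_map=p_map, secondary_map=s_map,
    )


class TestSharedMatrices:
    def test_shapes_and_group_order(self, surgical_spec):
        Mp, Ms = build_shared_matrices(surgical_spec)
        assert Mp.entries.shape == (3, 8)
        assert Ms.entries.shape == (3, 6)
        assert Mp.group_labels == Ms.group_labels
        assert (Mp.entries.sum(axis=0) == 1).all()
        assert (Ms.entries.sum(axis=0) == 1).all()

    def test_background_group_empty_on_secondary_side(self, surgical_spec):
        _, Ms = build_shared_matrices(surgical_spec)
        bg_row = Ms.group_labels.index("cholecseg8k_background")
        assert Ms.entries[bg_row].sum() == 0

    def test_primary_matrix_equals_two_step_composition(self, surgical_spec,
                                                        table_grouping):
        """Direct 8-class -> 3-group matrix equals coarsening the 4-group
        assignment (matrix-product oracle)."""
        coarse = Grouping(
            table_grouping.groups,
            ("biological", "non_biological", "cholecseg8k_background"),
            {"tissue": "biological", "organ": "biological",
             "tool": "non_biological", "background": "cholecseg8k_background"},
        )
        composed = compose_groupings(coarse, table_grouping)
        Mp, _ = build_shared_matrices(surgical_spec)
        np.testing.assert_array_equal(Mp.entries, build_matrix(composed).entries)

    def test_identical_class_sets_identity_maps(self):
        classes = ("a", "b")
        spec = SharedGroupSpec(
            groups=classes, primary_classes=classes, secondary_classes=classes,
            primary_map={"a": "a", "b": "b"}, secondary_map={"a": "a", "b": "b"},
        )
        Mp, Ms = build_shared_matrices(spec)
        np.testing.assert_array_equal(Mp.entries, Ms.entries)

    def test_unmapped_secondary_class_rejected(self, surgical_spec):
        bad = SharedGroupSpec(
            groups=surgical_spec.groups,
            primary_classes=surgical_spec.primary_classes,
            secondary_classes=surgical_spec.secondary_classes + ("new",),
            primary_map=surgical_spec.primary_map,
            secondary_map=surgical_spec.secondary_map,
        )
        with pytest.raises(ValidationError, match="'new'"):
            build_shared_matrices(bad)

    def test_round_trip(self, tmp_path, surgical_spec):
        save_shared_spec(surgical_spec, tmp_path / "shared.yaml")
        assert load_shared_spec(tmp_path / "shared.yaml") == surgical_spec


@pytest.fixture(scope="module")
def secondary_samples():
    return generate_samples(secondary_scene_spec(), 4, 1, seed=8)


class TestConvertSecondary:

    def test_masks_reindexed_into_groups(self, secondary_samples):
        shared = default_shared_spec()
        converted = convert_secondary(secondary_samples, shared)
        used = set()
        for s in converted:
            assert s.label_space == "simplified"
            used |= set(np.unique(s.label))
        # biological + non_biological appear; the primary background never
        assert used == {0, 1}

    def test_resize_halves_dimensions(self, secondary_samples):
        shared = default_shared_spec()
        converted = convert_secondary(secondary_samples, shared, resize=(32, 32))
        assert all(s.image.shape == (32, 32, 3) for s in converted)
        assert all(s.label.shape == (32, 32) for s in converted)

    def test_histogram_pushes_through_the_map(self, secondary_samples):
        shared = default_shared_spec()
        _, Ms = build_shared_matrices(shared)
        converted = convert_secondary(secondary_samples, shared)
        for orig, conv in zip(secondary_samples, converted):
            class_hist = np.bincount(orig.label.ravel(), minlength=Ms.n_classes)
            group_hist = np.bincount(conv.label.ravel(), minlength=Ms.n_groups)
            np.testing.assert_array_equal(group_hist, Ms.entries @ class_hist)

    def test_idempotent_under_identity_remap(self, secondary_samples):
        """Re-converting an already-converted pool with an identity group map
        is a no-op."""
        shared = default_shared_spec()
        converted = convert_secondary(secondary_samples, shared)
        ident = SharedGroupSpec(
            groups=shared.groups, primary_classes=shared.groups,
            secondary_classes=shared.groups,
            primary_map={g: g for g in shared.groups},
            secondary_map={g: g for g in shared.groups},
        )
        again = convert_secondary(converted, ident)
        for a, b in zip(converted, again):
            np.testing.assert_array_equal(a.label, b.label)


@pytest.fixture(scope="module")
def tiny_joint():
    primary_spec = tiny_scene_spec()
    primary = generate_samples(primary_spec, 6, 2, seed=4)
    secondary = generate_samples(secondary_scene_spec(height=32, width=32),
                                 4, 1, seed=9)
    shared = SharedGroupSpec(
        groups=("biological", "non_biological", "primary_background"),
        primary_classes=primary_spec.classes,
        secondary_classes=secondary_scene_spec().classes,
        primary_map={"tissue_a": "biological", "tissue_b": "biological",
                     "tool_a": "non_biological",
                     "background": "primary_background"},
        secondary_map={c: ("non_biological" if c in ("probe", "needle_driver")
                           else "biological")
                       for c in secondary_scene_spec().classes},
    )
    return primary_spec, primary, convert_secondary(secondary, shared), shared


class TestJointTrain:
    def test_joint_run_evaluates_in_primary_space(self, tiny_joint):
        primary_spec, primary, converted, shared = tiny_joint
        n = len(primary_spec.classes)
        model = build_reference_model(n, width=8, seed=0)
        plan = make_schedule("mixed", stage_epochs=(2, 2, 1))
        joint_train(model, primary, converted, shared, seed=1, plan=plan)
        assert model.n_classes == n
        preds = model.predict(np.stack([s.image for s in primary[:2]]))
        assert preds.shape == (2, 32, 32)
        assert preds.max() < n

    def test_empty_secondary_equals_primary_only(self, tiny_joint):
        primary_spec, primary, _, shared = tiny_joint
        n = len(primary_spec.classes)
        plan = make_schedule("mixed", stage_epochs=(2, 2, 1))
        import warnings
        model_a = build_reference_model(n, width=8, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            joint_train(model_a, primary, [], shared, seed=2, plan=plan)
        model_b = build_reference_model(n, width=8, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train(model_b, primary, [], plan, 2)
        for pa, pb in zip(model_a.parameters(), model_b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_class_count_mismatch_rejected(self, tiny_joint):
        primary_spec, primary, converted, shared = tiny_joint
        model = build_reference_model(5, width=8, seed=0)
        with pytest.raises(DimensionError, match="classes"):
            joint_train(model, primary, converted, shared, seed=0)
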