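import numpy as np
import pytest

from simlabel.grouping import Grouping, cholecseg8k_grouping
from simlabel.synthetic import FamilySpec, SceneSpec, generate_samples


@pytest.fixture(scope="session")
def table_grouping() -> Grouping:
    """The standard 8-class laparoscopic grouping (Tissue/Organ/Tool/Background)."""
    return cholecseg8k_grouping()


def tiny_scene_spec(size: int = 32, noise_sigma: float = 8.0) -> SceneSpec:
    """A small 4-class spec for fast training tests."""
    families = (
        FamilySpec("tissue", "blob", ("tissue_a", "tissue_b"), (1.0, 0.5), (172, 76, 64)),
        FamilySpec("tool", "capsule", ("tool_a",), (1.0,), (92, 102, 144),
                   shapes_per_scene=(1, 2)),
        FamilySpec("backdrop", "background", ("background",), (1.0,), (28, 26, 32)),
    )
    return SceneSpec(height=size, width=size, families=families, noise_sigma=noise_sigma)


def tiny_grouping() -> Grouping:
    spec = tiny_scene_spec()
    return Grouping(
        spec.classes,
        ("tissue", "tool", "background"),
        {"tissue_a": "tissue", "tissue_b": "tissue", "tool_a": "tool",
         "background": "background"},
    )


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight deterministic 32x32 scenes with 4 folds."""
    return generate_samples(tiny_scene_spec(), 8, 4, seed=123)


def random_grouping(rng: np.random.Generator, max_classes: int = 12) -> Grouping:
    """A random valid grouping: n classes onto m nonempty groups."""
    n = int(rng.integers(1, max_classes + 1))
    m = int(rng.integers(1, n + 1))
    classes = tuple(f"c{i}" for i in range(n))
    groups = tuple(f"g{j}" for j in range(m))
    # guarantee every group nonempty, then assign the rest uniformly
    assignment = {classes[j]: groups[j] for j in range(m)}
    for i in range(m, n):
        assignment[classes[i]] = groups[int(rng.integers(0, m))]
    return Grouping(classes, groups, assignment)
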