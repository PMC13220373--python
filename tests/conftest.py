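import numpy as np
import pytest

from disconnectome import (
    CohortConfig,
    LesionMask,
    LesionSpec,
    ParcellationAtlas,
    disconnection_fractions,
    generate_cohort,
    weight_patient,
)


def nested_config(seed: int = 7) -> CohortConfig:
    """Standard shrinking-lesion cohort: nested spheres, no boundary jitter."""
    return CohortConfig(seed=seed)


def moving_config(seed: int = 11) -> CohortConfig:
    """Lesion that shifts and regrows, producing both losses and gains."""
    return CohortConfig(
        seed=seed,
        lesion_specs=(
            LesionSpec((15.0, 16.0, 16.0), 6.0),
            LesionSpec((18.5, 17.0, 15.0), 4.5),
            LesionSpec((13.0, 15.0, 18.0), 5.5),
        ),
    )


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(nested_config())


@pytest.fixture(scope="session")
def moving_cohort():
    return generate_cohort(moving_config())


def weighted_series(cohort) -> list[np.ndarray]:
    return [
        weight_patient(
            cohort.healthy,
            disconnection_fractions(cohort.streamlines, cohort.healthy, mask),
        )
        for mask in cohort.masks
    ]


@pytest.fixture(scope="session")
def nested_weighted(cohort):
    return weighted_series(cohort)


@pytest.fixture(scope="session")
def moving_weighted(moving_cohort):
    return weighted_series(moving_cohort)


@pytest.fixture
def plane_atlas():
    """4x4x4 grid split into two 32-voxel parcels by the x=2 plane."""
    labels = np.ones((4, 4, 4), dtype=np.int32)
    labels[2:] = 2
    return ParcellationAtlas(labels=labels, voxel_size=1.0,
                             networks={1: "NetA", 2: "NetB"})


def make_mask(data: np.ndarray, voxel_size: float = 1.0, timepoint: str = "S1") -> LesionMask:
    return LesionMask(data=np.asarray(data), voxel_size=voxel_size, timepoint=timepoint)
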