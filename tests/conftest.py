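import numpy as np
import pytest

from geostress import SyntheticSpec, generate_sms_dataset


@pytest.fixture(scope="session")
def rest_recording():
    """A balanced synthetic recording: 8 segments of 225 samples at 30 s."""
    return generate_sms_dataset(preset="rest", seed=11)


@pytest.fixture
def recording_csv(tmp_path, rest_recording):
    from geostress import write_sms_csv

    path = tmp_path / "recording.csv"
    write_sms_csv(path, rest_recording)
    return path


@pytest.fixture(scope="session")
def flat_spec():
    """Single-segment-profile spec used for correlation/marginal checks."""
    return SyntheticSpec(
        profiles={"HRV": [(2, 0.65)], "SF": [(2, 0.6)], "SpO2": [(2, 0.7)]},
        n_per_segment=2500,
        seed=5,
    )


@pytest.fixture(scope="session")
def mc_class_areas():
    """Expose the Monte-Carlo area oracle as a fixture-injected callable."""
    return monte_carlo_class_areas


def monte_carlo_class_areas(partition, n=100_000, seed=0):
    """Independent rejection-sampling oracle for the partitioned areas.

    Classifies uniform points in Ω by nearest hull directly (no
    triangulation involved) and scales the class fractions by meas(Ω).
    """
    import shapely
    from shapely.ops import unary_union

    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = partition.bounds
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
    )
    geoms = shapely.points(pts)
    dpos = shapely.distance(unary_union(partition.positive_polygons), geoms)
    dneg = shapely.distance(unary_union(partition.negative_polygons), geoms)
    frac_pos = float(np.mean(dpos <= dneg))
    return frac_pos * partition.meas_omega, (1 - frac_pos) * partition.meas_omega
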