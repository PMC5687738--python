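import numpy as np
import pytest

from mzvault import (
    BuildParams,
    CloudSpec,
    MsPoint,
    MzStore,
    StoreConfig,
    gen_cloud,
)


def uniform_cloud(seed: int, n: int, mz=(400.0, 1200.0), rt=(0.0, 600.0)):
    """A structureless uniform point cloud with random intensities."""
    rng = np.random.default_rng(seed)
    return [
        MsPoint(
            id=i,
            mz=float(rng.uniform(*mz)),
            rt=float(rng.uniform(*rt)),
            intensity=float(rng.exponential(100.0)),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_cloud():
    """~1.5k-point LC-MS-shaped cloud with ground-truth segmentation."""
    return gen_cloud(
        CloudSpec(seed=42, n_envelopes=3, noise_density=0.002, scan_interval=2.0)
    )


@pytest.fixture(scope="session")
def medium_cloud():
    """~25k-point LC-MS-shaped cloud for store-level tests."""
    return gen_cloud(CloudSpec(seed=7, n_envelopes=10, noise_density=0.04))


@pytest.fixture(scope="session")
def medium_store(medium_cloud, tmp_path_factory):
    store = MzStore.build(
        medium_cloud,
        tmp_path_factory.mktemp("medium_store"),
        BuildParams(leaf_capacity=500, branching=4),
    )
    yield store
    store.close()


@pytest.fixture()
def tiny_store(small_cloud, tmp_path):
    store = MzStore.build(
        small_cloud, tmp_path / "store", BuildParams(leaf_capacity=100, branching=3)
    )
    yield store
    store.close()


def scan_window(points, window):
    """Brute-force linear-scan oracle for window queries."""
    return sorted(
        (p for p in points if window.contains(p)), key=lambda p: (p.mz, p.rt, p.id)
    )


def point_key(p: MsPoint):
    return (p.mz, p.rt, p.intensity, p.trace_id, p.envelope_id)
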