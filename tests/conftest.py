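from datetime import datetime, timedelta, timezone

import pytest

from connqa import BoundingBox, DocumentStore, generate_world


class TickClock:
    """Deterministic test clock advancing one second per reading."""

    def __init__(self, start="2024-01-01T00:00:00+00:00"):
        self.t = datetime.fromisoformat(start).astimezone(timezone.utc)

    def __call__(self):
        self.t += timedelta(seconds=1)
        return self.t


@pytest.fixture
def store():
    s = DocumentStore(clock=TickClock())
    s.add_volume((0, 0, 0), (100, 100, 100), (4.0, 4.0, 40.0), volume_id="vol1")
    return s


@pytest.fixture
def small_world():
    """Compact world: 5 cells, ~20 synapses, 8 nm isotropic voxels."""
    extent = BoundingBox((0, 0, 0), (256, 256, 256))
    return generate_world(
        extent, (8.0, 8.0, 8.0), n_cells=5, synapse_density_per_um3=2.0, seed=42
    )
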