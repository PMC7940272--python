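import numpy as np
import pytest
from skimage.measure import regionprops

from punctaflux.puncta import PunctaSet, Punctum, equivalent_diameter


def puncta_from_labels(labels: np.ndarray, role: str = "") -> PunctaSet:
    """Wrap an arbitrary label image as a PunctaSet (no gating), for tests."""
    labels = np.ascontiguousarray(labels, dtype=np.int32)
    objects = []
    for prop in regionprops(labels):
        objects.append(
            Punctum(
                id=int(prop.label),
                area_px=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                equivalent_diameter_px=equivalent_diameter(prop.area),
                mean_intensity=0.0,
            )
        )
    objects.sort(key=lambda o: o.id)
    return PunctaSet(labels=labels, objects=tuple(objects), channel_role=role)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
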