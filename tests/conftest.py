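"""Shared fixtures: small analytic volumes and the phantom recovery experiment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from subsolidseg import (
    PhantomSpec,
    VesselSpec,
    generate_cohort,
    generate_phantom,
    voxel_scores,
)
from subsolidseg import pipeline
from subsolidseg.volume import Volume

ISO = (0.5, 0.5, 0.5)


@pytest.fixture(scope="session")
def coords40():
    """Physical (z, y, x) coordinate grids for a 40^3 volume at 0.5 mm."""
    return np.meshgrid(*[np.arange(40) * 0.5 for _ in range(3)], indexing="ij")


@pytest.fixture(scope="session")
def cylinder_volume(coords40):
    """Bright cylinder along z (radius 3 mm, +500 HU contrast on -900 HU)."""
    zz, yy, xx = coords40
    data = np.where((yy - 10.0) ** 2 + (xx - 10.0) ** 2 <= 3.0**2, -400.0, -900.0)
    return Volume(data, ISO)


@pytest.fixture(scope="session")
def simple_phantom():
    """One deterministic part-solid phantom with a crossing vessel."""
    spec = PhantomSpec(
        nodule_center=(20.0, 19.0, 19.0),
        nodule_radii=(6.5, 6.5, 6.5),
        core={"center": (20.0, 17.0, 17.0), "radius": 2.6},
        vessels=[
            VesselSpec(points=[(20.0, 2.0, 36.0), (20.0, 36.0, 2.0)], diameters=[2.5, 2.5])
        ],
        seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def recovery_experiment():
    """Train on 5 phantoms (~2000 annotation voxels), segment 5 held-out ones.

    All ten phantoms are part-solid with crossing vessels (all three classes
    present), noise sigma 20 HU.  Returns the model, the held-out bundles,
    their pipeline results, and the per-nodule 3D voxel scores on the source
    grid.
    """
    strata = (("part-solid+vessels", True),)
    bundles, _ = generate_cohort(10, seed=11, strata=strata)
    train_b, test_b = bundles[:5], bundles[5:]
    model = pipeline.train_on_bundles(train_b, per_class=133, seed=0)
    results = [pipeline.segment_bundle(b, model) for b in test_b]
    scores = pd.concat(
        [voxel_scores(r.final_labels, b.truth, nodule_id=i) for i, (r, b) in enumerate(zip(results, test_b))],
        ignore_index=True,
    )
    return {"model": model, "test_bundles": test_b, "results": results, "scores": scores}
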