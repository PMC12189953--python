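import numpy as np
import pandas as pd
import pytest

from nicheshift import GridSpec, RasterLayer, RunConfig
from nicheshift.occurrences import OccurrenceSet
from nicheshift.pipeline import run_pipeline


def make_layer(values, spec=None, mask=None, name="layer"):
    values = np.asarray(values, dtype=float)
    if spec is None:
        spec = GridSpec(0.0, 0.0, 1.0, values.shape[0], values.shape[1])
    return RasterLayer(spec, values, mask, name=name)


def make_occ(lons, lats, species_id="sp", flags=None):
    return OccurrenceSet(
        species_id=species_id,
        table=pd.DataFrame({"lon": lons, "lat": lats}),
        flags=None if flags is None else np.asarray(flags),
    )


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default synthetic world (7 species,
    100×200 grid, 500 presences each), shared by the slow end-to-end checks."""
    return run_pipeline(RunConfig(seed=1), write=False)
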