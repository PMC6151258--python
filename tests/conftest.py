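import warnings

import numpy as np
import pandas as pd
import pytest

from gapstack.pipeline import RunConfig, run_pipeline
from gapstack import generate_landscape, generate_zones_and_roads


@pytest.fixture(scope="session")
def landscape():
    """Small default landscape with zoning and roads attached."""
    land = generate_landscape(seed=11)
    zones, roads = generate_zones_and_roads(land, seed=11)
    return land, zones, roads


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("run") / "default"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(RunConfig(seed=1), outdir)
    return result


def make_records(rows):
    """Build an occurrence frame from (species, source, x, y, minutes, site) tuples."""
    t0 = pd.Timestamp("2017-06-01 08:00:00")
    recs = []
    for species, source, x, y, minutes, site in rows:
        recs.append({
            "species_id": species, "source": source, "x": float(x), "y": float(y),
            "elevation": 1000.0,
            "timestamp": (t0 + pd.Timedelta(minutes=minutes)) if minutes is not None else pd.NaT,
            "site_id": site, "group": "mammal",
        })
    return pd.DataFrame(recs)


def random_records(rng, n, sources=("camera", "transect"), n_species=3, n_sites=4,
                   extent=2000.0, max_minutes=600):
    rows = []
    for _ in range(n):
        src = sources[rng.integers(len(sources))]
        rows.append((f"sp{rng.integers(n_species)}", src,
                     rng.uniform(0, extent), rng.uniform(0, extent),
                     int(rng.integers(0, max_minutes)) if src in ("camera", "transect") else None,
                     f"site{rng.integers(n_sites)}" if src == "camera" else None))
    return make_records(rows)
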