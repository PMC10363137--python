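import warnings

import numpy as np
import pytest

from cardiorqa.sim import (ARRHYTHMIA_CLASSES, extract_traces, run_scenario,
                           scenario1_config, scenario2_config)
from cardiorqa.spatial import compute_metric_maps
from cardiorqa.detect import extract_feature_vector

warnings.filterwarnings("ignore", message="site .* skipped")

#: site stride used for the class feature grids (2 mm spacing on the 0.2 mm
#: simulation grid) — coarse enough to keep the suite fast, fine enough for
#: the class separations to hold.
FEATURE_STRIDE = 10

CLASS_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def class_recordings():
    """One simulation per (arrhythmia class, seed); shared session-wide."""
    recs = {}
    for cls in ARRHYTHMIA_CLASSES:
        for seed in CLASS_SEEDS:
            recs[(cls, seed)] = run_scenario(scenario2_config(cls, seed=seed))
    return recs


@pytest.fixture(scope="session")
def class_det_features(class_recordings):
    """(mean DET, Moran's I of DET) per class fixture simulation."""
    rows = []
    for (cls, seed), rec in class_recordings.items():
        tg = extract_traces(rec, FEATURE_STRIDE, (0.0, 1000.0))
        maps = compute_metric_maps(tg, measures=("DET",))
        feats = extract_feature_vector(maps)
        feats.update({"class": cls, "seed": seed})
        rows.append(feats)
    import pandas as pd
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def scenario1_recording():
    """Reduced rapidly paced sheet (6x6 cm) for bulk-DET behaviour."""
    cfg = scenario1_config(size_cm=6.0)
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def rotor_case(class_recordings):
    """Class-D fixture used for rotor detection: pinned rotor + wavebreak."""
    rec = class_recordings[("fibrillation_with_anchored_rotor", 0)]
    tg = extract_traces(rec, 5, (0.0, 1000.0))
    maps = compute_metric_maps(tg, measures=("Lmax", "Lmean"))
    return rec, maps
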