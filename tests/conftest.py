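import numpy as np
import pandas as pd
import pytest

from guidescape.dataset_io import MINMAX, RAW, Dataset
from guidescape.synthetic_data import sample_context

BASES = "ACGT"


def make_dataset(
    spacers,
    activities,
    pam_contexts=None,
    dataset_id="d",
    species="",
    scale_state=RAW,
    features=None,
):
    """Construct an in-memory dataset directly from parallel sequences."""
    n = len(spacers)
    if pam_contexts is None:
        pam_contexts = ["AGGT"] * n
    df = pd.DataFrame(
        {
            "guide_id": [f"g{i:05d}" for i in range(n)],
            "spacer": list(spacers),
            "pam_context": list(pam_contexts),
            "activity": np.asarray(activities, dtype=float),
        }
    )
    if features:
        for name, vals in features.items():
            df[name] = vals
    return Dataset(
        dataset_id=dataset_id, df=df, species=species, scale_state=scale_state
    )


def random_spacers(rng, n, length=20):
    arr = np.array(list(BASES))
    return ["".join(row) for row in arr[rng.integers(0, 4, size=(n, length))]]


def scaled(d):
    """Shortcut: mark/convert a dataset to the min-max state for predictor use."""
    from guidescape.dataset_io import minmax_scale

    return minmax_scale(d) if d.scale_state != MINMAX else d


@pytest.fixture(scope="session")
def map_a():
    return sample_context(species_seed=11, intrinsic_seed=7, k=5)


@pytest.fixture(scope="session")
def map_b():
    return sample_context(species_seed=23, intrinsic_seed=7, k=5)
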