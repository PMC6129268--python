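import numpy as np
import pandas as pd
import pytest

from micromdp import AbundanceMatrix, GeneratorSpec, LongitudinalDataset, PerturbationSchema


@pytest.fixture
def tiny_matrix():
    """3 samples × 4 taxa of counts."""
    data = pd.DataFrame(
        [[12000, 3000, 0, 5000], [8000, 1000, 0, 999], [30000, 15000, 0, 5000]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return AbundanceMatrix(data, units_mode="counts")


@pytest.fixture
def two_state_spec():
    """Well-separated 2-state, 2-action ground truth; action 'a' drives
    the system into the diverse state S2, action 'b' holds it back."""
    profiles = np.array(
        [
            [0.70, 0.20, 0.05, 0.05, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.1, 0.1, 0.2, 0.2, 0.2, 0.2],
        ]
    )
    trans = np.zeros((2, 2, 2))
    trans[0, 0] = [0.1, 0.9]   # S1, a -> mostly S2
    trans[0, 1] = [0.9, 0.1]   # S1, b -> mostly stays
    trans[1, 0] = [0.05, 0.95]
    trans[1, 1] = [0.05, 0.95]
    return GeneratorSpec(
        n_states=2,
        action_labels=["a", "b"],
        true_transition=trans,
        state_profiles=profiles,
        profile_concentration=200.0,
        read_depth=20_000,
        n_subjects=24,
        timepoints_per_subject=6,
        action_assignment="per_subject_constant",
        seed=7,
    )


@pytest.fixture
def small_dataset():
    """Hand-built 2-subject dataset with explicit states and a binary action."""
    data = pd.DataFrame(
        np.array(
            [
                [90, 5, 5],
                [10, 45, 45],
                [10, 40, 50],
                [80, 10, 10],
                [15, 40, 45],
            ]
        ),
        index=["p1_t0", "p1_t1", "p1_t2", "p2_t0", "p2_t1"],
        columns=["tA", "tB", "tC"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["p1_t0", "p1_t1", "p1_t2", "p2_t0", "p2_t1"],
            "subject_id": ["p1", "p1", "p1", "p2", "p2"],
            "time_point": [0, 1, 2, 0, 1],
            "drug": ["yes", "yes", "no", "no", "no"],
            "cst": ["low", "high", "high", "low", "high"],
        }
    )
    schema = PerturbationSchema(name="drug", kind="binary", levels=["no", "yes"])
    return LongitudinalDataset(AbundanceMatrix(data), meta, [schema])
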