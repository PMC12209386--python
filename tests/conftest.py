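import numpy as np
import pytest

from subtremor.features import FeatureSequence
from subtremor.sampling import Dataset
from subtremor.simdata import PD_MODEL, SimConfig, generate_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pd_recording():
    """One seeded PD-like synthetic recording (calibrated subclinical)."""
    return generate_recording(PD_MODEL, 1, SimConfig(), "rec-pd-0", "subj-pd-0",
                              seed=42)


def make_dummy_dataset(class_counts: dict[int, int], n_frames: int = 8,
                       n_features: int = 4, two_per_subject: bool = True,
                       seed: int = 0) -> Dataset:
    """Tiny labeled dataset with subject grouping for split/fold tests."""
    rng = np.random.default_rng(seed)
    seqs = []
    for label, n in sorted(class_counts.items()):
        i = 0
        subj = 0
        while i < n:
            k = 2 if (two_per_subject and i + 2 <= n and subj % 3 == 0) else 1
            for j in range(k):
                seqs.append(FeatureSequence(
                    values=rng.standard_normal((n_frames, n_features)),
                    columns=[("hand", float(f)) for f in range(n_features)],
                    label=label,
                    recording_id=f"r{label}-{i}",
                    subject_id=f"s{label}-{subj}"))
                i += 1
            subj += 1
    return Dataset(seqs)
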