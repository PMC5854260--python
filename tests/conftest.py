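import numpy as np
import pytest

import avve


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (56 mm cube, 1 mm grid, SNR ~30), reused read-only."""
    return avve.generate_phantom(avve.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return avve.generate_phantom(avve.PhantomSpec(noise_sd=0.0, seed=7))


def mixture_samples(rng, n, means, sds, weights):
    """Draw n samples from a Gaussian mixture (shared by several suites)."""
    comp = rng.choice(len(means), size=n, p=np.asarray(weights) / np.sum(weights))
    return rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])


def mixture_minima(means, sds, weights):
    """Brute-force interior minima of a Gaussian mixture density (oracle)."""
    from scipy.stats import norm

    x = np.linspace(min(means) - 4 * max(sds), max(means) + 4 * max(sds), 200001)
    d = sum(w * norm.pdf(x, m, s) for m, s, w in zip(means, sds, weights))
    interior = (d[1:-1] < d[:-2]) & (d[1:-1] < d[2:])
    return x[1:-1][interior]


def selection_table(seed, n_subjects=8, rows_per_subject=200, shift=2.0,
                    shuffle_labels=False):
    """Synthetic feature-selection table: f1/f2 class-separated Gaussians
    (|delta mean| = 4 sd with the default shift), f3/f4 pure noise."""
    import pandas as pd
    from avve.voxel_features import FeatureTable

    r = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        y = np.repeat([0, 1], rows_per_subject // 2)
        f1 = r.normal(shift * (2 * y - 1), 1.0)
        f2 = r.normal(shift * (1 - 2 * y), 1.0)
        f3 = r.normal(0, 1, rows_per_subject)
        f4 = r.normal(0, 1, rows_per_subject)
        if shuffle_labels:
            y = r.permutation(y)
        frames.append(
            pd.DataFrame(
                {"f1": f1, "f2": f2, "f3": f3, "f4": f4, "label": y,
                 "subject_id": f"s{s}"}
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    return FeatureTable(
        frame=frame,
        feature_names=("f1", "f2", "f3", "f4"),
        grids={f"s{s}": None for s in range(n_subjects)},
    )


def samples_to_volume(samples):
    """Reshape a 1D sample vector into the largest cube volume it fills."""
    n = int(len(samples) ** (1 / 3))
    while (n + 1) ** 3 <= len(samples):
        n += 1
    return avve.VolumeImage(
        np.asarray(samples[: n**3], dtype=float).reshape(n, n, n),
        np.eye(4), (1, 1, 1),
    )
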