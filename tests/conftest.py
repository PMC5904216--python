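import numpy as np
import pytest

from grud.core import Dataset, TimeSeriesSample, build_mask


def random_sample(rng, T=6, D=3, missing=0.4, sample_id=None):
    """A random irregular sample with the given expected missing rate."""
    raw = rng.normal(size=(T, D))
    raw[rng.random((T, D)) < missing] = np.nan
    values, mask = build_mask(raw)
    gaps = rng.uniform(0.1, 2.0, size=T - 1)
    stamps = np.concatenate([[0.0], np.cumsum(gaps)])
    return TimeSeriesSample(values=values, mask=mask, stamps=stamps,
                            sample_id=sample_id)


def random_dataset(rng, n=8, T=6, D=3, missing=0.4, ensure_observed=True):
    samples = [random_sample(rng, T, D, missing, sample_id=f"s{i}")
               for i in range(n)]
    if ensure_observed:
        # guarantee every variable is observed at least once in the set
        s0 = samples[0]
        mask = s0.mask.copy()
        mask[0, :] = 1.0
        vals = np.where((mask == 1) & (s0.mask == 0),
                        rng.normal(size=s0.values.shape), s0.values)
        samples[0] = TimeSeriesSample(values=vals, mask=mask, stamps=s0.stamps,
                                      sample_id=s0.sample_id)
    labels = rng.integers(0, 2, size=n)
    labels[: 2] = [0, 1]  # both classes present
    return Dataset(samples=samples, labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)
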