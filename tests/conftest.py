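import numpy as np
import pytest

from pefi.bench import run_benchmark

BENCH_SEED = 1


@pytest.fixture(scope="session")
def bench_run(tmp_path_factory):
    """One full synthetic benchmark run shared by the end-to-end tests."""
    out_dir = tmp_path_factory.mktemp("bench")
    results = run_benchmark(seed=BENCH_SEED, out_dir=out_dir)
    return out_dir, results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_gaussian_values():
    """Bimodal gray levels around 0.2 and 0.8 (sd 0.05), 1000 per mode."""
    gen = np.random.default_rng(7)
    vals = np.concatenate(
        [gen.normal(0.2, 0.05, 1000), gen.normal(0.8, 0.05, 1000)]
    )
    return np.clip(vals, 0.0, 1.0)
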