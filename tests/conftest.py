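import numpy as np
import pytest
from hypothesis import settings

import ecgrecon as er

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """5 subjects, shared linear lead field, no contaminants (8 s windows)."""
    cfg = er.SyntheticConfig(seed=3, powerline_mv=0.0, baseline_mv=0.0,
                             white_sigma_mv=0.0, subject_leadfield_jitter=0.0)
    return er.make_dataset(cfg, 5, segments_per_subject=3)


@pytest.fixture(scope="session")
def noisy_dataset():
    """10 subjects with per-subject lead fields, mild noise and ectopy."""
    cfg = er.SyntheticConfig(seed=11, ectopic_rate_per_min=8.0)
    return er.make_dataset(cfg, 10, segments_per_subject=2)


def numeric_gradient(f, params, eps=1e-6):
    """Central finite differences of scalar-valued f w.r.t. Tensor params."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = p.data[i]
            p.data[i] = orig + eps
            hi = float(f().data)
            p.data[i] = orig - eps
            lo = float(f().data)
            p.data[i] = orig
            g[i] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads
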