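import numpy as np
import pytest

import pondbounds as pb


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def linear_dataset(rng):
    """Noisy straight line on an identity x scale."""
    x = np.sort(rng.uniform(-2, 2, 80))
    y = 1.5 * x - 0.3 + rng.normal(0, 0.25, 80)
    return pb.GradientDataset(x, y)


def make_gradient(form, params, n=100, noise_sd=0.0, seed=0,
                  x_domain=(1e-3, 1e3), x_scale="log10"):
    spec = pb.GeneratorSpec(form=form, params=params, x_domain=x_domain,
                            x_scale=x_scale, n=n, noise_sd=noise_sd, seed=seed)
    return pb.generate_gradient(spec)


def brute_force_segmented_rss(x, y, min_seg_points=5, continuous=True):
    """Independent exhaustive-grid profile: conditional OLS at every interior
    midpoint between consecutive distinct x values, via plain normal equations."""
    xs = np.sort(np.unique(x))
    best = np.inf
    for lo, hi in zip(xs[:-1], xs[1:]):
        bp = (lo + hi) / 2.0
        n_left, n_right = (x <= bp).sum(), (x > bp).sum()
        if n_left < min_seg_points or n_right < min_seg_points:
            continue
        if continuous:
            design = np.column_stack([np.ones_like(x), x, np.where(x > bp, x - bp, 0.0)])
        else:
            left = (x <= bp).astype(float)
            design = np.column_stack([left, left * x, 1 - left, (1 - left) * x])
        coef = np.linalg.solve(design.T @ design, design.T @ y)
        resid = y - design @ coef
        best = min(best, float(resid @ resid))
    return best
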