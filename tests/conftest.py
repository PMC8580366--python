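import numpy as np
import pytest

from entropimg.phantom import PhantomSpec, simulate_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def template_demo_series() -> np.ndarray:
    """Series with one two-point template that recurs twice, extending once.

    Built on a strictly increasing ramp (gaps of 10, far beyond any
    tolerance) with three planted near-copies of the template value pair:
    the template itself at indices (6, 7), a first recurrence at (13, 14)
    whose third point stays on the ramp, and a second recurrence at (49, 50)
    whose third point (51) also continues the template's extension (8).
    With an absolute tolerance of 0.5, counting pairs that involve the
    template at index 6 with m = 2 gives exactly b = 2 and a = 1, hence
    SampEn = -ln(1/2).
    """
    x = 10.0 * np.arange(55)
    x[6], x[7], x[8] = 0.0, 0.0, 5.0
    x[13], x[14] = 0.4, 0.4
    x[49], x[50], x[51] = -0.4, -0.4, 4.6
    return x


def brute_force_counts(x, m: int, r: float):
    """Naive O(N^2) template-pair counting; the oracle for the fast path.

    Independent of the package implementation: explicit double loop over
    unordered pairs, Chebyshev distance computed point by point, strict
    inequality, tolerance r times the population std of the raw series.
    """
    x = [float(v) for v in np.asarray(x).ravel()]
    n = len(x)
    mean = sum(x) / n
    sd = (sum((v - mean) ** 2 for v in x) / n) ** 0.5
    r_abs = r * sd
    t = n - m
    b = a = 0
    for i in range(t):
        for j in range(i + 1, t):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm < r_abs:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) < r_abs:
                    a += 1
    return b, a


@pytest.fixture(scope="session")
def small_phantom_frame():
    """One moderate-size speckle frame shared across tests."""
    spec = PhantomSpec(axial_samples=384, num_lines=48, fat_level=0.2, seed=7)
    frame, _ = simulate_frame(spec)
    return frame
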