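"""Shared reference oracles for the test suite.

These are deliberately independent re-implementations (plain ``math``
term-by-term transcriptions, quadrature, brute-force sampling) used to
cross-check the package's vectorized code paths.
"""

import math

import numpy as np
import pytest


def reference_mixture_pdf(t, amps, taus, t_m, t_max):
    """Term-by-term censored mixture density, scalar arithmetic only."""
    norm = sum(a * (math.exp(-t_m / tau) - math.exp(-t_max / tau))
               for a, tau in zip(amps, taus))
    return sum(a / tau * math.exp(-t / tau)
               for a, tau in zip(amps, taus)) / norm


def reference_convolution_pdf(t, tau1, tau2, t_m, t_max):
    """Two-step convolution density with an explicit window normalizer."""
    raw = (math.exp(-t / tau1) - math.exp(-t / tau2)) / (tau1 - tau2)
    norm = (tau1 * (math.exp(-t_m / tau1) - math.exp(-t_max / tau1))
            - tau2 * (math.exp(-t_m / tau2) - math.exp(-t_max / tau2))) \
        / (tau1 - tau2)
    return raw / norm


def grid_cdf(pdf, t_m, t_max, n=20001):
    """Numerical CDF oracle: trapezoid-integrate a pdf on a dense grid,
    returning a callable suitable for scipy.stats.kstest."""
    grid = np.linspace(t_m, t_max, n)
    vals = np.asarray([pdf(x) for x in grid])
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (vals[1:] + vals[:-1]) * np.diff(grid))])
    cum /= cum[-1]

    def cdf(x):
        return np.interp(x, grid, cum)

    return cdf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
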