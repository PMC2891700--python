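"""Shared analytic REMD walker: exact OU sampling of harmonic oscillators."""

import numpy as np

from cgfold.units import KB


class HarmonicWalker:
    """Exact sampler for independent 1-D harmonic oscillators.

    Propagation applies an exact Ornstein-Uhlenbeck update per coordinate,
    so every chunk of dynamics leaves the Boltzmann distribution invariant:
    an analytic detailed-balance oracle for the exchange machinery.
    """

    def __init__(self, k=100.0, ndof=3, relax_per_step=0.05):
        self.k = k
        self.ndof = ndof
        self.rate = relax_per_step

    def propagate(self, x, T, n_steps, rng):
        c = np.exp(-self.rate * n_steps)
        sigma = np.sqrt(KB * T / self.k * (1 - c * c))
        return c * x + sigma * rng.standard_normal(self.ndof)

    def energy(self, x):
        return 0.5 * self.k * float((x ** 2).sum())

    def rescale_velocities(self, x, factor):
        return x

    def snapshot(self, x):
        return x.copy()

    def direct_samples(self, T, n, rng):
        x = rng.standard_normal((n, self.ndof)) * np.sqrt(KB * T / self.k)
        return 0.5 * self.k * (x ** 2).sum(axis=1)
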