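"""Random-walk Metropolis-Hastings benchmark for the stochastic inverse problem.

The sampler is deliberately the simplest possible baseline against which the
conditional GAN is compared: an isotropic Gaussian random walk over the
varied conductances with a uniform prior on [0, 2*mu_p] and a Gaussian
pseudo-likelihood on the standardized discrepancy between simulated and
target features,

    log L(theta) = -1/2 * sum_f ((F_f(theta) - y_f) / h_f)^2,

with per-feature bandwidths h_f (by default the feature standard deviations
over the training sweep). One chain is run per target feature vector and the
post-burn-in draws are thinned to the requested sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence
import warnings

import numpy as np

__all__ = ["MCMCConfig", "mh_sample", "mh_chain"]


@dataclass
class MCMCConfig:
    """Metropolis-Hastings settings.

    ``proposal_scale`` defaults to 10% of each prior width; ``bandwidths``
    are the pseudo-likelihood kernel widths per feature.
    """

    prior_low: np.ndarray
    prior_high: np.ndarray
    bandwidths: Optional[np.ndarray] = None
    proposal_scale: Optional[np.ndarray] = None
    n_steps: int = 10_000
    burn_in: int = 2_000
    thin: Optional[int] = None        # derived from requested n if None
    seed: int = 0

    def __post_init__(self):
        self.prior_low = np.asarray(self.prior_low, float)
        self.prior_high = np.asarray(self.prior_high, float)
        if self.n_steps <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.proposal_scale is None:
            self.proposal_scale = 0.1 * (self.prior_high - self.prior_low)
        self.proposal_scale = np.asarray(self.proposal_scale, float)
        if self.bandwidths is not None:
            self.bandwidths = np.asarray(self.bandwidths, float)
            if np.any(self.bandwidths <= 0):
                raise ValueError("bandwidths must be positive")


def mh_chain(log_density: Callable[[np.ndarray], float], x0: np.ndarray,
             config: MCMCConfig, rng: Optional[np.random.Generator] = None
             ) -> tuple[np.ndarray, float]:
    """One random-walk MH chain targeting ``log_density`` on the prior box.

    Returns (all post-burn-in states, acceptance rate). Proposals falling
    outside the box are rejected through the prior factor (-inf density).
    """
    rng = rng or np.random.default_rng(config.seed)
    d = len(x0)
    x = np.asarray(x0, float).copy()
    lp = log_density(x)
    out = np.empty((config.n_steps - config.burn_in, d))
    accepted = 0
    window_rejects = 0
    for step in range(config.n_steps):
        prop = x + config.proposal_scale * rng.standard_normal(d)
        if np.any(prop < config.prior_low) or np.any(prop > config.prior_high):
            lp_prop = -np.inf
        else:
            lp_prop = log_density(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
            window_rejects = 0
        else:
            window_rejects += 1
            if window_rejects == 1000:
                warnings.warn(
                    f"no acceptance over 1000 consecutive proposals at step "
                    f"{step}; proposal scale {config.proposal_scale} may be "
                    f"too large", RuntimeWarning)
        if step >= config.burn_in:
            out[step - config.burn_in] = x
    return out, accepted / config.n_steps


def mh_sample(targets: np.ndarray, forward: Callable[[np.ndarray], np.ndarray],
              config: MCMCConfig, n_per_target: int = 1,
              log_density: Optional[Callable] = None) -> dict:
    """Parameter samples for one or many target feature vectors.

    ``forward`` maps a parameter vector to its feature vector (NaN where the
    simulation fails, which contributes -inf log-likelihood). When
    ``log_density`` is given it replaces the pseudo-likelihood entirely
    (used for analytic sanity checks). One independent chain runs per target
    vector, seeded deterministically from ``config.seed``.

    Returns a dict with ``samples`` (n_targets * n_per_target, d) stacked in
    target order and ``acceptance`` per chain.
    """
    targets = np.atleast_2d(np.asarray(targets, float))
    d = len(config.prior_low)
    mid = 0.5 * (config.prior_low + config.prior_high)
    all_samples = []
    acc = []
    for i, y in enumerate(targets):
        rng = np.random.default_rng((config.seed, i))

        if log_density is not None:
            ld = log_density
        else:
            if config.bandwidths is None:
                raise ValueError("bandwidths required for the pseudo-likelihood")

            def ld(theta, _y=y):
                f = forward(theta)
                if f is None or np.any(~np.isfinite(f)):
                    return -np.inf
                r = (f - _y) / config.bandwidths
                return -0.5 * float(r @ r)

        chain, a = mh_chain(ld, mid, config, rng)
        thin = config.thin or max(len(chain) // max(n_per_target, 1), 1)
        all_samples.append(chain[thin - 1::thin][:n_per_target])
        acc.append(a)
    return {"samples": np.vstack(all_samples), "acceptance": np.array(acc)}
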