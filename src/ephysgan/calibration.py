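"""Model calibration: differential-evolution trace fitting and Sobol screening.

Two tools used before the inverse model is trained:

* :func:`de_fit` minimizes an objective (typically the summed squared error
  between simulated and category-average voltage traces) over maximal
  conductances with differential evolution (DE/rand/1/bin). Two modes mirror
  the study design: the 8 maximal conductances free, or those plus the
  half-activation voltage of the transient sodium current (``V_mNaT``).

* :func:`sobol_screen` ranks parameters by variance-based (Sobol) sensitivity
  of the 13 features, using Saltelli sampling with the Jansen total-effect
  estimator. Parameters whose feature-averaged total-effect index exceeds 0.1
  are flagged highly influential; the others can be held fixed when building
  the training sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from scipy.stats import qmc

from . import model as M
from .datasets import ForwardModel

__all__ = [
    "DEConfig",
    "DEResult",
    "SobolResult",
    "objective_trace_sse",
    "TraceSSEObjective",
    "de_fit",
    "sobol_screen",
    "sobol_indices",
    "NO_AP_PENALTY",
]

#: objective value assigned to candidates whose simulation fails or never spikes
NO_AP_PENALTY = 1e9


@dataclass
class DEConfig:
    """Differential-evolution settings (DE/rand/1/bin, Storn-Price defaults:
    population 15 x dim, F=0.8, CR=0.9)."""

    bounds: dict                      # name -> (low, high)
    popsize: int = 15                 # members per free dimension
    mutation: float = 0.8             # F
    recombination: float = 0.9        # CR
    max_generations: int = 100
    tol: float = 1e-8
    seed: int = 0
    polish: bool = False
    vectorized: bool = True

    def __post_init__(self):
        if not 0 < self.recombination <= 1:
            raise ValueError("CR must be in (0, 1]")
        if self.mutation <= 0:
            raise ValueError("F must be positive")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with low < high")


@dataclass
class DEResult:
    x: dict                           # name -> fitted value
    fun: float
    convergence: list                 # per-generation best objective
    nfev: int


class TraceSSEObjective:
    """Summed squared error between simulated and target voltage traces.

    Targets are one or more categories, each holding an average trace per
    protocol on the protocol's output grid. Candidates whose simulation fails
    or (for the depolarizing protocol) never crosses the spike-detection
    level incur :data:`NO_AP_PENALTY`. Calls accept a single parameter vector
    or a population matrix (vectorized evaluation for DE).
    """

    def __init__(self, targets: Sequence[dict], free: Sequence[str],
                 base: Optional[M.ModelParameters] = None,
                 dep_protocol: Optional[M.StimulusProtocol] = None,
                 hyp_protocol: Optional[M.StimulusProtocol] = None,
                 dt_dep: float = 0.02, dt_hyp: float = 0.05,
                 spike_level: float = -20.0):
        self.free = tuple(free)
        self.base = base or M.default_parameters()
        self.dep_protocol = dep_protocol or M.depolarizing_protocol()
        self.hyp_protocol = hyp_protocol or M.hyperpolarizing_protocol()
        self.dt_dep, self.dt_hyp = dt_dep, dt_hyp
        self.spike_level = spike_level
        self.targets = list(targets)
        self.n_failed = 0

    def _param_sets(self, X: np.ndarray) -> list:
        sets = []
        for row in X:
            kw = {}
            params = self.base
            for name, v in zip(self.free, row):
                if name == "V_mNaT":
                    params = params.with_gate("m_NaT", v_half=float(v))
                else:
                    kw[name] = float(v)
            sets.append(params.replace(**kw))
        return sets

    def __call__(self, X: np.ndarray) -> np.ndarray | float:
        X = np.asarray(X, float)
        scalar = X.ndim == 1
        # scipy's vectorized interface passes (n_params, S)
        pop = X[None, :] if scalar else X.T
        sets = self._param_sets(pop)
        sse = np.zeros(len(sets))
        _, Vd, sd = M.simulate_batch(sets, self.dep_protocol, dt=self.dt_dep)
        _, Vh, sh = M.simulate_batch(sets, self.hyp_protocol, dt=self.dt_hyp)
        for j in range(len(sets)):
            if sd[j] != 0 or sh[j] != 0 or Vd[j].max() < self.spike_level:
                sse[j] = NO_AP_PENALTY
                self.n_failed += 1
                continue
            acc = 0.0
            for tgt in self.targets:
                acc += float(np.sum((Vd[j] - tgt["dep"]) ** 2))
                acc += float(np.sum((Vh[j] - tgt["hyp"]) ** 2))
            sse[j] = acc
        return float(sse[0]) if scalar else sse


def objective_trace_sse(params_vector: np.ndarray,
                        objective: TraceSSEObjective) -> float:
    """Scalar evaluation of a :class:`TraceSSEObjective` candidate."""
    return float(objective(np.asarray(params_vector, float)))


def de_fit(objective: Callable, config: DEConfig) -> DEResult:
    """Global minimization by differential evolution within box bounds.

    ``objective`` must accept an (n_params,) vector, or an (n_params, S)
    population when ``config.vectorized`` (as scipy's vectorized interface
    passes it). Candidates never leave the bounds.
    """
    names = list(config.bounds)
    bounds = [config.bounds[n] for n in names]
    best_per_gen = []

    def callback(xk, convergence=0.0):
        best_per_gen.append(np.asarray(xk, float).copy())

    res = differential_evolution(
        objective, bounds, strategy="rand1bin",
        popsize=config.popsize, mutation=config.mutation,
        recombination=config.recombination, maxiter=config.max_generations,
        tol=config.tol, seed=config.seed, polish=config.polish,
        vectorized=config.vectorized, updating="deferred",
        callback=callback, init="sobol")
    if best_per_gen:
        G = np.asarray(best_per_gen)
        conv = list(np.atleast_1d(
            objective(G.T) if config.vectorized
            else np.array([objective(x) for x in G])))
        conv = [float(v) for v in conv]
    else:
        conv = []
    return DEResult(x=dict(zip(names, res.x)), fun=float(res.fun),
                    convergence=conv, nfev=int(res.nfev))


# ---------------------------------------------------------------------------
# Sobol variance-based screening
# ---------------------------------------------------------------------------

@dataclass
class SobolResult:
    """First-order (S1) and total-effect (ST) indices per (parameter, output),
    their across-output averages, and the retained parameter set."""

    s1: pd.DataFrame                  # parameters x outputs
    st: pd.DataFrame
    s1_mean: pd.Series
    st_mean: pd.Series
    retained: tuple
    n_base: int
    excluded_outputs: tuple = ()


def sobol_indices(func: Callable, bounds: dict, n_base: int, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Saltelli-sampled Sobol indices of a vector-valued function.

    ``func`` maps an (n, d) matrix to an (n, m) output; returns (S1, ST)
    with shape (d, m) plus the validity mask of outputs. S1 uses the
    Saltelli-2010 estimator, ST the Jansen estimator; ``n_base`` should be a
    power of 2 for the scrambled-Sobol base sample.
    """
    if n_base & (n_base - 1):
        raise ValueError("n_base must be a power of 2")
    names = list(bounds)
    d = len(names)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    eng = qmc.Sobol(2 * d, scramble=True, seed=seed)
    base = eng.random(n_base)
    A = lo + base[:, :d] * (hi - lo)
    B = lo + base[:, d:] * (hi - lo)
    fA = np.asarray(func(A), float).reshape(n_base, -1)
    fB = np.asarray(func(B), float).reshape(n_base, -1)
    m = fA.shape[1]
    S1 = np.empty((d, m))
    ST = np.empty((d, m))
    var = np.var(np.vstack([fA, fB]), axis=0, ddof=0)
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = np.atleast_2d(np.asarray(func(ABi), float)).reshape(n_base, -1)
        with np.errstate(divide="ignore", invalid="ignore"):
            S1[i] = np.mean(fB * (fABi - fA), axis=0) / var
            ST[i] = 0.5 * np.mean((fA - fABi) ** 2, axis=0) / var
    valid = var > 0
    return S1, ST, valid


def sobol_screen(func: Callable, bounds: dict, n_base: int = 1024,
                 seed: int = 0, output_names: Optional[Sequence[str]] = None,
                 threshold: float = 0.1) -> SobolResult:
    """Screen parameters by feature-averaged Sobol indices.

    ``func`` is the parameters -> outputs pushforward (for the CA1 problem:
    simulate both protocols and extract the 13 features; rows that fail may
    carry NaN and are dropped before estimation by the caller or tolerated
    here via nan-aware means). Outputs with zero variance are excluded from
    the averages. Parameters with mean total-effect index above ``threshold``
    form the retained set.
    """
    names = list(bounds)
    S1, ST, valid = sobol_indices(func, bounds, n_base, seed)
    out_names = (list(output_names) if output_names is not None
                 else [f"y{j}" for j in range(S1.shape[1])])
    s1 = pd.DataFrame(S1, index=names, columns=out_names)
    st = pd.DataFrame(ST, index=names, columns=out_names)
    keep = [c for c, v in zip(out_names, valid) if v]
    excluded = tuple(c for c, v in zip(out_names, valid) if not v)
    s1_mean = s1[keep].mean(axis=1)
    st_mean = st[keep].mean(axis=1)
    retained = tuple(n for n in names if st_mean[n] > threshold)
    return SobolResult(s1=s1, st=st, s1_mean=s1_mean, st_mean=st_mean,
                       retained=retained, n_base=n_base,
                       excluded_outputs=excluded)


def feature_pushforward(forward: Optional[ForwardModel] = None) -> Callable:
    """Parameters -> 13-feature matrix function for :func:`sobol_screen`.

    Failed rows are imputed with the column mean of the successful rows so
    the estimators stay finite; the discarded fraction is reported via the
    returned function's ``last_discard_fraction`` attribute.
    """
    fm = forward or ForwardModel()

    def func(X: np.ndarray) -> np.ndarray:
        feats, ok = fm.features(X)
        out = feats.to_numpy()
        if (~ok).any():
            col_mean = np.nanmean(np.where(ok[:, None], out, np.nan), axis=0)
            out = np.where(ok[:, None], out, col_mean)
        func.last_discard_fraction = float((~ok).mean())
        return out

    func.last_discard_fraction = 0.0
    return func
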