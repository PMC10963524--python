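"""Synthetic dataset generation for training and validating the inverse model.

Every dataset the pipeline consumes is produced here:

* uniform training sweeps over the five varied conductances,
* clamped-normal synthetic target populations,
* enumerated two-group ("wildtype vs mutant") parameter-structure scenarios,
* a four-category experimental mimic standing in for the unavailable
  patch-clamp recordings,
* the Rosenbrock toy problem used to illustrate GAN training.

The five varied conductances are g_NaT, g_CaH, g_KDR, g_KM and g_H (the
sensitivity screening retains these; g_NaP, g_CaT and g_L stay at their
defaults). Training draws are i.i.d. uniform on [0, 2*mu_p] per conductance
(bounds at +/-100% of the default mu_p); target populations draw from
N(mu, (mu_p/8)^2) with values clamped to [0, 2*mu_p].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from . import features as F
from . import model as M

__all__ = [
    "VARIED_CONDUCTANCES",
    "ParameterBounds",
    "ForwardModel",
    "TrainingDataset",
    "TwoGroupScenario",
    "make_training_dataset",
    "sample_truncated_normal",
    "enumerate_scenarios",
    "make_two_group_targets",
    "make_category_mimic",
    "rosenbrock_dataset",
    "rosenbrock",
    "CATEGORIES",
    "DEFAULT_CELL_COUNTS",
]

#: the conductances varied in training and inference, in canonical order
VARIED_CONDUCTANCES = ("g_NaT", "g_CaH", "g_KDR", "g_KM", "g_H")

#: experimental-mimic categories and their cell counts
CATEGORIES = ("WT12", "rTg4510", "WT24", "PDAPP")
DEFAULT_CELL_COUNTS = {"WT12": 26, "rTg4510": 26, "WT24": 19, "PDAPP": 30}


@dataclass(frozen=True)
class Box:
    """Generic named axis-aligned parameter box (used e.g. by the toy
    problems; conductance sweeps use :class:`ParameterBounds`)."""

    _names: tuple
    _low: np.ndarray
    _high: np.ndarray

    @property
    def names(self) -> tuple:
        return tuple(self._names)

    @property
    def low(self) -> np.ndarray:
        return np.asarray(self._low, float)

    @property
    def high(self) -> np.ndarray:
        return np.asarray(self._high, float)


@dataclass(frozen=True)
class ParameterBounds:
    """Default values mu_p and [0, 2*mu_p] bounds for the varied parameters."""

    mu: dict

    def __post_init__(self):
        for name, v in self.mu.items():
            if v <= 0:
                raise ValueError(f"default for {name} must be positive")

    @classmethod
    def from_defaults(cls, params: Optional[M.ModelParameters] = None,
                      names: Sequence[str] = VARIED_CONDUCTANCES
                      ) -> "ParameterBounds":
        params = params or M.default_parameters()
        return cls(mu={n: float(getattr(params, n)) for n in names})

    @property
    def names(self) -> tuple:
        return tuple(self.mu)

    @property
    def low(self) -> np.ndarray:
        return np.zeros(len(self.mu))

    @property
    def high(self) -> np.ndarray:
        return 2.0 * np.array(list(self.mu.values()))

    @property
    def centers(self) -> np.ndarray:
        return np.array(list(self.mu.values()))


class ForwardModel:
    """The push-forward map from varied conductances to the 13 features.

    Simulates both current-clamp protocols with the compiled fixed-step
    integrator (chunked to bound memory) and extracts features. Rows whose
    simulation fails, that do not spike, or whose hyperpolarization fit fails
    are flagged rather than raising.
    """

    def __init__(self, base: Optional[M.ModelParameters] = None,
                 varied: Sequence[str] = VARIED_CONDUCTANCES,
                 dep_protocol: Optional[M.StimulusProtocol] = None,
                 hyp_protocol: Optional[M.StimulusProtocol] = None,
                 dt_dep: float = 0.02, dt_hyp: float = 0.05,
                 chunk: int = 256):
        self.base = base or M.default_parameters()
        self.varied = tuple(varied)
        self.dep_protocol = dep_protocol or M.depolarizing_protocol()
        self.hyp_protocol = hyp_protocol or M.hyperpolarizing_protocol()
        self.dt_dep = dt_dep
        self.dt_hyp = dt_hyp
        self.chunk = chunk

    def param_sets(self, X: np.ndarray) -> list:
        X = np.atleast_2d(X)
        return [self.base.replace(**dict(zip(self.varied, row))) for row in X]

    def features(self, X: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
        """Features for an (n, n_varied) parameter matrix.

        Returns a DataFrame with the 13 canonical columns (NaN where the
        forward map failed) and a boolean validity mask.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(X)
        out = np.full((n, 13), np.nan)
        ok = np.zeros(n, dtype=bool)
        for lo in range(0, n, self.chunk):
            sl = slice(lo, min(lo + self.chunk, n))
            sets = self.param_sets(X[sl])
            td, Vd, sd = M.simulate_batch(sets, self.dep_protocol, dt=self.dt_dep)
            th, Vh, sh = M.simulate_batch(sets, self.hyp_protocol, dt=self.dt_hyp)
            for j in range(len(sets)):
                if sd[j] != 0 or sh[j] != 0:
                    continue
                try:
                    fv = F.extract_features(
                        M.VoltageTrace(td, Vd[j], self.dep_protocol),
                        M.VoltageTrace(th, Vh[j], self.hyp_protocol))
                except (F.NoAPError, RuntimeError, ValueError):
                    continue
                out[lo + j] = fv.to_array()
                ok[lo + j] = True
        return pd.DataFrame(out, columns=list(F.FEATURE_NAMES)), ok

    def mean_traces(self, X: np.ndarray) -> dict:
        """Mean depolarizing/hyperpolarizing traces over a parameter matrix."""
        sets = self.param_sets(X)
        td, Vd, sd = M.simulate_batch(sets, self.dep_protocol, dt=self.dt_dep)
        th, Vh, sh = M.simulate_batch(sets, self.hyp_protocol, dt=self.dt_hyp)
        return {
            "t_dep": td, "V_dep_mean": Vd[sd == 0].mean(axis=0),
            "V_dep_sd": Vd[sd == 0].std(axis=0),
            "t_hyp": th, "V_hyp_mean": Vh[sh == 0].mean(axis=0),
            "V_hyp_sd": Vh[sh == 0].std(axis=0),
        }


@dataclass
class TrainingDataset:
    """Paired (parameters, features) table with normalization metadata."""

    params: pd.DataFrame      # n x n_varied
    features: pd.DataFrame    # n x 13
    bounds: ParameterBounds
    discarded: int
    seed: int

    def __post_init__(self):
        if len(self.params) != len(self.features):
            raise ValueError("parameter and feature tables must align")

    @property
    def n(self) -> int:
        return len(self.params)

    @property
    def normalization(self) -> dict:
        """Per-column offset/scale: features are z-scored, parameters
        min-max scaled to [0, 1] by their bounds."""
        return {
            "feature_mean": self.features.mean(),
            "feature_std": self.features.std(ddof=0).replace(0.0, 1.0),
            "param_low": pd.Series(self.bounds.low, index=self.bounds.names),
            "param_high": pd.Series(self.bounds.high, index=self.bounds.names),
        }

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("params", data=self.params.to_numpy())
            f.create_dataset("features", data=self.features.to_numpy())
            f.attrs["param_names"] = list(self.params.columns)
            f.attrs["feature_names"] = list(self.features.columns)
            f.attrs["low"] = self.bounds.low
            f.attrs["high"] = self.bounds.high
            f.attrs["discarded"] = self.discarded
            f.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path: str) -> "TrainingDataset":
        with h5py.File(path, "r") as f:
            pnames = [str(s) for s in f.attrs["param_names"]]
            fnames = [str(s) for s in f.attrs["feature_names"]]
            low = np.asarray(f.attrs["low"], float)
            high = np.asarray(f.attrs["high"], float)
            if np.allclose(low, 0.0):
                bounds = ParameterBounds(mu=dict(zip(pnames, high / 2.0)))
            else:
                bounds = Box(tuple(pnames), low, high)
            return cls(
                params=pd.DataFrame(f["params"][:], columns=pnames),
                features=pd.DataFrame(f["features"][:], columns=fnames),
                bounds=bounds,
                discarded=int(f.attrs["discarded"]),
                seed=int(f.attrs["seed"]),
            )


#: full-scale simulation count used in the reference study configuration
PAPER_SCALE_TRAINING_N = 3_000_000


def make_training_dataset(n: int, bounds: Optional[ParameterBounds] = None,
                          seed: int = 0,
                          forward: Optional[ForwardModel] = None,
                          max_discard_fraction: float = 0.9
                          ) -> TrainingDataset:
    """Uniform sweep over the varied conductances with feature extraction.

    Parameters are i.i.d. uniform on [0, 2*mu_p]. Draws whose forward map
    fails (typically: no action potential) are discarded and redrawn until
    ``n`` valid rows exist; the discard count is recorded. Aborts when the
    discard fraction exceeds ``max_discard_fraction``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    bounds = bounds or ParameterBounds.from_defaults()
    forward = forward or ForwardModel(varied=bounds.names)
    rng = np.random.default_rng(seed)
    kept_X, kept_F = [], []
    n_kept = 0
    discarded = 0
    while n_kept < n:
        m = max(n - n_kept, 32)
        X = rng.uniform(bounds.low, bounds.high, size=(m, len(bounds.names)))
        feats, ok = forward.features(X)
        kept_X.append(X[ok])
        kept_F.append(feats[ok])
        n_kept += int(ok.sum())
        discarded += int((~ok).sum())
        total = n_kept + discarded
        if total >= max(200, n) and discarded / total > max_discard_fraction:
            raise RuntimeError(
                f"discard fraction {discarded/total:.2f} exceeds "
                f"{max_discard_fraction}; check the model configuration")
    X = np.vstack(kept_X)[:n]
    feats = pd.concat(kept_F, ignore_index=True).iloc[:n].reset_index(drop=True)
    return TrainingDataset(
        params=pd.DataFrame(X, columns=list(bounds.names)),
        features=feats, bounds=bounds, discarded=discarded, seed=seed)


def sample_truncated_normal(mu: float, sigma: Optional[float] = None,
                            low: float = 0.0, high: Optional[float] = None,
                            n: int = 1,
                            rng: np.random.Generator | int | None = None
                            ) -> np.ndarray:
    """Normal draws clamped (not resampled) to [low, high].

    ``sigma`` defaults to mu/8 and ``high`` to 2*mu, the target-population
    convention; out-of-range draws are set to the violated bound, so the
    realized moments are slightly biased toward the interior.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sigma is None:
        sigma = abs(mu) / 8.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if high is None:
        high = 2.0 * mu if mu > 0 else np.inf
    x = rng.normal(mu, sigma, size=n)
    return np.clip(x, low, high)


@dataclass(frozen=True)
class TwoGroupScenario:
    """Which of the varied conductances differ between groups G1 and G2.

    ``signs[i] = +1`` means the i-th altered parameter has the low mean
    (0.5*mu_p) in G1 and the high mean (1.5*mu_p) in G2; ``-1`` the reverse.
    Scenarios are counted modulo a global group swap, canonicalized by fixing
    the first altered parameter to +1.
    """

    subset: tuple
    signs: tuple
    n_per_group: int = 100

    def __post_init__(self):
        if len(self.subset) != len(self.signs):
            raise ValueError("subset and signs must have equal length")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs are +/-1")

    @property
    def k(self) -> int:
        return len(self.subset)

    @property
    def label(self) -> str:
        return "+".join(f"{n}{'^' if s > 0 else 'v'}"
                        for n, s in zip(self.subset, self.signs))


def enumerate_scenarios(k: int, names: Sequence[str] = VARIED_CONDUCTANCES,
                        n_per_group: int = 100) -> list[TwoGroupScenario]:
    """All C(5,k) * 2^(k-1) distinct two-group structures with k altered
    parameters, in deterministic order (lexicographic subset, then binary
    sign code with the first altered parameter fixed to +1)."""
    if not 1 <= k <= len(names):
        raise ValueError(f"k must be in 1..{len(names)}")
    out = []
    for subset in itertools.combinations(names, k):
        for rest in itertools.product((1, -1), repeat=k - 1):
            out.append(TwoGroupScenario(subset=subset, signs=(1,) + rest,
                                        n_per_group=n_per_group))
    return out


def _group_param_draws(bounds: ParameterBounds, means: np.ndarray, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    cols = [
        sample_truncated_normal(mu=means[i], sigma=bounds.centers[i] / 8.0,
                                low=0.0, high=bounds.high[i], n=n, rng=rng)
        for i in range(len(bounds.names))
    ]
    return np.column_stack(cols)


def make_two_group_targets(scenario: TwoGroupScenario,
                           bounds: Optional[ParameterBounds] = None,
                           seed: int = 0,
                           forward: Optional[ForwardModel] = None,
                           ) -> dict:
    """Target parameter draws and simulated features for both groups.

    Unaltered parameters are N(mu_p, (mu_p/8)^2) in both groups; altered
    parameters have mean 0.5*mu_p or 1.5*mu_p per the sign pattern. All
    draws are clamped to [0, 2*mu_p]. Draws whose forward map fails are
    redrawn so each group has ``n_per_group`` complete rows.
    """
    bounds = bounds or ParameterBounds.from_defaults()
    forward = forward or ForwardModel(varied=bounds.names)
    rng = np.random.default_rng(seed)
    result = {}
    for group in (1, 2):
        means = bounds.centers.copy()
        for name, sign in zip(scenario.subset, scenario.signs):
            i = bounds.names.index(name)
            low_here = (sign > 0) == (group == 1)
            means[i] = (0.5 if low_here else 1.5) * bounds.centers[i]
        X_rows, F_rows = [], []
        n_kept = 0
        n_failed = 0
        while n_kept < scenario.n_per_group:
            m = scenario.n_per_group - n_kept
            X = _group_param_draws(bounds, means, m, rng)
            feats, ok = forward.features(X)
            X_rows.append(X[ok])
            F_rows.append(feats[ok])
            n_kept += int(ok.sum())
            n_failed += int((~ok).sum())
            if n_failed > 50 * scenario.n_per_group:
                raise RuntimeError(
                    f"group {group} of scenario {scenario.label}: forward "
                    f"map failed {n_failed} times")
        result[f"G{group}"] = {
            "params": pd.DataFrame(np.vstack(X_rows), columns=list(bounds.names)),
            "features": pd.concat(F_rows, ignore_index=True),
            "n_failed": n_failed,
        }
    return result


def make_category_mimic(shifts: Optional[dict] = None,
                        n_cells: Optional[dict] = None,
                        bounds: Optional[ParameterBounds] = None,
                        seed: int = 0,
                        forward: Optional[ForwardModel] = None
                        ) -> pd.DataFrame:
    """Labeled per-cell feature table emulating the four mouse categories.

    Synthetic stand-in for the unavailable patch-clamp recordings: each
    category draws conductances from clamped normals whose means are the
    defaults times a per-category, per-conductance multiplier. With all
    multipliers at 1.0 the categories are exchangeable.

    ``shifts`` maps category -> {conductance: multiplier}; ``n_cells`` maps
    category -> count (defaults: WT12 26, rTg4510 26, WT24 19, PDAPP 30).
    """
    bounds = bounds or ParameterBounds.from_defaults()
    forward = forward or ForwardModel(varied=bounds.names)
    shifts = shifts or {}
    n_cells = n_cells or dict(DEFAULT_CELL_COUNTS)
    rng = np.random.default_rng(seed)
    frames = []
    for cat in CATEGORIES:
        mult = shifts.get(cat, {})
        means = np.array([bounds.mu[n] * mult.get(n, 1.0)
                          for n in bounds.names])
        n_kept = 0
        rows_X, rows_F = [], []
        while n_kept < n_cells[cat]:
            X = _group_param_draws(bounds, means, n_cells[cat] - n_kept, rng)
            feats, ok = forward.features(X)
            rows_X.append(X[ok])
            rows_F.append(feats[ok])
            n_kept += int(ok.sum())
        df = pd.concat(rows_F, ignore_index=True)
        dfp = pd.DataFrame(np.vstack(rows_X),
                           columns=[f"true_{n}" for n in bounds.names])
        df = pd.concat([df, dfp], axis=1)
        df.insert(0, "category", cat)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "cell_id", np.arange(len(out)))
    return out


def rosenbrock(X1, X2):
    """Y = (1 - X1)^2 + 100*(X2 - X1^2)^2."""
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    return (1.0 - X1) ** 2 + 100.0 * (X2 - X1 ** 2) ** 2


#: full-scale sample count for the Rosenbrock illustration
PAPER_SCALE_ROSENBROCK_N = 1_000_000


def rosenbrock_dataset(n: int, low: float = -5.0, high: float = 5.0,
                       seed: int = 0) -> pd.DataFrame:
    """(X1, X2, Y) with X1, X2 i.i.d. uniform on [low, high]."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    X1 = rng.uniform(low, high, n)
    X2 = rng.uniform(low, high, n)
    return pd.DataFrame({"X1": X1, "X2": X2, "Y": rosenbrock(X1, X2)})


def rosenbrock_training_dataset(n: int, low: float = -5.0, high: float = 5.0,
                                seed: int = 0) -> TrainingDataset:
    """Rosenbrock toy wrapped as a GAN training dataset (Y is the feature)."""
    df = rosenbrock_dataset(n, low, high, seed)
    return TrainingDataset(
        params=df[["X1", "X2"]], features=df[["Y"]],
        bounds=Box(("X1", "X2"), np.array([low, low]), np.array([high, high])),
        discarded=0, seed=seed)
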