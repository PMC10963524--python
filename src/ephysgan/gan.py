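"""Conditional GAN solver for the stochastic inverse problem.

The generator G(z||y) maps a Gaussian latent z and a feature vector y (the
condition) to a parameter set; the discriminator D(x||y) scores whether a
(parameters, features) pair comes from the training data or from G. Training
minimizes the implemented adversarial losses

    D:  - E[log D(x||y)] - E[log(1 - D(G(z||y)||y))]
    G:    E[log(1 - D(G(z||y)||y))] - E[log D(G(z||y)||y)]

(the generator uses the non-saturating variant). The discriminator is
*unrolled*: the generator's gradient is taken against a copy of the
discriminator advanced by several inner Adam steps, which stabilizes training
against mode collapse. Every few iterations the generator is checkpointed and
scored by the Jensen-Shannon divergence between its pushforward and a
held-out slice of the training data; the minimum-JSD checkpoint is the
selected model (training quality degrades past an optimum as gradients
vanish, so the JSD acts as the stopping criterion).

Everything runs in NumPy with hand-written backpropagation; the networks are
plain ReLU multi-layer perceptrons.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import TrainingDataset

__all__ = [
    "GANConfig",
    "TrainedGenerator",
    "adversarial_losses",
    "jsd",
    "jsd_discrete",
    "train",
    "sample",
]

_PROB_CLIP = 1e-7


# ---------------------------------------------------------------------------
# Losses and divergence
# ---------------------------------------------------------------------------

def adversarial_losses(p_real: np.ndarray, p_fake: np.ndarray
                       ) -> tuple[float, float]:
    """Implemented (discriminator, generator) losses from D's probabilities.

    ``p_real`` are D's outputs on real pairs, ``p_fake`` on generated pairs;
    probabilities are clipped to [1e-7, 1 - 1e-7] before the logarithms.
    """
    pr = np.clip(np.asarray(p_real, float), _PROB_CLIP, 1 - _PROB_CLIP)
    pf = np.clip(np.asarray(p_fake, float), _PROB_CLIP, 1 - _PROB_CLIP)
    d_loss = -np.mean(np.log(pr)) - np.mean(np.log(1 - pf))
    g_loss = np.mean(np.log(1 - pf)) - np.mean(np.log(pf))
    if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
        raise FloatingPointError(
            f"non-finite adversarial loss (d={d_loss}, g={g_loss})")
    return float(d_loss), float(g_loss)


def jsd_discrete(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (log base 2, in [0, 1]) of two discrete
    distributions on the same support."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def jsd_pairwise(samples_a: np.ndarray, samples_b: np.ndarray,
                 pairs: Sequence[tuple], bins: int = 12,
                 eps: float = 1e-10,
                 ranges: Optional[np.ndarray] = None) -> float:
    """JSD averaged over 2-D histograms of selected dimension pairs.

    Unlike per-dimension marginals, 2-D pair histograms respond to changes
    in the *dependence* between dimensions (e.g. parameter-feature
    coupling), which is what distinguishes a conditionally accurate
    generator from one that merely matches marginals.
    """
    A = np.asarray(samples_a, float)
    B = np.asarray(samples_b, float)
    if A.size == 0 or B.size == 0:
        raise ValueError("empty sample set")
    vals = []
    for (i, j) in pairs:
        edges = []
        for d in (i, j):
            if ranges is not None:
                lo, hi = ranges[d]
            else:
                lo = min(A[:, d].min(), B[:, d].min())
                hi = max(A[:, d].max(), B[:, d].max())
            if hi <= lo:
                hi = lo + 1.0
            edges.append(np.linspace(lo, hi, bins + 1))
        ha, _, _ = np.histogram2d(np.clip(A[:, i], edges[0][0], edges[0][-1]),
                                  np.clip(A[:, j], edges[1][0], edges[1][-1]),
                                  bins=edges)
        hb, _, _ = np.histogram2d(np.clip(B[:, i], edges[0][0], edges[0][-1]),
                                  np.clip(B[:, j], edges[1][0], edges[1][-1]),
                                  bins=edges)
        vals.append(jsd_discrete(ha.ravel() + eps, hb.ravel() + eps))
    return float(np.mean(vals))


def jsd(samples_a: np.ndarray, samples_b: np.ndarray, bins: int = 20,
        eps: float = 1e-10, ranges: Optional[np.ndarray] = None) -> float:
    """Histogram-based JSD between two sample sets, averaged over dimensions.

    Each dimension is binned on a shared grid spanning both sample sets
    (with ``eps`` smoothing), its base-2 JSD computed, and the per-dimension
    values averaged; the result lies in [0, 1]. A dense joint histogram is
    hopeless beyond a few dimensions, so the joint space is summarized
    through its marginals.
    """
    A = np.asarray(samples_a, float)
    B = np.asarray(samples_b, float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.size == 0 or B.size == 0:
        raise ValueError("empty sample set")
    if A.shape[1] != B.shape[1]:
        raise ValueError("sample sets must share dimensionality")
    vals = []
    for d in range(A.shape[1]):
        if ranges is not None:
            lo, hi = ranges[d]
        else:
            lo = min(A[:, d].min(), B[:, d].min())
            hi = max(A[:, d].max(), B[:, d].max())
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
        # clip into the grid so out-of-range mass lands in the edge bins
        # instead of silently vanishing before normalization
        pa, _ = np.histogram(np.clip(A[:, d], lo, hi), bins=edges)
        pb, _ = np.histogram(np.clip(B[:, d], lo, hi), bins=edges)
        vals.append(jsd_discrete(pa + eps, pb + eps))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Multi-layer perceptron with manual backprop
# ---------------------------------------------------------------------------

class _MLP:
    """ReLU MLP; linear output. Parameters live in ``W``/``b`` lists."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.sizes = tuple(sizes)
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                             size=(sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, x: np.ndarray, cache: Optional[list] = None) -> np.ndarray:
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            if cache is not None:
                cache.append(h)
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
        return h

    def backward(self, cache: list, grad_out: np.ndarray
                 ) -> tuple[list, list, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(output).

        Returns (dW list, db list, d(loss)/d(input)).
        """
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        g = grad_out
        for i in reversed(range(len(self.W))):
            h_in = cache[i]
            if i < len(self.W) - 1:
                # grad through ReLU: recompute the mask from the pre-activation
                pre = h_in @ self.W[i] + self.b[i]
                g = g * (pre > 0)
            dW[i] = h_in.T @ g
            db[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return dW, db, g

    def copy(self) -> "_MLP":
        new = object.__new__(_MLP)
        new.sizes = self.sizes
        new.W = [w.copy() for w in self.W]
        new.b = [b.copy() for b in self.b]
        return new


class _Adam:
    def __init__(self, net: _MLP, lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(w) for w in net.W]
        self.vW = [np.zeros_like(w) for w in net.W]
        self.mb = [np.zeros_like(b) for b in net.b]
        self.vb = [np.zeros_like(b) for b in net.b]

    def step(self, net: _MLP, dW: list, db: list, lr: Optional[float] = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for i in range(len(net.W)):
            self.mW[i] = b1 * self.mW[i] + (1 - b1) * dW[i]
            self.vW[i] = b2 * self.vW[i] + (1 - b2) * dW[i] ** 2
            net.W[i] -= lr * corr * self.mW[i] / (np.sqrt(self.vW[i]) + self.eps)
            self.mb[i] = b1 * self.mb[i] + (1 - b1) * db[i]
            self.vb[i] = b2 * self.vb[i] + (1 - b2) * db[i] ** 2
            net.b[i] -= lr * corr * self.mb[i] / (np.sqrt(self.vb[i]) + self.eps)

    def copy(self) -> "_Adam":
        new = object.__new__(_Adam)
        new.lr, new.beta1, new.beta2, new.eps = self.lr, self.beta1, self.beta2, self.eps
        new.t = self.t
        new.mW = [m.copy() for m in self.mW]
        new.vW = [v.copy() for v in self.vW]
        new.mb = [m.copy() for m in self.mb]
        new.vb = [v.copy() for v in self.vb]
        return new


def _sigmoid(s):
    out = np.empty_like(s)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    es = np.exp(s[~pos])
    out[~pos] = es / (1.0 + es)
    return out


# ---------------------------------------------------------------------------
# Configuration and trained-model container
# ---------------------------------------------------------------------------

@dataclass
class GANConfig:
    """Hyperparameters of the conditional GAN.

    The reference-scale constants are a 3M-row dataset, minibatch 10,000,
    400 epochs and 180/130-wide 8-hidden-layer networks; ``desk()`` and
    ``smoke()`` provide scaled-down profiles for single-CPU runs.
    """

    latent_dim: int = 5
    gen_layers: tuple = (180,) * 8
    disc_layers: tuple = (130,) * 8
    epochs: int = 400
    minibatch: int = 10_000
    lr_gen: float = 1e-4
    lr_disc: float = 2e-5
    beta1: float = 0.9
    beta2: float = 0.999
    unroll_steps: int = 5
    lr_unroll: float = 5e-4
    checkpoint_interval: int = 10   # iterations between generator checkpoints
    holdout: int = 10_000           # rows reserved for the JSD score
    jsd_bins: int = 20
    feature_transform: str = "zscore"   # or "quantile" (normal scores)
    ema_decay: float = 0.0          # generator weight averaging; 0 disables
    #: weight of the generator's paired reconstruction auxiliary
    #: lambda * E||G(z||y) - x||^2 added to the adversarial loss; anchors
    #: the conditional mean while the adversarial term shapes the spread
    recon_weight: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.lr_gen, self.lr_disc, self.lr_unroll) <= 0:
            raise ValueError("step sizes must be positive")
        if self.unroll_steps < 0:
            raise ValueError("unroll_steps must be nonnegative")

    @classmethod
    def paper_scale(cls, **kw) -> "GANConfig":
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "GANConfig":
        # a desk run sees ~1000x fewer optimizer steps than the reference
        # configuration, so the step sizes are scaled up accordingly and the
        # reconstruction auxiliary anchors the conditional mean that a long
        # full-scale adversarial run would reach on its own
        kw.setdefault("gen_layers", (64, 64, 64))
        kw.setdefault("disc_layers", (64, 64, 64))
        kw.setdefault("epochs", 400)
        kw.setdefault("minibatch", 512)
        kw.setdefault("holdout", 500)
        kw.setdefault("checkpoint_interval", 20)
        kw.setdefault("lr_gen", 1e-3)
        kw.setdefault("lr_disc", 2e-4)
        kw.setdefault("lr_unroll", 1e-3)
        kw.setdefault("recon_weight", 3.0)
        return cls(**kw)

    @classmethod
    def smoke(cls, **kw) -> "GANConfig":
        kw.setdefault("gen_layers", (32, 32))
        kw.setdefault("disc_layers", (32, 32))
        kw.setdefault("epochs", 10)
        kw.setdefault("minibatch", 64)
        kw.setdefault("holdout", 100)
        kw.setdefault("checkpoint_interval", 5)
        return cls(**kw)


@dataclass
class TrainedGenerator:
    """Checkpointed generator states plus training diagnostics."""

    config: GANConfig
    param_names: tuple
    feature_names: tuple
    norm: dict                       # feature mean/std, param low/high (np arrays)
    checkpoints: list = field(default_factory=list)   # (iteration, jsd, weights)
    log: Optional[pd.DataFrame] = None  # iteration, epoch, d_loss, g_loss
    selected: int = -1               # index into checkpoints
    #: per-checkpoint JSD of the 1-D marginals of the pushforward joint (the
    #: selection score in `checkpoints` uses 2-D parameter-feature pairs,
    #: which has a higher small-sample floor)
    marginal_jsd: Optional[np.ndarray] = None

    @property
    def selected_checkpoint(self) -> tuple:
        return self.checkpoints[self.selected]

    @property
    def jsd_trace(self) -> np.ndarray:
        return np.array([c[1] for c in self.checkpoints])

    def generator_net(self, index: Optional[int] = None) -> _MLP:
        weights = self.checkpoints[self.selected if index is None else index][2]
        net = object.__new__(_MLP)
        net.W = [w.copy() for w in weights["W"]]
        net.b = [b.copy() for b in weights["b"]]
        net.sizes = tuple([net.W[0].shape[0]] + [w.shape[1] for w in net.W])
        return net

    # -- persistence --------------------------------------------------------
    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        it, js, weights = self.selected_checkpoint
        arrays = {f"W{i}": w for i, w in enumerate(weights["W"])}
        arrays.update({f"b{i}": b for i, b in enumerate(weights["b"])})
        np.savez(os.path.join(outdir, "generator.npz"), **arrays)
        meta = {
            "config": asdict(self.config),
            "param_names": list(self.param_names),
            "feature_names": list(self.feature_names),
            "norm": {k: np.asarray(v).tolist() for k, v in self.norm.items()},
            "selected_iteration": int(it),
            "selected_jsd": float(js),
        }
        with open(os.path.join(outdir, "model.json"), "w") as f:
            json.dump(meta, f, indent=1)
        if self.log is not None:
            self.log.to_csv(os.path.join(outdir, "training_log.csv"), index=False)
        pd.DataFrame(
            {"iteration": [c[0] for c in self.checkpoints],
             "jsd": [c[1] for c in self.checkpoints]}
        ).to_csv(os.path.join(outdir, "jsd_trace.csv"), index=False)

    @classmethod
    def load(cls, outdir: str) -> "TrainedGenerator":
        with open(os.path.join(outdir, "model.json")) as f:
            meta = json.load(f)
        dat = np.load(os.path.join(outdir, "generator.npz"))
        nW = len([k for k in dat.files if k.startswith("W")])
        weights = {"W": [dat[f"W{i}"] for i in range(nW)],
                   "b": [dat[f"b{i}"] for i in range(nW)]}
        cfg = GANConfig(**{**meta["config"],
                           "gen_layers": tuple(meta["config"]["gen_layers"]),
                           "disc_layers": tuple(meta["config"]["disc_layers"])})
        return cls(
            config=cfg,
            param_names=tuple(meta["param_names"]),
            feature_names=tuple(meta["feature_names"]),
            norm={k: np.asarray(v, float) for k, v in meta["norm"].items()},
            checkpoints=[(meta["selected_iteration"], meta["selected_jsd"], weights)],
            selected=0,
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

_N_QUANTILES = 257


def _transform_features(Y: np.ndarray, norm: dict) -> np.ndarray:
    """Apply the stored feature scaling (z-score or normal scores)."""
    if norm.get("feature_mode", [0.0])[0] == 1.0:
        Q = norm["feature_quantiles"]           # (d_y, K) ascending
        z = norm["quantile_scores"]             # (K,) normal scores
        out = np.empty_like(Y, dtype=float)
        for j in range(Y.shape[1]):
            out[:, j] = np.interp(Y[:, j], Q[j], z)
        return out
    return (Y - norm["feature_mean"]) / norm["feature_std"]


def _normalize(ds: TrainingDataset, config: "GANConfig"
               ) -> tuple[np.ndarray, np.ndarray, dict]:
    from scipy.stats import norm as _norm_dist

    nm = ds.normalization
    norm = {
        "feature_mean": nm["feature_mean"].to_numpy(),
        "feature_std": nm["feature_std"].to_numpy(),
        "param_low": nm["param_low"].to_numpy(),
        "param_high": nm["param_high"].to_numpy(),
        "feature_mode": np.array(
            [1.0 if config.feature_transform == "quantile" else 0.0]),
    }
    Yraw = ds.features.to_numpy()
    if config.feature_transform == "quantile":
        # monotone map of each feature through its empirical quantiles onto
        # standard-normal scores; robust to the heavy tails of spike-shape
        # features, monotone-invertible by construction
        p = np.linspace(0.005, 0.995, _N_QUANTILES)
        Q = np.quantile(Yraw, p, axis=0).T          # (d_y, K)
        # strictly increasing knots for interpolation
        Q += np.arange(_N_QUANTILES) * 1e-12
        norm["feature_quantiles"] = Q
        norm["quantile_scores"] = _norm_dist.ppf(p)
    elif config.feature_transform != "zscore":
        raise ValueError(
            f"unknown feature_transform {config.feature_transform!r}")
    X = (ds.params.to_numpy() - norm["param_low"]) / (
        norm["param_high"] - norm["param_low"])
    Y = _transform_features(Yraw, norm)
    return X, Y, norm


def _disc_grads(disc: _MLP, real_in: np.ndarray, fake_in: np.ndarray):
    cache_r, cache_f = [], []
    s_r = disc.forward(real_in, cache_r)[:, 0]
    s_f = disc.forward(fake_in, cache_f)[:, 0]
    p_r, p_f = _sigmoid(s_r), _sigmoid(s_f)
    n_r, n_f = len(s_r), len(s_f)
    # d/ds of -mean log sigma(s) and -mean log(1 - sigma(s))
    g_r = (-(1.0 - p_r) / n_r)[:, None]
    g_f = (p_f / n_f)[:, None]
    dWr, dbr, _ = disc.backward(cache_r, g_r)
    dWf, dbf, _ = disc.backward(cache_f, g_f)
    dW = [a + b for a, b in zip(dWr, dWf)]
    db = [a + b for a, b in zip(dbr, dbf)]
    return dW, db, p_r, p_f


def train(dataset: TrainingDataset, config: Optional[GANConfig] = None
          ) -> TrainedGenerator:
    """Train the conditional generator on a (parameters, features) dataset.

    Features are z-scored and parameters min-max scaled to [0, 1] before
    training; the scaling is stored with the model. Returns every checkpoint
    with the minimum-JSD one selected.
    """
    config = config or GANConfig()
    rng = np.random.default_rng(config.seed)
    X, Y, norm = _normalize(dataset, config)
    n, d_x = X.shape
    d_y = Y.shape[1]

    n_hold = min(config.holdout, max(n // 5, 1))
    X_tr, Y_tr = X[:-n_hold], Y[:-n_hold]
    X_ho, Y_ho = X[-n_hold:], Y[-n_hold:]
    ref_joint = np.hstack([X_ho, Y_ho])
    # shared histogram ranges so checkpoint JSDs are comparable; one bin
    # width of slack on each side catches generator mass just outside the
    # data range without washing out the resolution
    lo = ref_joint.min(axis=0)
    hi = ref_joint.max(axis=0)
    pad = (hi - lo) / config.jsd_bins
    jsd_ranges = np.column_stack([lo - pad, hi + pad])

    gen = _MLP([config.latent_dim + d_y, *config.gen_layers, d_x], rng)
    disc = _MLP([d_x + d_y, *config.disc_layers, 1], rng)
    opt_g = _Adam(gen, config.lr_gen, config.beta1, config.beta2)
    opt_d = _Adam(disc, config.lr_disc, config.beta1, config.beta2)
    ema = gen.copy() if config.ema_decay > 0 else gen

    def gen_forward(Yc, cache=None, z=None, rng_local=None):
        r = rng_local if rng_local is not None else rng
        if z is None:
            z = r.standard_normal((len(Yc), config.latent_dim))
        return gen.forward(np.hstack([z, Yc]), cache), z

    # checkpoint score: JSD over all (parameter, feature) 2-D pair
    # histograms of the pushforward joint vs the held-out joint; sensitive
    # to the parameter-feature coupling the conditional generator must learn
    score_pairs = [(i, d_x + j) for i in range(d_x) for j in range(d_y)]

    def pushforward_jsd() -> tuple[float, float]:
        z = rng.standard_normal((len(Y_ho), config.latent_dim))
        xg = ema.forward(np.hstack([z, Y_ho]))
        joint = np.hstack([xg, Y_ho])
        pair = jsd_pairwise(joint, ref_joint, pairs=score_pairs,
                            ranges=jsd_ranges)
        marg = jsd(joint, ref_joint, bins=config.jsd_bins, ranges=jsd_ranges)
        return pair, marg

    result = TrainedGenerator(
        config=config, param_names=tuple(dataset.params.columns),
        feature_names=tuple(dataset.features.columns), norm=norm)
    marginal_scores = []

    def checkpoint(iteration):
        pair, marg = pushforward_jsd()
        marginal_scores.append(marg)
        weights = {"W": [w.copy() for w in ema.W],
                   "b": [b.copy() for b in ema.b]}
        result.checkpoints.append((iteration, pair, weights))

    rows = []
    iteration = 0
    checkpoint(iteration)
    n_tr = len(X_tr)
    bs = min(config.minibatch, n_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n_tr)
        for lo_i in range(0, n_tr - bs + 1, bs):
            idx = order[lo_i: lo_i + bs]
            xb, yb = X_tr[idx], Y_tr[idx]
            real_in = np.hstack([xb, yb])

            # --- discriminator update --------------------------------------
            xg, _ = gen_forward(yb)
            fake_in = np.hstack([xg, yb])
            dW, db, p_r, p_f = _disc_grads(disc, real_in, fake_in)
            d_loss, g_loss = adversarial_losses(p_r, p_f)
            opt_d.step(disc, dW, db)

            # --- unrolled copy of the discriminator ------------------------
            if config.unroll_steps > 0:
                disc_u = disc.copy()
                opt_u = opt_d.copy()
                for _ in range(config.unroll_steps):
                    xg_u, _ = gen_forward(yb)
                    dWu, dbu, _, _ = _disc_grads(
                        disc_u, real_in, np.hstack([xg_u, yb]))
                    opt_u.step(disc_u, dWu, dbu, lr=config.lr_unroll)
            else:
                disc_u = disc

            # --- generator update against the unrolled discriminator -------
            cache_g = []
            xg, z = gen_forward(yb, cache=cache_g)
            cache_d = []
            s = disc_u.forward(np.hstack([xg, yb]), cache_d)[:, 0]
            # non-saturating loss: dL/ds = -1/B per sample
            g_out = np.full((len(s), 1), -1.0 / len(s))
            _, _, g_in = disc_u.backward(cache_d, g_out)
            grad_x = g_in[:, :d_x]
            if config.recon_weight > 0:
                # paired reconstruction pulls the conditional toward the
                # true parameters of the batch (pix2pix-style auxiliary)
                grad_x = grad_x + config.recon_weight * 2.0 * (xg - xb) / len(xb)
            dWg, dbg, _ = gen.backward(cache_g, grad_x)
            opt_g.step(gen, dWg, dbg)
            if config.ema_decay > 0:
                d_ema = config.ema_decay
                for li in range(len(gen.W)):
                    ema.W[li] *= d_ema
                    ema.W[li] += (1 - d_ema) * gen.W[li]
                    ema.b[li] *= d_ema
                    ema.b[li] += (1 - d_ema) * gen.b[li]

            iteration += 1
            rows.append((iteration, epoch, d_loss, g_loss))
            if iteration % config.checkpoint_interval == 0:
                checkpoint(iteration)

    if result.checkpoints[-1][0] != iteration:
        checkpoint(iteration)
    result.log = pd.DataFrame(
        rows, columns=["iteration", "epoch", "d_loss", "g_loss"])
    result.marginal_jsd = np.array(marginal_scores)
    result.selected = int(np.argmin(result.jsd_trace))
    return result


# ---------------------------------------------------------------------------
# Amortized inference
# ---------------------------------------------------------------------------

@dataclass
class GeneratorEnsemble:
    """Several independently trained generators pooled at inference.

    Each requested sample is drawn from a uniformly chosen member, which
    averages out member-specific conditional bias (a deep-ensemble
    analogue). Exposes the attributes `sample` needs, so it can stand in
    for a single :class:`TrainedGenerator` anywhere inference happens.
    """

    members: list

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    @property
    def param_names(self):
        return self.members[0].param_names

    @property
    def feature_names(self):
        return self.members[0].feature_names

    @property
    def norm(self):
        return self.members[0].norm

    def save(self, outdir: str) -> None:
        for i, m in enumerate(self.members):
            m.save(os.path.join(outdir, f"member{i}"))

    @classmethod
    def load(cls, outdir: str) -> "GeneratorEnsemble":
        members = []
        i = 0
        while os.path.isdir(os.path.join(outdir, f"member{i}")):
            members.append(TrainedGenerator.load(
                os.path.join(outdir, f"member{i}")))
            i += 1
        return cls(members=members)


def sample(gen: "TrainedGenerator | GeneratorEnsemble",
           conditions: np.ndarray,
           n_per_condition: int = 1,
           seed: int | np.random.Generator | None = 0,
           clip: bool = True) -> np.ndarray:
    """Draw parameter sets conditioned on feature vectors.

    ``conditions`` is one feature vector or an (m, 13) matrix in raw units
    (apply out-of-range replacement first); the result has
    ``m * n_per_condition`` rows in raw parameter units, clipped to the
    training bounds. Inference is amortized: no retraining, just a forward
    pass through the stored generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = np.atleast_2d(np.asarray(conditions, float))
    if C.shape[1] != len(gen.feature_names):
        raise ValueError(
            f"condition has {C.shape[1]} features, expected {len(gen.feature_names)}")
    if isinstance(gen, GeneratorEnsemble):
        reps = np.repeat(C, n_per_condition, axis=0)
        member = rng.integers(0, len(gen.members), len(reps))
        out = np.empty((len(reps), len(gen.param_names)))
        for mi, m in enumerate(gen.members):
            mask = member == mi
            if mask.any():
                out[mask] = sample(m, reps[mask], 1, seed=rng, clip=clip)
        return out
    net = gen.generator_net()
    Yn = _transform_features(C, gen.norm)
    Yrep = np.repeat(Yn, n_per_condition, axis=0)
    z = rng.standard_normal((len(Yrep), gen.config.latent_dim))
    Xn = net.forward(np.hstack([z, Yrep]))
    lo, hi = gen.norm["param_low"], gen.norm["param_high"]
    X = lo + Xn * (hi - lo)
    if clip:
        X = np.clip(X, lo, hi)
    return X
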