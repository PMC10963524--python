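"""End-to-end orchestration: dataset -> training -> inference -> validation.

Every stochastic stage is gated by a scale profile:

* ``smoke``  — minutes-scale plumbing check (tiny sweep, tiny networks),
* ``desk``   — single-CPU working scale used by the test-suite experiments,
* ``paper_scale`` — the reference configuration (3M-row sweep, minibatch
  10,000, 400 epochs, 100 samples per cell); encoded but not exercised by
  the tests.

Runs are reconstructible from their manifest: the manifest records the
profile, seeds, and the digests of every artifact written.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import datasets as D
from . import evaluation as E
from . import features as F
from . import gan as G

__all__ = [
    "ScaleProfile",
    "PROFILES",
    "RunManifest",
    "train_inverse_model",
    "run_scenario_suite",
    "run_category_analysis",
]


@dataclass(frozen=True)
class ScaleProfile:
    name: str
    n_train: int
    n_per_group: int
    n_samples_per_cell: int
    n_members: int = 1          # independently seeded generators pooled
    gan_kwargs: dict = field(default_factory=dict)

    def gan_config(self, seed: int = 0) -> G.GANConfig:
        factory = {"smoke": G.GANConfig.smoke, "desk": G.GANConfig.desk,
                   "paper_scale": G.GANConfig.paper_scale}[self.name]
        return factory(seed=seed, **self.gan_kwargs)


PROFILES = {
    "smoke": ScaleProfile("smoke", n_train=150, n_per_group=20,
                          n_samples_per_cell=10),
    "desk": ScaleProfile("desk", n_train=6000, n_per_group=100,
                         n_samples_per_cell=100, n_members=2),
    "paper_scale": ScaleProfile("paper_scale", n_train=D.PAPER_SCALE_TRAINING_N,
                                n_per_group=100, n_samples_per_cell=100),
}


@dataclass
class RunManifest:
    command: str
    profile: str
    seed: int
    config: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)   # path -> sha256
    timing_s: dict = field(default_factory=dict)

    def add_artifact(self, path: str) -> None:
        h = hashlib.sha256()
        with open(path, "rb") as f:
            for blk in iter(lambda: f.read(65536), b""):
                h.update(blk)
        self.artifacts[os.path.basename(path)] = h.hexdigest()

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1, default=str)


def _seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def train_inverse_model(profile: ScaleProfile, seed: int,
                        forward: Optional[D.ForwardModel] = None,
                        dataset: Optional[D.TrainingDataset] = None
                        ) -> tuple["G.TrainedGenerator | G.GeneratorEnsemble",
                                   D.TrainingDataset]:
    """Uniform sweep plus conditional-GAN training at the given scale.

    Profiles with ``n_members > 1`` train that many independently seeded
    generators and pool them at inference.
    """
    child = _seeds(seed, 1 + profile.n_members)
    if dataset is None:
        dataset = D.make_training_dataset(profile.n_train, seed=child[0],
                                          forward=forward)
    members = [G.train(dataset, profile.gan_config(seed=s))
               for s in child[1:]]
    model = members[0] if profile.n_members == 1 else G.GeneratorEnsemble(members)
    return model, dataset


def _sample_and_simulate(model: G.TrainedGenerator, fm: D.ForwardModel,
                         feats: np.ndarray, rng: np.random.Generator,
                         max_retries: int = 10
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """One inferred parameter set per condition, pushed through the model.

    The training prior is itself conditioned on producing a spike, so a
    latent draw whose parameters fail the forward map is redrawn (up to
    ``max_retries`` per condition); rows that still fail keep their last
    draw and are dropped from the feature table only.
    """
    X = G.sample(model, feats, 1, seed=rng)
    fc, ok = fm.features(X)
    for _ in range(max_retries):
        if ok.all():
            break
        bad = np.flatnonzero(~ok)
        X_new = G.sample(model, feats[bad], 1, seed=rng)
        fc_new, ok_new = fm.features(X_new)
        X[bad] = X_new
        fc.iloc[bad] = fc_new.to_numpy()
        ok[bad] = ok_new
    return X, fc[ok]


def run_scenario_suite(k_values: Sequence[int], profile: ScaleProfile,
                       seed: int,
                       model: Optional[G.TrainedGenerator] = None,
                       dataset: Optional[D.TrainingDataset] = None,
                       forward: Optional[D.ForwardModel] = None,
                       max_scenarios_per_k: Optional[int] = None,
                       alpha: float = 0.01) -> dict:
    """Two-group structure-recovery validation across enumerated scenarios.

    For every scenario: generate target groups, infer parameters per target
    feature vector, push the inferred parameters back through the model, and
    score G1-vs-G2 KS agreement plus cGAN-vs-target rejections.
    """
    if model is None:
        model, dataset = train_inverse_model(profile, seed, forward=forward)
    fm = forward or D.ForwardModel()
    bounds = D.ParameterBounds.from_defaults(fm.base)
    ranges = None
    if dataset is not None:
        ranges = F.feature_ranges(dataset.features)
    reports = []
    rows = []
    t_start = time.time()
    for k in k_values:
        scenarios = D.enumerate_scenarios(k, n_per_group=profile.n_per_group)
        if max_scenarios_per_k is not None:
            scenarios = scenarios[:max_scenarios_per_k]
        child = _seeds((seed * 101 + k) % (2 ** 31), len(scenarios))
        for sc, s_sc in zip(scenarios, child):
            target = D.make_two_group_targets(sc, bounds, seed=s_sc, forward=fm)
            cgan = {}
            rng = np.random.default_rng(s_sc + 1)
            for grp in ("G1", "G2"):
                feats = target[grp]["features"].to_numpy()
                if ranges is not None:
                    feats = np.vstack([
                        F.replace_out_of_range(f, ranges)[0].to_array()
                        for f in feats])
                X, fc = _sample_and_simulate(model, fm, feats, rng)
                cgan[grp] = {
                    "params": pd.DataFrame(X, columns=list(bounds.names)),
                    "features": fc,
                }
            rep = E.scenario_agreement(
                sc, target, cgan, bounds.names, F.FEATURE_NAMES, alpha=alpha)
            reports.append(rep)
            rows.append({
                "k": k, "scenario": sc.label, "n_agree": rep.n_agree,
                "n_tests": rep.n_tests,
                "rej_G1": rep.cgan_vs_target_rejections["G1"],
                "rej_G2": rep.cgan_vs_target_rejections["G2"],
            })
    summary = pd.DataFrame(rows)
    return {
        "summary": summary,
        "reports": reports,
        "totals": {
            "n_agree": int(summary["n_agree"].sum()),
            "n_tests": int(summary["n_tests"].sum()),
            "rej_G1": int(summary["rej_G1"].sum()),
            "rej_G2": int(summary["rej_G2"].sum()),
        },
        "elapsed_s": time.time() - t_start,
    }


#: the four pairwise comparisons reported for the experimental categories
CATEGORY_COMPARISONS = (
    ("rTg4510", "WT12"),   # tauopathy disease effect
    ("PDAPP", "WT24"),     # amyloidopathy disease effect
    ("WT24", "WT12"),      # age effect, wildtype
    ("PDAPP", "rTg4510"),  # age effect, mutants
)


def run_category_analysis(model: G.TrainedGenerator,
                          dataset: D.TrainingDataset,
                          mimic: Optional[pd.DataFrame] = None,
                          shifts: Optional[dict] = None,
                          n_cells: Optional[dict] = None,
                          seed: int = 0,
                          n_samples_per_cell: int = 100,
                          forward: Optional[D.ForwardModel] = None,
                          replace_strategy: str = "median",
                          thresholds=E.EFFECT_SIZE_THRESHOLDS) -> dict:
    """Which conductances differ between mouse categories.

    Per cell: replace out-of-training-range features, draw
    ``n_samples_per_cell`` parameter sets from the generator, pool them per
    category, then report pairwise Cohen's d with categorical labels for
    every varied conductance.
    """
    fm = forward or D.ForwardModel()
    bounds = D.ParameterBounds.from_defaults(fm.base)
    s_mimic, s_inf = _seeds(seed, 2)
    if mimic is None:
        mimic = D.make_category_mimic(shifts=shifts, n_cells=n_cells,
                                      bounds=bounds, seed=s_mimic, forward=fm)
    for cat in D.CATEGORIES:
        if cat not in set(mimic["category"]):
            raise ValueError(f"category {cat} missing from the cell table")
    ranges = F.feature_ranges(dataset.features)
    rng = np.random.default_rng(s_inf)
    pooled = {}
    n_replaced = 0
    for cat in D.CATEGORIES:
        rowsc = mimic[mimic["category"] == cat]
        feats = rowsc[list(F.FEATURE_NAMES)].to_numpy()
        reps = []
        for fvec in feats:
            fv, mask = F.replace_out_of_range(fvec, ranges, replace_strategy,
                                              dataset.features)
            n_replaced += int(mask.sum())
            reps.append(fv.to_array())
        X = G.sample(model, np.vstack(reps), n_samples_per_cell, seed=rng)
        pooled[cat] = pd.DataFrame(X, columns=list(bounds.names))
    rows = []
    for a, b in CATEGORY_COMPARISONS:
        for n in bounds.names:
            try:
                d = E.cohens_d(pooled[a][n], pooled[b][n])
            except ZeroDivisionError:
                # both pools degenerate (e.g. clipped to a bound): the
                # standardized difference is 0 or unbounded
                same = pooled[a][n].mean() == pooled[b][n].mean()
                d = 0.0 if same else float("inf")
            rows.append({
                "comparison": f"{a} vs {b}", "parameter": n, "cohens_d": d,
                "label": E.classify_effect_size(d, thresholds),
                "direction": float(np.sign(pooled[a][n].mean()
                                           - pooled[b][n].mean())),
            })
    return {
        "effect_sizes": pd.DataFrame(rows),
        "pooled": pooled,
        "mimic": mimic,
        "n_features_replaced": n_replaced,
    }
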