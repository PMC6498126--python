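"""Dataset splitting, supervised training, evaluation and hyperparameter
search.

The protocol: 90% of the data trains the network, the remaining 10% is
split equally into validation (early stopping / model selection) and a
held-out test set that never influences any parameter. Networks minimize
mean squared error on their head's targets (16 level energies in eV, or the
broadened spectrum sampled on the grid) with the Adam update scheme;
hyperparameters can be tuned by sequential model-based (Bayesian)
optimization with a Gaussian-process surrogate and expected improvement, or
by seeded random search.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .models import Model, ModelConfig, build_model
from .molio import Dataset
from .spectra import (MetricsReport, Spectrum, broaden, levels_report,
                      spectra_report)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.90
    validation_fraction: float = 0.05
    test_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if min(fr) <= 0 or abs(sum(fr) - 1.0) > 1e-12:
            raise ValueError("fractions must be positive and sum to 1")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    lr_decay: float = 0.5      # reduce-on-plateau factor (1.0 disables)
    lr_patience: int = 8       # plateau epochs before decaying
    min_lr: float = 1e-5
    sigma: float = 0.5     # eV, broadening for spectrum-head targets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.patience < 1:
            raise ValueError("need lr > 0, batch_size >= 1, patience >= 1")


def split_dataset(ds: Dataset | int, spec: SplitSpec
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded disjoint-exhaustive (train, validation, test) index partition.

    Validation and test get round(N * fraction) records each; the remainder
    goes to train, so the 90/5/5 rule gives exactly 900/50/50 at N = 1000.
    """
    n = ds if isinstance(ds, int) else len(ds)
    if n < 20:
        raise ValueError(f"dataset too small to split ({n} < 20)")
    n_val = round(n * spec.validation_fraction)
    n_test = round(n * spec.test_fraction)
    if n_val < 1 or n_test < 1 or n_val + n_test >= n:
        raise ValueError("split fractions leave an empty subset")
    perm = np.random.default_rng(spec.seed).permutation(n)
    test = np.sort(perm[:n_test])
    val = np.sort(perm[n_test:n_test + n_val])
    train = np.sort(perm[n_test + n_val:])
    return train, val, test


def make_targets(ds: Dataset, config: ModelConfig,
                 sigma: float = 0.5) -> np.ndarray:
    """Training targets for a head: (N, 16) levels or (N, grid) intensities."""
    if config.output_mode == "levels":
        return ds.levels
    grid = config.grid
    return np.stack([broaden(lev, sigma=sigma, grid=grid).intensity
                     for _, lev in ds.records])


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = math.inf
    wall_seconds: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def train(config: ModelConfig, ds: Dataset, train_idx: np.ndarray,
          val_idx: np.ndarray, tc: TrainConfig) -> tuple[Model, TrainHistory]:
    """Train a model on the given split; restore the best-validation epoch.

    Fully reproducible given ``config.seed`` (initialization) and
    ``tc.seed`` (batch shuffling). Aborts with a diagnostic if the loss
    leaves the finite range.
    """
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation sets must be nonempty")
    t0 = time.perf_counter()
    model = build_model(config)
    targets = make_targets(ds, config, sigma=tc.sigma)
    mols = ds.molecules
    # standardize the output head on train-split statistics
    y_tr = targets[train_idx]
    model.y_shift = y_tr.mean(axis=0)
    scale = y_tr.std(axis=0)
    model.y_scale = np.where(scale > 1e-12, scale, 1.0)

    x_train = model.featurize([mols[i] for i in train_idx])
    x_val = model.featurize([mols[i] for i in val_idx])
    model.fit_input_stats(x_train)
    y_train, y_val = targets[train_idx], targets[val_idx]

    opt = Adam(model.params, lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    hist = TrainHistory()
    best_state = model.get_state()
    since_best = 0
    n_tr = len(train_idx)
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n_tr)
        ep_loss = 0.0
        for start in range(0, n_tr, tc.batch_size):
            sel = order[start:start + tc.batch_size]
            batch = {k: v[sel] for k, v in x_train.items()}
            opt.zero_grad()
            loss = _mse(model.forward(batch), y_train[sel])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"try a smaller learning rate than {tc.learning_rate}")
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(sel)
        hist.train_loss.append(ep_loss / n_tr)
        val_loss = float(_mse(model.forward(x_val), y_val).data)
        hist.val_loss.append(val_loss)
        if val_loss < hist.best_val_loss:
            hist.best_val_loss = val_loss
            hist.best_epoch = epoch
            best_state = model.get_state()
            since_best = 0
        else:
            since_best += 1
            if (tc.lr_decay < 1.0 and since_best % tc.lr_patience == 0
                    and opt.lr > tc.min_lr):
                opt.lr = max(opt.lr * tc.lr_decay, tc.min_lr)
                logger.info("epoch %d: reducing learning rate to %.2g",
                            epoch, opt.lr)
            if since_best >= tc.patience:
                logger.info("early stop at epoch %d (best %d)", epoch,
                            hist.best_epoch)
                break
    model.set_state(best_state)
    hist.wall_seconds = time.perf_counter() - t0
    return model, hist


def evaluate(model: Model, ds: Dataset, test_idx: np.ndarray,
             train_idx: np.ndarray | None = None,
             sigma: float = 0.5) -> MetricsReport:
    """Held-out-set metrics; refuses a test set overlapping the train set."""
    if train_idx is not None:
        overlap = np.intersect1d(test_idx, train_idx)
        if overlap.size:
            raise ValueError(f"test/train overlap at indices {overlap[:5]}")
    sub = ds.subset(list(test_idx))
    pred = model.predict(sub.molecules)
    if model.config.output_mode == "levels":
        from .models import count_monotonicity_violations
        n_bad = count_monotonicity_violations(pred)
        if n_bad:
            logger.info("%d/%d predictions violate descending level order",
                        n_bad, len(pred))
        return levels_report(pred, sub.levels)
    grid = model.config.grid
    ref = [broaden(lev, sigma=sigma, grid=grid) for _, lev in sub.records]
    pred_specs = [Spectrum(grid, p, r.molecule_id)
                  for p, r in zip(pred, ref)]
    return spectra_report(pred_specs, ref)


def mean_spectrum_baseline(ds: Dataset, train_idx: np.ndarray,
                           test_idx: np.ndarray, grid,
                           sigma: float = 0.5) -> MetricsReport:
    """Predict the train-set mean spectrum for every test molecule."""
    tr = [broaden(lev, sigma=sigma, grid=grid)
          for _, lev in ds.subset(list(train_idx)).records]
    mean_int = np.mean([s.intensity for s in tr], axis=0)
    ref = [broaden(lev, sigma=sigma, grid=grid)
           for _, lev in ds.subset(list(test_idx)).records]
    pred = [Spectrum(grid, mean_int, r.molecule_id) for r in ref]
    return spectra_report(pred, ref)


# --------------------------------------------------------------------------
# hyperparameter optimization

@dataclass
class HPOConfig:
    """Search-space + budget for sequential model-based optimization.

    ``space`` maps parameter name -> spec tuple:
      ("int", lo, hi) | ("float", lo, hi) | ("logfloat", lo, hi)
      | ("choice", [options...])
    """

    space: dict = field(default_factory=dict)
    budget: int = 10
    strategy: str = "bayesian"  # or "random"
    n_init: int = 4             # random trials before the GP takes over
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.strategy not in ("bayesian", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name, spec in self.space.items():
            if spec[0] == "choice" and not spec[1]:
                raise ValueError(f"empty choice range for {name!r}")


def _decode(u: np.ndarray, space: dict) -> dict:
    """Map a unit-cube point to a parameter assignment."""
    out = {}
    for x, (name, spec) in zip(u, space.items()):
        kind = spec[0]
        if kind == "int":
            lo, hi = spec[1], spec[2]
            out[name] = int(lo + min(x, 1 - 1e-12) * (hi - lo + 1))
        elif kind == "float":
            out[name] = spec[1] + x * (spec[2] - spec[1])
        elif kind == "logfloat":
            out[name] = float(np.exp(np.log(spec[1])
                                     + x * (np.log(spec[2]) - np.log(spec[1]))))
        elif kind == "choice":
            opts = spec[1]
            out[name] = opts[int(min(x, 1 - 1e-12) * len(opts))]
        else:
            raise ValueError(f"unknown space kind {kind!r}")
    return out


def _enumerable(space: dict) -> list[dict] | None:
    """Full grid when every dimension is discrete; None otherwise."""
    grids = []
    for name, spec in space.items():
        if spec[0] == "choice":
            grids.append([(name, v) for v in spec[1]])
        elif spec[0] == "int":
            grids.append([(name, v) for v in range(spec[1], spec[2] + 1)])
        else:
            return None
    combos = [{}]
    for g in grids:
        combos = [dict(c, **{k: v}) for c in combos for (k, v) in g]
    return combos


def _expected_improvement(mu: np.ndarray, sd: np.ndarray,
                          best: float) -> np.ndarray:
    from scipy.stats import norm
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def optimize_hyperparameters(hpo: HPOConfig, objective
                             ) -> tuple[dict, list[dict]]:
    """Minimize ``objective(params) -> float`` over the search space.

    Bayesian strategy: seeded random initialization, then a Gaussian-process
    surrogate with expected-improvement acquisition maximized over a seeded
    candidate cloud. Returns the best parameter assignment and the full
    trial log. Deterministic for a fixed seed and deterministic objective.
    """
    rng = np.random.default_rng(hpo.seed)
    d = len(hpo.space)
    log: list[dict] = []

    grid = _enumerable(hpo.space)
    if grid is not None and len(grid) <= hpo.budget:
        candidates = grid  # exhaustible space: enumerate it
        for params in candidates:
            log.append(_run_trial(objective, params))
        return _best(log), log

    us = [rng.random(d) for _ in range(hpo.budget)]
    if hpo.strategy == "random":
        for u in us:
            log.append(_run_trial(objective, _decode(u, hpo.space)))
        return _best(log), log

    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    n_init = min(hpo.n_init, hpo.budget)
    xs: list[np.ndarray] = []
    for u in us[:n_init]:
        log.append(_run_trial(objective, _decode(u, hpo.space)))
        xs.append(u)
    for _ in range(hpo.budget - n_init):
        ys = np.array([t["loss"] if np.isfinite(t["loss"]) else np.nan
                       for t in log])
        finite = np.isfinite(ys)
        if finite.sum() < 2:
            u = rng.random(d)
        else:
            y = ys.copy()
            y[~finite] = np.nanmax(ys[finite]) + 1.0  # penalize failures
            kernel = ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5)
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          alpha=1e-6, random_state=0)
            gp.fit(np.array(xs), y)
            cand = rng.random((256, d))
            mu, sd = gp.predict(cand, return_std=True)
            u = cand[int(np.argmax(_expected_improvement(mu, sd, y.min())))]
        log.append(_run_trial(objective, _decode(u, hpo.space)))
        xs.append(u)
    return _best(log), log


def _run_trial(objective, params: dict) -> dict:
    try:
        loss = float(objective(params))
    except Exception as exc:  # trial failure is data, not a crash
        logger.warning("trial %r failed: %s", params, exc)
        loss = math.inf
        return {"params": params, "loss": loss, "error": str(exc)}
    return {"params": params, "loss": loss}


def _best(log: list[dict]) -> dict:
    finite = [t for t in log if np.isfinite(t["loss"])]
    if not finite:
        raise RuntimeError(
            "all trials failed: " + "; ".join(
                f"{t['params']} -> {t.get('error', 'inf')}" for t in log))
    return min(finite, key=lambda t: t["loss"])["params"]


def validation_objective(ds: Dataset, base_config: ModelConfig,
                         base_tc: TrainConfig, split: SplitSpec):
    """Objective factory: params override config fields; score = best val loss."""
    train_idx, val_idx, _ = split_dataset(ds, split)

    def objective(params: dict) -> float:
        cfg_kwargs = asdict(base_config)
        tc_kwargs = asdict(base_tc)
        for k, v in params.items():
            if k in tc_kwargs:
                tc_kwargs[k] = v
            else:
                cfg_kwargs[k] = v
        _, hist = train(ModelConfig(**cfg_kwargs), ds, train_idx, val_idx,
                        TrainConfig(**tc_kwargs))
        return hist.best_val_loss

    return objective


def write_manifest(path: str | Path, *, config: ModelConfig, tc: TrainConfig,
                   split: SplitSpec, history: TrainHistory,
                   metrics: MetricsReport | None = None,
                   extra: dict | None = None) -> None:
    """Run manifest: configuration, seeds, history, metrics — one JSON file."""
    payload = {
        "model_config": asdict(config),
        "train_config": asdict(tc),
        "split": asdict(split),
        "history": history.to_dict(),
    }
    if metrics is not None:
        payload["metrics"] = json.loads(metrics.to_json())
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
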