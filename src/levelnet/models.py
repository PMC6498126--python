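"""The three predictor architectures: MLP, CNN, and the tensor-interaction
network (DTNN), each with a 16-level head or a 300-point spectrum head.

* MLP — stacked affine layers + nonlinearity on the flattened (sorted)
  Coulomb-matrix upper triangle.
* CNN — convolution/nonlinearity/pooling blocks over the Coulomb matrix
  treated as an image, then a dense head.
* DTNN — atoms carry learned embedding vectors c_i refined over T
  "interaction passes": each pass adds, for every atom, a sum over
  neighbors of a gated term mixing the neighbor's projected state with the
  projected Gaussian expansion of the pair distance,

      c_i^t = c_i^{t-1} + sum_{j != i} tanh( W_fc [ (W_cf c_j^{t-1} + b_cf)
                                               ⊙ (W_df g(d_ij) + b_df) ] )

  followed by a per-atom readout network, sum pooling over real atoms, and a
  final linear map. Distances are the only geometric input, so predictions
  are invariant to rigid motions; sum pooling makes them invariant to atom
  order. The interaction update is isolated in ``_interaction_pass`` so the
  gating form can be swapped.

The levels head emits 16 unconstrained reals (state 0 = HOMO slot); no
sorting layer is imposed, but monotonicity violations can be counted
post hoc. The spectrum head is an unconstrained linear map to the grid, so
predicted spectra may contain (flagged) negative intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, glorot, parameter
from .featurize import (coulomb_matrix, default_centers, expand_distances,
                        flatten_upper, sort_coulomb)
from .molio import Molecule
from .spectra import SpectrumGrid, make_grid

ARCHITECTURES = ("mlp", "cnn", "dtnn")
OUTPUT_MODES = ("levels", "spectrum")


@dataclass
class ModelConfig:
    """Architecture + featurization hyperparameters (JSON-serializable)."""

    architecture: str = "dtnn"
    output_mode: str = "levels"
    n_max: int = 23
    # spectrum head grid
    grid_e_min: float = -30.0
    grid_e_max: float = 0.0
    grid_points: int = 300
    # mlp
    mlp_hidden: tuple[int, ...] = (128, 128)
    # cnn
    cnn_blocks: tuple[tuple[int, int], ...] = ((8, 3), (16, 3))
    cnn_pool: str = "max"          # or "avg"
    cnn_pool_size: int = 2
    cnn_dense: tuple[int, ...] = (128,)
    # dtnn
    dtnn_embed: int = 32
    dtnn_passes: int = 2           # T interaction passes
    dtnn_readout: tuple[int, ...] = (96, 96)
    basis_r_min: float = 0.0
    basis_r_max: float = 4.0
    basis_step: float = 0.2
    basis_width: float = 0.2
    max_z: int = 9                 # largest atomic number in the embedding table
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.output_mode not in OUTPUT_MODES:
            raise ValueError(f"unknown output mode {self.output_mode!r}")
        if self.dtnn_passes < 0 or self.dtnn_embed < 1:
            raise ValueError("need T >= 0 and embedding dimension >= 1")
        # tuples may arrive as lists from JSON
        self.mlp_hidden = tuple(self.mlp_hidden)
        self.cnn_blocks = tuple(tuple(b) for b in self.cnn_blocks)
        self.cnn_dense = tuple(self.cnn_dense)
        self.dtnn_readout = tuple(self.dtnn_readout)

    @property
    def output_dim(self) -> int:
        return 16 if self.output_mode == "levels" else self.grid_points

    @property
    def grid(self) -> SpectrumGrid:
        return make_grid(self.grid_e_min, self.grid_e_max, self.grid_points)

    @property
    def centers(self) -> np.ndarray:
        return default_centers(self.basis_r_min, self.basis_r_max,
                               self.basis_step)


class Model:
    """Base: parameter bookkeeping, featurization glue, prediction."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.params: list[Tensor] = []
        # output affine de-standardization, set by training from train targets
        self.y_shift = np.zeros(config.output_dim)
        self.y_scale = np.ones(config.output_dim)
        # input standardization for the Coulomb-matrix channels ("x" inputs);
        # distance expansions are already in [0, 1] and stay untouched
        self.x_shift: np.ndarray | float = 0.0
        self.x_scale: np.ndarray | float = 1.0
        self._build()

    # subclasses fill self.params and implement _forward / featurize
    def _build(self) -> None:
        raise NotImplementedError

    def _forward(self, inputs: dict[str, np.ndarray]) -> Tensor:
        raise NotImplementedError

    def featurize(self, mols: list[Molecule]) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def _param(self, arr: np.ndarray) -> Tensor:
        t = parameter(arr)
        self.params.append(t)
        return t

    def forward(self, inputs: dict[str, np.ndarray]) -> Tensor:
        if "x" in inputs and not np.isscalar(self.x_shift):
            inputs = dict(inputs,
                          x=(inputs["x"] - self.x_shift) / self.x_scale)
        raw = self._forward(inputs)
        return raw * Tensor(self.y_scale) + Tensor(self.y_shift)

    def fit_input_stats(self, inputs: dict[str, np.ndarray]) -> None:
        """Set per-feature standardization from (train-split) features."""
        if "x" in inputs:
            x = inputs["x"]
            self.x_shift = x.mean(axis=0)
            sd = x.std(axis=0)
            self.x_scale = np.where(sd > 1e-12, sd, 1.0)

    def predict(self, mols: list[Molecule], batch_size: int = 256) -> np.ndarray:
        """Deterministic batch prediction, (N, output_dim)."""
        out = []
        for i in range(0, len(mols), batch_size):
            inputs = self.featurize(mols[i:i + batch_size])
            out.append(self.forward(inputs).data)
        return np.concatenate(out, axis=0)

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p.data = s.copy()

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config JSON + parameter arrays."""
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params)}
        cfg = json.dumps({"schema": 1, "config": asdict(self.config)})
        np.savez(path, __meta__=np.array(cfg), y_shift=self.y_shift,
                 y_scale=self.y_scale, x_shift=np.asarray(self.x_shift),
                 x_scale=np.asarray(self.x_scale), **arrays)

    @staticmethod
    def load(path: str | Path) -> "Model":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            if meta.get("schema") != 1:
                raise ValueError("unknown checkpoint schema")
            config = ModelConfig(**meta["config"])
            model = build_model(config)
            model.y_shift = f["y_shift"]
            model.y_scale = f["y_scale"]
            if f["x_shift"].ndim:
                model.x_shift = f["x_shift"]
                model.x_scale = f["x_scale"]
            state = [f[f"param_{i}"] for i in range(len(model.params))]
        model.set_state(state)
        return model


def _dense_stack(model: Model, rng: np.random.Generator, in_dim: int,
                 widths: tuple[int, ...], out_dim: int):
    """Create parameters for affine layers in_dim -> widths... -> out_dim."""
    layers = []
    d = in_dim
    for w in widths:
        layers.append((model._param(glorot(rng, d, w)),
                       model._param(np.zeros(w))))
        d = w
    final = (model._param(glorot(rng, d, out_dim)),
             model._param(np.zeros(out_dim)))
    return layers, final


def _apply_dense(x: Tensor, layers, final) -> Tensor:
    for w, b in layers:
        x = (x @ w + b).relu()
    w, b = final
    return x @ w + b


class MLPModel(Model):
    """Dense network on the flattened sorted Coulomb matrix."""

    def _build(self) -> None:
        cfg = self.config
        in_dim = cfg.n_max * (cfg.n_max + 1) // 2
        self.layers, self.final = _dense_stack(
            self, self.rng, in_dim, cfg.mlp_hidden, cfg.output_dim)

    def featurize(self, mols: list[Molecule]) -> dict[str, np.ndarray]:
        x = np.stack([
            flatten_upper(sort_coulomb(coulomb_matrix(m, self.config.n_max)))
            for m in mols])
        return {"x": x}

    def _forward(self, inputs: dict[str, np.ndarray]) -> Tensor:
        return _apply_dense(Tensor(inputs["x"]), self.layers, self.final)


def _im2col_indices(c: int, h: int, w: int, k: int) -> tuple[np.ndarray, int, int]:
    """Indices into a flattened (c*h*w,) image yielding (L, c*k*k) patches."""
    oh, ow = h - k + 1, w - k + 1
    idx = np.empty((oh * ow, c * k * k), dtype=np.int64)
    p = 0
    for i in range(oh):
        for j in range(ow):
            patch = []
            for ch in range(c):
                base = ch * h * w
                for di in range(k):
                    row = base + (i + di) * w + j
                    patch.extend(range(row, row + k))
            idx[p] = patch
            p += 1
    return idx, oh, ow


class CNNModel(Model):
    """Convolution/pooling blocks over the Coulomb matrix image."""

    def _build(self) -> None:
        cfg = self.config
        c, h, w = 1, cfg.n_max, cfg.n_max
        self.blocks = []
        for filters, k in cfg.cnn_blocks:
            if h < k or w < k:
                raise ValueError(
                    f"input {h}x{w} smaller than {k}x{k} receptive field")
            idx, oh, ow = _im2col_indices(c, h, w, k)
            wgt = self._param(glorot(self.rng, c * k * k, filters))
            bias = self._param(np.zeros(filters))
            p = cfg.cnn_pool_size
            ph, pw = oh // p, ow // p
            if ph < 1 or pw < 1:
                raise ValueError("feature map smaller than pooling window")
            self.blocks.append({"idx": idx, "w": wgt, "b": bias, "oh": oh,
                                "ow": ow, "ph": ph, "pw": pw, "p": p,
                                "filters": filters})
            c, h, w = filters, ph, pw
        self.flat_dim = c * h * w
        self.layers, self.final = _dense_stack(
            self, self.rng, self.flat_dim, cfg.cnn_dense, cfg.output_dim)

    def featurize(self, mols: list[Molecule]) -> dict[str, np.ndarray]:
        x = np.stack([
            sort_coulomb(coulomb_matrix(m, self.config.n_max)).values
            for m in mols])
        return {"x": x[:, None, :, :]}  # (B, 1, n, n)

    def _forward(self, inputs: dict[str, np.ndarray]) -> Tensor:
        x = Tensor(inputs["x"])
        b = x.shape[0]
        for blk in self.blocks:
            cin_hw = int(np.prod(x.shape[1:]))
            cols = x.reshape(b, cin_hw).col_gather(blk["idx"])  # (B, L, ckk)
            y = (cols @ blk["w"] + blk["b"]).relu()             # (B, L, F)
            y = y.transpose((0, 2, 1)).reshape(
                b, blk["filters"], blk["oh"], blk["ow"])
            p, ph, pw = blk["p"], blk["ph"], blk["pw"]
            # crop to a multiple of the pooling window, then pool
            y = _crop(y, ph * p, pw * p)
            y = y.reshape(b, blk["filters"], ph, p, pw, p)
            if self.config.cnn_pool == "max":
                y = y.max(axis=5).max(axis=3)
            else:
                y = y.mean(axis=5).mean(axis=3)
            x = y
        x = x.reshape(b, self.flat_dim)
        return _apply_dense(x, self.layers, self.final)


def _crop(t: Tensor, h: int, w: int) -> Tensor:
    """Crop the trailing two axes of a (B, C, H, W) tensor to (h, w)."""
    if t.shape[2] == h and t.shape[3] == w:
        return t
    b, c = t.shape[0], t.shape[1]
    idx = (np.arange(h)[:, None] * t.shape[3] + np.arange(w)[None, :]).ravel()
    full = np.arange(c)[:, None] * (t.shape[2] * t.shape[3]) + idx[None, :]
    out = t.reshape(b, c * t.shape[2] * t.shape[3]).col_gather(full.ravel())
    return out.reshape(b, c, h, w)


class DTNNModel(Model):
    """Tensor-interaction network on atom embeddings and pair distances."""

    def _build(self) -> None:
        cfg = self.config
        d = cfg.dtnn_embed
        g = len(cfg.centers)
        rng = self.rng
        # embedding row 0 is the padding slot; masked out of every sum
        self.embed = self._param(rng.normal(0.0, 1.0, size=(cfg.max_z + 1, d)))
        self.w_cf = self._param(glorot(rng, d, d))
        self.b_cf = self._param(np.zeros(d))
        self.w_df = self._param(glorot(rng, g, d))
        self.b_df = self._param(np.zeros(d))
        self.w_fc = self._param(glorot(rng, d, d))
        self.readout, self.final = _readout_stack(self, rng, d,
                                                  cfg.dtnn_readout,
                                                  cfg.output_dim)

    def featurize(self, mols: list[Molecule]) -> dict[str, np.ndarray]:
        cfg = self.config
        n = cfg.n_max
        centers = cfg.centers
        b = len(mols)
        z = np.zeros((b, n), dtype=np.int64)
        exp = np.zeros((b, n, n, len(centers)))
        mask = np.zeros((b, n))
        for i, mol in enumerate(mols):
            na = mol.n_atoms
            if na > n:
                raise ValueError(f"molecule {mol.id!r} exceeds n_max={n}")
            if mol.atomic_numbers.max() > cfg.max_z:
                raise ValueError(
                    f"molecule {mol.id!r}: atomic number "
                    f"{mol.atomic_numbers.max()} outside embedding table "
                    f"(max_z={cfg.max_z})")
            z[i, :na] = mol.atomic_numbers
            feats = expand_distances(mol, centers, cfg.basis_width)
            exp[i, :na, :na] = feats.expansion
            mask[i, :na] = 1.0
        return {"z": z, "expansion": exp, "mask": mask}

    def _interaction_pass(self, c: Tensor, df: Tensor,
                          pair_mask: np.ndarray) -> Tensor:
        """One refinement round: gated neighbor-state x distance mixing."""
        cf = c @ self.w_cf + self.b_cf                 # (B, n, d)
        # v[b, i, j] couples atom i to neighbor j's state
        nbr = cf.reshape(cf.shape[0], 1, cf.shape[1], cf.shape[2])
        v = ((nbr * df) @ self.w_fc).tanh()
        v = v * Tensor(pair_mask[..., None])
        return c + v.sum(axis=2)

    def _forward(self, inputs: dict[str, np.ndarray]) -> Tensor:
        mask = inputs["mask"]                          # (B, n)
        n = mask.shape[1]
        eye = np.eye(n)[None, :, :]
        pair_mask = mask[:, :, None] * mask[:, None, :] * (1.0 - eye)
        c = self.embed.take_rows(inputs["z"])          # (B, n, d)
        exp = Tensor(inputs["expansion"])
        # the distance projection is shared by all passes (weights are tied)
        df = exp @ self.w_df + self.b_df               # (B, n, n, d)
        for _ in range(self.config.dtnn_passes):
            c = self._interaction_pass(c, df, pair_mask)
        h = c
        for w, b in self.readout:
            h = ((h @ w) + b).tanh()
        h = h * Tensor(mask[..., None])                # zero padded atoms
        pooled = h.sum(axis=1)                         # (B, d_read)
        w, b = self.final
        return pooled @ w + b


def _readout_stack(model: Model, rng: np.random.Generator, in_dim: int,
                   widths: tuple[int, ...], out_dim: int):
    layers = []
    d = in_dim
    for w in widths:
        layers.append((model._param(glorot(rng, d, w)),
                       model._param(np.zeros(w))))
        d = w
    final = (model._param(glorot(rng, d, out_dim)),
             model._param(np.zeros(out_dim)))
    return layers, final


def build_model(config: ModelConfig) -> Model:
    cls = {"mlp": MLPModel, "cnn": CNNModel, "dtnn": DTNNModel}
    return cls[config.architecture](config)


def predict_levels(model: Model, mols: list[Molecule] | Molecule) -> np.ndarray:
    """Predict the 16 level energies (eV); raw head output, not re-sorted."""
    if model.config.output_mode != "levels":
        raise ValueError("model has a spectrum head, not a levels head")
    single = isinstance(mols, Molecule)
    pred = model.predict([mols] if single else mols)
    return pred[0] if single else pred


def predict_spectrum(model: Model, mols: list[Molecule] | Molecule):
    """Predict broadened spectra on the model's grid."""
    from .spectra import Spectrum
    if model.config.output_mode != "spectrum":
        raise ValueError("model has a levels head, not a spectrum head")
    single = isinstance(mols, Molecule)
    mol_list = [mols] if single else mols
    pred = model.predict(mol_list)
    grid = model.config.grid
    specs = [Spectrum(grid, p, m.id) for p, m in zip(pred, mol_list)]
    return specs[0] if single else specs


def count_monotonicity_violations(levels_pred: np.ndarray) -> int:
    """Rows of a (N, 16) prediction whose energies are not descending."""
    return int(np.any(np.diff(levels_pred, axis=1) > 0, axis=1).sum())
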