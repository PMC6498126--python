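"""Broadened density-of-states spectra and evaluation metrics.

Each discrete level ε_k is broadened into a unit-area Gaussian of width
σ = 0.5 eV and the sum is sampled on a fixed 300-point grid spanning
[−30, 0] eV, so a 16-level spectrum integrates to 16 states. Metrics:

* per-state RMSE and squared Pearson correlation (R²) across molecules;
* the relative spectral error RSE = Σ|pred − ref| / Σ ref, an L1-relative
  deviation between a predicted and a reference spectrum.

Reference spectra are nonnegative by construction; network-predicted
spectra may dip below zero (a known artifact) and are flagged, not clipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .molio import LevelSet

logger = logging.getLogger(__name__)

SIGMA_DEFAULT = 0.5  # eV; interpreted as the Gaussian σ (a FWHM reading is a flag)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpectrumGrid:
    e_min: float = -30.0
    e_max: float = 0.0
    n_points: int = 300
    energies: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (self.e_min < self.e_max) or self.n_points < 2:
            raise ValueError("need e_min < e_max and n_points >= 2")
        object.__setattr__(
            self, "energies",
            np.linspace(self.e_min, self.e_max, self.n_points))

    @property
    def spacing(self) -> float:
        return (self.e_max - self.e_min) / (self.n_points - 1)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, SpectrumGrid)
                and self.e_min == other.e_min and self.e_max == other.e_max
                and self.n_points == other.n_points)


@dataclass(frozen=True)
class Spectrum:
    grid: SpectrumGrid
    intensity: np.ndarray  # (n_points,), states/eV
    molecule_id: str = ""

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensity shape {inten.shape} != grid ({self.grid.n_points},)")
        if inten.min() < 0:
            logger.debug("spectrum %r has negative intensity (min %.3g)",
                         self.molecule_id, inten.min())
        object.__setattr__(self, "intensity", inten)

    @property
    def has_negative(self) -> bool:
        return bool(self.intensity.min() < 0)

    def integral(self) -> float:
        """Trapezoidal integral over the grid (≈ number of states in range)."""
        return float(np.trapezoid(self.intensity, self.grid.energies))


def make_grid(e_min: float = -30.0, e_max: float = 0.0,
              n_points: int = 300) -> SpectrumGrid:
    return SpectrumGrid(e_min, e_max, n_points)


def broaden(levels: LevelSet | np.ndarray, sigma: float = SIGMA_DEFAULT,
            grid: SpectrumGrid | None = None, *,
            width_is_fwhm: bool = False,
            molecule_id: str | None = None) -> Spectrum:
    """Gaussian-broaden discrete levels into a density-of-states spectrum.

    Each level contributes a unit-area Gaussian, so the integral of the
    spectrum equals the number of levels inside the grid.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if width_is_fwhm:
        sigma = sigma * FWHM_TO_SIGMA
    if grid is None:
        grid = make_grid()
    if isinstance(levels, LevelSet):
        if molecule_id is None:
            molecule_id = levels.molecule_id
        e = levels.energies
    else:
        e = np.asarray(levels, dtype=float).ravel()
    if e.size == 0:
        return Spectrum(grid, np.zeros(grid.n_points), molecule_id or "")
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    s = norm * np.exp(-((grid.energies[:, None] - e[None, :]) ** 2)
                      / (2.0 * sigma ** 2)).sum(axis=1)
    return Spectrum(grid, s, molecule_id or "")


# --------------------------------------------------------------------------
# metrics

def rmse_per_level(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-state RMSE over molecules: sqrt(mean_m (pred[m,k]-ref[m,k])^2)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 2:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if pred.shape[0] < 2:
        raise ValueError("need at least 2 molecules")
    return np.sqrt(np.mean((pred - ref) ** 2, axis=0))


def r2_per_level(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-state squared Pearson correlation across molecules."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 2:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if pred.shape[0] < 2:
        raise ValueError("need at least 2 molecules")
    pc = pred - pred.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    var_r = (rc ** 2).sum(axis=0)
    bad = np.flatnonzero(var_r == 0)
    if bad.size:
        raise ValueError(f"zero reference variance at state {bad[0]}")
    var_p = (pc ** 2).sum(axis=0)
    with np.errstate(invalid="ignore"):
        r = (pc * rc).sum(axis=0) / np.sqrt(var_p * var_r)
    r = np.where(var_p == 0, 0.0, r)  # constant predictor: no correlation
    return r ** 2


def r2_determination(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Coefficient of determination per state, reported alongside Pearson²."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ss_res = ((pred - ref) ** 2).sum(axis=0)
    ss_tot = ((ref - ref.mean(axis=0)) ** 2).sum(axis=0)
    return 1.0 - ss_res / ss_tot


def rse(pred: Spectrum, ref: Spectrum) -> float:
    """Relative spectral error: total |pred − ref| over total reference mass."""
    if pred.grid != ref.grid:
        raise ValueError("spectra are on different grids")
    denom = float(np.abs(ref.intensity).sum())
    if denom == 0.0:
        raise ValueError("reference spectrum is identically zero")
    return float(np.abs(pred.intensity - ref.intensity).sum() / denom)


def triage(rse_values: np.ndarray, ids: list[str]) -> tuple[str, str, str]:
    """Pick (best, nearest-to-mean, worst) exemplar ids by RSE.

    Ties break toward the lexicographically smallest id.
    """
    rse_values = np.asarray(rse_values, dtype=float)
    if rse_values.size < 3:
        raise ValueError("need at least 3 molecules for triage")
    order = sorted(range(len(ids)), key=lambda i: ids[i])

    def pick(key):
        return ids[min(order, key=key)]

    mean = rse_values.mean()
    best = pick(lambda i: rse_values[i])
    avg = pick(lambda i: abs(rse_values[i] - mean))
    worst = pick(lambda i: -rse_values[i])
    return best, avg, worst


@dataclass
class MetricsReport:
    """Held-out-set evaluation summary for either output head."""

    rmse_per_level: np.ndarray | None = None   # (16,) eV
    r2_per_level: np.ndarray | None = None     # (16,) Pearson²
    r2_determination_per_level: np.ndarray | None = None
    mean_rmse: float | None = None             # eV
    rse_per_molecule: np.ndarray | None = None
    mean_rse: float | None = None
    exemplars: tuple[str, str, str] | None = None  # best / average / worst ids
    n_molecules: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x
        payload = {k: conv(v) for k, v in self.__dict__.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def levels_report(pred: np.ndarray, ref: np.ndarray) -> MetricsReport:
    rmse = rmse_per_level(pred, ref)
    return MetricsReport(
        rmse_per_level=rmse,
        r2_per_level=r2_per_level(pred, ref),
        r2_determination_per_level=r2_determination(pred, ref),
        mean_rmse=float(rmse.mean()),
        n_molecules=pred.shape[0],
    )


def spectra_report(pred: list[Spectrum], ref: list[Spectrum]) -> MetricsReport:
    ids = [r.molecule_id for r in ref]
    vals = np.array([rse(p, r) for p, r in zip(pred, ref, strict=True)])
    exemplars = triage(vals, ids) if vals.size >= 3 else None
    return MetricsReport(
        rse_per_molecule=vals,
        mean_rse=float(vals.mean()),
        exemplars=exemplars,
        n_molecules=len(ref),
    )


def write_spectrum_tsv(spec: Spectrum, path: str | Path) -> None:
    """Two-column TSV: energy_eV, intensity."""
    with open(path, "w") as fh:
        fh.write("energy_eV\tintensity\n")
        for e, s in zip(spec.grid.energies, spec.intensity):
            fh.write(f"{e:.6f}\t{s:.8e}\n")
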