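"""Spectral-scan screening over a structure collection.

Given predicted spectra for a library of molecules, the scan summarizes
where spectral weight lives (a per-energy histogram of molecules whose
intensity exceeds a threshold), what the typical spectrum looks like (the
pointwise average, optionally with a ±1 ensemble-standard-deviation band),
and which molecules stand out: those with above-threshold intensity below a
low-energy bound, and the top-k by ionization energy, read Koopmans-style
as the negated HOMO prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import Spectrum, SpectrumGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    intensity_threshold: float = 0.1
    low_energy_bound: float = -18.0   # eV
    top_k_ionization: int = 6
    ensemble_size: int = 3

    def __post_init__(self) -> None:
        if self.intensity_threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


def _check_shared_grid(spectra: list[Spectrum]) -> SpectrumGrid:
    if not spectra:
        raise ValueError("no spectra given")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("spectra are on different grids")
    return grid


def spectral_scan(spectra: list[Spectrum],
                  cfg: ScanConfig = ScanConfig()) -> np.ndarray:
    """Per-grid-point count of molecules with intensity above the threshold."""
    _check_shared_grid(spectra)
    stack = np.stack([s.intensity for s in spectra])
    return (stack > cfg.intensity_threshold).sum(axis=0)


def average_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of the collection."""
    grid = _check_shared_grid(spectra)
    mean = np.mean([s.intensity for s in spectra], axis=0)
    return Spectrum(grid, mean, "average")


def find_low_energy_outliers(spectra: list[Spectrum],
                             cfg: ScanConfig = ScanConfig()) -> list[str]:
    """Molecules with above-threshold intensity below the low-energy bound.

    Sorted by the lowest energy at which each exceeds the threshold.
    """
    grid = _check_shared_grid(spectra)
    if not (grid.e_min <= cfg.low_energy_bound <= grid.e_max):
        raise ValueError("low_energy_bound outside the spectrum grid")
    below = grid.energies < cfg.low_energy_bound
    hits = []
    for s in spectra:
        mask = below & (s.intensity > cfg.intensity_threshold)
        if mask.any():
            hits.append((float(grid.energies[mask].min()), s.molecule_id))
    hits.sort()
    return [mol_id for _, mol_id in hits]


def rank_ionization(homo_by_id: dict[str, float], k: int = 6) -> list[str]:
    """Top-k ids by ionization energy, the Koopmans proxy −ε_HOMO.

    Ties break toward the lexicographically smaller id; k larger than the
    collection is clipped with a warning.
    """
    if k > len(homo_by_id):
        logger.warning("k=%d exceeds collection size %d; clipping",
                       k, len(homo_by_id))
        k = len(homo_by_id)
    ranked = sorted(homo_by_id, key=lambda i: (-(-homo_by_id[i]), i))
    return ranked[:k]


def confidence_band(ensemble: list[list[Spectrum]]
                    ) -> tuple[Spectrum, Spectrum, Spectrum]:
    """(mean, mean−std, mean+std) spectra from an ensemble of predictions.

    ``ensemble[m]`` holds member m's predicted spectra for the whole
    collection; the pointwise mean and sample standard deviation are taken
    across members per molecule, then averaged over molecules. A single
    member gives a zero-width band (warned).
    """
    if not ensemble or not ensemble[0]:
        raise ValueError("empty ensemble")
    n_members = len(ensemble)
    if n_members == 1:
        logger.warning("ensemble of size 1: confidence band has zero width")
    grid = _check_shared_grid([s for member in ensemble for s in member])
    stack = np.array([[s.intensity for s in member] for member in ensemble])
    mean_per_mol = stack.mean(axis=0)                      # (N, G)
    if n_members > 1:
        std_per_mol = stack.std(axis=0, ddof=1)
    else:
        std_per_mol = np.zeros_like(mean_per_mol)
    mean = mean_per_mol.mean(axis=0)
    lo = (mean_per_mol - std_per_mol).mean(axis=0)
    hi = (mean_per_mol + std_per_mol).mean(axis=0)
    return (Spectrum(grid, mean, "ensemble_mean"),
            Spectrum(grid, lo, "ensemble_minus_std"),
            Spectrum(grid, hi, "ensemble_plus_std"))


@dataclass
class ScanReport:
    """Aggregate screening output for one structure collection."""

    histogram: np.ndarray
    average: Spectrum
    low_energy_outliers: list[str]
    top_ionization: list[str]
    band: tuple[Spectrum, Spectrum, Spectrum] | None = None
    n_molecules: int = 0
    config: ScanConfig = field(default_factory=ScanConfig)

    def write(self, out_dir: str | Path) -> None:
        from .spectra import write_spectrum_tsv
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid = self.average.grid
        with open(out / "histogram.tsv", "w") as fh:
            fh.write("energy_eV\tcount\n")
            for e, c in zip(grid.energies, self.histogram):
                fh.write(f"{e:.6f}\t{int(c)}\n")
        write_spectrum_tsv(self.average, out / "average_spectrum.tsv")
        if self.band is not None:
            for name, spec in zip(("mean", "minus_std", "plus_std"), self.band):
                write_spectrum_tsv(spec, out / f"band_{name}.tsv")
        (out / "outliers.json").write_text(json.dumps(
            {"low_energy_outliers": self.low_energy_outliers,
             "low_energy_bound_eV": self.config.low_energy_bound}, indent=2))
        (out / "top_ionization.json").write_text(json.dumps(
            {"top_ionization": self.top_ionization,
             "k": self.config.top_k_ionization}, indent=2))


def run_scan(spectra: list[Spectrum], homo_by_id: dict[str, float],
             cfg: ScanConfig = ScanConfig(),
             ensemble: list[list[Spectrum]] | None = None) -> ScanReport:
    """Full screening pass over predicted spectra and level predictions."""
    report = ScanReport(
        histogram=spectral_scan(spectra, cfg),
        average=average_spectrum(spectra),
        low_energy_outliers=find_low_energy_outliers(spectra, cfg),
        top_ionization=rank_ionization(homo_by_id, cfg.top_k_ionization),
        n_molecules=len(spectra),
        config=cfg,
    )
    if ensemble is not None:
        report.band = confidence_band(ensemble)
    return report
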