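"""Synthetic microscan ensembles with known correlation structure.

The generative model is the minimal one that produces both the genuine
fragment-fragment correlations the method detects and the spurious
common-mode correlations the TIC partial covariance must remove:

* per scan, a global factor g ~ LogNormal(0, tic_fluctuation) modulates
  all precursor rates (source fluctuation / injection-time confound);
* each mixture component (one combinatorial isomer) contributes
  N ~ Poisson(g * lambda) precursor ions;
* every precursor independently selects a fragmentation channel by its
  branching ratio (or stays undissociated); the channel deposits *all*
  its product ions into the same scan — this co-deposition is the sole
  source of true correlation;
* products land on a uniform m/z grid as Gaussian profiles, plus
  additive detector noise, clipped non-negative.

Defaults mirror the acquisition regime of the experiments emulated:
ensembles of 10^4 microscans with ~100 precursor ions per scan (AGC-style
ion-count control), singly charged products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import ModifiedPeptide
from .combinatorics import IsomerSet, correlation_pairs
from .pcov import GridSpec, ScanEnsemble

#: total mean precursor count per microscan, shared across components
DEFAULT_TOTAL_PRECURSORS = 100.0
#: relative SD of the per-scan common-mode factor
DEFAULT_TIC_FLUCTUATION = 0.3
#: Gaussian peak profile SD (Th) — unit-resolution ion-trap-like peaks
DEFAULT_PEAK_WIDTH = 0.12
#: additive per-bin noise SD, in ion-count units
DEFAULT_NOISE_SD = 0.05
#: total dissociation probability spread uniformly over a component's channels
DEFAULT_DISSOCIATION_PROB = 0.8


@dataclass(frozen=True)
class FragmentationChannel:
    """One dissociation pathway: co-produced products and branching ratio."""

    products: tuple[tuple[float, float], ...]  # (m/z, yield in (0, 1])
    probability: float

    def __post_init__(self) -> None:
        if not (0 < self.probability <= 1):
            raise ValueError("channel probability must be in (0, 1]")
        for mz, y in self.products:
            if not (0 < y <= 1):
                raise ValueError("product yields must be in (0, 1]")
            if mz <= 0:
                raise ValueError("product m/z must be positive")


@dataclass(frozen=True)
class MixtureComponent:
    name: str
    mean_count: float  # lambda: mean precursor ions per scan
    channels: tuple[FragmentationChannel, ...]

    def __post_init__(self) -> None:
        if self.mean_count <= 0:
            raise ValueError("mean precursor count must be > 0")
        total = sum(c.probability for c in self.channels)
        if total > 1 + 1e-9:
            raise ValueError(
                f"channel probabilities of {self.name!r} sum to {total:.4f} > 1"
            )


@dataclass(frozen=True)
class MixtureModel:
    components: tuple[MixtureComponent, ...]
    grid: GridSpec
    tic_fluctuation: float = DEFAULT_TIC_FLUCTUATION
    noise_sd: float = DEFAULT_NOISE_SD
    peak_width: float = DEFAULT_PEAK_WIDTH
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("empty model")
        if self.peak_width <= 0:
            raise ValueError("peak width must be > 0")
        if self.tic_fluctuation < 0 or self.noise_sd < 0:
            raise ValueError("fluctuation/noise parameters must be >= 0")


def make_isomer_mixture_model(
    iso_set: IsomerSet,
    abundances: Sequence[float],
    channel_policy: str = "pairs",
    grid: GridSpec | None = None,
    total_precursors: float = DEFAULT_TOTAL_PRECURSORS,
    dissociation_prob: float = DEFAULT_DISSOCIATION_PROB,
    max_charge: int = 1,
    names: Sequence[str] | None = None,
    **model_kwargs,
) -> MixtureModel:
    """Build a mixture model from a combinatorial isomer set.

    ``channel_policy='pairs'`` gives every isomer one channel per
    complementary-or-shorter b/y pair and one per disjoint
    terminal/internal pair, with uniform branching summing to
    ``dissociation_prob``.  Component precursor rates are
    ``total_precursors`` split by the given abundances.
    """
    if channel_policy != "pairs":
        raise ValueError(f"unknown channel policy {channel_policy!r}")
    abundances = np.asarray(list(abundances), dtype=float)
    if len(abundances) != len(iso_set):
        raise ValueError("one abundance per isomer required")
    if np.any(abundances <= 0):
        raise ValueError("abundances must be positive")
    if not (0 < dissociation_prob <= 1):
        raise ValueError("dissociation probability must be in (0, 1]")
    lam = total_precursors * abundances / abundances.sum()

    if names is None:
        names = [iso.label for iso in iso_set.isomers]
    components = []
    for iso, rate, name in zip(iso_set.isomers, lam, names):
        pairs = correlation_pairs(iso, max_charge=max_charge)
        if not pairs:
            raise ValueError(f"isomer {name!r} has no fragmentation channels")
        p = dissociation_prob / len(pairs)
        channels = tuple(
            FragmentationChannel(
                products=((a.mz, 1.0), (b.mz, 1.0)), probability=p
            )
            for a, b in pairs
        )
        components.append(
            MixtureComponent(name=name, mean_count=float(rate), channels=channels)
        )
    if grid is None:
        mzs = [mz for c in components for ch in c.channels for mz, _ in ch.products]
        grid = GridSpec(lo=np.floor(min(mzs) - 5), hi=np.ceil(max(mzs) + 5))
    return MixtureModel(components=tuple(components), grid=grid, **model_kwargs)


def _deposition_matrix(model: MixtureModel) -> tuple[np.ndarray, np.ndarray]:
    """(n_channels_total, n_bins) expected deposit per channel event, and the
    per-component channel probability table padded with the no-dissociation
    remainder column."""
    grid = model.grid
    centers = grid.centers()
    n_bins = grid.n_bins
    rows = []
    for comp in model.components:
        for ch in comp.channels:
            row = np.zeros(n_bins)
            for mz, yield_frac in ch.products:
                lo = mz - 4 * model.peak_width
                hi = mz + 4 * model.peak_width
                i0 = max(int(np.floor((lo - grid.lo) / grid.step)), 0)
                i1 = min(int(np.ceil((hi - grid.lo) / grid.step)) + 1, n_bins)
                if i1 <= i0:
                    continue  # product outside grid
                prof = np.exp(
                    -0.5 * ((centers[i0:i1] - mz) / model.peak_width) ** 2
                )
                s = prof.sum()
                if s > 0:
                    row[i0:i1] += yield_frac * prof / s
            rows.append(row)
    return np.stack(rows), centers


def simulate_scan_ensemble(
    model: MixtureModel, n_scans: int, seed: int | None = None
) -> ScanEnsemble:
    """Draw a reproducible ensemble of microscans from the mixture model."""
    if n_scans < 2:
        raise ValueError("need n_scans >= 2")
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)

    D, centers = _deposition_matrix(model)
    g = rng.lognormal(mean=0.0, sigma=model.tic_fluctuation, size=n_scans) \
        if model.tic_fluctuation > 0 else np.ones(n_scans)

    counts_cols = []
    for comp in model.components:
        n_prec = rng.poisson(g * comp.mean_count)
        probs = np.array([c.probability for c in comp.channels])
        rest = 1.0 - probs.sum()
        pvals = np.append(probs, max(rest, 0.0))
        pvals /= pvals.sum()
        counts = rng.multinomial(n_prec, pvals)[:, :-1]
        counts_cols.append(counts)
    counts_all = np.concatenate(counts_cols, axis=1).astype(float)

    intensities = counts_all @ D
    if model.noise_sd > 0:
        intensities += rng.normal(0.0, model.noise_sd, intensities.shape)
    np.clip(intensities, 0.0, None, out=intensities)

    return ScanEnsemble(
        mz_grid=centers,
        intensities=intensities,
        metadata={
            "n_scans": n_scans,
            "seed": seed,
            "components": [c.name for c in model.components],
            "mean_counts": [c.mean_count for c in model.components],
            "tic_fluctuation": model.tic_fluctuation,
            "noise_sd": model.noise_sd,
            "peak_width": model.peak_width,
            "grid": (model.grid.lo, model.grid.hi, model.grid.step),
        },
    )


def expected_mean_spectrum(model: MixtureModel) -> np.ndarray:
    """Law-of-large-numbers limit of the mean scan (common-mode factor has
    mean exp(sigma^2 / 2))."""
    D, _ = _deposition_matrix(model)
    rates = np.concatenate(
        [
            comp.mean_count * np.array([c.probability for c in comp.channels])
            for comp in model.components
        ]
    )
    gmean = np.exp(model.tic_fluctuation**2 / 2)
    return gmean * rates @ D
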