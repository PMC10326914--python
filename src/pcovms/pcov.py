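"""TIC partial-covariance mapping, peak detection, jackknife scoring,
marker matching and relative quantification.

The map estimator is the total-ion-current (TIC) partial covariance

    pCov(x, y) = Cov(X_x, X_y) - Cov(X_x, T) Cov(T, X_y) / Var(T)

computed with sample covariances over an ensemble of microscans, where
X_x is the intensity in m/z channel x and T the scan's TIC.  Partialling
out T removes the spurious all-against-all correlations induced by
scan-to-scan fluctuations of precursor number, leaving the genuine
fragment-fragment correlations of single dissociation events.

Peak significance is the jackknife score V / sigma_JK: the full-ensemble
peak volume divided by the standard deviation of the volume under
leave-one-block-out resampling of the scan ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GridSpec:
    """Uniform m/z binning: [lo, hi) at ``step`` Th per bin."""

    lo: float
    hi: float
    step: float = 0.2

    def __post_init__(self) -> None:
        if not (self.hi > self.lo and self.step > 0):
            raise ValueError("need hi > lo and step > 0")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.hi - self.lo) / self.step))

    def centers(self) -> np.ndarray:
        return self.lo + self.step * (np.arange(self.n_bins) + 0.5)

    def index_of(self, mz: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(mz) - self.lo) / self.step).astype(int)


@dataclass
class ScanEnsemble:
    """A stack of microscans binned onto a common uniform m/z grid."""

    mz_grid: np.ndarray  # bin centers, strictly increasing, uniform
    intensities: np.ndarray  # (n_scans, n_bins), non-negative
    tic: np.ndarray | None = None  # per-scan total ion current
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz_grid = np.asarray(self.mz_grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be (n_scans, n_bins)")
        if self.intensities.shape[0] < 2:
            raise ValueError("need at least 2 microscans")
        if self.intensities.shape[1] != self.mz_grid.size:
            raise ValueError("grid / intensity width mismatch")
        d = np.diff(self.mz_grid)
        if self.mz_grid.size > 1 and (
            np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6)
        ):
            raise ValueError("mz grid must be strictly increasing and uniform")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.tic is None:
            self.tic = self.intensities.sum(axis=1)
        else:
            self.tic = np.asarray(self.tic, dtype=float)
            if self.tic.shape != (self.intensities.shape[0],):
                raise ValueError("tic length must equal n_scans")
        if np.count_nonzero(self.tic) < 2:
            raise ValueError("need positive TIC in at least two scans")

    @property
    def n_scans(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_bins(self) -> int:
        return self.intensities.shape[1]


@dataclass
class PCovMap:
    """Symmetric partial-covariance matrix over the m/z grid."""

    matrix: np.ndarray
    mz_grid: np.ndarray
    n_scans: int
    estimator_params: dict = field(default_factory=dict)

    def mz_of(self, index: int) -> float:
        return float(self.mz_grid[index])


ESTIMATORS = ("tic", "self_correcting")


def compute_pcov_map(
    ensemble: ScanEnsemble, ddof: int = 1, estimator: str = "tic"
) -> PCovMap:
    """Estimate the partial-covariance map from a microscan ensemble.

    ``estimator='tic'`` is the classical TIC partial covariance given in
    the module docstring.  ``estimator='self_correcting'`` removes the two
    channels of interest from the conditioning variable — for each pair
    (x, y) it uses T' = T - X_x - X_y — so that a genuinely correlated
    pair is not partially subtracted through its own contribution to the
    TIC.  The self-correcting form expands in closed form from the same
    covariance sums:

        Cov(x, T') = Cov(x, T) - Var(x) - Cov(x, y)
        Var(T')    = Var(T) - 2 Cov(x, T) - 2 Cov(y, T)
                     + Var(x) + Var(y) + 2 Cov(x, y)

    so the full map still costs one Gram matrix.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    X = ensemble.intensities
    T = ensemble.tic
    n = ensemble.n_scans
    if n < 2:
        raise ValueError("partial covariance needs >= 2 scans")
    Tc = T - T.mean()
    var_t = float(Tc @ Tc) / (n - ddof)
    if var_t <= 0:
        raise ValueError("degenerate TIC: Var(T) = 0")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - ddof)
    cov_xt = (Xc.T @ Tc) / (n - ddof)
    if estimator == "tic":
        M = cov - np.outer(cov_xt, cov_xt) / var_t
    else:
        M = _self_correcting(cov, cov_xt, var_t)
    M = 0.5 * (M + M.T)
    return PCovMap(
        matrix=M,
        mz_grid=ensemble.mz_grid,
        n_scans=n,
        estimator_params={"estimator": estimator, "ddof": ddof},
    )


def _self_correcting(
    cov: np.ndarray, cov_xt: np.ndarray, var_t: float
) -> np.ndarray:
    """Partial covariance conditioned on T' = T - X_x - X_y, elementwise
    over all pairs, from the plain covariance sufficient statistics."""
    d = np.diag(cov)
    a = cov_xt[:, None] - d[:, None] - cov  # Cov(x, T')
    b = cov_xt[None, :] - cov - d[None, :]  # Cov(y, T')
    v = (
        var_t
        - 2 * cov_xt[:, None]
        - 2 * cov_xt[None, :]
        + d[:, None]
        + d[None, :]
        + 2 * cov
    )  # Var(T')
    eps = 1e-12 * max(var_t, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(v > eps, a * b / np.where(v > eps, v, 1.0), 0.0)
    return cov - corr


def compute_cov_map(ensemble: ScanEnsemble, ddof: int = 1) -> PCovMap:
    """Plain covariance map (no TIC correction) — the comparison baseline."""
    X = ensemble.intensities
    n = ensemble.n_scans
    Xc = X - X.mean(axis=0)
    M = (Xc.T @ Xc) / (n - ddof)
    return PCovMap(
        matrix=0.5 * (M + M.T),
        mz_grid=ensemble.mz_grid,
        n_scans=n,
        estimator_params={"estimator": "cov", "ddof": ddof},
    )


@dataclass
class PeakCandidate:
    """A local apex of the map's upper triangle with its integration window."""

    apex: tuple[int, int]  # (bin_x, bin_y), bin_x <= bin_y
    apex_mz: tuple[float, float]
    apex_height: float
    window: int  # half-width in bins
    volume: float
    score: float | None = None


def _window_slices(ix: int, iy: int, w: int, n: int) -> tuple[slice, slice]:
    return (
        slice(max(ix - w, 0), min(ix + w + 1, n)),
        slice(max(iy - w, 0), min(iy + w + 1, n)),
    )


def map_mad(pmap: PCovMap, diag_exclusion: int = 3) -> float:
    """Median absolute deviation of the off-diagonal upper triangle."""
    M = pmap.matrix
    iu = np.triu_indices_from(M, k=diag_exclusion)
    vals = M[iu]
    return float(np.median(np.abs(vals - np.median(vals))))


def detect_peaks(
    pmap: PCovMap,
    apex_threshold: float | None = None,
    window: int = 2,
    diag_exclusion: int = 3,
    max_peaks: int | None = None,
) -> list[PeakCandidate]:
    """Local maxima of the upper triangle, above threshold, with the
    autocorrelation diagonal band excluded; sorted by apex height.

    Default threshold is 5x the MAD of the map's off-diagonal upper
    triangle.  Volume is the map integral over the (2*window+1)^2 square.
    """
    M = pmap.matrix
    n = M.shape[0]
    if not np.all(np.isfinite(M)):
        raise ValueError("map contains non-finite values")
    if 2 * window + 1 > n:
        raise ValueError("window larger than map")
    if apex_threshold is None:
        apex_threshold = 5.0 * map_mad(pmap, diag_exclusion)
    local_max = M == ndimage.maximum_filter(M, size=3, mode="nearest")
    ix, iy = np.nonzero(local_max)
    keep = (iy - ix >= diag_exclusion) & (M[ix, iy] > apex_threshold)
    ix, iy = ix[keep], iy[keep]
    order = np.argsort(M[ix, iy])[::-1]
    peaks = []
    for k in order[: max_peaks if max_peaks is not None else len(order)]:
        x, y = int(ix[k]), int(iy[k])
        sx, sy = _window_slices(x, y, window, n)
        peaks.append(
            PeakCandidate(
                apex=(x, y),
                apex_mz=(pmap.mz_of(x), pmap.mz_of(y)),
                apex_height=float(M[x, y]),
                window=window,
                volume=float(M[sx, sy].sum()),
            )
        )
    return peaks


# --- jackknife scoring ------------------------------------------------------


def _block_bounds(n_scans: int, n_groups: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n_scans, n_groups + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _split_masks(
    n_bins: int, chunk: int = 50, guard: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Assign bins to two interleaved half-TICs by alternating chunks,
    dropping ``guard`` bins at each chunk edge so a peak profile never
    straddles the two halves."""
    chunk = max(min(chunk, max(n_bins // 4, 2)), 2)
    guard = min(guard, max(chunk // 4, 0))
    idx = np.arange(n_bins)
    pos = idx % chunk
    interior = (pos >= guard) & (pos < chunk - guard)
    odd = (idx // chunk) % 2 == 1
    return interior & odd, interior & ~odd


def _pcov_window_volume(s: Mapping[str, object], estimator: str = "tic") -> float:
    """Partial-covariance volume over a window from raw sufficient sums.

    For the self-correcting estimator the conditioning variable excludes
    both window slices (T' = T - U - V, tails included), and — when the
    data allow it — the common-mode variance is estimated by the
    covariance of the two parity half-TICs (odd vs even m/z bins).  The
    half-TICs carry independent shot noise, so their covariance is an
    unbiased estimate of the confound variance; using it as an
    instrumental regressor removes the attenuation that a noisy TIC proxy
    leaves behind.
    """
    n = int(s["n"])
    ddof = 1
    if n - ddof <= 0:
        return np.nan
    denom = n - ddof

    def covv(sum_ab, sum_a, sum_b):
        return (sum_ab - np.multiply.outer(sum_a, sum_b) / n) / denom

    cov = covv(s["xy"], s["x"], s["y"])
    cxt = covv(s["xt"], s["x"], s["t"])
    cyt = covv(s["yt"], s["y"], s["t"])
    var_t = float(covv(s["tt"], s["t"], s["t"]))
    if var_t <= 0:
        return float(cov.sum())
    if estimator == "tic":
        return float((cov - np.outer(cxt, cyt) / var_t).sum())

    cov_xx = covv(s["xx"], s["x"], s["x"])
    cov_yy = covv(s["yy"], s["y"], s["y"])
    mxo, mxe = s["mask_xo"], s["mask_xe"]
    myo, mye = s["mask_yo"], s["mask_ye"]

    # half-TIC covariances with the window slices removed
    c_xto = covv(s["xto"], s["x"], s["to"])
    c_xte = covv(s["xte"], s["x"], s["te"])
    c_yto = covv(s["yto"], s["y"], s["to"])
    c_yte = covv(s["yte"], s["y"], s["te"])
    cx_t1 = c_xto - cov_xx[:, mxo].sum(1) - cov[:, myo].sum(1)
    cx_t2 = c_xte - cov_xx[:, mxe].sum(1) - cov[:, mye].sum(1)
    cy_t1 = c_yto - cov[mxo, :].sum(0) - cov_yy[:, myo].sum(1)
    cy_t2 = c_yte - cov[mxe, :].sum(0) - cov_yy[:, mye].sum(1)

    c_t1t2 = (
        float(covv(s["tote"], s["to"], s["te"]))
        - c_xto[mxe].sum()
        - c_yto[mye].sum()
        - c_xte[mxo].sum()
        - c_yte[myo].sum()
        + cov_xx[mxo][:, mxe].sum()
        + cov[mxo][:, mye].sum()
        + cov[mxe][:, myo].sum()
        + cov_yy[myo][:, mye].sum()
    )

    def var_half(c_xth, c_yth, s_thth, s_th, mo_x, mo_y):
        v = float(covv(s_thth, s_th, s_th))
        v -= 2 * (c_xth[mo_x].sum() + c_yth[mo_y].sum())
        v += (
            cov_xx[mo_x][:, mo_x].sum()
            + 2 * cov[mo_x][:, mo_y].sum()
            + cov_yy[mo_y][:, mo_y].sum()
        )
        return v

    var_t1 = var_half(c_xto, c_yto, s["toto"], s["to"], mxo, myo)
    var_t2 = var_half(c_xte, c_yte, s["tete"], s["te"], mxe, mye)

    use_split = (
        var_t1 > 0
        and var_t2 > 0
        and c_t1t2 > 0.2 * np.sqrt(var_t1 * var_t2)
    )
    if use_split:
        corr = (np.outer(cx_t1, cy_t2) + np.outer(cx_t2, cy_t1)) / (2 * c_t1t2)
        return float((cov - corr).sum())

    # fall back to conditioning on T' = T - U - V directly
    a = cxt - cov_xx.sum(1) - cov.sum(1)
    b = cyt - cov.sum(0) - cov_yy.sum(1)
    v = (
        var_t
        + cov_xx.sum()
        + cov_yy.sum()
        + 2 * cov.sum()
        - 2 * cxt.sum()
        - 2 * cyt.sum()
    )
    if v <= 1e-12 * max(var_t, 1.0):
        return float(cov.sum())
    return float((cov - np.outer(a, b) / v).sum())


def jackknife_score(
    ensemble: ScanEnsemble,
    peak: PeakCandidate,
    n_groups: int = 100,
    estimator: str = "tic",
) -> float:
    """Score = V / sigma_JK for the peak's window volume.

    The ensemble is split into ``n_groups`` contiguous scan blocks;
    sigma_JK is the delete-one-block jackknife standard deviation of the
    recomputed window volume.  Uses per-block sufficient statistics, so
    each leave-one-out volume is O(window^2), not a full map rebuild.
    A perfectly stable volume (sigma_JK = 0) returns +inf with a warning.
    """
    if n_groups < 2:
        raise ValueError("need >= 2 jackknife groups")
    X = ensemble.intensities
    T = ensemble.tic
    n = ensemble.n_scans
    nb = ensemble.n_bins
    sx, sy = _window_slices(peak.apex[0], peak.apex[1], peak.window, nb)
    Xw, Yw = X[:, sx], X[:, sy]

    # half-TICs from alternating m/z chunks with guard bands, so that a
    # peak profile contributes wholly to one half (or neither) and the two
    # halves carry independent shot noise; cached per ensemble
    if not hasattr(ensemble, "_tic_split"):
        mo, me = _split_masks(nb)
        ensemble._tic_split = (
            X[:, mo].sum(axis=1),
            X[:, me].sum(axis=1),
            mo,
            me,
        )
    To, Te, half_o, half_e = ensemble._tic_split

    blocks = _block_bounds(n, min(n_groups, n))
    g = len(blocks)
    per_block = {
        "x": np.stack([Xw[a:b].sum(axis=0) for a, b in blocks]),
        "y": np.stack([Yw[a:b].sum(axis=0) for a, b in blocks]),
        "xx": np.stack([Xw[a:b].T @ Xw[a:b] for a, b in blocks]),
        "yy": np.stack([Yw[a:b].T @ Yw[a:b] for a, b in blocks]),
        "xy": np.stack([Xw[a:b].T @ Yw[a:b] for a, b in blocks]),
        "xt": np.stack([Xw[a:b].T @ T[a:b] for a, b in blocks]),
        "yt": np.stack([Yw[a:b].T @ T[a:b] for a, b in blocks]),
        "xto": np.stack([Xw[a:b].T @ To[a:b] for a, b in blocks]),
        "xte": np.stack([Xw[a:b].T @ Te[a:b] for a, b in blocks]),
        "yto": np.stack([Yw[a:b].T @ To[a:b] for a, b in blocks]),
        "yte": np.stack([Yw[a:b].T @ Te[a:b] for a, b in blocks]),
        "t": np.array([T[a:b].sum() for a, b in blocks]),
        "tt": np.array([(T[a:b] ** 2).sum() for a, b in blocks]),
        "to": np.array([To[a:b].sum() for a, b in blocks]),
        "te": np.array([Te[a:b].sum() for a, b in blocks]),
        "toto": np.array([(To[a:b] ** 2).sum() for a, b in blocks]),
        "tete": np.array([(Te[a:b] ** 2).sum() for a, b in blocks]),
        "tote": np.array([(To[a:b] * Te[a:b]).sum() for a, b in blocks]),
        "n": np.array([b - a for a, b in blocks]),
    }
    masks = {
        "mask_xo": half_o[sx],
        "mask_xe": half_e[sx],
        "mask_yo": half_o[sy],
        "mask_ye": half_e[sy],
    }
    totals = {k: v.sum(axis=0) for k, v in per_block.items()}
    totals["n"] = int(totals["n"])
    totals.update(masks)
    v_full = _pcov_window_volume(totals, estimator=estimator)

    def leave_out(j):
        s = {k: totals[k] - per_block[k][j] for k in per_block}
        s["n"] = int(s["n"])
        s.update(masks)
        return s

    v_loo = np.array(
        [_pcov_window_volume(leave_out(j), estimator=estimator) for j in range(g)]
    )
    peak.volume = float(v_full)  # keep volume consistent with the score
    sigma = float(np.sqrt((g - 1) / g * np.sum((v_loo - v_loo.mean()) ** 2)))
    if sigma == 0.0:
        warnings.warn(
            "jackknife volume perfectly stable (sigma_JK = 0); score = +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return v_full / sigma


def score_peaks(
    ensemble: ScanEnsemble,
    peaks: Sequence[PeakCandidate],
    n_groups: int = 100,
    estimator: str = "tic",
) -> list[PeakCandidate]:
    """Fill in jackknife scores; returns peaks sorted by score descending."""
    for p in peaks:
        p.score = jackknife_score(ensemble, p, n_groups, estimator)
    return sorted(peaks, key=lambda p: (p.score is None, -(p.score or 0.0)))


def score_at(
    ensemble: ScanEnsemble,
    pmap: PCovMap,
    apex: tuple[int, int],
    window: int = 2,
    n_groups: int = 100,
    estimator: str | None = None,
) -> PeakCandidate:
    """Build and score a candidate at an arbitrary map coordinate
    (used for null-coordinate sampling and direct marker interrogation).
    The estimator defaults to the one that built ``pmap``."""
    if estimator is None:
        estimator = pmap.estimator_params.get("estimator", "tic")
    x, y = (int(apex[0]), int(apex[1]))
    if x > y:
        x, y = y, x
    sx, sy = _window_slices(x, y, window, pmap.matrix.shape[0])
    peak = PeakCandidate(
        apex=(x, y),
        apex_mz=(pmap.mz_of(x), pmap.mz_of(y)),
        apex_height=float(pmap.matrix[x, y]),
        window=window,
        volume=float(pmap.matrix[sx, sy].sum()),
    )
    peak.score = jackknife_score(ensemble, peak, n_groups, estimator)
    return peak


# --- marker matching and quantification -------------------------------------


@dataclass
class MarkerMatch:
    marker: tuple[float, float]
    peak: PeakCandidate
    distance: float  # max coordinate distance, Th


@dataclass
class IsomerEvidence:
    """Per-isomer matched marker correlations and derived quantities.

    When decoy calibration is available (``null_mean``/``null_sd`` set),
    the presence call uses the calibrated combined score: each marker's
    jackknife score is standardised against the decoy-coordinate null and
    the standardised scores are combined Stouffer-style over the isomer's
    marker set.  Without calibration the call falls back to the
    single-best-marker rule (any marker above ``score_threshold``)."""

    matches: Mapping[str, list[MarkerMatch]]
    score_threshold: float
    relative_abundance: dict[str, float] = field(default_factory=dict)
    calibrated: dict[str, float] | None = None
    combined_threshold: float = 3.0

    def best_score(self, isomer: str) -> float:
        ms = self.matches.get(isomer, [])
        return max((m.peak.score or 0.0) for m in ms) if ms else 0.0

    def best_volume(self, isomer: str) -> float:
        ms = [m for m in self.matches.get(isomer, []) if m.peak.score is not None]
        if not ms:
            return 0.0
        return max(ms, key=lambda m: m.peak.score).peak.volume

    def combined_score(self, isomer: str) -> float:
        """Decoy-calibrated Stouffer combination of the isomer's marker
        scores when calibration ran; otherwise the raw combination."""
        if self.calibrated is not None:
            return self.calibrated.get(isomer, 0.0)
        scores = [
            m.peak.score
            for m in self.matches.get(isomer, [])
            if m.peak.score is not None and np.isfinite(m.peak.score)
        ]
        if not scores:
            return 0.0
        return float(sum(scores) / np.sqrt(len(scores)))

    def detected(self, isomer: str) -> bool:
        if self.calibrated is not None:
            return self.combined_score(isomer) >= self.combined_threshold
        return self.best_score(isomer) >= self.score_threshold

    @property
    def isomers(self) -> list[str]:
        return list(self.matches.keys())


def match_markers(
    peaks: Sequence[PeakCandidate],
    marker_pairs: Mapping[str, Sequence[tuple[float, float]]],
    tolerance: float = 0.3,
    score_threshold: float = 5.0,
) -> IsomerEvidence:
    """Assign each theoretical marker pair its nearest scored peak.

    A marker matches at most one peak: the nearest within ``tolerance`` on
    both coordinates (Chebyshev distance); exact distance ties break toward
    the higher-scoring peak.  Unmatched markers are simply absent from the
    result.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    matches: dict[str, list[MarkerMatch]] = {iso: [] for iso in marker_pairs}
    for iso, pairs in marker_pairs.items():
        for a, b in pairs:
            lo, hi = (a, b) if a <= b else (b, a)
            best: MarkerMatch | None = None
            for p in peaks:
                d = max(abs(p.apex_mz[0] - lo), abs(p.apex_mz[1] - hi))
                if d > tolerance:
                    continue
                if (
                    best is None
                    or d < best.distance - 1e-12
                    or (
                        abs(d - best.distance) <= 1e-12
                        and (p.score or 0.0) > (best.peak.score or 0.0)
                    )
                ):
                    best = MarkerMatch(marker=(lo, hi), peak=p, distance=d)
            if best is not None:
                matches[iso].append(best)
    return IsomerEvidence(matches=matches, score_threshold=score_threshold)


def select_marker_pairs(
    iso_set,
    names: Sequence[str] | None = None,
    mz_range: tuple[float, float] | None = None,
    min_separation: float = 2.0,
    max_per_isomer: int | None = None,
    uniqueness_tolerance: float = 0.3,
) -> dict[str, list[tuple[float, float]]]:
    """Theoretical unique 2D marker pairs per isomer, restricted to the
    measurable region: both coordinates inside ``mz_range`` and at least
    ``min_separation`` Th apart (near-diagonal pairs are swallowed by the
    autocorrelation band and cannot be interrogated).

    Uniqueness is assessed at ``uniqueness_tolerance`` — the instrument
    matching tolerance, not the exact in-silico one — so that a selected
    marker cannot collide with another isomer's correlation within the
    resolution actually available on the map."""
    from .combinatorics import find_unique_markers

    report = find_unique_markers(
        iso_set, mode="2d", tolerance=uniqueness_tolerance
    )
    if names is None:
        names = report.isomer_labels
    out: dict[str, list[tuple[float, float]]] = {}
    for name, pairs in zip(names, report.unique):
        sel = [
            p
            for p in pairs
            if (p[1] - p[0]) >= min_separation
            and (
                mz_range is None
                or (mz_range[0] < p[0] and p[1] < mz_range[1])
            )
        ]
        out[name] = sel[:max_per_isomer] if max_per_isomer else sel
    return out


def interrogate_markers(
    ensemble: ScanEnsemble,
    pmap: PCovMap,
    marker_pairs: Mapping[str, Sequence[tuple[float, float]]],
    window: int = 2,
    n_groups: int = 100,
    refine: int = 1,
) -> list[PeakCandidate]:
    """Score the map at every theoretical marker coordinate.

    Each marker (a, b) is snapped to its grid bin, refined to the local
    apex within ``refine`` bins, and jackknife-scored.  Returns the
    deduplicated candidate list, ready for :func:`match_markers`.
    """
    M = pmap.matrix
    n = M.shape[0]
    grid = pmap.mz_grid
    step = grid[1] - grid[0]
    seen: dict[tuple[int, int], PeakCandidate] = {}
    for pairs in marker_pairs.values():
        for a, b in pairs:
            ix = int(np.floor((min(a, b) - (grid[0] - step / 2)) / step))
            iy = int(np.floor((max(a, b) - (grid[0] - step / 2)) / step))
            if not (0 <= ix < n and 0 <= iy < n):
                continue
            best = (ix, iy)
            for dx in range(-refine, refine + 1):
                for dy in range(-refine, refine + 1):
                    x, y = ix + dx, iy + dy
                    if 0 <= x < n and 0 <= y < n and M[x, y] > M[best]:
                        best = (x, y)
            if best not in seen:
                seen[best] = score_at(ensemble, pmap, best, window, n_groups)
    return list(seen.values())


def _channel_load(iso_set, max_charge: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per fragment m/z, the number of co-production channels (summed over
    candidate isomers) depositing there — an a-priori contamination proxy
    for map coordinates, computable from theory alone."""
    from .combinatorics import correlation_pairs

    loads: dict[float, int] = {}
    for iso in iso_set.isomers:
        for fa, fb in correlation_pairs(iso, max_charge=max_charge):
            for f in (fa, fb):
                key = round(f.mz, 4)
                loads[key] = loads.get(key, 0) + 1
    mzs = np.array(sorted(loads))
    return mzs, np.array([loads[m] for m in mzs], dtype=float)


def _coordinate_load(
    mzs: np.ndarray, weights: np.ndarray, mz: float, halfwidth: float = 0.3
) -> float:
    i0, i1 = np.searchsorted(mzs, (mz - halfwidth, mz + halfwidth))
    return float(weights[i0:i1].sum())


def rank_markers_by_cleanliness(
    markers: Mapping[str, Sequence[tuple[float, float]]],
    iso_set,
    max_charge: int = 1,
    halfwidth: float = 0.3,
) -> dict[str, list[tuple[float, float]]]:
    """Order each isomer's markers by predicted coordinate contamination
    (product of theoretical channel loads at the two m/z values), cleanest
    first.  Interrogating clean coordinates first maximises the power of
    the combined evidence score."""
    mzs, w = _channel_load(iso_set, max_charge)
    out = {}
    for name, pairs in markers.items():
        scored = sorted(
            pairs,
            key=lambda p: _coordinate_load(mzs, w, p[0], halfwidth)
            * _coordinate_load(mzs, w, p[1], halfwidth),
        )
        out[name] = list(scored)
    return out


def sample_decoy_pairs(
    iso_set,
    n: int,
    rng: np.random.Generator,
    mz_range: tuple[float, float],
    min_separation: float = 2.0,
    tolerance: float = 0.3,
    max_charge: int = 1,
) -> list[tuple[float, float]]:
    """Decoy coordinate pairs for score calibration: both coordinates are
    theoretical fragment m/z values of the candidate isomers (so they carry
    realistic spectral contamination) but the pair is not within tolerance
    of any candidate isomer's correlation pair (so it carries no genuine
    co-fragmentation signal)."""
    from .chem import generate_fragments
    from .combinatorics import signature_2d

    frag_mzs = sorted(
        {
            round(f.mz, 4)
            for iso in iso_set.isomers
            for f in generate_fragments(
                iso, ("b", "y", "internal_b"), max_charge
            )
            if mz_range[0] < f.mz < mz_range[1]
        }
    )
    sigs = signature_2d(iso_set, max_charge=max_charge)
    all_pairs = sorted({p for sig in sigs for p in sig})
    firsts = np.array([p[0] for p in all_pairs])

    def is_true_pair(a: float, b: float) -> bool:
        i0, i1 = np.searchsorted(firsts, (a - tolerance, a + tolerance))
        return any(abs(all_pairs[i][1] - b) <= tolerance for i in range(i0, i1))

    decoys: list[tuple[float, float]] = []
    attempts = 0
    while len(decoys) < n and attempts < 100 * n:
        attempts += 1
        a, b = rng.choice(frag_mzs, size=2, replace=False)
        a, b = (float(a), float(b)) if a < b else (float(b), float(a))
        if b - a < min_separation or is_true_pair(a, b):
            continue
        decoys.append((a, b))
    return decoys


def identify_isomers(
    ensemble: ScanEnsemble,
    iso_set,
    names: Sequence[str] | None = None,
    estimator: str = "self_correcting",
    window: int = 1,
    n_groups: int = 100,
    tolerance: float = 0.3,
    score_threshold: float = 5.0,
    combined_threshold: float = 3.0,
    min_marker_separation: float = 2.0,
    max_markers_per_isomer: int | None = 10,
    n_decoys: int = 200,
    seed: int | None = 0,
    pmap: PCovMap | None = None,
) -> tuple[IsomerEvidence, PCovMap]:
    """End-to-end isomer identification: map -> marker interrogation ->
    decoy-calibrated evidence.

    Each candidate isomer's unique marker correlations (cleanest
    ``max_markers_per_isomer``, ranked by predicted coordinate
    contamination) are interrogated and jackknife-scored on the map.
    Decoy coordinates — fragment-m/z pairs that no candidate isomer can
    co-produce — provide the empirical null; an isomer is reported present
    when its calibrated combined marker score exceeds
    ``combined_threshold`` null standard deviations."""
    if pmap is None:
        pmap = compute_pcov_map(ensemble, estimator=estimator)
    lo = float(ensemble.mz_grid[0])
    hi = float(ensemble.mz_grid[-1])
    step = float(ensemble.mz_grid[1] - ensemble.mz_grid[0])
    # a marker must be unique out to the full reach of the interrogation:
    # matching tolerance + apex refinement + integration window + the
    # extent of a peak profile (so no tail of a genuine correlation of
    # another isomer can leak into the window)
    exclusion = tolerance + (window + 1) * step
    markers = select_marker_pairs(
        iso_set,
        names,
        mz_range=(lo + tolerance, hi - tolerance),
        min_separation=min_marker_separation,
        uniqueness_tolerance=exclusion,
    )
    markers = rank_markers_by_cleanliness(
        {n: p for n, p in markers.items()}, iso_set
    )
    if max_markers_per_isomer:
        markers = {
            n: p[:max_markers_per_isomer] for n, p in markers.items()
        }
    peaks = interrogate_markers(ensemble, pmap, markers, window, n_groups)
    evidence = match_markers(peaks, markers, tolerance, score_threshold)
    evidence.combined_threshold = combined_threshold

    if n_decoys > 0:
        rng = np.random.default_rng(seed)
        decoys = sample_decoy_pairs(
            iso_set,
            n_decoys,
            rng,
            (lo + tolerance, hi - tolerance),
            min_separation=min_marker_separation,
            tolerance=tolerance,
        )
        decoy_peaks = interrogate_markers(
            ensemble, pmap, {"__decoy__": decoys}, window, n_groups
        )
        # decoy scores carry a contamination-dependent bias (busier
        # coordinates are pulled down harder by the TIC correction), so
        # the null is modelled as a linear function of log channel load
        # and each marker is standardised against its own load stratum
        mzs_l, w_l = _channel_load(iso_set)

        def load_of(pair):
            return np.log1p(
                _coordinate_load(mzs_l, w_l, pair[0])
                * _coordinate_load(mzs_l, w_l, pair[1])
            )

        d_scores, d_loads = [], []
        for p, d in zip(decoy_peaks, decoys):
            if np.isfinite(p.score):
                d_scores.append(p.score)
                d_loads.append(load_of(d))
        if len(d_scores) >= 20:
            A = np.vstack([np.ones(len(d_loads)), d_loads]).T
            coef, *_ = np.linalg.lstsq(A, np.array(d_scores), rcond=None)
            resid = np.array(d_scores) - A @ coef
            sd = float(resid.std(ddof=2)) or 1.0
            calibrated = {}
            for iso_name, ms in evidence.matches.items():
                zs = [
                    (m.peak.score - (coef[0] + coef[1] * load_of(m.marker))) / sd
                    for m in ms
                    if m.peak.score is not None and np.isfinite(m.peak.score)
                ]
                calibrated[iso_name] = (
                    float(sum(zs) / np.sqrt(len(zs))) if zs else 0.0
                )
            evidence.calibrated = calibrated
    return evidence, pmap


def relative_quantify(
    evidence: IsomerEvidence, rule: str = "median"
) -> dict[str, float]:
    """Abundance fractions proportional to matched marker-correlation
    volumes (correlation volume is proportional to precursor
    concentration).  ``rule='median'`` takes each isomer's median positive
    marker volume, which is robust against the occasional marker whose
    coordinate aggregates several dissociation channels;
    ``rule='best'`` uses the single highest-scoring marker."""
    volumes: dict[str, float] = {}
    for iso in evidence.isomers:
        if not evidence.matches.get(iso):
            continue
        if rule == "best":
            v = evidence.best_volume(iso)
        elif rule == "median":
            pos = [
                m.peak.volume for m in evidence.matches[iso] if m.peak.volume > 0
            ]
            v = float(np.median(pos)) if pos else 0.0
        else:
            raise ValueError(f"unknown quantification rule {rule!r}")
        volumes[iso] = v
    volumes = {iso: v for iso, v in volumes.items() if v > 0}
    if not volumes:
        raise ValueError("no positive marker-correlation volumes to quantify")
    total = sum(volumes.values())
    fractions = {iso: v / total for iso, v in volumes.items()}
    evidence.relative_abundance = fractions
    return fractions
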