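"""Free-energy reconstruction from biased and unbiased sampling.

Implements the two estimators used to turn umbrella-sampling window data into
potentials of mean force:

* WHAM — the weighted histogram analysis method, solving the standard
  self-consistent equations for the unbiased bin probabilities ``p_j`` and the
  per-window free energies ``f_i``:

      p_j ∝ M_j / Σ_i N_i exp(β(f_i − w_ij)),
      exp(−β f_i) = Σ_j p_j exp(−β w_ij),

  where ``M_j`` is the pooled count in bin j, ``N_i`` the sample count of
  window i, and ``w_ij`` the bias energy of window i evaluated at bin j.

* DHAM — the dynamic histogram analysis method: per-window transition counts
  between bins at a fixed lag are combined into a single unbiased Markov
  transition matrix using symmetric square-root bias factors
  ``exp(−β(w_ik − w_ij)/2)``; the free energy is read off the stationary
  distribution.

Both report ΔG relative to bulk solvent: profiles are shifted so the mean of
G over bins with |z| ∈ [24, 25] Å is zero (falling back to the mean over all
occupied bins for toy datasets that never reach the bulk region).

Block-splitting error bars (5 equal-length segments per window by default),
unbiased-density free energies for freely diffusing ions, integrated
autocorrelation times, and extrema/barrier readout complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .potentials import (
    CylinderRestraint,
    HarmonicBias,
    T_DEFAULT,
    bias_energy,
    thermal_energy,
)

BULK_ANCHOR_RANGE = (24.0, 25.0)  # |z| band averaged to zero


class WhamGapError(ValueError):
    """Adjacent umbrella windows share no occupied histogram bin."""


class ConvergenceError(RuntimeError):
    """Self-consistent iteration did not converge within max_iter."""


class ConnectivityError(ValueError):
    """The DHAM transition graph over visited bins is disconnected."""


@dataclass
class UmbrellaWindowData:
    """One umbrella window: bias parameters plus the sampled (time, z, b) series."""

    bias: HarmonicBias | None
    restraint: CylinderRestraint
    T: float
    time: np.ndarray  # ps
    z: np.ndarray  # Å
    b: np.ndarray  # Å
    sample_interval: float  # ps
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.z.size < 2:
            raise ValueError("window must contain at least 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.z.size

    def slice(self, start: int, stop: int) -> "UmbrellaWindowData":
        return UmbrellaWindowData(
            bias=self.bias,
            restraint=self.restraint,
            T=self.T,
            time=self.time[start:stop],
            z=self.z[start:stop],
            b=self.b[start:stop],
            sample_interval=self.sample_interval,
            meta=dict(self.meta),
        )


@dataclass
class FreeEnergyProfile:
    """Binned ΔG estimate anchored to the bulk region.

    ``G`` is NaN in bins with no occupancy. For 1D profiles ``bin_centers``
    is a 1D array; for 2D surfaces it is a (z_centers, b_centers) tuple and
    ``G`` has shape (n_z, n_b).
    """

    bin_centers: np.ndarray | tuple[np.ndarray, np.ndarray]
    G: np.ndarray  # kcal·mol⁻¹
    stderr: np.ndarray | None
    anchor: str
    n_eff: np.ndarray
    T: float = T_DEFAULT

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.G)


@dataclass
class AcfResult:
    """Normalized autocorrelation function and integrated autocorrelation time."""

    lags: np.ndarray  # ps
    acf: np.ndarray
    tau: float  # ps


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def _anchor_1d(centers: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, str]:
    absz = np.abs(centers)
    bulk = (absz >= BULK_ANCHOR_RANGE[0]) & (absz <= BULK_ANCHOR_RANGE[1])
    bulk &= np.isfinite(G)
    if np.any(bulk):
        shift = float(np.mean(G[bulk]))
        desc = f"mean G over occupied bins with |z| in {BULK_ANCHOR_RANGE} set to 0"
    else:
        shift = float(np.nanmean(G))
        desc = "mean G over all occupied bins set to 0 (no bulk bins present)"
    return G - shift, desc


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


def _check_overlap(
    windows: list[UmbrellaWindowData], hists: np.ndarray, centers: np.ndarray
) -> None:
    """Every adjacent pair of windows (by center) must share an occupied bin."""
    biased = [i for i, w in enumerate(windows) if w.bias is not None]
    if len(biased) < 2:
        return
    order = sorted(biased, key=lambda i: windows[i].bias.z0)
    for a, bidx in zip(order[:-1], order[1:]):
        if not np.any((hists[a] > 0) & (hists[bidx] > 0)):
            raise WhamGapError(
                "no mutually occupied bin between windows centered at "
                f"z0={windows[a].bias.z0:g} and z0={windows[bidx].bias.z0:g} Å"
            )


def _bias_matrix(
    windows: list[UmbrellaWindowData], z_centers: np.ndarray
) -> np.ndarray:
    w = np.zeros((len(windows), z_centers.size))
    for i, win in enumerate(windows):
        w[i] = bias_energy(win.bias, win.restraint, z_centers, 0.0)
    return w


def _wham_solve(
    counts: np.ndarray,
    w_mat: np.ndarray,
    kT: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent iteration; returns (p over bins, f per window)."""
    N = counts.sum(axis=1)  # samples per window
    M = counts.sum(axis=0)  # pooled counts per bin
    occ = M > 0
    B = np.exp(-w_mat / kT)  # (n_win, n_bins)
    f = np.zeros(len(N))
    p = np.zeros(w_mat.shape[1])
    for _ in range(int(max_iter)):
        weights = N * np.exp(f / kT)  # (n_win,)
        denom = weights @ B  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occ & (denom > 0), M / denom, 0.0)
        total = p.sum()
        if total <= 0:
            raise ValueError("all histogram bins empty")
        p /= total
        f_new = -kT * np.log(B @ p)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol * kT:
            return p, f
    raise ConvergenceError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(residual {delta / kT:.3e} kBT, tol {tol:g} kBT)"
    )


def wham_1d(
    windows: list[UmbrellaWindowData],
    bin_edges: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> FreeEnergyProfile:
    """1D WHAM over the z coordinate.

    Requires uniform temperature across windows and histogram overlap between
    adjacent windows. The result is anchored to the bulk region.
    """
    if not windows:
        raise ValueError("no windows supplied")
    T = windows[0].T
    if any(abs(w.T - T) > 1e-9 for w in windows):
        raise ValueError("windows must share one temperature")
    kT = thermal_energy(T)
    edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(w.z, bins=edges)[0] for w in windows]).astype(float)
    _check_overlap(windows, counts, centers)
    w_mat = _bias_matrix(windows, centers)
    p, _ = _wham_solve(counts, w_mat, kT, tol, max_iter)
    M = counts.sum(axis=0)
    with np.errstate(divide="ignore"):
        G = np.where(p > 0, -kT * np.log(p), np.nan)
    G, anchor = _anchor_1d(centers, G)
    return FreeEnergyProfile(
        bin_centers=centers, G=G, stderr=None, anchor=anchor, n_eff=M, T=T
    )


def wham_2d(
    windows: list[UmbrellaWindowData],
    z_edges: np.ndarray,
    b_edges: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    jacobian_correct: bool = True,
) -> FreeEnergyProfile:
    """2D WHAM over (z, b). The umbrella bias depends only on z.

    With ``jacobian_correct`` the distance-from-axis measure is removed:
    G(z, b) = −kBT·ln(p / b_center), so a flat landscape stays flat in b.
    """
    if not windows:
        raise ValueError("no windows supplied")
    T = windows[0].T
    if any(abs(w.T - T) > 1e-9 for w in windows):
        raise ValueError("windows must share one temperature")
    kT = thermal_energy(T)
    z_edges = np.asarray(z_edges, dtype=float)
    b_edges = np.asarray(b_edges, dtype=float)
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    bc = 0.5 * (b_edges[:-1] + b_edges[1:])
    nz, nb = zc.size, bc.size
    counts2 = np.stack(
        [np.histogram2d(w.z, w.b, bins=(z_edges, b_edges))[0] for w in windows]
    ).astype(float)
    counts_flat = counts2.reshape(len(windows), nz * nb)
    # overlap check on the z marginal (bias varies only along z)
    _check_overlap(windows, counts2.sum(axis=2), zc)
    w_z = _bias_matrix(windows, zc)  # (n_win, nz)
    w_flat = np.repeat(w_z, nb, axis=1)
    p_flat, _ = _wham_solve(counts_flat, w_flat, kT, tol, max_iter)
    p = p_flat.reshape(nz, nb)
    M = counts2.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = p / bc[None, :] if jacobian_correct else p
        G = np.where(p > 0, -kT * np.log(dens), np.nan)
    # anchor on bulk z-slices
    absz = np.abs(zc)
    bulk = (absz >= BULK_ANCHOR_RANGE[0]) & (absz <= BULK_ANCHOR_RANGE[1])
    sel = np.isfinite(G) & bulk[:, None]
    if np.any(sel):
        shift = float(np.mean(G[sel]))
        anchor = f"mean G over occupied bins with |z| in {BULK_ANCHOR_RANGE} set to 0"
    else:
        shift = float(np.nanmean(G))
        anchor = "mean G over all occupied bins set to 0 (no bulk bins present)"
    return FreeEnergyProfile(
        bin_centers=(zc, bc), G=G - shift, stderr=None, anchor=anchor, n_eff=M, T=T
    )


# ---------------------------------------------------------------------------
# DHAM
# ---------------------------------------------------------------------------


def dham_1d(
    windows: list[UmbrellaWindowData],
    bin_edges: np.ndarray,
    lag: int = 1,
) -> FreeEnergyProfile:
    """Markov-model unbiasing of window transition counts at a fixed lag.

    The unbiased transition matrix is the maximum-likelihood combination of
    the per-window counts with the symmetric bias factor
    exp(−(w_k − w_j)/(2 kBT)); G = −kBT·ln π of its stationary distribution.
    Unvisited bins are removed from the chain and reported as NaN.
    """
    if not windows:
        raise ValueError("no windows supplied")
    if lag < 1:
        raise ValueError("lag must be ≥ 1")
    T = windows[0].T
    kT = thermal_energy(T)
    edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nbins = centers.size
    w_mat = _bias_matrix(windows, centers)

    C = np.zeros((len(windows), nbins, nbins))
    for i, win in enumerate(windows):
        idx = np.digitize(win.z, edges) - 1
        idx[(win.z < edges[0]) | (win.z >= edges[-1])] = -1
        src, dst = idx[:-lag], idx[lag:]
        ok = (src >= 0) & (dst >= 0)
        np.add.at(C[i], (src[ok], dst[ok]), 1.0)

    total = C.sum(axis=0)
    visited = (total.sum(axis=0) + total.sum(axis=1)) > 0
    # MLE combination: M_jk = Σ_i c^i_jk / Σ_i n^i_j · exp(−(w_ik − w_ij)/2kT)
    n_from = C.sum(axis=2)  # (n_win, nbins) transition starts per bin
    M_num = total
    # exponent clipped: overflowing pairs are bins never linked by a
    # transition, but 0·inf would otherwise poison the einsum with NaN
    expo = np.clip(-(w_mat[:, None, :] - w_mat[:, :, None]) / (2.0 * kT), -700, 700)
    factor = np.exp(expo)
    M_den = np.einsum("ij,ijk->jk", n_from, factor)
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(M_den > 0, M_num / M_den, 0.0)

    keep = visited & (M.sum(axis=1) > 0)
    if keep.sum() < 2:
        raise ConnectivityError("fewer than 2 visited bins with outgoing transitions")
    Mk = M[np.ix_(keep, keep)]
    n_comp, _ = connected_components(
        (Mk + Mk.T) > 0, directed=False, return_labels=True
    )
    if n_comp > 1:
        raise ConnectivityError(
            f"transition graph over visited bins has {n_comp} disconnected components"
        )
    Tm = Mk / Mk.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(Tm.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    pi = np.abs(pi)
    pi /= pi.sum()

    G = np.full(nbins, np.nan)
    G[keep] = -kT * np.log(pi)
    G, anchor = _anchor_1d(centers, G)
    n_eff = total.sum(axis=0)
    return FreeEnergyProfile(
        bin_centers=centers, G=G, stderr=None, anchor=anchor, n_eff=n_eff, T=T
    )


# ---------------------------------------------------------------------------
# block errors
# ---------------------------------------------------------------------------


def split_block_errors(
    windows: list[UmbrellaWindowData],
    n_blocks: int = 5,
    estimator=wham_1d,
    **estimator_kwargs,
) -> FreeEnergyProfile:
    """Segment-wise error estimate.

    Each window's time series is divided into ``n_blocks`` equal-length
    contiguous segments; the estimator runs independently on each segment
    dataset, and the per-bin mean and standard error of the mean across
    segments are reported. Bins not occupied in every segment are NaN.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be ≥ 2")
    for w in windows:
        if w.n_samples < n_blocks:
            raise ValueError(
                f"window at z0={getattr(w.bias, 'z0', None)} has {w.n_samples} "
                f"samples; needs ≥ {n_blocks}"
            )
    profiles = []
    for blk in range(n_blocks):
        block_windows = []
        for w in windows:
            seg = w.n_samples // n_blocks
            block_windows.append(w.slice(blk * seg, (blk + 1) * seg))
        profiles.append(estimator(block_windows, **estimator_kwargs))
    Gs = np.stack([p.G for p in profiles])
    all_occ = np.all(np.isfinite(Gs), axis=0)
    mean = np.where(all_occ, np.mean(Gs, axis=0), np.nan)
    sem = np.where(
        all_occ, np.std(Gs, axis=0, ddof=1) / np.sqrt(n_blocks), np.nan
    )
    ref = profiles[0]
    return FreeEnergyProfile(
        bin_centers=ref.bin_centers,
        G=mean,
        stderr=sem,
        anchor=ref.anchor + f"; mean ± SEM over {n_blocks} equal-length segments",
        n_eff=np.sum([p.n_eff for p in profiles], axis=0),
        T=ref.T,
    )


# ---------------------------------------------------------------------------
# unbiased densities (free ions)
# ---------------------------------------------------------------------------


def density_free_energy(
    trajectories,
    bin_edges: np.ndarray,
    T: float = T_DEFAULT,
    weights=None,
) -> FreeEnergyProfile:
    """G = −kBT·ln(density) from pooled unbiased trajectories.

    ``trajectories`` is a list of UmbrellaWindowData (bias-free) or plain
    arrays of z samples; all samples are pooled, so the result is independent
    of how many copies of the same trajectory are supplied. Importance-sampled
    input is supported through ``weights`` (one array per trajectory): the
    histogram then accumulates weights instead of counts, letting rarely
    visited high-barrier regions be represented accurately.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    zs = []
    for t in trajectories:
        zs.append(t.z if isinstance(t, UmbrellaWindowData) else np.asarray(t, float))
    z = np.concatenate(zs)
    w = None
    if weights is not None:
        w = np.concatenate([np.asarray(wi, dtype=float) for wi in weights])
        if w.shape != z.shape:
            raise ValueError("weights must match samples one-to-one")
    edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(z, bins=edges)
    mass, _ = np.histogram(z, bins=edges, weights=w)
    if mass.sum() == 0:
        raise ValueError("all histogram bins are empty")
    dens = mass / mass.sum()
    kT = thermal_energy(T)
    with np.errstate(divide="ignore"):
        G = np.where(mass > 0, -kT * np.log(dens), np.nan)
    G, anchor = _anchor_1d(centers, G)
    return FreeEnergyProfile(
        bin_centers=centers,
        G=G,
        stderr=None,
        anchor=anchor,
        n_eff=counts.astype(float),
        T=T,
    )


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------


def autocorrelation(
    series,
    max_lag: int | None = None,
    sample_interval: float = 1.0,
) -> AcfResult:
    """Normalized ACF and the integrated autocorrelation time.

    τ = Δt · (1 + 2·Σ acf(k)), with the sum truncated at the first negative
    ACF value (initial-positive-sequence rule). The floor is one sampling
    interval.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / x.size
    if c0 <= 0:
        raise ValueError("series has zero variance")
    n = x.size
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)
    # FFT-based autocovariance
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1] / n
    acf = acov / acov[0]
    neg = np.nonzero(acf[1:] < 0)[0]
    m = int(neg[0]) if neg.size else max_lag  # lags 1..m kept
    tau = sample_interval * (1.0 + 2.0 * float(np.sum(acf[1 : m + 1])))
    tau = max(tau, sample_interval)
    lags = sample_interval * np.arange(max_lag + 1)
    return AcfResult(lags=lags, acf=acf, tau=tau)


# ---------------------------------------------------------------------------
# extrema / barriers
# ---------------------------------------------------------------------------


@dataclass
class ProfileFeature:
    z: float
    G: float
    kind: str  # "minimum" | "maximum"
    barrier: float | None  # for maxima: ΔG‡ above the lower adjacent minimum


def profile_features(
    profile: FreeEnergyProfile, smooth_bins: int = 3
) -> list[ProfileFeature]:
    """Local extrema of a 1D profile, with barrier heights for each maximum.

    A light moving-average smoothing (``smooth_bins``-wide, set 0/1 to
    disable) suppresses single-bin noise before extremum detection; reported
    G values come from the unsmoothed profile.
    """
    centers = np.asarray(profile.bin_centers)
    if centers.ndim != 1:
        raise ValueError("profile_features requires a 1D profile")
    occ = np.isfinite(profile.G)
    z = centers[occ]
    G = profile.G[occ]
    if G.size < 3:
        return []
    Gs = G
    if smooth_bins and smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        pad = smooth_bins // 2
        padded = np.pad(G, pad, mode="edge")
        Gs = np.convolve(padded, kernel, mode="valid")[: G.size]

    features: list[ProfileFeature] = []
    d = np.diff(Gs)
    for i in range(1, Gs.size - 1):
        left = d[i - 1]
        right = d[i]
        # ties on the trailing side (an extremum falling exactly between two
        # bins) count, so symmetric peaks straddling a bin edge are found
        if left < 0 and right >= 0 and not (left == 0 and right == 0):
            features.append(ProfileFeature(float(z[i]), float(G[i]), "minimum", None))
        elif left > 0 and right <= 0:
            features.append(ProfileFeature(float(z[i]), float(G[i]), "maximum", None))
    # barrier = height above the lower of the adjacent minima
    for j, f in enumerate(features):
        if f.kind != "maximum":
            continue
        adj = []
        for k in range(j - 1, -1, -1):
            if features[k].kind == "minimum":
                adj.append(features[k].G)
                break
        for k in range(j + 1, len(features)):
            if features[k].kind == "minimum":
                adj.append(features[k].G)
                break
        ref = min(adj) if adj else 0.0
        features[j] = ProfileFeature(f.z, f.G, f.kind, f.G - ref)
    return features
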