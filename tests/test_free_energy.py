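"""Estimator checks: oracle equivalence, analytic limits, recovery of planted
free-energy features, block-error behaviour and autocorrelation times."""

import numpy as np
import pytest
from scipy import signal

from poreflux import (
    HarmonicBias,
    CylinderRestraint,
    FreeEnergyProfile,
    SimulationSpec,
    UmbrellaWindowData,
    autocorrelation,
    density_free_energy,
    dham_1d,
    generate_us_dataset,
    get_fixture,
    profile_features,
    split_block_errors,
    thermal_energy,
    wham_1d,
    wham_2d,
)
from poreflux.free_energy import ConvergenceError, WhamGapError
from poreflux.potentials import PmfModel

from conftest import BIN_EDGES

KT = thermal_energy()


# ---------------------------------------------------------------------------
# independent brute-force WHAM oracle: plain-loop fixed-point solver of the
# same self-consistent equations, written without any shared code paths
# ---------------------------------------------------------------------------


def brute_force_wham(windows, bin_edges, n_iter=200_000, tol=1e-13):
    edges = np.asarray(bin_edges)
    centers = [(edges[j] + edges[j + 1]) / 2.0 for j in range(len(edges) - 1)]
    nbins = len(centers)
    nwin = len(windows)
    kT = thermal_energy(windows[0].T)
    hist = []
    for w in windows:
        h = [0] * nbins
        for val in w.z:
            for j in range(nbins):
                if edges[j] <= val < edges[j + 1]:
                    h[j] += 1
                    break
        hist.append(h)
    N = [sum(h) for h in hist]
    M = [sum(hist[i][j] for i in range(nwin)) for j in range(nbins)]
    bias = [
        [
            0.5 * w.bias.k * (centers[j] - w.bias.z0) ** 2 if w.bias else 0.0
            for j in range(nbins)
        ]
        for w in windows
    ]
    f = [0.0] * nwin
    p = [0.0] * nbins
    for _ in range(n_iter):
        for j in range(nbins):
            denom = 0.0
            for i in range(nwin):
                denom += N[i] * np.exp((f[i] - bias[i][j]) / kT)
            p[j] = M[j] / denom if (M[j] > 0 and denom > 0) else 0.0
        s = sum(p)
        p = [pj / s for pj in p]
        f_new = []
        for i in range(nwin):
            acc = sum(p[j] * np.exp(-bias[i][j] / kT) for j in range(nbins))
            f_new.append(-kT * np.log(acc))
        delta = max(abs(a - b) for a, b in zip(f, f_new))
        f = f_new
        if delta < tol:
            break
    G = [(-kT * np.log(pj) if pj > 0 else np.nan) for pj in p]
    finite = [g for g in G if np.isfinite(g)]
    shift = sum(finite) / len(finite)
    return np.array(centers), np.array([g - shift for g in G])


class TestWham1d:
    def test_matches_brute_force_oracle(self, toy_windows):
        edges = np.linspace(-2.5, 2.5, 11)
        prof = wham_1d(toy_windows, edges, tol=1e-12)
        zc, G_oracle = brute_force_wham(toy_windows, edges)
        occ = np.isfinite(prof.G) & np.isfinite(G_oracle)
        # both anchored to their occupied-bin mean (toy has no bulk bins)
        assert np.max(np.abs(prof.G[occ] - G_oracle[occ])) < 1e-8

    def test_zero_bias_degenerates_to_histogram(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(-5, 5, 20_000)
        w = UmbrellaWindowData(
            bias=HarmonicBias(0.0, 0.0),
            restraint=CylinderRestraint(),
            T=303.15,
            time=np.arange(z.size, dtype=float),
            z=z,
            b=np.zeros_like(z),
            sample_interval=1.0,
        )
        prof = wham_1d([w], np.linspace(-5, 5, 21))
        counts, _ = np.histogram(z, bins=np.linspace(-5, 5, 21))
        direct = -KT * np.log(counts / counts.sum())
        direct -= direct.mean()
        np.testing.assert_allclose(prof.G, direct, atol=1e-10)
        # flat within sampling error
        assert np.ptp(prof.G) < 0.1

    def test_gauge_invariance_under_constant_offset(self):
        # adding a constant to the PMF leaves forces, samples and therefore
        # every anchored ΔG unchanged
        base = get_fixture("barrier_1")
        shifted = PmfModel(name="shifted", terms=base.terms)

        class Offset(PmfModel):
            def energy(self, z, b=None):
                return super().energy(z, b) + 123.0

        off = Offset(name="off", terms=base.terms)
        wins = [HarmonicBias(z, 5.0) for z in np.arange(-8, -3.9, 0.5)]
        spec = SimulationSpec(model=base, bias=None, n_steps=2000, sample_stride=2)
        edges = np.arange(-9.25, -2.74, 0.5)
        d1 = generate_us_dataset(base, wins, spec_defaults=spec, seed=3)
        d2 = generate_us_dataset(off, wins, spec_defaults=spec, seed=3)
        p1 = wham_1d(d1, edges)
        p2 = wham_1d(d2, edges)
        np.testing.assert_array_equal(p1.G, p2.G)

    def test_gap_between_windows_reported(self):
        model = get_fixture("flat")
        wins = [HarmonicBias(-10.0, 5.0), HarmonicBias(10.0, 5.0)]
        spec = SimulationSpec(model=model, bias=None, n_steps=1000, sample_stride=2)
        data = generate_us_dataset(model, wins, spec_defaults=spec, seed=2)
        with pytest.raises(WhamGapError, match="z0=-10"):
            wham_1d(data, BIN_EDGES)

    def test_max_iter_exceeded_raises(self, us_dataset_38):
        with pytest.raises(ConvergenceError):
            wham_1d(us_dataset_38[:20], BIN_EDGES, tol=1e-12, max_iter=3)

    def test_recovers_planted_barrier(self, us_dataset_38):
        blocks = split_block_errors(us_dataset_38, n_blocks=5, bin_edges=BIN_EDGES)
        feats = profile_features(blocks)
        maxima = [f for f in feats if f.kind == "maximum"]
        peak = min(maxima, key=lambda f: abs(f.z + 6.0))
        pooled = float(np.sqrt(np.nanmean(blocks.stderr**2)))
        assert abs(peak.G - 3.8) < 3 * pooled


@pytest.fixture(scope="module")
def flat_2d_windows():
    # a narrow cylinder and fast diffusion so the radial coordinate fully
    # equilibrates within the run; the first quarter is discarded because b
    # starts uniform in [0, b_max/2], away from its ∝ b stationary density
    model = PmfModel(name="flat_2d", dimensionality=2, radial_stiffness=0.0)
    wins = [HarmonicBias(z, 5.0) for z in np.arange(-3, 3.1, 0.5)]
    restraint = CylinderRestraint(b_max=6.0)
    spec = SimulationSpec(
        model=model, bias=None, restraint=restraint,
        n_steps=40_000, sample_stride=4, D=2.0,
    )
    data = generate_us_dataset(model, wins, restraint, spec_defaults=spec, seed=21)
    return [w.slice(w.n_samples // 4, w.n_samples) for w in data]


FLAT2D_Z_EDGES = np.arange(-3.25, 3.26, 0.5)
FLAT2D_B_EDGES = np.arange(0.5, 6.01, 0.5)


class TestWham2d:
    def test_jacobian_on_flattens_b(self, flat_2d_windows):
        prof = wham_2d(
            flat_2d_windows, FLAT2D_Z_EDGES, FLAT2D_B_EDGES, jacobian_correct=True
        )
        # the pure distance-from-axis measure is removed: no trend with b
        g_of_b = np.nanmean(prof.G, axis=0)
        assert np.ptp(g_of_b[np.isfinite(g_of_b)]) < 0.15

    def test_jacobian_off_shows_entropic_measure(self, flat_2d_windows):
        prof = wham_2d(
            flat_2d_windows, FLAT2D_Z_EDGES, FLAT2D_B_EDGES, jacobian_correct=False
        )
        bc = prof.bin_centers[1]
        g_of_b = np.nanmean(prof.G, axis=0)
        expected = -KT * np.log(bc)  # G falls as −kBT·ln b without correction
        ok = np.isfinite(g_of_b)
        resid = (g_of_b - expected)[ok]
        assert np.ptp(resid - resid.mean()) < 0.15
        assert np.ptp(g_of_b[ok]) > 0.8  # the trend itself is present

    def test_marginal_consistent_with_1d(self):
        model = get_fixture("barrier_3.8_2d")
        wins = [HarmonicBias(z, 5.0) for z in np.arange(-12, 0.1, 0.5)]
        spec = SimulationSpec(model=model, bias=None, n_steps=10_000, sample_stride=2)
        data = generate_us_dataset(model, wins, spec_defaults=spec, seed=6)
        z_edges = np.arange(-12.25, 0.26, 0.5)
        b_edges = np.arange(0.0, 12.1, 1.0)
        prof2 = wham_2d(data, z_edges, b_edges, jacobian_correct=False)
        prof1 = wham_1d(data, z_edges)
        p_zb = np.exp(-np.nan_to_num(prof2.G, nan=np.inf) / KT)
        marg = -KT * np.log(p_zb.sum(axis=1))
        marg -= np.nanmean(marg)
        g1 = prof1.G - np.nanmean(prof1.G)
        blocks = split_block_errors(data, n_blocks=5, bin_edges=z_edges)
        pooled = float(np.sqrt(np.nanmean(blocks.stderr**2)))
        assert np.nanmax(np.abs(marg - g1)) < max(2 * pooled, 0.1)


class TestDham1d:
    def test_symmetric_two_bin_chain(self):
        # z sequence realizing transition counts [[9, 1], [1, 9]] at lag 1
        z = np.array([0.25] * 10 + [0.75] * 10 + [0.25])
        w = UmbrellaWindowData(
            bias=None,
            restraint=CylinderRestraint(),
            T=303.15,
            time=np.arange(z.size, dtype=float),
            z=z,
            b=np.zeros_like(z),
            sample_interval=1.0,
        )
        prof = dham_1d([w], np.array([0.0, 0.5, 1.0]))
        # stationary distribution (0.5, 0.5) → ΔG = 0 between the bins
        assert prof.G[0] == pytest.approx(prof.G[1], abs=1e-12)

    def test_unvisited_bin_masked(self):
        z = np.array([0.25] * 10 + [0.75] * 10 + [0.25])
        w = UmbrellaWindowData(
            bias=None,
            restraint=CylinderRestraint(),
            T=303.15,
            time=np.arange(z.size, dtype=float),
            z=z,
            b=np.zeros_like(z),
            sample_interval=1.0,
        )
        prof = dham_1d([w], np.array([0.0, 0.5, 1.0, 1.5]))
        assert np.isnan(prof.G[2])
        assert np.isfinite(prof.G[:2]).all()

    def test_agrees_with_wham_on_us_dataset(self, us_dataset_38):
        wham = wham_1d(us_dataset_38, BIN_EDGES)
        dham = dham_1d(us_dataset_38, BIN_EDGES)
        blocks = split_block_errors(us_dataset_38, n_blocks=5, bin_edges=BIN_EDGES)
        pooled = float(np.sqrt(np.nanmean(blocks.stderr**2)))
        both = np.isfinite(wham.G) & np.isfinite(dham.G)
        assert np.max(np.abs(wham.G[both] - dham.G[both])) <= 3 * pooled


class TestSplitBlockErrors:
    def test_positive_stderr_in_occupied_interior(self, us_dataset_38):
        prof = split_block_errors(us_dataset_38, n_blocks=5, bin_edges=BIN_EDGES)
        zc = np.asarray(prof.bin_centers)
        interior = (np.abs(zc) < 20) & np.isfinite(prof.G)
        assert np.all(prof.stderr[interior] > 0)

    def test_identical_blocks_give_zero_stderr(self):
        rng = np.random.default_rng(1)
        z_block = rng.normal(0.0, 0.35, 100)
        z = np.tile(z_block, 5)
        w = UmbrellaWindowData(
            bias=HarmonicBias(0.0, 5.0),
            restraint=CylinderRestraint(),
            T=303.15,
            time=np.arange(z.size, dtype=float),
            z=z,
            b=np.zeros_like(z),
            sample_interval=1.0,
        )
        prof = split_block_errors([w], n_blocks=5, bin_edges=np.linspace(-2, 2, 9))
        occ = np.isfinite(prof.G)
        np.testing.assert_allclose(prof.stderr[occ], 0.0, atol=1e-12)

    def test_stderr_shrinks_with_more_sampling(self):
        # Monte-Carlo scaling: quadrupling the samples per window should
        # roughly halve the per-bin standard error. Checked in the
        # zero-bias (direct histogram) regime where errors are multinomial
        # and cleanly ∝ 1/√n, pooled over matched central bins.
        edges = np.linspace(-2.0, 2.0, 18)
        rng = np.random.default_rng(14)
        pooled = {}
        big = rng.normal(0.0, 0.6, 40_000)
        for n in (10_000, 40_000):
            w = UmbrellaWindowData(
                bias=HarmonicBias(0.0, 0.0),
                restraint=CylinderRestraint(),
                T=303.15,
                time=np.arange(n, dtype=float),
                z=big[:n],
                b=np.zeros(n),
                sample_interval=1.0,
            )
            prof = split_block_errors([w], n_blocks=5, bin_edges=edges)
            zc = np.asarray(prof.bin_centers)
            central = np.abs(zc) <= 1.0
            pooled[n] = float(np.sqrt(np.nanmean(prof.stderr[central] ** 2)))
        ratio = pooled[10_000] / pooled[40_000]
        assert 1.5 < ratio < 2.7  # ≈ √4 = 2 under 1/√n scaling

    def test_too_short_window_rejected(self, toy_windows):
        short = toy_windows[0].slice(0, 3)
        with pytest.raises(ValueError):
            split_block_errors([short], n_blocks=5, bin_edges=BIN_EDGES)


class TestDensityFreeEnergy:
    def test_uniform_samples_give_flat_profile(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(-20, 20, 200_000)
        prof = density_free_energy([z], np.linspace(-20, 20, 41))
        assert np.ptp(prof.G) < 0.1

    def test_duplicate_trajectories_change_nothing(self):
        rng = np.random.default_rng(6)
        z = rng.uniform(-20, 20, 10_000)
        p1 = density_free_energy([z], np.linspace(-20, 20, 21))
        p2 = density_free_energy([z, z], np.linspace(-20, 20, 21))
        np.testing.assert_allclose(p1.G, p2.G, atol=1e-12)

    def test_recovers_high_barrier_from_boltzmann_sample(self):
        # importance sampling against the 7.6 kcal/mol barrier fixture:
        # uniform proposal, Boltzmann weights exp(-U/kBT) from the generator
        # truth; the weighted density must reproduce the barrier top that a
        # direct long-run sample could never populate
        model = get_fixture("barrier_7.6")
        rng = np.random.default_rng(76)
        maxima = []
        edges = np.arange(-26.25, 26.26, 0.5)
        for _ in range(5):
            z = rng.uniform(-26.25, 26.25, size=500_000)
            w = np.exp(-model.energy(z) / KT)
            prof = density_free_energy([z], edges, weights=[w])
            maxima.append(np.nanmax(prof.G))
        sem = np.std(maxima, ddof=1) / np.sqrt(len(maxima))
        assert abs(np.mean(maxima) - 7.6) < max(3 * sem, 0.1)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            density_free_energy([np.array([50.0, 60.0])], np.linspace(-20, 20, 11))


class TestAutocorrelation:
    def test_white_noise_tau_is_one_interval(self):
        rng = np.random.default_rng(7)
        res = autocorrelation(rng.standard_normal(100_000), sample_interval=2.0)
        assert res.tau == pytest.approx(2.0, rel=0.20)
        assert res.acf[0] == pytest.approx(1.0)

    def test_ar1_closed_form(self):
        phi = 0.9
        rng = np.random.default_rng(8)
        x = signal.lfilter([1.0], [1.0, -phi], rng.standard_normal(200_000))
        res = autocorrelation(x, max_lag=2000, sample_interval=1.0)
        assert res.tau == pytest.approx((1 + phi) / (1 - phi), rel=0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.ones(100))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.arange(5.0))

    def test_tau_shorter_than_window_length(self, us_dataset_38):
        # sampling is well-decorrelated relative to the window length
        w = us_dataset_38[52]
        res = autocorrelation(w.z, sample_interval=w.sample_interval)
        assert res.tau < w.time[-1]


class TestProfileFeatures:
    def _profile_from_model(self, name, lo=-26, hi=26):
        model = get_fixture(name)
        zc = np.arange(lo + 0.25, hi, 0.5)
        G = model.energy(zc)
        return FreeEnergyProfile(
            bin_centers=zc, G=G, stderr=None, anchor="analytic", n_eff=np.ones_like(zc)
        )

    def test_single_barrier_location_and_height(self):
        feats = profile_features(self._profile_from_model("barrier_3.8"), smooth_bins=0)
        maxima = [f for f in feats if f.kind == "maximum"]
        assert len(maxima) == 1
        assert maxima[0].z == pytest.approx(-6.0, abs=0.5)
        assert maxima[0].barrier == pytest.approx(3.8, abs=0.05)

    def test_monotone_profile_has_no_extrema(self):
        zc = np.linspace(-10, 10, 41)
        prof = FreeEnergyProfile(
            bin_centers=zc, G=0.3 * zc, stderr=None, anchor="", n_eff=np.ones_like(zc)
        )
        assert profile_features(prof) == []

    def test_three_well_fixture_minima_positions(self):
        feats = profile_features(self._profile_from_model("three_well"), smooth_bins=0)
        minima = [f for f in feats if f.kind == "minimum"]
        assert len(minima) == 3
        for f, expected in zip(minima, (-12.0, -5.0, 6.0)):
            assert f.z == pytest.approx(expected, abs=0.75)
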