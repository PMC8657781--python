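import numpy as np
import pytest
from scipy.signal import hilbert
from scipy.stats import spearmanr

import braincrit as bc


class TestConnectome:
    @pytest.mark.parametrize("n,density,hub_fraction,seed", [
        (78, 0.15, 0.15, 1),
        (10, 0.9, 0.1, 0),
        (40, 0.1, 0.2, 3),
    ])
    def test_invariants(self, n, density, hub_fraction, seed):
        c = bc.generate_connectome(n, density, hub_fraction, seed=seed)
        a, d = c.adjacency, c.distances
        assert a.shape == (n, n) and np.array_equal(a, a.T)
        assert np.all(np.diag(a) == 0) and set(np.unique(a)) <= {0, 1}
        assert np.allclose(d, d.T) and np.all(d >= 0)
        assert np.all(d[a == 1] > 0)
        import networkx as nx

        assert nx.is_connected(nx.from_numpy_array(a))

    def test_hub_degree_heterogeneity(self):
        c = bc.generate_connectome(78, 0.15, 0.15, seed=1)
        deg = c.degrees
        assert deg.max() >= 2 * np.median(deg)

    def test_deterministic_under_seed(self):
        a = bc.generate_connectome(78, 0.15, 0.15, seed=1)
        b = bc.generate_connectome(78, 0.15, 0.15, seed=1)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.distances, b.distances)

    @pytest.mark.parametrize("kwargs", [
        {"density": 0.0}, {"density": 1.0}, {"hub_fraction": 0.6}, {"n_nodes": 5},
    ])
    def test_argument_validation(self, kwargs):
        args = {"n_nodes": 20, "density": 0.2, "hub_fraction": 0.2, "seed": 0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            bc.generate_connectome(**args)

    def test_rejects_disconnected_matrix(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        dist = adj.astype(float)
        with pytest.raises(ValueError, match="connected"):
            bc.Connectome(adjacency=adj, distances=dist, labels=list("abcd"))


class TestFrequencies:
    def test_sample_moments(self):
        fs = bc.generate_frequencies(78, 10.0, 0.5, seed=7)
        assert abs(fs.hz.mean() - 10.0) < 0.2
        fs_big = bc.generate_frequencies(1000, 10.0, 0.5, seed=7)
        assert abs(fs_big.hz.std() - 0.5) < 0.05

    def test_zero_variance(self):
        fs = bc.generate_frequencies(5, 10.0, 0.0, seed=0)
        assert np.allclose(fs.omega, 2 * np.pi * 10.0)

    def test_all_positive_even_with_huge_sd(self):
        fs = bc.generate_frequencies(500, 1.0, 5.0, seed=0)
        assert np.all(fs.omega > 0)


def _windowed_R(sig, fs, window=0.25, overlap=0.05):
    phases = np.angle(hilbert(sig, axis=1))
    s = bc.order_parameter(phases, fs=fs)
    wins = bc.windowize(sig.shape[1], fs, window, overlap)
    return np.array([s.r[w.start : w.stop].mean() for w in wins])


class TestSurrogateEEG:
    def test_full_coherence_limit(self):
        sig = bc.generate_surrogate_eeg(16, 10, 500, np.ones(10), seed=0)
        assert np.all(_windowed_R(sig, 500) > 0.9)

    def test_incoherent_limit_matches_random_phase_expectation(self):
        # analytic mean order parameter for N uniform random phases
        n = 64
        sig = bc.generate_surrogate_eeg(n, 20, 500, np.zeros(10), seed=1)
        R = _windowed_R(sig, 500)
        expect = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert R.mean() < expect + 3 * R.std(ddof=1) / np.sqrt(len(R))

    def test_windowed_R_tracks_profile(self):
        prof = np.tile([0.0, 1.0], 20)
        fs = 500
        sig = bc.generate_surrogate_eeg(32, 40, fs, prof, seed=4)
        n = sig.shape[1]
        w = np.interp(np.arange(n), np.linspace(0, n - 1, len(prof)), prof)
        wins = bc.windowize(n, fs, 0.25, 0.05)
        R = _windowed_R(sig, fs)
        W = np.array([w[x.start : x.stop].mean() for x in wins])
        assert spearmanr(W, R).statistic > 0.8

    def test_mean_R_increasing_in_profile_level(self):
        means = [
            _windowed_R(bc.generate_surrogate_eeg(32, 15, 500, np.full(10, lvl), seed=3), 500).mean()
            for lvl in (0.0, 0.5, 1.0)
        ]
        assert means[0] < means[1] < means[2]

    def test_band_validation(self):
        with pytest.raises(ValueError):
            bc.generate_surrogate_eeg(4, 1, 500, np.ones(3), band=(4.0, 300.0))
        with pytest.raises(ValueError):
            bc.generate_surrogate_eeg(4, 1, 100, np.ones(3))

    def test_deterministic(self):
        a = bc.generate_surrogate_eeg(8, 2, 500, np.full(5, 0.5), seed=9)
        b = bc.generate_surrogate_eeg(8, 2, 500, np.full(5, 0.5), seed=9)
        assert np.array_equal(a, b)


class TestParcelBold:
    occupancy = {"high": np.array([1.0, 0.0, 0.0]), "low": np.array([0.0, 0.5, 0.5])}

    def test_noiseless_volumes_equal_templates(self):
        # template 0 is uniform-sign (used by the high class), templates 1-2
        # zero-mean mixed sign (low class), so class rendering is the identity
        tem = bc.default_cap_templates(3, 50, seed=0)
        vols, tt, tc = bc.generate_parcel_bold(
            50, 200, tem, self.occupancy, noise_sd=0.0, seed=1
        )
        assert np.allclose(vols, tem[tt])

    def test_planted_occupancy_recovered(self):
        tem = bc.default_cap_templates(3, 60, seed=0)
        occ = {"high": np.array([0.7, 0.2, 0.1]), "low": np.array([0.1, 0.4, 0.5])}
        vols, tt, tc = bc.generate_parcel_bold(60, 4000, tem, occ, seed=2)
        for cls_idx, cls in ((1, "high"), (0, "low")):
            sel = tt[tc == cls_idx]
            rates = np.bincount(sel, minlength=3) / len(sel)
            # binomial sampling error at n ~ 2000
            assert np.all(np.abs(rates - occ[cls]) < 4 * np.sqrt(0.25 / len(sel)))

    def test_class_separation_by_sign_structure(self):
        tem = bc.default_cap_templates(3, 90, seed=0)
        vols, tt, tc = bc.generate_parcel_bold(90, 600, tem, self.occupancy, seed=5)
        r = bc.volume_sync(vols)
        assert r[tc == 1].mean() > r[tc == 0].mean()

    def test_validation(self):
        tem = bc.default_cap_templates(3, 20, seed=0)
        with pytest.raises(ValueError):
            bc.generate_parcel_bold(20, 2, tem, self.occupancy)
        bad = {"high": np.array([0.5, 0.0, 0.0]), "low": np.array([0.0, 0.5, 0.5])}
        with pytest.raises(ValueError):
            bc.generate_parcel_bold(20, 50, tem, bad)
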