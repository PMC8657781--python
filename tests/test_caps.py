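import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import braincrit as bc

OCC = {"high": np.array([1.0, 0.0, 0.0]), "low": np.array([0.0, 0.5, 0.5])}


@pytest.fixture(scope="module")
def planted():
    templates = bc.default_cap_templates(3, 90, seed=0)
    vols, tt, tc = bc.generate_parcel_bold(90, 600, templates, OCC, noise_sd=0.2, seed=5)
    return templates, vols, tt, tc


class TestExtractCaps:
    def test_recovers_planted_templates(self, planted):
        _, vols, tt, _ = planted
        _, labels = bc.extract_caps(vols, k=3, seed=0)
        assert adjusted_rand_score(tt, labels) > 0.9

    def test_k_validation(self, planted):
        _, vols, _, _ = planted
        with pytest.raises(ValueError):
            bc.extract_caps(vols, k=1)
        with pytest.raises(ValueError):
            bc.extract_caps(vols[:5], k=10)

    def test_deterministic_under_seed(self, planted):
        _, vols, _, _ = planted
        _, a = bc.extract_caps(vols, k=3, seed=3)
        _, b = bc.extract_caps(vols, k=3, seed=3)
        assert np.array_equal(a, b)


class TestSelectK:
    def test_planted_k_maximizes_index(self):
        # hierarchical templates: two families, two variants each. At k = 2 the
        # variants merge and the group occupancy profiles become identical
        # (0.5/0.5 everywhere), so only k = 4 resolves the planted contrast.
        rng = np.random.default_rng(2)
        base = rng.standard_normal((2, 40))
        delta = 0.6 * rng.standard_normal((2, 40))
        templates = np.vstack([base[0] + delta[0], base[0] - delta[0],
                               base[1] + delta[1], base[1] - delta[1]])

        def group(occ, seed):
            # one class only, so every volume is rendered the same way and the
            # planted spatial patterns number exactly k
            v, _, _ = bc.generate_parcel_bold(
                40, 300, templates,
                {"high": occ, "low": occ}, noise_sd=0.15, high_fraction=0.0, seed=seed)
            return v

        cons_occ = np.array([0.4, 0.1, 0.4, 0.1])
        uncs_occ = np.array([0.1, 0.4, 0.1, 0.4])
        groups = {
            "conscious": [group(cons_occ, 10 + i) for i in range(4)],
            "unresponsive": [group(uncs_occ, 20 + i) for i in range(4)],
        }
        idx = bc.select_k(groups, k_range=[2, 3, 4, 6], seed=0)
        assert max(idx, key=idx.get) == 4
        assert idx[2] < 2.0  # merged variants erase the group contrast

    def test_identical_groups_give_unit_index(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((100, 20))
        idx = bc.select_k({"conscious": [v, v], "unresponsive": [v, v]}, k_range=[2], seed=0)
        assert idx[2] == pytest.approx(1.0)

    def test_single_entry_range(self, planted):
        _, vols, _, _ = planted
        groups = {"conscious": [vols[:150], vols[150:300]],
                  "unresponsive": [vols[300:450], vols[450:]]}
        idx = bc.select_k(groups, k_range=[2], seed=0)
        assert list(idx) == [2]

    def test_requires_two_groups_per_side(self, planted):
        _, vols, _, _ = planted
        with pytest.raises(ValueError):
            bc.select_k({"conscious": [vols], "unresponsive": [vols, vols]})


class TestVolumeSync:
    def test_shared_time_course_fully_synchronized(self):
        t = np.linspace(0, 8 * np.pi, 200)
        vols = np.tile(np.sin(t)[:, None], (1, 10)) + 1e-9 * np.random.default_rng(0).random((200, 10))
        r = bc.volume_sync(vols, detrend=False)
        assert np.all(r > 0.99)

    def test_evenly_spread_phases_cancel(self):
        t = np.linspace(0, 8 * np.pi, 400)
        offsets = 2 * np.pi * np.arange(8) / 8
        vols = np.sin(t[:, None] + offsets[None, :])
        r = bc.volume_sync(vols, detrend=False)
        assert np.median(r) < 0.1

    def test_constant_parcel_flagged(self):
        vols = np.random.default_rng(1).random((50, 4))
        vols[:, 2] = 1.0
        with pytest.raises(ValueError):
            bc.volume_sync(vols)

    def test_planted_high_class_more_synchronized(self, planted):
        _, vols, _, tc = planted
        r = bc.volume_sync(vols)
        assert r[tc == 1].mean() > r[tc == 0].mean()


class TestPermutationTest:
    def test_planted_dominant_template_flagged(self, planted):
        _, vols, _, _ = planted
        _, labels = bc.extract_caps(vols, k=3, seed=0)
        classes = bc.classify_volumes(bc.volume_sync(vols))
        res = bc.occurrence_permutation_test(labels, classes, k=3,
                                             n_perm=2000, alpha=0.005, seed=0)
        # the planted high-class template is the one dominating high windows
        high_t = int(np.nanargmax(res.occurrence["high"]))
        assert res.significant["high"][high_t]
        assert not res.significant["low"][high_t]

    def test_type_one_rate_under_uniform_labels(self):
        rng = np.random.default_rng(8)
        k, alpha = 8, 0.005
        flags = []
        for rep in range(50):
            labels = rng.integers(0, k, 600)
            classes = np.array(["low", "high", "neither"])[rng.integers(0, 3, 600)]
            res = bc.occurrence_permutation_test(labels, classes, k=k, n_perm=1000,
                                                 alpha=alpha, seed=rep)
            flags.append(np.r_[res.significant["low"], res.significant["high"]])
        rate = np.concatenate(flags).mean()
        assert rate < 4 * alpha

    def test_empty_class_flagged_not_tested(self):
        labels = np.zeros(100, dtype=int)
        classes = np.full(100, "low", dtype=object)
        res = bc.occurrence_permutation_test(labels, classes, k=2, n_perm=1000, seed=0)
        assert np.all(np.isnan(res.occurrence["high"]))
        assert not res.significant["high"].any()

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            bc.occurrence_permutation_test(np.zeros(10, int), np.full(10, "low"), n_perm=10)

    def test_occurrence_rates_sum_to_one(self, planted):
        _, vols, _, _ = planted
        _, labels = bc.extract_caps(vols, k=3, seed=0)
        classes = bc.classify_volumes(bc.volume_sync(vols))
        res = bc.occurrence_permutation_test(labels, classes, k=3, n_perm=1000, seed=0)
        for cls in ("low", "high"):
            assert np.nansum(res.occurrence[cls]) == pytest.approx(1.0)


class TestFullPlantedPipeline:
    def test_sensitivity_and_false_flags_over_replicates(self):
        """generate -> volume_sync -> classify -> permutation test, 25 replicates."""
        templates = bc.default_cap_templates(3, 90, seed=0)
        hits, false_flags, slots = 0, 0, 0
        reps = 25
        for rep in range(reps):
            vols, tt, tc = bc.generate_parcel_bold(90, 600, templates, OCC,
                                                   noise_sd=0.2, seed=100 + rep)
            _, labels = bc.extract_caps(vols, k=3, seed=rep)
            # align k-means cluster ids to planted template ids by majority vote
            remap = {}
            for c in range(3):
                remap[c] = np.bincount(tt[labels == c], minlength=3).argmax()
            labels = np.array([remap[c] for c in labels])
            classes = bc.classify_volumes(bc.volume_sync(vols))
            res = bc.occurrence_permutation_test(labels, classes, k=3, n_perm=1000,
                                                 alpha=0.005, seed=rep)
            hits += bool(res.significant["high"][0])
            # template 0 never appears in the low class: a low-class flag is false
            false_flags += int(res.significant["low"][0])
            slots += 1
        assert hits / reps > 0.9
        assert false_flags / slots <= 0.08
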