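"""Tests of primitive clustering and functional labeling."""

import numpy as np
import pytest

from synlab import classify, nmf, synthetic
from synlab.classify import _curve_r2, cluster_primitives, mean_cycle
from synlab.datatypes import COMBINED_LABEL, PrincipalShapes

from conftest import wrapped_bell

PEAKS = (25, 75, 125, 175)
EXPECTED = ("weight_acceptance", "propulsion", "early_swing", "late_swing")


@pytest.fixture(scope="module")
def pure_primitives():
    return [wrapped_bell(p) for p in PEAKS for _ in range(20)]


class TestClusterPrimitives:
    def test_separable_bells_all_fundamental(self, pure_primitives):
        _, labels = cluster_primitives(pure_primitives, max_rank=4, seed=0)
        assert all(l.is_fundamental for l in labels)
        got = [l.label for l in labels]
        for peak, expected in zip(PEAKS, EXPECTED):
            block = got[PEAKS.index(peak) * 20 : (PEAKS.index(peak) + 1) * 20]
            assert set(block) == {expected}

    def test_thresholds_match_hand_stepping(self, pure_primitives):
        """The blend of two bells must be labeled exactly as the
        weight/R^2 decision rules dictate when stepped by hand on the
        clustering output."""
        prims = pure_primitives + [wrapped_bell(25) + wrapped_bell(125)]
        shapes, labels = cluster_primitives(prims, max_rank=4, seed=0)

        # hand-step: redo the clustering factorization and apply the rules
        G = np.asarray(prims)
        best = max(
            (nmf.nmf_factorize(G, 5, seed=j) for j in range(10)),
            key=lambda m: m.r2,
        )
        smax = best.P.max(axis=1)
        W = best.M * smax[None, :]
        S = best.P / smax[:, None]
        w_mean = W.mean()
        i = len(prims) - 1
        j_star = int(np.argmax(W[i]))
        if W[i, j_star] < w_mean:
            expected_combined = True
        else:
            r2_i = _curve_r2(G[i], W[i, j_star] * S[j_star])
            others = [
                _curve_r2(G[m], W[m, np.argmax(W[m])] * S[np.argmax(W[m])])
                for m in range(len(prims) - 1)
                if W[m, np.argmax(W[m])] >= w_mean
            ]
            ref = float(np.mean(others))
            thr = 0.25 * ref if ref >= 0 else 4.0 * ref
            expected_combined = r2_i < thr
        assert (not labels[-1].is_fundamental) == expected_combined

    def test_dissimilar_primitive_labeled_combined(self, pure_primitives):
        flat = np.full(200, 0.5) + 0.01 * np.sin(np.linspace(0, 2 * np.pi, 200))
        _, labels = cluster_primitives(pure_primitives + [flat], max_rank=4, seed=0)
        assert labels[-1].label == COMBINED_LABEL

    def test_trial_order_invariance(self, pure_primitives):
        _, fwd = cluster_primitives(pure_primitives, max_rank=4, seed=0)
        perm = np.random.default_rng(5).permutation(len(pure_primitives))
        shuffled = [pure_primitives[i] for i in perm]
        _, shf = cluster_primitives(shuffled, max_rank=4, seed=0)
        for new_pos, old_pos in enumerate(perm):
            assert shf[new_pos].label == fwd[old_pos].label

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            cluster_primitives([wrapped_bell(25)], max_rank=4)


class TestAssignFunction:
    @pytest.mark.parametrize(
        "peak, expected",
        [(20, "weight_acceptance"), (75, "propulsion"), (125, "early_swing"), (190, "late_swing")],
    )
    def test_peak_window_labels(self, peak, expected):
        shapes = PrincipalShapes(shapes=np.stack([wrapped_bell(peak), wrapped_bell((peak + 100) % 200)]))
        labels = classify.assign_function(shapes)
        assert labels[0] == expected

    def test_duplicate_labels_warn(self):
        shapes = PrincipalShapes(shapes=np.stack([wrapped_bell(20), wrapped_bell(30)]))
        with pytest.warns(UserWarning, match="share"):
            classify.assign_function(shapes)


class TestModelClassification:
    def test_noiseless_synthetic_recall_is_total(self):
        """On noiseless data built from the four fundamental bells the
        classifier must recover every synergy as fundamental."""
        trials = [
            synthetic.generate_trial(r=4, noise_sd=0.0, jitter_sd=0.0, amplitude_cv=0.0, seed=s)
            for s in range(3)
        ]
        models = []
        for t, b in enumerate(trials):
            models.append(
                max(
                    (nmf.nmf_factorize(b.envelopes, 4, seed=10 * t + j) for j in range(10)),
                    key=lambda m: m.r2,
                )
            )
        _, per_trial = classify.classify_models(models, seed=0)
        all_labels = [l for trial in per_trial for l in trial]
        assert all(l.is_fundamental for l in all_labels)
        assert classify.combined_fraction(all_labels) == 0.0
        # every trial exhibits the four distinct functions
        for trial in per_trial:
            assert sorted(l.label for l in trial) == sorted(EXPECTED)

    def test_mean_cycle_shape(self):
        prim = np.tile(wrapped_bell(50), 30)
        np.testing.assert_allclose(mean_cycle(prim), wrapped_bell(50))
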