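"""Promoter scanning, the consecutive-window call rule, and occlusion."""

import numpy as np
import pytest

from srescan import cnn, scan
from srescan.encode import decode
from srescan.genomic_io import GenomicInterval


class MotifModel:
    """Stand-in classifier: high probability iff the decoded forward window
    contains a fixed motif; loss concentrates on motif bases under occlusion."""

    def __init__(self, motif="acgtacgtac", hi=0.95, lo=0.05):
        self.motif, self.hi, self.lo = motif, hi, lo

    def predict_proba(self, matrices):
        matrices = np.asarray(matrices)
        if matrices.ndim == 2:
            matrices = matrices[None]
        return np.array(
            [self.hi if self.motif in decode(m[:100]) else self.lo for m in matrices]
        )


def constant_model(prob_logit=4.0):
    model = cnn.build_model(cnn.ModelConfig(n_filters=32, kernel_size=3, rng_seed=0))
    for name in model.params:
        model.params[name][:] = 0.0
    model.params["b4"][:] = prob_logit
    return model


def random_promoter(rng, length=500):
    return "".join(rng.choice(list("atcg"), length))


class TestWindowPromoter:
    def test_twenty_one_windows_cover_the_promoter(self):
        rng = np.random.default_rng(0)
        seq = random_promoter(rng)
        windows = scan.window_promoter(seq)
        assert len(windows) == 21
        offsets = [off for off, _ in windows]
        assert offsets == list(range(0, 401, 20))
        assert windows[0][1] == seq[:100]
        assert windows[-1][1] == seq[400:]
        assert all(len(w) == 100 for _, w in windows)

    def test_step_100_gives_disjoint_windows(self):
        rng = np.random.default_rng(1)
        seq = random_promoter(rng)
        cfg = scan.ScanConfig(scan_step=100)
        assert len(scan.window_promoter(seq, cfg)) == 5

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            scan.window_promoter("acgt" * 10)


class TestCallPositive:
    def pad(self, head, n=21, fill=0.2):
        return np.array(list(head) + [fill] * (n - len(head)))

    def test_three_consecutive_above_threshold_is_positive(self):
        positive, run = scan.call_positive(self.pad([0.95, 0.92, 0.91]))
        assert positive and run == (0, 2)

    def test_max_run_of_two_is_negative(self):
        positive, run = scan.call_positive(self.pad([0.95, 0.92, 0.3, 0.95, 0.92]))
        assert not positive and run == (-1, -1)

    def test_exactly_threshold_is_negative(self):
        positive, _ = scan.call_positive(np.full(21, 0.9))
        assert not positive

    def test_longest_qualifying_run_reported(self):
        p = self.pad([0.95] * 3 + [0.1] + [0.95] * 5)
        positive, run = scan.call_positive(p)
        assert positive and run == (4, 8)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            scan.call_positive(np.array([]))

    def test_mean_rule_variant(self):
        cfg = scan.ScanConfig(run_rule="mean")
        p = self.pad([0.95, 0.95, 0.82])
        assert scan.call_positive(p, cfg)[0]          # mean 0.9067 > 0.9
        assert not scan.call_positive(p)[0]           # 0.82 breaks the strict rule

    def test_against_brute_force_run_enumeration(self):
        """The scan-time rule must agree with explicit enumeration of all
        runs on random probability vectors."""
        rng = np.random.default_rng(9)
        cfg = scan.ScanConfig()
        for _ in range(2000):
            p = rng.choice([0.95, 0.92, 0.89, 0.5, 0.91], size=21)
            got, (i, j) = scan.call_positive(p, cfg)
            runs = [
                (a, b)
                for a in range(21)
                for b in range(a + cfg.call_run_length - 1, 21)
                if all(p[a : b + 1] > cfg.call_threshold)
            ]
            assert got == bool(runs)
            if runs:
                best_len = max(b - a for a, b in runs)
                assert j - i == best_len


class TestScanPromoter:
    def test_structural_profile(self, tiny_model):
        rng = np.random.default_rng(2)
        seq = random_promoter(rng)
        profile = scan.scan_promoter(tiny_model, seq, gene_id="g")
        assert len(profile.probabilities) == 21
        assert np.all((profile.probabilities > 0) & (profile.probabilities < 1))
        again = scan.scan_promoter(tiny_model, seq, gene_id="g")
        assert np.array_equal(profile.probabilities, again.probabilities)


class TestOccludeWindow:
    def test_vector_length_is_window_length(self, tiny_model):
        rng = np.random.default_rng(3)
        losses = scan.occlude_window(tiny_model, random_promoter(rng, 100))
        assert losses.shape == (100,)

    def test_input_blind_classifier_has_zero_loss(self):
        rng = np.random.default_rng(4)
        losses = scan.occlude_window(constant_model(), random_promoter(rng, 100))
        assert np.allclose(losses, 0.0)

    def test_losses_concentrate_on_the_motif(self):
        model = MotifModel()
        rng = np.random.default_rng(5)
        window = random_promoter(rng, 100)
        window = window[:40] + model.motif + window[50:]
        losses = scan.occlude_window(model, window)
        # breaking any motif base kills the prediction; elsewhere nothing
        assert np.allclose(losses[40:50], model.hi - model.lo)
        assert np.allclose(np.delete(losses, range(40, 50)), 0.0, atol=1e-9)

    def test_wrong_length_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            scan.occlude_window(tiny_model, "acgt")


class TestAveragedOcclusion:
    def test_window_grid_and_coverage_counts(self):
        """81 windows at step 5; with every window qualifying, the center of
        the promoter is covered by 20 windows and the first base by one."""
        rng = np.random.default_rng(6)
        profile = scan.averaged_occlusion(constant_model(), random_promoter(rng))
        assert profile.n_windows.sum() == 81 * 100
        assert profile.n_windows[0] == 1
        assert profile.n_windows.max() == 20

    def test_single_qualifying_window_profile_equals_its_loss_vector(self):
        model = MotifModel()
        rng = np.random.default_rng(7)
        seq = random_promoter(rng)
        # motif at the very start: only the offset-0 window contains it whole
        seq = model.motif + seq[10:]
        profile = scan.averaged_occlusion(model, seq)
        expected = scan.occlude_window(model, seq[:100])
        assert np.allclose(profile.mean_loss[:100], expected)
        assert np.all(np.isnan(profile.mean_loss[100:]))
        assert np.all(profile.n_windows[100:] == 0)

    def test_no_qualifying_window_gives_empty_profile(self):
        model = MotifModel()
        rng = np.random.default_rng(8)
        profile = scan.averaged_occlusion(model, random_promoter(rng))
        assert np.all(np.isnan(profile.mean_loss))
        assert profile.n_windows.sum() == 0


class TestGenomeCoordinates:
    def make_profile(self, positive=True):
        return scan.ScanProfile(
            gene_id="g",
            offsets=np.arange(0, 401, 20),
            probabilities=np.linspace(0.1, 0.95, 21),
            positive=positive,
            run_start=2,
            run_end=4,
        )

    def test_plus_strand_mapping(self):
        promoter = GenomicInterval("chr1", 9500, 10000, "+")
        rows = scan.scan_to_rows(self.make_profile(), promoter)
        assert rows[0]["genomic_position"] == 9500
        assert rows[-1]["genomic_position"] == 9900
        bed = scan.called_region_bed_row(self.make_profile(), promoter)
        assert bed == ("chr1", 9540, 9680, "g", 0, "+")

    def test_minus_strand_mapping(self):
        promoter = GenomicInterval("chr1", 22000, 22500, "-")
        rows = scan.scan_to_rows(self.make_profile(), promoter)
        assert rows[0]["genomic_position"] == 22400
        bed = scan.called_region_bed_row(self.make_profile(), promoter)
        assert bed == ("chr1", 22320, 22460, "g", 0, "-")

    def test_negative_profile_has_no_bed_row(self):
        promoter = GenomicInterval("chr1", 9500, 10000, "+")
        assert scan.called_region_bed_row(self.make_profile(False), promoter) is None
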