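"""Labeling: HF-class resolution, soft-label aggregation, Fleiss' kappa."""

import numpy as np
import pytest

from dryeeg.labeling import (
    AnnotationTrack,
    HFRule,
    Label,
    aggregate_soft_labels,
    band_rms,
    fleiss_kappa,
    resolve_hf_labels,
    weighted_fleiss_kappa,
    weighted_kappa_average,
)


def track(labels, reviewer="r1", channel="FC3-CP3", rate=100.0):
    return AnnotationTrack(reviewer_id=reviewer, channel_name=channel,
                           labels=np.asarray(labels, dtype=np.uint8), rate=rate)


def longhand_fleiss(table):
    """Independent textbook computation of Fleiss' kappa from a count table."""
    table = np.asarray(table, dtype=float)
    n_items, _ = table.shape
    n_raters = table.sum(axis=1)[0]
    p_j = table.sum(axis=0) / (n_items * n_raters)
    p_i = ((table**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_e = (p_j**2).sum()
    return (p_bar - p_e) / (1 - p_e)


class TestResolveHF:
    def test_quiet_signal_becomes_clean(self):
        t = track([Label.CLEAN_HF] * 200)
        out = resolve_hf_labels(t, np.zeros(200), HFRule())
        assert np.all(out.labels == Label.CLEAN)

    def test_strong_30hz_burst_becomes_artifact(self):
        """100 uV 30 Hz sinusoid has band RMS ~100/sqrt(2) ~ 70.7 uV >> 10 uV."""
        rate = 100.0
        n = 1000
        sig = 100.0 * np.sin(2 * np.pi * 30 * np.arange(n) / rate)
        rms = band_rms(sig, rate, 25, 35, 1.0)
        assert rms[n // 2] == pytest.approx(100 / np.sqrt(2), rel=0.05)
        t = track([Label.CLEAN_HF] * n)
        out = resolve_hf_labels(t, sig, HFRule(rms_threshold=10.0))
        mid = out.labels[200:800]
        assert np.all(mid == Label.ARTIFACT)

    def test_no_hf_samples_is_noop(self):
        labels = [Label.CLEAN] * 50 + [Label.ARTIFACT] * 50
        t = track(labels)
        out = resolve_hf_labels(t, np.random.default_rng(0).normal(size=100), HFRule())
        np.testing.assert_array_equal(out.labels, t.labels)

    def test_clean_and_artifact_never_touched(self, rng):
        labels = rng.choice(
            [Label.CLEAN, Label.ARTIFACT, Label.CLEAN_HF], size=500
        ).astype(np.uint8)
        sig = rng.normal(scale=50, size=500)
        out = resolve_hf_labels(track(labels), sig, HFRule())
        fixed = labels != Label.CLEAN_HF
        np.testing.assert_array_equal(out.labels[fixed], labels[fixed])
        assert not np.any(out.labels == Label.CLEAN_HF)

    def test_misaligned_lengths_raise(self):
        with pytest.raises(ValueError):
            resolve_hf_labels(track([Label.CLEAN] * 10), np.zeros(11))


class TestSoftLabels:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            ((Label.CLEAN, Label.CLEAN, Label.ARTIFACT), 2 / 3),
            ((Label.CLEAN,) * 4, 1.0),
            ((Label.CLEAN, Label.ARTIFACT, Label.ARTIFACT, Label.ARTIFACT), 0.25),
        ],
    )
    def test_vote_fraction_formula(self, votes, expected):
        tracks = [track([v], reviewer=f"r{i}") for i, v in enumerate(votes)]
        out = aggregate_soft_labels(tracks)
        assert out.values[0] == pytest.approx(expected, abs=1e-15)

    def test_all_vote_patterns_enumerated(self):
        """Soft label equals #clean/#votes on every 3- and 4-reviewer pattern."""
        for n_rev in (3, 4):
            for pattern in range(2**n_rev):
                votes = [
                    Label.CLEAN if (pattern >> i) & 1 else Label.ARTIFACT
                    for i in range(n_rev)
                ]
                tracks = [track([v], reviewer=f"r{i}") for i, v in enumerate(votes)]
                expected = sum(v == Label.CLEAN for v in votes) / n_rev
                assert aggregate_soft_labels(tracks).values[0] == expected

    def test_unannotated_excluded_from_denominator(self):
        tracks = [
            track([Label.CLEAN, Label.UNANNOTATED]),
            track([Label.ARTIFACT, Label.UNANNOTATED], reviewer="r2"),
        ]
        out = aggregate_soft_labels(tracks)
        assert out.values[0] == 0.5
        assert np.isnan(out.values[1])
        assert out.n_reviewers[1] == 0

    def test_reviewer_permutation_invariance(self, rng):
        labels = [
            rng.choice([Label.CLEAN, Label.ARTIFACT], size=200).astype(np.uint8)
            for _ in range(3)
        ]
        tracks = [track(l, reviewer=f"r{i}") for i, l in enumerate(labels)]
        shuffled = [tracks[2], tracks[0], tracks[1]]
        np.testing.assert_array_equal(
            aggregate_soft_labels(tracks).values,
            aggregate_soft_labels(shuffled).values,
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_soft_labels([])


class TestFleissKappa:
    def test_perfect_agreement(self):
        labels = [Label.CLEAN] * 50 + [Label.ARTIFACT] * 50
        tracks = [track(labels, reviewer=f"r{i}") for i in range(3)]
        assert fleiss_kappa(tracks) == pytest.approx(1.0)

    def test_independence_null_near_zero(self):
        """3 independent raters over 2 categories: kappa within +/-0.02 of 0."""
        rng = np.random.default_rng(777)
        n = 20000
        tracks = [
            track(rng.choice([Label.CLEAN, Label.ARTIFACT], size=n).astype(np.uint8),
                  reviewer=f"r{i}")
            for i in range(3)
        ]
        assert abs(fleiss_kappa(tracks)) <= 0.02

    def test_small_table_matches_longhand(self):
        """5-item, 3-rater block equals the textbook P-bar / P-bar-e formula."""
        votes = [
            [Label.CLEAN, Label.CLEAN, Label.CLEAN],
            [Label.ARTIFACT, Label.ARTIFACT, Label.ARTIFACT],
            [Label.CLEAN, Label.CLEAN, Label.ARTIFACT],
            [Label.CLEAN, Label.ARTIFACT, Label.CLEAN_HF],
            [Label.ARTIFACT, Label.ARTIFACT, Label.CLEAN],
        ]
        tracks = [
            track([votes[i][r] for i in range(5)], reviewer=f"r{r}")
            for r in range(3)
        ]
        table = np.zeros((5, 3))
        for i, row in enumerate(votes):
            for v in row:
                table[i, [Label.CLEAN, Label.CLEAN_HF, Label.ARTIFACT].index(v)] += 1
        assert fleiss_kappa(tracks) == pytest.approx(longhand_fleiss(table), abs=1e-12)

    def test_random_tables_match_longhand(self, rng):
        """Property: implementation equals longhand formula on random blocks."""
        for _ in range(20):
            n = int(rng.integers(5, 50))
            labels = rng.choice(
                [Label.CLEAN, Label.CLEAN_HF, Label.ARTIFACT], size=(4, n)
            ).astype(np.uint8)
            tracks = [track(labels[r], reviewer=f"r{r}") for r in range(4)]
            table = np.stack(
                [(labels == c).sum(axis=0) for c in
                 (Label.CLEAN, Label.CLEAN_HF, Label.ARTIFACT)], axis=1
            )
            if (table.sum(axis=0) > 0).sum() < 2:
                continue
            assert fleiss_kappa(tracks) == pytest.approx(
                longhand_fleiss(table), abs=1e-12
            )

    def test_category_relabeling_and_item_order_invariance(self, rng):
        labels = rng.choice([Label.CLEAN, Label.ARTIFACT], size=(3, 300)).astype(np.uint8)
        tracks = [track(labels[r], reviewer=f"r{r}") for r in range(3)]
        base = fleiss_kappa(tracks)
        # swap the two categories
        swapped = np.where(labels == Label.CLEAN, Label.ARTIFACT, Label.CLEAN).astype(np.uint8)
        tracks_sw = [track(swapped[r], reviewer=f"r{r}") for r in range(3)]
        assert fleiss_kappa(tracks_sw) == pytest.approx(base, abs=1e-12)
        # permute items
        perm = rng.permutation(300)
        tracks_pm = [track(labels[r][perm], reviewer=f"r{r}") for r in range(3)]
        assert fleiss_kappa(tracks_pm) == pytest.approx(base, abs=1e-12)

    def test_varying_rater_count_raises(self):
        t1 = track([Label.CLEAN, Label.CLEAN])
        t2 = track([Label.CLEAN, Label.UNANNOTATED], reviewer="r2")
        t3 = track([Label.ARTIFACT, Label.ARTIFACT], reviewer="r3")
        with pytest.raises(ValueError, match="stratify"):
            fleiss_kappa([t1, t2, t3])


class TestWeightedKappa:
    def test_single_block_identity(self, rng):
        labels = rng.choice([Label.CLEAN, Label.ARTIFACT], size=(3, 200)).astype(np.uint8)
        tracks = [track(labels[r], reviewer=f"r{r}") for r in range(3)]
        assert weighted_fleiss_kappa([tracks]) == pytest.approx(fleiss_kappa(tracks))

    def test_weighted_mean_arithmetic(self):
        assert weighted_kappa_average([0.6, 0.8], [1000, 3000]) == pytest.approx(0.75)

    def test_equal_weights_is_plain_mean(self):
        assert weighted_kappa_average([0.2, 0.6], [500, 500]) == pytest.approx(0.4)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            weighted_fleiss_kappa([])
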