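import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import resttremor as rt
from resttremor import evaluation as ev


def brute_force_auc(scores, labels):
    """Concordant-pair fraction: (concordant + 0.5*ties) / (n_pos*n_neg)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = concordant = ties = 0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                concordant += 1
            elif p == q:
                ties += 1
    return (concordant + 0.5 * ties) / total


def brute_force_operating_point(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    uniq = np.unique(scores)
    cands = np.concatenate(([uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]))
    best = None
    for thr in cands:
        pred = scores >= thr
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        key = (-abs(sens - spec), spec, thr)
        if best is None or key > best[0]:
            best = (key, (thr, sens, spec))
    return best[1]


class TestSplits:
    def test_loso_folds_partition_subjects(self):
        subjects = [f"s{i}" for i in range(18)]
        folds = rt.loso_split(subjects)
        assert len(folds) == 18
        held = [h for _, h in folds]
        assert sorted(held) == sorted(subjects)
        for train, test in folds:
            assert test not in train and len(train) == 17

    def test_two_subjects(self):
        folds = rt.loso_split(["a", "b"])
        assert folds == [(["b"], "a"), (["a"], "b")]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            rt.loso_split(["only"])

    def test_stratified_folds_preserve_proportions(self):
        labels = np.array([0] * 50 + [1] * 50)
        folds = rt.stratified_kfold_split(labels, k=10, seed=0)
        for _, test_idx in folds:
            assert (labels[test_idx] == 0).sum() == 5
            assert (labels[test_idx] == 1).sum() == 5

    def test_stratified_seeded_and_degenerate_k(self):
        labels = np.array([0, 1] * 20)
        f1 = rt.stratified_kfold_split(labels, k=4, seed=3)
        f2 = rt.stratified_kfold_split(labels, k=4, seed=3)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            assert np.array_equal(te1, te2)
        with pytest.raises(ValueError):
            rt.stratified_kfold_split(labels, k=1)


class TestROCMetrics:
    def test_perfect_and_uninformative_auc(self):
        assert rt.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert rt.roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_example_matches_pair_counting(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        assert rt.roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_auc_equals_brute_force(self, data):
        n = data.draw(st.integers(4, 50))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        scores = np.round(rng.random(n), 2)  # rounding provokes ties
        labels = np.zeros(n, int)
        labels[: n // 2] = 1
        rng.shuffle(labels)
        assert rt.roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rt.roc_auc([0.1, 0.9], [1, 1])


class TestEqualSensSpec:
    def test_perfect_separation(self):
        thr, sens, spec = rt.equal_sens_spec_threshold(
            [0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0

    @given(st.data())
    @settings(deadline=None, max_examples=40)
    def test_matches_exhaustive_scan(self, data):
        n = data.draw(st.integers(4, 200))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        scores = np.round(rng.random(n), 2)
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        got = rt.equal_sens_spec_threshold(scores, labels)
        want = brute_force_operating_point(scores, labels)
        assert got == pytest.approx(want)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rt.equal_sens_spec_threshold([0.1, 0.9], [0, 0])


class TestHanley:
    def test_closed_form_value(self):
        assert rt.hanley_auc_se(0.5, 10, 10) == pytest.approx(
            np.sqrt(0.0175), abs=1e-6)

    def test_perfect_auc_zero_se(self):
        assert rt.hanley_auc_se(1.0, 25, 40) == 0.0

    def test_se_decreases_with_sample_size(self):
        ses = [rt.hanley_auc_se(0.8, n, 30) for n in (5, 10, 40, 200)]
        assert all(a > b for a, b in zip(ses, ses[1:]))

    def test_significance_of_difference(self):
        z, p = rt.auc_diff_significance(0.96, 3000, 3000, 0.95, 3000, 3000)
        assert p < 0.05
        z2, p2 = rt.auc_diff_significance(0.80, 20, 20, 0.78, 20, 20)
        assert p2 > 0.05

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rt.hanley_auc_se(1.2, 10, 10)
        with pytest.raises(ValueError):
            rt.hanley_auc_se(0.8, 0, 10)


class TestAgreement:
    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(0)
        la = rng.normal(100, 5, size=30)
        scores = np.repeat([0, 1, 2], 10)
        rep = rt.amplitude_agreement(la, scores)
        assert rep.kruskal_p > 0.05
        assert set(rep.shapiro_p) == {0, 1, 2}

    def test_separated_groups_all_pairs_significant(self):
        # group size 10: with 3 groups, complete rank separation at n=8
        # cannot clear Bonferroni-adjusted 0.05 (rank statistics saturate)
        rng = np.random.default_rng(1)
        la = np.concatenate([rng.normal(90, 1.5, 10), rng.normal(104, 1.5, 10),
                             rng.normal(118, 1.5, 10)])
        scores = np.repeat([0, 1, 2], 10)
        rep = rt.amplitude_agreement(la, scores)
        assert rep.kruskal_p < 0.01
        for a in (0, 1, 2):
            for b in (0, 1, 2):
                if a != b:
                    assert rep.dunn_p.loc[a, b] <= 0.05
        # symmetry
        assert np.allclose(rep.dunn_p.values, rep.dunn_p.values.T)

    def test_identical_constant_groups_degenerate(self):
        with pytest.raises(ValueError):
            rt.amplitude_agreement(np.full(12, 100.0), np.repeat([0, 1], 6))

    def test_insufficient_group_sizes(self):
        with pytest.raises(ValueError):
            rt.amplitude_agreement(np.arange(4.0), np.array([0, 0, 1, 1]))

    def test_dunn_holm_not_larger_than_bonferroni(self):
        rng = np.random.default_rng(2)
        groups = {i: rng.normal(10 * i, 3, 9) for i in range(3)}
        bonf = ev.dunn_test(groups, adjust="bonferroni")
        holm = ev.dunn_test(groups, adjust="holm")
        assert np.all(holm.values <= bonf.values + 1e-12)


class TestConstancyCorrelation:
    def test_exact_and_inverted(self):
        ref = np.array([10.0, 30.0, 50.0, 80.0])
        r, _ = rt.constancy_correlation(ref, ref)
        assert r == pytest.approx(1.0)
        r, _ = rt.constancy_correlation(100 - ref, ref)
        assert r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rt.constancy_correlation([50.0, 50.0, 50.0], [10.0, 20.0, 30.0])

    def test_oracle_cohort_correlation(self, oracle_assessments):
        est = [va.constancy_pct for _, _, va in oracle_assessments]
        ref = [truth.true_constancy_pct for _, truth, _ in oracle_assessments]
        r, _ = rt.constancy_correlation(est, ref)
        assert r >= 0.95
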