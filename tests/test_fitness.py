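import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from goafs.fitness import (
    FitnessConfig,
    SvmParams,
    cached_fitness,
    evaluate_subset,
    make_fitness_fn,
    train_final,
)
from goafs.mask import FeatureMask
from goafs.synthetic import default_spec, generate, inject_missing, planted_spec

from conftest import build_dataset


def separable_dataset(n=120, seed=0):
    """Labels determined by Age with a huge margin — trivially separable."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    age = np.where(labels == 1, 70.0, 35.0) + rng.normal(0, 1.0, n)
    return build_dataset(n=n, overrides={"Age": age}, labels=labels)


class TestEvaluateSubset:
    def test_separable_fixture_reaches_zero_error(self):
        ds = separable_dataset()
        fv = evaluate_subset(ds, FeatureMask.from_indices((1,), 13),
                             FitnessConfig(seed=1))
        assert fv.value == 0.0
        assert fv.accuracy == 1.0

    def test_acc_per_size_arithmetic(self):
        ds = separable_dataset()
        fv = evaluate_subset(ds, FeatureMask.from_indices((1, 2, 3), 13),
                             FitnessConfig(objective="acc_per_size", seed=1))
        assert fv.subset_size == 3
        assert fv.value == pytest.approx(fv.accuracy / 3)
        # maximization objective is negated on the minimization scale
        assert fv.as_minimization() == -fv.value

    def test_error_complements_accuracy(self):
        ds = generate(planted_spec(seed=2), 200)
        fv = evaluate_subset(ds, FeatureMask.full(13), FitnessConfig(seed=3))
        assert fv.value == pytest.approx(1.0 - fv.accuracy)

    def test_single_split_matches_manual_protocol(self):
        """White-box oracle: replicate the split/scale/fit pipeline by hand."""
        ds = generate(planted_spec(seed=4), 150)
        cfg = FitnessConfig(seed=5, n_executions=1)
        mask = FeatureMask.from_indices((3, 8, 12, 13), 13)
        fv = evaluate_subset(ds, mask, cfg)

        idx = np.arange(ds.n)
        tr, te = train_test_split(idx, test_size=0.3, random_state=5,
                                  stratify=ds.labels, shuffle=True)
        cols = mask.columns()
        model = cfg.svm.build()
        model.fit(ds.values[np.ix_(tr, cols)], ds.labels[tr])
        pred = model.predict(ds.values[np.ix_(te, cols)])
        assert fv.value == pytest.approx(np.abs(ds.labels[te] - pred).mean())

    def test_deterministic_given_seed(self):
        ds = generate(planted_spec(seed=6), 150)
        cfg = FitnessConfig(seed=7)
        m = FeatureMask.from_indices((2, 3), 13)
        assert evaluate_subset(ds, m, cfg) == evaluate_subset(ds, m, cfg)

    def test_missing_cells_rejected(self):
        ds = inject_missing(generate(default_spec(seed=8), 50), 0.1, seed=9)
        with pytest.raises(ValueError, match="impute"):
            evaluate_subset(ds, FeatureMask.full(13), FitnessConfig())

    def test_single_class_table_raises_with_context(self):
        ds = build_dataset(n=30, labels=[0] * 30)
        with pytest.raises(ValueError, match="stratified"):
            evaluate_subset(ds, FeatureMask.full(13), FitnessConfig(seed=10))

    def test_averaging_uses_all_executions(self):
        ds = generate(planted_spec(seed=11), 150)
        m = FeatureMask.from_indices((3, 12, 13), 13)
        singles = [evaluate_subset(ds, m, FitnessConfig(seed=20 + r, n_executions=1)).value
                   for r in range(3)]
        avg = evaluate_subset(ds, m, FitnessConfig(seed=20, n_executions=3)).value
        assert avg == pytest.approx(np.mean(singles))


class TestCachedFitness:
    def test_repeat_evaluations_hit_the_cache(self):
        calls = []

        def fn(mask):
            calls.append(mask)
            return float(mask.size)

        wrapped = cached_fitness(fn)
        m = FeatureMask.from_indices((1, 2), 13)
        assert wrapped(m) == wrapped(m) == 2.0
        assert len(calls) == 1
        assert wrapped.evaluations == 1

    def test_distinct_masks_get_distinct_entries(self):
        wrapped = cached_fitness(lambda m: float(m.size))
        wrapped(FeatureMask.from_indices((1,), 13))
        wrapped(FeatureMask.from_indices((2,), 13))
        assert len(wrapped.cache) == 2

    def test_cache_disabled_re_evaluates(self):
        ds = separable_dataset(n=60)
        calls = {"n": 0}
        cfg = FitnessConfig(seed=1, cache=False, n_executions=1)
        fn = make_fitness_fn(ds, cfg)
        m = FeatureMask.from_indices((1,), 13)
        assert fn(m) == fn(m)
        assert not hasattr(fn, "cache")


class TestTrainFinal:
    def test_fold_sizes_are_70_15_15(self):
        ds = generate(planted_spec(seed=12), 100)
        _, reports = train_final(ds, FeatureMask.full(13), seed=13)
        assert reports["train"].n == 70
        assert reports["test"].n == 15
        assert reports["validation"].n == 15

    def test_same_seed_reproduces_reports(self):
        ds = generate(planted_spec(seed=14), 120)
        _, a = train_final(ds, FeatureMask.full(13), seed=15)
        _, b = train_final(ds, FeatureMask.full(13), seed=15)
        assert a["test"].to_dict() == b["test"].to_dict()

    def test_informative_mask_beats_all_noise_mask(self):
        spec = planted_spec(seed=16)
        informative = spec.informative
        noise = FeatureMask.from_indices((1, 4, 5, 6), 13)
        diffs = []
        for s in range(6):
            ds = generate(planted_spec(seed=30 + s), 200)
            _, ri = train_final(ds, informative, seed=s)
            _, rn = train_final(ds, noise, seed=s)
            diffs.append(ri["test"].accuracy - rn["test"].accuracy)
        assert np.mean(diffs) > 0

    def test_tiny_table_raises_remediation_error(self):
        ds = build_dataset(n=6, labels=[0, 1, 0, 1, 0, 1])
        with pytest.raises(ValueError, match="stratify"):
            train_final(ds, FeatureMask.full(13), seed=17)


def test_svm_params_validation():
    with pytest.raises(ValueError):
        SvmParams(penalty=0.0)
    with pytest.raises(ValueError):
        SvmParams(gamma=-1.0)
    with pytest.raises(ValueError):
        SvmParams(gamma="bogus")
    with pytest.raises(ValueError):
        SvmParams(kernel="linear")
    # the printed fixed-width setting remains expressible
    assert SvmParams(gamma=32.0).gamma == 32.0


def test_evaluation_log_records_uncached_evaluations(tmp_path):
    ds = separable_dataset(n=60)
    log = tmp_path / "fitness_log.csv"
    from goafs.fitness import make_fitness_fn
    fn = make_fitness_fn(ds, FitnessConfig(seed=1, n_executions=1), log_path=str(log))
    m1 = FeatureMask.from_indices((1,), 13)
    m2 = FeatureMask.from_indices((2,), 13)
    fn(m1); fn(m1); fn(m2)
    lines = log.read_text().strip().splitlines()
    assert lines[0].startswith("mask,objective")
    assert len(lines) == 3  # header + two distinct masks (repeat was cached)
    assert lines[1].split(",")[0] == m1.bitstring
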