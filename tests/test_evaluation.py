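import numpy as np
import pandas as pd
import pytest

from kinosim import (
    ArrayValidationError,
    EvaluationConfig,
    SynthesisParams,
    compare_methods,
    qc_plots,
    run_performance_evaluation,
    synthesize_replicate,
)
from kinosim.evaluation import _scatter_figure, rms_deviation

from oracles import brown_forsythe_oracle, paired_t_oracle


def _mini_config(**overrides):
    defaults = dict(n_pairs=3, max_seeds=5, methods=("raw",), master_seed=11)
    defaults.update(overrides)
    return EvaluationConfig(**defaults)


def test_no_seed_run_flags_vacuous_sensitivity(small_repository_arrays):
    result = run_performance_evaluation(small_repository_arrays, _mini_config(max_seeds=0))
    assert (result.records["n_seeded"] == 0).all()
    assert result.records["flags"].str.contains("sensitivity_vacuous").all()
    fp_fraction = result.records["n_detected"] / small_repository_arrays[0].m
    assert np.allclose(result.records["specificity"], 1 - fp_fraction)


def test_seeded_count_never_exceeds_max(small_repository_arrays):
    result = run_performance_evaluation(small_repository_arrays, _mini_config(max_seeds=5))
    assert (result.records["n_seeded"] <= 5).all()
    for p in result.provenance:
        assert len(p["seeded"]) + len(p["failed"]) == 5


def test_full_reproducibility_under_master_seed(small_repository_arrays):
    a = run_performance_evaluation(small_repository_arrays, _mini_config())
    b = run_performance_evaluation(small_repository_arrays, _mini_config())
    pd.testing.assert_frame_equal(a.records, b.records)
    assert a.provenance == b.provenance


def test_record_count_and_ranges(small_repository_arrays):
    config = _mini_config(methods=("raw", "log2"))
    result = run_performance_evaluation(small_repository_arrays, config)
    assert len(result.records) == config.n_pairs * len(config.methods)
    for measure in ("specificity", "sensitivity", "precision", "accuracy"):
        assert result.records[measure].between(0, 1).all()


def test_n_pairs_cannot_exceed_repository(small_repository_arrays):
    with pytest.raises(ArrayValidationError):
        run_performance_evaluation(small_repository_arrays, _mini_config(n_pairs=99))


# --- method comparison ------------------------------------------------------

def _records_frame(values_a, values_b):
    rows = []
    for i, (va, vb) in enumerate(zip(values_a, values_b)):
        for method, v in (("m1", va), ("m2", vb)):
            rows.append(
                dict(pair_id=f"P{i}", method=method, specificity=v, sensitivity=v,
                     precision=v, accuracy=v, n_seeded=10, n_detected=10, flags="")
            )
    return pd.DataFrame(rows)


def test_compare_methods_identical_records_give_null_result():
    rng = np.random.default_rng(2)
    vals = rng.uniform(0.3, 0.9, 12)
    comparison = compare_methods(_records_frame(vals, vals), "m1", "m2")
    for mc in comparison.measures.values():
        assert mc.t_stat == 0.0 and mc.p_value == 1.0
        assert mc.df == 11


def test_compare_methods_constant_offset_is_deterministic_flagged():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0.2, 0.6, 10)
    comparison = compare_methods(_records_frame(vals, vals + 0.3), "m1", "m2")
    for mc in comparison.measures.values():
        assert mc.degenerate
        assert np.isinf(mc.t_stat) and mc.t_stat > 0
        assert mc.mean_b == pytest.approx(mc.mean_a + 0.3)


def test_compare_methods_matches_bruteforce_oracles():
    rng = np.random.default_rng(4)
    a = rng.uniform(0.2, 0.9, 24)
    b = np.clip(a + rng.normal(0.05, 0.08, 24), 0, 1)
    comparison = compare_methods(_records_frame(a, b), "m1", "m2")
    f_ref, fp_ref = brown_forsythe_oracle(a, b)
    t_ref, tp_ref = paired_t_oracle(a, b)
    for mc in comparison.measures.values():
        assert mc.levene_stat == pytest.approx(f_ref, rel=1e-10)
        assert mc.levene_p == pytest.approx(fp_ref, rel=1e-10)
        assert mc.t_stat == pytest.approx(t_ref, rel=1e-10)
        assert mc.p_value == pytest.approx(tp_ref, rel=1e-10)
        assert mc.mean_a == pytest.approx(a.mean())
        assert mc.mean_b == pytest.approx(b.mean())


def test_compare_methods_mismatched_pairs_rejected():
    rng = np.random.default_rng(5)
    frame = _records_frame(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
    frame = frame.drop(frame[(frame.pair_id == "P0") & (frame.method == "m2")].index)
    with pytest.raises(ArrayValidationError):
        compare_methods(frame, "m1", "m2")


# --- QC plots ---------------------------------------------------------------

def test_qc_plot_files_written(tmp_path, small_repository, small_repository_arrays):
    template = small_repository_arrays[0]
    replicate = synthesize_replicate(small_repository, template, SynthesisParams(seed=3)).array
    paths = qc_plots(template, replicate, seeded=set(template.peptide_ids[:4]), out_dir=tmp_path)
    assert len(paths) == 3
    for p in paths:
        assert p.exists() and p.stat().st_size > 0


def test_scatter_highlights_exactly_seeded_points(small_repository_arrays):
    template = small_repository_arrays[0]
    replicate = small_repository_arrays[1]
    seeded = frozenset(list(template.peptide_ids)[:7])
    fig = _scatter_figure(template, replicate, seeded)
    ax = fig.axes[0]
    sizes = [len(coll.get_offsets()) for coll in ax.collections]
    assert sizes == [template.m - 7, 7]


def test_identical_arrays_lie_on_identity_line(small_repository_arrays):
    template = small_repository_arrays[0]
    assert rms_deviation(template, template) == 0.0


def test_larger_threshold_and_theta_increase_scatter(default_repository, default_repository_arrays):
    template = default_repository_arrays[0]
    rms_small, rms_large = [], []
    for seed in range(5):
        tight = synthesize_replicate(
            default_repository, template,
            SynthesisParams(fold_change_threshold=2.0, noisy_fraction=0.05, seed=seed),
        ).array
        loose = synthesize_replicate(
            default_repository, template,
            SynthesisParams(fold_change_threshold=4.0, noisy_fraction=0.15, seed=seed),
        ).array
        rms_small.append(rms_deviation(template, tight))
        rms_large.append(rms_deviation(template, loose))
    assert np.mean(rms_large) > np.mean(rms_small)


def test_config_validation():
    with pytest.raises(ArrayValidationError):
        EvaluationConfig(methods=("nope",))
    with pytest.raises(ArrayValidationError):
        EvaluationConfig(n_pairs=0)
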