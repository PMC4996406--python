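import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinosim import (
    SIGN_CROSSING,
    ArrayValidationError,
    SeedSpec,
    SynthesisParams,
    build_repository,
    fold_change_bounds,
    generalized_fold_change,
    mean_equivalent,
    mean_within_bounds,
    peptide_mean_abc,
    seed_phosphorylation,
    synthesize_replicate,
)
from kinosim.synthesis import FoldChangeBounds, one_sample_t

from conftest import make_array
from oracles import one_sample_t_oracle


# --- generalized fold change ------------------------------------------------

@pytest.mark.parametrize(
    "initial,final,expected",
    [(2, 8, 4.0), (-8, -2, 4.0), (5, 5, 1.0), (1, 3, 3.0), (-2, -6, 1 / 3)],
)
def test_generalized_fold_change_same_sign(initial, final, expected):
    assert generalized_fold_change(initial, final) == pytest.approx(expected)


@pytest.mark.parametrize("initial,final", [(-3, 6), (6, -3), (0, 5), (5, 0), (0, 0)])
def test_generalized_fold_change_sign_crossing_marker(initial, final):
    assert generalized_fold_change(initial, final) is SIGN_CROSSING


# --- fold-change bounds -----------------------------------------------------

@pytest.mark.parametrize(
    "abc,T,v,w",
    [(10, 2, 20, 5), (-10, 2, -5, -20), (0, 2, 0, 0), (6, 3, 18, 2)],
)
def test_fold_change_bounds_branches(abc, T, v, w):
    bounds = fold_change_bounds(abc, T)
    assert (bounds.v, bounds.w) == (pytest.approx(v), pytest.approx(w))


def test_fold_change_bounds_requires_threshold_above_one():
    with pytest.raises(ArrayValidationError):
        fold_change_bounds(10, 1.0)
    with pytest.raises(ArrayValidationError):
        fold_change_bounds(10, 0.5)


@settings(deadline=None)
@given(abc=st.floats(-1e6, 1e6, allow_nan=False), T=st.floats(1.0001, 50))
def test_fold_change_bounds_ordering_invariant(abc, T):
    bounds = fold_change_bounds(abc, T)
    assert bounds.v >= bounds.w
    # abc always lies inside the closed band
    assert bounds.w <= abc <= bounds.v or abc == 0


# --- candidate predicates ---------------------------------------------------

def _peptide(values):
    return make_array([values]).peptides[0]


def test_mean_within_bounds_zero_variance_direct_comparison():
    assert mean_within_bounds(_peptide([10.0] * 5), FoldChangeBounds(v=20, w=5), 0.05)
    assert not mean_within_bounds(_peptide([30.0] * 5), FoldChangeBounds(v=20, w=5), 0.05)


def test_mean_within_bounds_matches_one_sided_t_oracle():
    values = [18, 19, 20, 21, 22, 18, 20, 21, 19]
    v, w, alpha = 20.0, 5.0, 0.05
    _, _, p_greater, _ = one_sample_t_oracle(values, v)
    _, _, _, p_less = one_sample_t_oracle(values, w)
    expected = (p_greater >= alpha) and (p_less >= alpha)
    assert mean_within_bounds(_peptide(values), FoldChangeBounds(v=v, w=w), alpha) == expected


@pytest.mark.parametrize("alpha", [0.01, 0.05, 0.2])
def test_predicates_match_oracle_on_random_candidates(alpha):
    rng = np.random.default_rng(21)
    for _ in range(200):
        values = rng.normal(rng.uniform(-50, 50), rng.uniform(0.5, 30), size=9)
        target = rng.uniform(-60, 60)
        bounds = FoldChangeBounds(v=target + abs(rng.normal(0, 20)), w=target - abs(rng.normal(0, 20)))
        _, p_two, _, _ = one_sample_t_oracle(values, target)
        assert mean_equivalent(_peptide(values), target, alpha) == (p_two >= alpha)
        _, _, pg, _ = one_sample_t_oracle(values, bounds.v)
        _, _, _, pl = one_sample_t_oracle(values, bounds.w)
        assert mean_within_bounds(_peptide(values), bounds, alpha) == ((pg >= alpha) and (pl >= alpha))


def test_mean_equivalent_degenerate_and_extreme():
    assert mean_equivalent(_peptide([7.0] * 9), 7.0, 0.05)
    assert not mean_equivalent(_peptide([7.0] * 9), 7.0001, 0.05)
    values = 1000.0 + np.array([-1, 1, 0, -1, 1, 0, -1, 1, 0], dtype=float)
    assert not mean_equivalent(_peptide(values), 0.0, 0.05)


def test_one_sample_t_matches_oracle():
    rng = np.random.default_rng(3)
    for _ in range(100):
        values = rng.normal(0, 5, size=rng.integers(2, 12))
        popmean = rng.normal(0, 5)
        t, p_two, p_greater, p_less = one_sample_t_oracle(values, popmean)
        for alt, expected_p in [("two-sided", p_two), ("greater", p_greater), ("less", p_less)]:
            t_impl, p_impl = one_sample_t(values, popmean, alt)
            assert t_impl == pytest.approx(t, rel=1e-10)
            assert p_impl == pytest.approx(expected_p, rel=1e-10)


# --- repository -------------------------------------------------------------

def test_build_repository_pools_entries(small_repository_arrays, small_repository):
    n, m = len(small_repository_arrays), small_repository_arrays[0].m
    assert len(small_repository) == n * m
    # entry lookup returns the exact source spots
    assert small_repository.entry(m + 3) == small_repository_arrays[1].peptides[3]
    assert small_repository.source(m + 3) == (
        small_repository_arrays[1].array_id,
        small_repository_arrays[1].peptides[3].peptide_id,
    )


def test_default_repository_entry_count(default_repository):
    assert len(default_repository) == 48 * 297


def test_build_repository_rejects_incomparable():
    a = make_array([[1, 2], [3, 4]], array_id="A")
    b = make_array([[1, 2], [3, 4]], array_id="B", peptide_ids=["p1", "px"])
    with pytest.raises(ArrayValidationError, match="px"):
        build_repository([a, b])


# --- replicate synthesis ----------------------------------------------------

def test_self_repository_every_peptide_assigned_equivalently(small_repository_arrays):
    template = small_repository_arrays[0]
    repo = build_repository([template])
    result = synthesize_replicate(repo, template, SynthesisParams(noisy_fraction=0.0, seed=1))
    assert result.array.comparable_with(template)
    for prov, peptide, original in zip(
        result.provenance, result.array.peptides, template.peptides
    ):
        assert not prov.fallback  # the peptide's own entry always qualifies
        assert mean_equivalent(peptide, peptide_mean_abc(original), 0.05)


def test_universal_fallback_returns_template_exactly(small_repository_arrays):
    template = small_repository_arrays[0]
    shifted = make_array(
        template.corrected_matrix() + 1e6,
        array_id="far",
        peptide_ids=list(template.peptide_ids),
    )
    repo = build_repository([shifted])
    result = synthesize_replicate(repo, template, SynthesisParams(seed=2))
    assert result.array.peptides == template.peptides
    assert all(p.fallback for p in result.provenance)


def test_synthesis_deterministic_under_seed(small_repository, small_repository_arrays):
    params = SynthesisParams(seed=123)
    a = synthesize_replicate(small_repository, small_repository_arrays[0], params)
    b = synthesize_replicate(small_repository, small_repository_arrays[0], params)
    assert a.array == b.array
    assert a.provenance == b.provenance


def test_spot_set_provenance_no_invented_values(small_repository, small_repository_arrays):
    template = small_repository_arrays[2]
    result = synthesize_replicate(small_repository, template, SynthesisParams(seed=9))
    for t, (prov, peptide) in enumerate(zip(result.provenance, result.array.peptides)):
        if prov.fallback:
            assert peptide.spots == template.peptides[t].spots
        else:
            assert peptide.spots == small_repository.entry(prov.entry_index).spots


def test_empty_repository_rejected(small_repository_arrays):
    with pytest.raises(ArrayValidationError):
        build_repository([])


# --- artificial phosphorylation --------------------------------------------

def test_empty_seed_spec_is_noop(small_repository, small_repository_arrays):
    template = small_repository_arrays[0]
    replicate = synthesize_replicate(small_repository, template, SynthesisParams(seed=4)).array
    result = seed_phosphorylation(small_repository, template, replicate, SeedSpec((), ()), seed=5)
    assert result.array.peptides == replicate.peptides
    assert result.seeded == frozenset() and result.failed == frozenset()


def test_saturated_peptide_reported_failed(small_repository, small_repository_arrays):
    template_values = small_repository_arrays[0].corrected_matrix()
    template_values[0] = 1e9  # far above every repository entry
    template = make_array(
        template_values, array_id="T", peptide_ids=list(small_repository_arrays[0].peptide_ids)
    )
    replicate = make_array(
        template_values, array_id="R", peptide_ids=list(small_repository_arrays[0].peptide_ids)
    )
    result = seed_phosphorylation(
        small_repository, template, replicate, SeedSpec((1,), (1,)), seed=6
    )
    pid = template.peptides[0].peptide_id
    assert result.failed == frozenset({pid})
    assert result.array.peptides[0] == replicate.peptides[0]


def test_seeded_peptides_pass_one_sided_oracle(default_repository, default_repository_arrays):
    template = default_repository_arrays[0]
    replicate = synthesize_replicate(default_repository, template, SynthesisParams(seed=31)).array
    rng = np.random.default_rng(32)
    indices = np.sort(rng.choice(template.m, size=30, replace=False)) + 1
    directions = rng.integers(0, 2, size=30)
    spec = SeedSpec(tuple(int(i) for i in indices), tuple(int(d) for d in directions))
    result = seed_phosphorylation(default_repository, template, replicate, spec, seed=33)
    assert result.seeded | result.failed == {
        template.peptides[i - 1].peptide_id for i in spec.peptide_indices
    }
    assert not (result.seeded & result.failed)
    direction_of = {
        template.peptides[i - 1].peptide_id: d
        for i, d in zip(spec.peptide_indices, spec.directions)
    }
    index_of = {pid: j for j, pid in enumerate(template.peptide_ids)}
    for pid in result.seeded:
        t = index_of[pid]
        abc = peptide_mean_abc(template.peptides[t])
        bounds = fold_change_bounds(abc, 2.0)
        values = result.array.peptides[t].corrected_values()
        if direction_of[pid] == 1:
            _, _, p_greater, _ = one_sample_t_oracle(values, bounds.v)
            assert p_greater < 0.05
        else:
            _, _, _, p_less = one_sample_t_oracle(values, bounds.w)
            assert p_less < 0.05


def test_seed_spec_validation():
    with pytest.raises(ArrayValidationError):
        SeedSpec((1, 1), (1, 0))
    with pytest.raises(ArrayValidationError):
        SeedSpec((1, 2), (1,))
    with pytest.raises(ArrayValidationError):
        SeedSpec((1,), (2,))


def test_seed_spec_out_of_range_and_warning(small_repository, small_repository_arrays):
    template = small_repository_arrays[0]
    replicate = small_repository_arrays[1]
    with pytest.raises(ArrayValidationError, match="out of range"):
        seed_phosphorylation(
            small_repository, template, replicate, SeedSpec((999,), (1,)), seed=1
        )
    big = tuple(range(1, 11))  # 10 of 40 peptides = 25% > 15%
    with pytest.warns(UserWarning, match="15%"):
        seed_phosphorylation(
            small_repository, template, replicate, SeedSpec(big, (1,) * 10), seed=1
        )


def test_synthesis_params_validation():
    with pytest.raises(ArrayValidationError):
        SynthesisParams(fold_change_threshold=1.0)
    with pytest.raises(ArrayValidationError):
        SynthesisParams(noisy_fraction=1.5)
    with pytest.raises(ArrayValidationError):
        SynthesisParams(significance_level=0.0)
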