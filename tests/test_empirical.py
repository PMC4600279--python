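import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methclonal import (
    ClonalityLabel,
    InputValidationError,
    Laterality,
    LRResult,
    NullDistribution,
    SimulationConfig,
    build_null_distribution,
    classify_empirical,
    empirical_p_value,
    enumerate_cross_pairs,
    gene_log_ratio,
    simulate_cohort,
)
from methclonal.simulate import _simulate_call_codes
from methclonal.likelihood import log_ratio_table, lr_from_codes

from .conftest import make_pair


def _cohort(n, seed=0, uninformative_rate=0.0):
    """n non-recurrent pairs from the generator (null-population cohort)."""
    cfg = SimulationConfig(
        n_ipsilateral=n,
        n_contralateral=0,
        recurrence_rate={Laterality.IPSILATERAL: 0.0, Laterality.CONTRALATERAL: 0.0},
        uninformative_rate=uninformative_rate,
        seed=seed,
    )
    return simulate_cohort(cfg)[0]


@pytest.mark.parametrize("n", range(2, 11))
def test_cross_pair_count_matches_closed_form(n):
    pairs = _cohort(n)
    assert len(enumerate_cross_pairs(pairs)) == 2 * n * 2 * (n - 1)


def test_two_individuals_give_eight_ordered_pairings():
    pairs = _cohort(2)
    crosses = enumerate_cross_pairs(pairs)
    assert len(crosses) == 8
    # every ordered pairing mixes patients and keeps both orientations
    ids = {(a.sample_id, b.sample_id) for a, b in crosses}
    assert len(ids) == 8
    assert all(a.patient_id != b.patient_id for a, b in crosses)


def test_single_individual_rejected(panel, params):
    pairs = _cohort(2)
    with pytest.raises(InputValidationError):
        enumerate_cross_pairs(pairs[:1])
    with pytest.raises(InputValidationError):
        build_null_distribution(pairs[:1], panel, params)


def test_null_distribution_matches_scalar_lr_path(panel, params):
    """The vectorized null must reproduce per-pairing scalar LRs exactly."""
    pairs = _cohort(4, seed=3, uninformative_rate=0.1)
    null = build_null_distribution(pairs, panel, params)
    p_eff = panel.effective_p(params.epsilon)

    def scalar_lr(a, b):
        contribs = [
            gene_log_ratio(g, a.calls[g], b.calls[g], p_eff[g], params)
            for g in panel.genes
        ]
        return sum(c.log_ratio for c in contribs), sum(not c.skipped for c in contribs)

    expected = []
    for a, b in enumerate_cross_pairs(pairs):
        lr, ninf = scalar_lr(a, b)
        if ninf > 0:
            expected.append(lr)
    assert null.n_comparisons == 2 * 4 * 2 * 3
    assert len(null) + null.n_degenerate_dropped == null.n_comparisons
    assert np.allclose(np.sort(null.values), np.sort(expected))


def test_identical_profiles_give_zero_variance_null(panel, params):
    pairs = [
        make_pair("M" * 13, "M" * 13, panel, patient_id=f"pt{i}") for i in range(4)
    ]
    null = build_null_distribution(pairs, panel, params)
    assert len(null) == 2 * 4 * 2 * 3
    assert np.ptp(null.values) == 0.0


def test_leave_one_individual_out_null(panel, params):
    pairs = _cohort(5, seed=1)
    null = build_null_distribution(pairs, panel, params, exclude_patient=pairs[0].patient_id)
    assert null.n_individuals == 4
    assert null.n_comparisons == 2 * 4 * 2 * 3


def test_null_mean_and_sd_match_monte_carlo_of_independent_pairs(panel, params):
    """Cross-pairings of iid tumours estimate the same LR law as fresh
    independent non-recurrent pairs; means must agree within sampling error."""
    n_ind = 250
    pairs = _cohort(n_ind, seed=11, uninformative_rate=0.05)
    null = build_null_distribution(pairs, panel, params)

    rng = np.random.default_rng(12)
    p = np.array([panel.p[g] for g in panel.genes])
    prim, sec = _simulate_call_codes(rng, p, 100_000, np.zeros(100_000, bool), 0.05, 2.0, 0.05)
    table = log_ratio_table(panel, params)
    lr, ninf = lr_from_codes(prim, sec, table)
    lr = lr[ninf > 0]
    # the null mean is a U-statistic over 2*n_ind tumours: SE <= 2*sd/sqrt(T)
    tol_mean = 4 * lr.std() / np.sqrt(2 * n_ind)
    assert abs(null.mean - lr.mean()) < tol_mean
    assert abs(null.sd - lr.std(ddof=1)) / lr.std(ddof=1) < 0.1


@pytest.mark.parametrize(
    "lr,expected",
    [(1.5, 0.2), (3.0, 0.0), (-3.0, 1.0), (0.0, 0.4)],
)
def test_empirical_p_counts_strictly_greater(lr, expected):
    null = NullDistribution(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]), 3, 5)
    assert empirical_p_value(lr, null) == pytest.approx(expected)


def test_ties_are_excluded_from_the_count():
    values = np.array([-1.0, 0.0, 0.0, 0.0, 1.0, 2.0])
    null = NullDistribution(values, 3, 6)
    brute = sum(v > 0.0 for v in values) / len(values)
    assert empirical_p_value(0.0, null) == pytest.approx(brute) == pytest.approx(2 / 6)
    # +1 smoothing keeps p away from 0
    assert empirical_p_value(10.0, null, smoothing=True) == pytest.approx(1 / 7)
    with pytest.raises(InputValidationError):
        empirical_p_value(0.0, NullDistribution(np.array([]), 0, 0))


@settings(deadline=None)
@given(
    null_values=st.lists(
        st.floats(min_value=-50, max_value=50), min_size=1, max_size=60
    ),
    a=st.floats(min_value=-60, max_value=60),
    b=st.floats(min_value=-60, max_value=60),
)
def test_empirical_p_is_non_increasing_in_lr(null_values, a, b):
    null = NullDistribution(np.array(null_values), 1, len(null_values))
    lo, hi = sorted((a, b))
    assert empirical_p_value(hi, null) <= empirical_p_value(lo, null)


def _result(lr, n_informative=13):
    return LRResult(
        patient_id="pt1",
        laterality=Laterality.IPSILATERAL,
        contributions=[],
        n_informative=n_informative,
        LR=lr,
    )


def test_classify_empirical_strict_alpha(params):
    # 100-value null: exactly 4 values above 0 -> p = 0.04 -> recurrent
    null = NullDistribution(np.concatenate([np.full(96, -1.0), np.full(4, 1.0)]), 50, 100)
    res = classify_empirical(_result(0.0), null, params)
    assert res.empirical_p == pytest.approx(0.04)
    assert res.empirical_label is ClonalityLabel.RECURRENT
    # 5 values above -> p = 0.05, not < alpha -> de novo
    null5 = NullDistribution(np.concatenate([np.full(95, -1.0), np.full(5, 1.0)]), 50, 100)
    res5 = classify_empirical(_result(0.0), null5, params)
    assert res5.empirical_p == pytest.approx(0.05)
    assert res5.empirical_label is ClonalityLabel.DE_NOVO
    # p = 1.0 -> de novo
    res_low = classify_empirical(_result(-99.0), null, params)
    assert res_low.empirical_p == 1.0
    assert res_low.empirical_label is ClonalityLabel.DE_NOVO
    # degenerate input stays unset
    deg = classify_empirical(_result(0.0, n_informative=0), null, params)
    assert deg.empirical_p is None and deg.empirical_label is None
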