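import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methclonal import (
    ClonalityParams,
    GenePanel,
    MethylationStatus,
    ParameterError,
    default_panel,
    gene_log_ratio,
    joint_prob_nonrecurrence,
    joint_prob_recurrence,
    pair_log_ratio,
)
from methclonal.likelihood import (
    cross_lr_matrix,
    encode_calls,
    log_ratio_table,
    lr_from_codes,
)

from .conftest import make_pair, single_gene_panel

M = MethylationStatus.METHYLATED
U = MethylationStatus.UNMETHYLATED
NA = MethylationStatus.UNINFORMATIVE

MEASURED = (U, M)


@pytest.mark.parametrize(
    "primary,second,p,expected",
    [
        (M, M, 0.5, 0.25),
        (U, U, 0.0, 1.0),
        (M, U, 0.64, 0.2304),
        (U, M, 0.64, 0.2304),
        (U, U, 0.64, 0.36 * 0.36),
    ],
)
def test_joint_prob_nonrecurrence_cells(primary, second, p, expected):
    assert joint_prob_nonrecurrence(primary, second, p) == pytest.approx(expected)


@pytest.mark.parametrize(
    "primary,second,p,gamma,gain,expected",
    [
        (M, M, 0.5, 0.05, 2, 0.475),  # (1-gamma) p
        (U, M, 0.5, 0.05, 2, 0.05),  # 2 gamma (1-p)
        (M, U, 0.3, 0.0, 2, 0.0),  # gamma=0 forbids loss
        (U, U, 0.5, 0.05, 2, 0.45),  # (1-2 gamma)(1-p)
        (M, U, 0.5, 0.05, 2, 0.025),  # gamma p
    ],
)
def test_joint_prob_recurrence_cells(primary, second, p, gamma, gain, expected):
    assert joint_prob_recurrence(primary, second, p, gamma, gain) == pytest.approx(expected)


def test_joint_probs_reject_uninformative_and_bad_params():
    with pytest.raises(ParameterError):
        joint_prob_nonrecurrence(NA, M, 0.5)
    with pytest.raises(ParameterError):
        joint_prob_recurrence(M, NA, 0.5, 0.05)
    with pytest.raises(ParameterError):
        joint_prob_recurrence(M, M, 0.5, 0.6, 2)  # gain 1.2 > 1


@settings(deadline=None)
@given(
    p=st.floats(min_value=0, max_value=1),
    gamma=st.floats(min_value=0, max_value=0.5),
    gain=st.floats(min_value=0, max_value=2),
)
def test_both_tables_are_probability_distributions(p, gamma, gain):
    if gain * gamma > 1:
        return
    cells_r = [
        joint_prob_recurrence(a, b, p, gamma, gain) for a in MEASURED for b in MEASURED
    ]
    cells_n = [joint_prob_nonrecurrence(a, b, p) for a in MEASURED for b in MEASURED]
    assert all(c >= 0 for c in cells_r + cells_n)
    assert sum(cells_r) == pytest.approx(1.0)
    assert sum(cells_n) == pytest.approx(1.0)


@pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
def test_joint_pattern_probabilities_sum_to_one_over_all_outcomes(k):
    """Brute force: the product measure over k genes must normalise to 1."""
    ps = [0.64, 0.5, 0.19, 0.02, 0.35][:k]
    gamma, gain = 0.05, 2.0
    total_r = total_n = 0.0
    for pattern in itertools.product(itertools.product(MEASURED, repeat=2), repeat=k):
        pr = pn = 1.0
        for (a, b), p in zip(pattern, ps):
            pr *= joint_prob_recurrence(a, b, p, gamma, gain)
            pn *= joint_prob_nonrecurrence(a, b, p)
        total_r += pr
        total_n += pn
    assert total_r == pytest.approx(1.0)
    assert total_n == pytest.approx(1.0)


def test_gene_log_ratio_values_and_skip_rule(params):
    c = gene_log_ratio("g", M, M, 0.5, params)
    assert not c.skipped and c.log_ratio == pytest.approx(math.log(0.475 / 0.25))
    c = gene_log_ratio("g", U, M, 0.5, params)
    assert c.log_ratio == pytest.approx(math.log(0.2))
    c = gene_log_ratio("g", M, NA, 0.5, params)
    assert c.skipped and c.log_ratio == 0.0


def test_contribution_signs_follow_the_algebra(params):
    """Concordant/discordant signs hold exactly where the inequalities do."""
    gamma, gain = params.gamma, params.gain_multiplier
    for p in np.linspace(0.05, 0.95, 19):
        mm = gene_log_ratio("g", M, M, p, params).log_ratio
        uu = gene_log_ratio("g", U, U, p, params).log_ratio
        loss = gene_log_ratio("g", M, U, p, params).log_ratio
        gainc = gene_log_ratio("g", U, M, p, params).log_ratio
        assert (mm > 0) == (p < 1 - gamma) or math.isclose(p, 1 - gamma)
        assert (uu > 0) == (1 - p < 1 - gain * gamma) or math.isclose(p, gain * gamma)
        if gamma < 1 - p:
            assert loss < 0
        if gain * gamma < p:
            assert gainc < 0


def test_pair_log_ratio_single_gene(params):
    panel = single_gene_panel(0.5)
    res = pair_log_ratio(make_pair("M", "M", panel), panel, params)
    assert res.LR == pytest.approx(math.log(1.9), abs=1e-4)
    assert res.n_informative == 1 and not res.degenerate


def test_pair_log_ratio_all_uninformative_is_degenerate(params):
    panel = default_panel()
    res = pair_log_ratio(make_pair("N" * 13, "N" * 13, panel), panel, params)
    assert res.degenerate and res.LR == 0.0 and res.n_informative == 0
    assert res.PLR is None and res.bayesian_label is None


@settings(deadline=None, max_examples=50)
@given(st.lists(st.sampled_from("MU"), min_size=13, max_size=13))
def test_self_pairing_has_positive_lr_on_default_panel(calls):
    """A tumour compared with itself looks clonal: every concordant profile
    sums to a strictly positive LR under the default frequencies."""
    panel = default_panel()
    params = ClonalityParams()
    s = "".join(calls)
    res = pair_log_ratio(make_pair(s, s, panel), panel, params)
    assert res.LR > 0


def test_lr_is_additive_over_disjoint_subpanels(params):
    genes = ("A", "B", "C", "D")
    ps = {"A": 0.64, "B": 0.3, "C": 0.05, "D": 0.9}
    full = GenePanel(genes, ps)
    left = GenePanel(genes[:2], {g: ps[g] for g in genes[:2]})
    right = GenePanel(genes[2:], {g: ps[g] for g in genes[2:]})
    prim, sec = "MUMN", "MMUU"
    lr_full = pair_log_ratio(make_pair(prim, sec, full), full, params).LR
    lr_left = pair_log_ratio(make_pair(prim[:2], sec[:2], left), left, params).LR
    lr_right = pair_log_ratio(make_pair(prim[2:], sec[2:], right), right, params).LR
    assert lr_full == pytest.approx(lr_left + lr_right)


@pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
def test_role_swap_shifts_each_discordant_gene_by_log_2_1mp_over_p(p, params):
    """Swapping primary and second changes only discordant genes, each by
    ln(2(1-p)/p) in the gain direction (ln 2 exactly when p = 0.5)."""
    panel = single_gene_panel(p)
    lr_mu = pair_log_ratio(make_pair("M", "U", panel), panel, params).LR
    lr_um = pair_log_ratio(make_pair("U", "M", panel), panel, params).LR
    assert lr_um - lr_mu == pytest.approx(math.log(2 * (1 - p) / p))
    if p == 0.5:
        assert lr_um - lr_mu == pytest.approx(math.log(2))


def test_vectorized_lr_matches_scalar_path(params):
    panel = default_panel()
    profiles = ["M" * 13, "U" * 13, "MUNMUNMUNMUNM", "UUMMNNUUMMNNU"]
    from .conftest import STATUS

    calls = [{g: STATUS[c] for g, c in zip(panel.genes, s)} for s in profiles]
    codes = encode_calls(calls, panel)
    table = log_ratio_table(panel, params)
    lr_mat, ninf_mat = cross_lr_matrix(codes, table)
    for i, prim in enumerate(profiles):
        for j, sec in enumerate(profiles):
            res = pair_log_ratio(make_pair(prim, sec, panel), panel, params)
            assert lr_mat[i, j] == pytest.approx(res.LR)
            assert ninf_mat[i, j] == res.n_informative
    lr_vec, ninf_vec = lr_from_codes(codes, codes[::-1], table)
    for i in range(len(profiles)):
        res = pair_log_ratio(
            make_pair(profiles[i], profiles[len(profiles) - 1 - i], panel), panel, params
        )
        assert lr_vec[i] == pytest.approx(res.LR)
        assert ninf_vec[i] == res.n_informative
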