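"""DEC statistic: penalty, informative filter, signed points, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from decstat import (
    DECConfig,
    InformativeCountError,
    PenaltyParams,
    compute_dec,
    filter_informative,
    penalty,
    signed_points,
    spearman,
)
from conftest import make_pair
from oracles import spearman_bruteforce, spearman_no_ties

# frozen by direct evaluation of the logistic penalty at the defaults
PEN_04 = 0.9525741268224334   # 1/(1+e^{-3})
PEN_02 = 0.04742587317756678  # 1/(1+e^{+3})
PEN_1 = 1.0 / (1.0 + np.exp(-21.0))  # ~ 1 - 7.58e-10


# --- penalty ---------------------------------------------------------------


def test_penalty_is_half_at_midpoint():
    assert penalty(0.3) == 0.5


@pytest.mark.parametrize("sigma,expected", [(0.4, PEN_04), (0.2, PEN_02)])
def test_penalty_matches_direct_evaluation(sigma, expected):
    assert penalty(sigma) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("d", [0.1, 0.5, 0.7])
def test_penalty_symmetric_about_midpoint(d):
    assert penalty(0.3 + d) + penalty(0.3 - d) == pytest.approx(1.0, abs=1e-12)


def test_penalty_strictly_increasing_and_bounded():
    grid = np.linspace(-1.0, 1.0, 101)
    vals = np.array([penalty(s) for s in grid])
    assert np.all(np.diff(vals) > 0)
    assert np.all((vals > 0) & (vals < 1))


def test_penalty_validates_inputs():
    with pytest.raises(ValueError):
        penalty(1.5)
    with pytest.raises(ValueError):
        PenaltyParams(k1=0)


@settings(max_examples=50, derandomize=True)
@given(st.floats(-1, 1), st.floats(-1, 1))
def test_penalty_monotone_property(s1, s2):
    lo, hi = sorted((s1, s2))
    assert penalty(lo) <= penalty(hi)
    if hi - lo > 1e-12:  # strict beyond float resolution of the exponent
        assert penalty(lo) < penalty(hi)


# --- informative filter ----------------------------------------------------


def test_filter_keeps_snps_reaching_threshold_in_either_scan():
    pair = make_pair([2.0, 1.0, 1.3, 0.2], [0.5, 1.0, 0.1, 1.5])
    kept = filter_informative(pair, DECConfig())
    assert [r.snp_id for r in kept.records_disease] == ["s0", "s2", "s3"]


def test_filter_with_zero_threshold_is_vacuous():
    pair = make_pair([0.4, 0.1, 0.6], [0.2, 0.3, 0.5])
    cfg = DECConfig(informative_threshold=0.0)
    assert len(filter_informative(pair, cfg)) == 3


def test_filter_raises_when_everything_is_uninformative():
    pair = make_pair([0.4, 0.1, 0.6], [0.2, 0.3, 0.5])
    with pytest.raises(InformativeCountError, match="0 informative"):
        filter_informative(pair, DECConfig())


def test_filter_threshold_is_inclusive():
    pair = make_pair([1.2, 1.2, 1.2, 0.0], [0.0, 0.0, 0.0, 0.0])
    kept = filter_informative(pair, DECConfig())
    assert len(kept) == 3


# --- signed points ---------------------------------------------------------


def test_signed_points_duplicates_with_joint_negation():
    pair = make_pair([3.0], [2.0], betas_disease=[0.5], betas_eqtl=[0.2])
    pts = signed_points(pair)
    assert len(pts) == 2
    assert set(zip(pts.u, pts.v)) == {(3.0, 2.0), (-3.0, -2.0)}


def test_signed_points_with_opposite_effect_signs():
    pair = make_pair([3.0], [2.0], betas_disease=[0.5], betas_eqtl=[-0.2])
    pts = signed_points(pair)
    assert set(zip(pts.u, pts.v)) == {(3.0, -2.0), (-3.0, 2.0)}


def test_signed_points_invariant_under_reference_flip():
    pair = make_pair([3.0, 1.5], [2.0, 2.5], betas_disease=[0.5, -0.1],
                     betas_eqtl=[-0.2, 0.4])
    flipped = type(pair)(
        records_disease=tuple(r.flipped() for r in pair.records_disease),
        records_eqtl=tuple(r.flipped() for r in pair.records_eqtl),
    )
    assert set(zip(signed_points(pair).u, signed_points(pair).v)) == set(
        zip(signed_points(flipped).u, signed_points(flipped).v)
    )


def test_signed_points_symmetry_invariant():
    rng = np.random.default_rng(1)
    pair = make_pair(rng.uniform(0, 5, 8), rng.uniform(0, 5, 8),
                     betas_disease=rng.standard_normal(8),
                     betas_eqtl=rng.standard_normal(8))
    pts = signed_points(pair)
    s = set(zip(pts.u, pts.v))
    assert all((-u, -v) in s for u, v in s)


def test_zero_beta_counts_as_positive_sign(caplog):
    pair = make_pair([3.0], [2.0], betas_disease=[0.0], betas_eqtl=[1.0])
    with caplog.at_level("WARNING"):
        pts = signed_points(pair)
    assert (3.0, 2.0) in set(zip(pts.u, pts.v))
    assert "zero effect" in caplog.text


# --- spearman --------------------------------------------------------------


def test_spearman_frozen_example():
    assert spearman([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5, abs=1e-12)


def test_spearman_perfect_monotone_and_antitone():
    u = np.array([0.3, 1.2, 2.0, 5.5])
    assert spearman(u, np.exp(u)) == pytest.approx(1.0)
    assert spearman(u, -u) == pytest.approx(-1.0)


def test_spearman_rejects_constant_input():
    with pytest.raises(ValueError, match="constant"):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize("seed", range(10))
def test_spearman_matches_bruteforce_midranks_with_ties(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 20)
    u = rng.integers(0, 5, n).astype(float)  # heavy ties
    v = rng.integers(0, 5, n).astype(float)
    if len(set(u)) < 2 or len(set(v)) < 2:
        u[0], v[0] = u[0] + 7, v[0] + 7
    assert spearman(u, v) == pytest.approx(spearman_bruteforce(u, v), abs=1e-12)


def test_spearman_matches_classic_formula_without_ties():
    rng = np.random.default_rng(3)
    u = rng.permutation(12).astype(float)
    v = rng.permutation(12).astype(float)
    assert spearman(u, v) == pytest.approx(spearman_no_ties(u, v), abs=1e-12)


def test_spearman_matches_scipy():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(4)
    u = rng.integers(0, 6, 30).astype(float)
    v = u + rng.integers(0, 6, 30)
    assert spearman(u, v) == pytest.approx(spearmanr(u, v).statistic, abs=1e-12)


# --- compute_dec -----------------------------------------------------------


def _identical_tracks_pair(k=8, seed=0):
    rng = np.random.default_rng(seed)
    log1ps = rng.uniform(1.3, 6.0, k)
    betas = rng.standard_normal(k)
    return make_pair(log1ps, log1ps, betas_disease=betas, betas_eqtl=betas)


def test_identical_tracks_give_unit_correlations():
    res = compute_dec(_identical_tracks_pair())
    assert res.sigma == pytest.approx(1.0)
    assert res.signed_correlation == pytest.approx(1.0)
    assert res.dec == pytest.approx(PEN_1, abs=1e-12)
    assert 1.0 - res.dec == pytest.approx(7.58256e-10, rel=1e-4)


def test_sign_flipped_eqtl_betas_negate_sc_only():
    rng = np.random.default_rng(2)
    log1ps = rng.uniform(1.3, 6.0, 8)
    betas = rng.standard_normal(8)
    pair = make_pair(log1ps, log1ps, betas_disease=betas, betas_eqtl=-betas)
    res = compute_dec(pair)
    assert res.sigma == pytest.approx(1.0)
    assert res.signed_correlation == pytest.approx(-1.0)
    assert res.dec == pytest.approx(-PEN_1, abs=1e-12)


def test_dec_equals_penalty_times_sc_and_is_bounded():
    rng = np.random.default_rng(5)
    pair = make_pair(rng.uniform(0, 4, 20), rng.uniform(0, 4, 20),
                     betas_disease=rng.standard_normal(20),
                     betas_eqtl=rng.standard_normal(20))
    res = compute_dec(pair)
    assert res.dec == pytest.approx(res.penalty * res.signed_correlation, abs=1e-12)
    assert abs(res.dec) <= abs(res.signed_correlation)
    assert 0 < res.penalty < 1
    assert -1 <= res.signed_correlation <= 1


@pytest.mark.parametrize("seed", range(6))
def test_dec_invariant_under_reference_allele_flips(seed):
    """Flipping the reference allele of any SNP subset in either track
    before pairing must not change any component of the result."""
    rng = np.random.default_rng(seed)
    k = 12
    pair = make_pair(rng.uniform(0, 5, k), rng.uniform(0, 5, k),
                     betas_disease=rng.standard_normal(k),
                     betas_eqtl=rng.standard_normal(k))
    base = compute_dec(pair)
    from decstat import harmonize

    dis = [r.flipped() if rng.random() < 0.5 else r for r in pair.records_disease]
    eqt = [r.flipped() if rng.random() < 0.5 else r for r in pair.records_eqtl]
    flipped = compute_dec(harmonize(dis, eqt))
    assert flipped.dec == pytest.approx(base.dec, abs=1e-12)
    assert flipped.sigma == pytest.approx(base.sigma, abs=1e-12)
    assert flipped.signed_correlation == pytest.approx(
        base.signed_correlation, abs=1e-12
    )


def test_dec_invariant_under_snp_order_permutation():
    rng = np.random.default_rng(7)
    k = 15
    pair = make_pair(rng.uniform(0, 5, k), rng.uniform(0, 5, k),
                     betas_disease=rng.standard_normal(k),
                     betas_eqtl=rng.standard_normal(k))
    base = compute_dec(pair)
    perm = rng.permutation(k)
    shuffled = type(pair)(
        records_disease=tuple(pair.records_disease[i] for i in perm),
        records_eqtl=tuple(pair.records_eqtl[i] for i in perm),
    )
    res = compute_dec(shuffled)
    assert res.dec == pytest.approx(base.dec, abs=1e-12)
    assert res.n_informative == base.n_informative


def test_sigma_scope_all_uses_every_harmonized_snp():
    pair = make_pair([2.0, 1.5, 1.4, 0.1, 0.2], [2.0, 1.5, 1.4, 0.2, 0.1])
    res_inf = compute_dec(pair, DECConfig(sigma_scope="informative"))
    res_all = compute_dec(pair, DECConfig(sigma_scope="all"))
    assert res_inf.sigma == pytest.approx(1.0)
    assert res_all.sigma < 1.0  # the two sub-threshold SNPs disagree in rank


def test_dec_config_validation():
    with pytest.raises(ValueError):
        DECConfig(informative_threshold=-0.1)
    with pytest.raises(ValueError):
        DECConfig(min_informative=1)
    with pytest.raises(ValueError):
        DECConfig(sigma_scope="everything")
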