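"""Fold construction, ranking, adaptive shifts, and pooling."""

import numpy as np
import pytest

from mixshift.data import MixtureDataset, ShiftSpec
from mixshift.discovery import (
    AnalysisConfig,
    BlockResult,
    PositivityError,
    adapt_delta,
    make_folds,
    pool_folds,
    rank_consistency,
    rank_pairs,
    run_discovery_estimation,
)
from mixshift.nuisance import fit_conditional_density, fit_outcome_regression
from mixshift.simulation import SimScenario, simulate_dataset
from mixshift.tmle import ShiftTargetingData, shift_targeting_data

from conftest import make_outcome_model, unit_ratio_model

FAST = ("mean", "glm", "poly2")


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_make_folds_sizes_and_disjointness():
    plan = make_folds(500, 3, seed=0)
    sizes = sorted(len(v) for _, v in plan)
    assert sizes == [166, 167, 167]
    all_val = np.concatenate([v for _, v in plan])
    assert len(all_val) == 500 and len(np.unique(all_val)) == 500
    for tr, va in plan:
        assert len(np.intersect1d(tr, va)) == 0
        assert len(tr) + len(va) == 500


def test_make_folds_leave_one_out_and_determinism():
    plan = make_folds(10, 10, seed=3)
    assert all(len(v) == 1 for _, v in plan)
    p1, p2 = make_folds(100, 4, seed=9), make_folds(100, 4, seed=9)
    for (t1, v1), (t2, v2) in zip(p1, p2):
        np.testing.assert_array_equal(v1, v2)


def test_make_folds_errors():
    with pytest.raises(ValueError):
        make_folds(5, 6, 0)
    with pytest.raises(ValueError):
        make_folds(5, 1, 0)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _dataset(n=100, p=6, seed=0):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, 1))
    A = rng.standard_normal((n, p))
    Y = rng.standard_normal(n)
    return MixtureDataset(W=W, A=A, Y=Y, confounder_names=("W1",),
                          exposure_names=tuple(f"A{i+1}" for i in range(p)))


def test_rank_pairs_counts_all_pairs_and_sign_rule():
    ds = _dataset(p=6)
    # additive regression: every contrast is exactly zero -> both sets empty
    Q_add = make_outcome_model(lambda X: X[:, 1] + 2.0 * X[:, 3])
    ranked = rank_pairs(ds, Q_add, 0.5, s=2)
    assert len(ranked.values) == 15
    assert ranked.synergy == [] and ranked.antagonism == []

    # one synergistic and one antagonistic product term
    Q = make_outcome_model(
        lambda X: 0.6 * X[:, 1] * X[:, 2] - 0.4 * X[:, 5] * X[:, 6])
    ranked = rank_pairs(ds, Q, 0.5, s=1)
    assert ranked.synergy[0][0] == ("A1", "A2")
    assert ranked.synergy[0][1] == pytest.approx(0.6 * 0.25)
    assert ranked.antagonism[0][0] == ("A5", "A6")
    assert ranked.antagonism[0][1] == pytest.approx(-0.4 * 0.25)


def test_rank_pairs_dgm_top_synergy(dgm_draw_2000):
    ds = dgm_draw_2000.subset(np.arange(1000))
    Q = fit_outcome_regression(ds, roster=FAST, seed=0)
    ranked = rank_pairs(ds, Q, 0.5, s=1)
    assert ranked.synergy[0][0] == ("A1", "A2")
    assert ranked.antagonism[0][0] == ("A5", "A6")


# ---------------------------------------------------------------------------
# adaptive delta
# ---------------------------------------------------------------------------

def test_adapt_delta_untouched_when_feasible(gaussian_exposure_data):
    ds = gaussian_exposure_data.subset(np.arange(2000))
    spec = ShiftSpec(("A1",), (0.5,))
    adapted, g = adapt_delta(ds, spec,
                             lambda d, s: fit_conditional_density(d, s),
                             lam=50.0)
    assert adapted.deltas == (0.5,)
    assert g.max_ratio_ < 50.0


def test_adapt_delta_stops_near_gaussian_critical_value(gaussian_exposure_data):
    """For a unit Gaussian exposure the ceiling is first violated at
    delta_crit = a_max - sqrt(a_max^2 - 2 ln(lam)); the grid search must
    stop within one step of it."""
    ds = gaussian_exposure_data.subset(np.arange(2000))
    a_max = float(np.max(ds.A))
    lam = 50.0
    delta_crit = a_max - np.sqrt(a_max**2 - 2 * np.log(lam))
    requested = ShiftSpec(("A1",), (2.0,))
    assert 2.0 > delta_crit  # requested shift is infeasible by the oracle
    adapted, g = adapt_delta(ds, requested,
                             lambda d, s: fit_conditional_density(d, s),
                             lam=lam)
    assert adapted.magnitude < 2.0
    assert g.max_ratio_ < lam
    # within KDE tolerance of the closed-form critical shift
    assert 0.75 * delta_crit <= adapted.magnitude <= 1.1 * delta_crit


def test_adapt_delta_positivity_failure():
    """If the ceiling is violated all the way down to 1% of the requested
    shift, the routine reports a positivity failure rather than returning
    an infeasible spec."""
    from mixshift.nuisance import RatioModel

    class AlwaysExtreme(RatioModel):
        def raw_ratio(self, W, A):  # noqa: D102
            return np.full(A.shape[0], 1e6)

    ds = _dataset(n=50, p=1, seed=1)

    def factory(d, s):
        return AlwaysExtreme(method="direct-density", spec=s)

    with pytest.raises(PositivityError, match="positivity"):
        adapt_delta(ds, ShiftSpec(("A1",), (1.0,)), factory, lam=50.0)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def _marginal_block(ds, fold, val_idx, seed):
    Q = fit_outcome_regression(ds.subset(val_idx), roster=("glm",), seed=seed)
    spec = ShiftSpec(("A1",), (0.5,))
    td = shift_targeting_data(ds.subset(val_idx), spec, Q,
                              unit_ratio_model(spec))
    return BlockResult(kind="marginal_pos", rank=1, fold=fold,
                       variables=("A1",), deltas={"A1": 0.5},
                       n=len(val_idx), shift_tds={"Marginal (A1)": td},
                       val_idx=np.asarray(val_idx))


def test_pool_identical_folds_shrinks_se_by_sqrt_k():
    ds = _dataset(n=200, p=2, seed=7)
    idx = np.arange(200)
    blocks = [_marginal_block(ds, k, idx, seed=0) for k in range(2)]
    cfg = AnalysisConfig(k_folds=2, targets=("marginal_pos",))
    pooled, dbars = pool_folds(blocks, ds, cfg)
    pooled_est = pooled[0].estimates["Marginal (A1)"]

    single, _ = pool_folds(blocks[:1], ds, cfg)
    single_est = single[0].estimates["Marginal (A1)"]
    assert pooled_est.psi == pytest.approx(single_est.psi, abs=1e-10)
    # sqrt(2) shrinkage up to the n-1 variance denominator
    assert pooled_est.se == pytest.approx(single_est.se / np.sqrt(2), rel=5e-3)
    assert dbars[("marginal_pos", 1)] == {"A1": 0.5}


def test_pool_distinct_folds_near_mean_of_fold_psis():
    ds = _dataset(n=300, p=2, seed=8)
    thirds = np.array_split(np.arange(300), 3)
    blocks = [_marginal_block(ds, k, t, seed=k) for k, t in enumerate(thirds)]
    cfg = AnalysisConfig(k_folds=3, targets=("marginal_pos",))
    pooled, _ = pool_folds(blocks, ds, cfg)
    pooled_est = pooled[0].estimates["Marginal (A1)"]
    fold_psis = []
    for blk in blocks:
        one, _ = pool_folds([blk], ds, cfg)
        fold_psis.append(one[0].estimates["Marginal (A1)"].psi)
    assert pooled_est.psi == pytest.approx(float(np.mean(fold_psis)), abs=0.05)
    assert pooled_est.se <= max(
        pool_folds([b], ds, cfg)[0][0].estimates["Marginal (A1)"].se
        for b in blocks)


def test_delta_bar_is_arithmetic_mean():
    ds = _dataset(n=300, p=2, seed=12)
    thirds = np.array_split(np.arange(300), 3)
    blocks = []
    for k, (t, d) in enumerate(zip(thirds, (1.0, 0.8, 0.9))):
        blk = _marginal_block(ds, k, t, seed=k)
        blk.deltas = {"A1": d}
        blocks.append(blk)
    cfg = AnalysisConfig(k_folds=3, targets=("marginal_pos",))
    _, dbars = pool_folds(blocks, ds, cfg)
    assert dbars[("marginal_pos", 1)]["A1"] == pytest.approx(0.9)


# ---------------------------------------------------------------------------
# rank consistency
# ---------------------------------------------------------------------------

def test_rank_consistency_robust_flag():
    pair = ("A1", "A2")
    rankings = [[(pair, 0.5)] for _ in range(3)]
    tab = rank_consistency(rankings, K=3)
    row = tab.iloc[0]
    assert row["variables"] == "A1+A2"
    assert row["frequency"] == 3 and row["mean_rank"] == 1.0 and row["robust"]

    rankings5 = [[(pair, 0.5)]] + [[(("A3", "A4"), 0.2)]] * 4
    tab5 = rank_consistency(rankings5, K=5)
    assert not tab5.set_index("variables").loc["A1+A2", "robust"]

    assert rank_consistency([[], []], K=2).empty
    with pytest.raises(ValueError):
        rank_consistency([[]], K=1)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def test_engine_rejects_single_fold():
    ds = _dataset()
    with pytest.raises(ValueError, match="K=2"):
        run_discovery_estimation(ds, AnalysisConfig(k_folds=1))


def test_engine_null_dgm_synergy_handled():
    """Under a null mechanism the engine either discovers nothing (the CV
    selection lands on an additive surface, so the signed sets are empty)
    or estimates a noise-pair interaction indistinguishable from zero."""
    sc = SimScenario(n=600, synergy=0.0, antagonism=0.0, seed=30,
                     replicates=1)
    ds = simulate_dataset(sc, seed=44)
    cfg = AnalysisConfig(k_folds=2, delta=0.5, q_roster=FAST,
                         ratio_roster=("logit2",), targets=("synergy",),
                         seed=5)
    res = run_discovery_estimation(ds, cfg)
    est = res.pooled_estimate("synergy", 1, "Interaction")
    if est is None:
        assert all(len(r) == 0 for r in res.fold_rankings["synergy"])
    else:
        assert abs(est.psi) < 3 * est.se + 0.05

    # forcing a learner with product terms guarantees noise-level
    # discoveries, whose estimate must sit within noise of zero
    cfg2 = AnalysisConfig(k_folds=2, delta=0.5, q_roster=("poly2",),
                          ratio_roster=("logit2",), targets=("synergy",),
                          seed=5)
    res2 = run_discovery_estimation(ds, cfg2)
    est2 = res2.pooled_estimate("synergy", 1, "Interaction")
    assert est2 is not None
    assert abs(est2.psi) < 3 * est2.se + 0.05
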