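"""Interaction estimators: algebraic identities, oracles, agreement."""

import numpy as np
import pytest

from mixshift.data import MixtureDataset, ShiftSpec
from mixshift.interaction import (
    combined_clever_covariate,
    gcomp_interaction,
    gcomp_single_shift,
    gcomp_threeway,
    interaction_delta_method,
    interaction_targeting_data,
    tmle_interaction_direct,
)
from mixshift.nuisance import fit_outcome_regression, fit_ratio_classifier
from mixshift.simulation import SimScenario, simulate_dataset
from mixshift.tmle import ShiftEstimate, baseline_mean, tmle_shift_mean

from conftest import make_outcome_model, unit_ratio_model

FAST = ("mean", "glm", "poly2")


def _estimate(psi, eif, deltas=None):
    return ShiftEstimate(psi=psi, se=0.0, ci_lo=psi, ci_hi=psi, p_value=1.0,
                         eif=np.asarray(eif, dtype=float), n=len(eif),
                         deltas=deltas or {})


# ---------------------------------------------------------------------------
# Delta-Method combination
# ---------------------------------------------------------------------------

def test_delta_method_additive_structure_gives_zero():
    z = np.zeros(4)
    a, b, c = 1.4, 0.6, 0.9
    est = interaction_delta_method(
        _estimate(a, z, {"A1": 0.5, "A2": 0.5}), _estimate(b, z),
        _estimate(c, z), _estimate(b + c - a, z), pair=("A1", "A2"))
    assert est.psi == pytest.approx(0.0)


def test_delta_method_variance_adds_for_independent_components():
    rng = np.random.default_rng(3)
    n = 4000
    eifs = [rng.standard_normal(n) for _ in range(4)]
    eifs = [e - e.mean() for e in eifs]
    est = interaction_delta_method(
        _estimate(1.0, eifs[0], {"A1": 0.5, "A2": 0.5}),
        _estimate(0.4, eifs[1]), _estimate(0.3, eifs[2]),
        _estimate(0.1, eifs[3]), pair=("A1", "A2"))
    component_var = sum(np.var(e, ddof=1) / n for e in eifs)
    assert est.variance == pytest.approx(component_var, rel=0.1)


def test_delta_method_rejects_misaligned_eifs():
    with pytest.raises(ValueError, match="misaligned"):
        interaction_delta_method(
            _estimate(1.0, np.zeros(5)), _estimate(0.0, np.zeros(4)),
            _estimate(0.0, np.zeros(5)), _estimate(0.0, np.zeros(5)))


# ---------------------------------------------------------------------------
# combined clever covariate H*
# ---------------------------------------------------------------------------

def test_combined_covariate_identity_at_zero_delta():
    ones = np.ones(7)
    np.testing.assert_allclose(
        combined_clever_covariate(ones, ones, ones), np.zeros(7))


def test_combined_covariate_factorizes_under_independence():
    rng = np.random.default_rng(0)
    h_i = np.abs(rng.standard_normal(50)) + 0.1
    h_j = np.abs(rng.standard_normal(50)) + 0.1
    np.testing.assert_allclose(
        combined_clever_covariate(h_i * h_j, h_i, h_j),
        (h_i - 1) * (h_j - 1), atol=1e-12)


def test_combined_covariate_gaussian_value_at_means():
    """Independent standard-normal exposures shifted by +0.5, evaluated at
    the means: H* = (exp(-1/8) - 1)^2 ~ 0.0138."""
    r = np.exp(-0.125)
    hstar = combined_clever_covariate(
        np.array([r * r]), np.array([r]), np.array([r]))
    assert hstar[0] == pytest.approx((r - 1) ** 2)
    assert hstar[0] == pytest.approx(0.0138, abs=5e-4)


def test_combined_covariate_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        combined_clever_covariate(np.ones(3), np.ones(2), np.ones(3))


# ---------------------------------------------------------------------------
# g-computation contrasts
# ---------------------------------------------------------------------------

def _dataset(n=50, p=3, seed=0):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, 1))
    A = rng.standard_normal((n, p))
    Y = rng.standard_normal(n)
    return MixtureDataset(W=W, A=A, Y=Y, confounder_names=("W1",),
                          exposure_names=tuple(f"A{i+1}" for i in range(p)))


def test_gcomp_additive_regression_cancels_exactly():
    ds = _dataset()
    Q = make_outcome_model(lambda X: 2.0 * X[:, 1] - 0.7 * X[:, 2] + X[:, 0])
    assert gcomp_interaction(Q, ds, ("A1", "A2"), 0.5, 0.5) == pytest.approx(0.0)


def test_gcomp_pure_product_gives_beta_delta_product():
    ds = _dataset()
    beta = 0.8
    Q = make_outcome_model(lambda X: beta * X[:, 1] * X[:, 2])
    val = gcomp_interaction(Q, ds, ("A1", "A2"), 0.4, -0.3)
    assert val == pytest.approx(beta * 0.4 * -0.3, abs=1e-12)


def test_gcomp_on_true_dgm_regression():
    """With the true outcome surface, the plug-in recovers synergy*di*dj."""
    sc = SimScenario(n=1000, synergy=0.25, antagonism=-0.45, seed=21,
                     replicates=1)
    ds = simulate_dataset(sc, seed=77)
    from mixshift.simulation import mean_outcome

    Q = make_outcome_model(
        lambda X: mean_outcome(X[:, :4], X[:, 4:], sc.synergy, sc.antagonism))
    assert gcomp_interaction(Q, ds, ("A1", "A2"), 0.5, 0.5) == \
        pytest.approx(0.0625, abs=1e-10)
    assert gcomp_interaction(Q, ds, ("A5", "A6"), 0.5, 0.5) == \
        pytest.approx(-0.45 * 0.25, abs=1e-10)
    assert gcomp_single_shift(Q, ds, "A3", 1.0) == pytest.approx(-0.3, abs=1e-10)


def test_gcomp_equals_untargeted_plugin():
    """The discovery contrast equals the direct TMLE's initial plug-in."""
    ds = _dataset(n=200, seed=5)
    Q = make_outcome_model(
        lambda X: 0.3 * X[:, 1] + 0.5 * X[:, 1] * X[:, 2] - 0.2 * X[:, 3])
    di, dj = 0.5, 0.5
    spec_ij = ShiftSpec(("A1", "A2"), (di, dj))
    td = interaction_targeting_data(
        ds, spec_ij, ShiftSpec(("A1",), (di,)), ShiftSpec(("A2",), (dj,)),
        Q, unit_ratio_model(spec_ij),
        unit_ratio_model(ShiftSpec(("A1",), (di,))),
        unit_ratio_model(ShiftSpec(("A2",), (dj,))))
    plugin = float(np.mean(td.q_joint - td.q_i - td.q_j + td.q_obs))
    assert plugin == pytest.approx(
        gcomp_interaction(Q, ds, ("A1", "A2"), di, dj), abs=1e-12)


@pytest.mark.parametrize(
    "func, expected",
    [
        (lambda X: 1.0 + X[:, 1] + 2 * X[:, 2] - X[:, 3], 0.0),
        (lambda X: X[:, 1] * X[:, 2] + X[:, 2] * X[:, 3] + X[:, 1] * X[:, 3], 0.0),
        (lambda X: 0.9 * X[:, 1] * X[:, 2] * X[:, 3], 0.9 * 0.5 * 0.4 * 0.3),
    ],
    ids=["additive", "pairwise-only", "triple-product"],
)
def test_gcomp_threeway_finite_difference(func, expected):
    ds = _dataset()
    Q = make_outcome_model(func)
    val = gcomp_threeway(Q, ds, ("A1", "A2", "A3"), (0.5, 0.4, 0.3))
    assert val == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# direct-targeting TMLE
# ---------------------------------------------------------------------------

def test_direct_tmle_zero_delta_gives_exact_zero():
    ds = _dataset(n=120, seed=9)
    Q = fit_outcome_regression(ds, roster=("glm",), seed=0)
    spec0 = ShiftSpec(("A1", "A2"), (0.0, 0.0))
    est = tmle_interaction_direct(
        ds, ("A1", "A2"), (0.0, 0.0), Q,
        unit_ratio_model(spec0),
        unit_ratio_model(ShiftSpec(("A1",), (0.0,))),
        unit_ratio_model(ShiftSpec(("A2",), (0.0,))))
    assert est.psi == 0.0
    assert est.epsilon == 0.0


def _fit_pair_nuisances(ds, pair, deltas, seed):
    i, j = pair
    di, dj = deltas
    Q = fit_outcome_regression(ds, roster=FAST, seed=seed)
    g_joint = fit_ratio_classifier(ds, ShiftSpec((i, j), (di, dj)),
                                   roster=("logit2",), seed=seed)
    g_i = fit_ratio_classifier(ds, ShiftSpec((i,), (di,)),
                               roster=("logit2",), seed=seed)
    g_j = fit_ratio_classifier(ds, ShiftSpec((j,), (dj,)),
                               roster=("logit2",), seed=seed)
    return Q, g_joint, g_i, g_j


def test_direct_and_delta_methods_agree_on_dgm():
    """Synergy 0.40 at n=2000: both routes land within 3 SEs of the closed
    form 0.40*0.25 = 0.10 and agree with each other within 2 SEs."""
    sc = SimScenario(n=2000, synergy=0.40, antagonism=-0.45, seed=13,
                     replicates=1)
    ds = simulate_dataset(sc, seed=99)
    pair, deltas = ("A1", "A2"), (0.5, 0.5)
    Q, g_joint, g_i, g_j = _fit_pair_nuisances(ds, pair, deltas, seed=0)

    direct = tmle_interaction_direct(ds, pair, deltas, Q, g_joint, g_i, g_j)
    joint = tmle_shift_mean(ds, ShiftSpec(pair, deltas), Q, g_joint)
    m_i = tmle_shift_mean(ds, ShiftSpec(("A1",), (0.5,)), Q, g_i)
    m_j = tmle_shift_mean(ds, ShiftSpec(("A2",), (0.5,)), Q, g_j)
    delta_est = interaction_delta_method(joint, m_i, m_j, baseline_mean(ds),
                                         pair=pair)
    truth = 0.40 * 0.25
    assert abs(direct.psi - truth) < 3 * direct.se
    assert abs(delta_est.psi - truth) < 3 * delta_est.se
    assert abs(direct.psi - delta_est.psi) < 2 * max(direct.se, delta_est.se)
    # score equation solved on the scaled outcome for the direct route
    assert abs(np.mean(direct.eif)) / (Q.y_hi - Q.y_lo) <= 1e-6


def test_null_dgm_interaction_within_noise():
    """Zero synergy and antagonism: the interaction is 0 within 2 SEs."""
    sc = SimScenario(n=1500, synergy=0.0, antagonism=0.0, seed=14,
                     replicates=1)
    ds = simulate_dataset(sc, seed=123)
    pair, deltas = ("A1", "A2"), (0.5, 0.5)
    Q, g_joint, g_i, g_j = _fit_pair_nuisances(ds, pair, deltas, seed=1)
    est = tmle_interaction_direct(ds, pair, deltas, Q, g_joint, g_i, g_j)
    assert abs(est.psi) < 2 * est.se
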