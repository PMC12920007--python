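"""Additive-scale interaction between two shifted exposures.

The interaction target for exposures (A_i, A_j) shifted by (delta_i,
delta_j) is the departure from additivity

    Psi_int = E_{ij}[Y] - E_i[Y] - E_j[Y] + E[Y],

where E_{ij}[Y] is the mean under the joint shift, E_i / E_j the means
under the single shifts, and E[Y] the unshifted baseline.  Positive
values indicate synergy (super-additivity), negative antagonism.

Two estimation routes are provided:

* the Delta-Method combination of four separately targeted estimates,
  with variance from the combined influence function; and
* a direct single-step TMLE using the combined clever covariate
  H* = H_joint - H_i - H_j + 1.

Untargeted g-computation contrasts of the same form are used for fast
pair ranking in the discovery stage, plus the third-order finite
difference generalization to exposure triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import expit, logit

from .data import MixtureDataset, ShiftSpec, apply_shift
from .nuisance import PROB_BOUNDS, OutcomeModel, RatioModel, clever_covariate
from .tmle import ShiftEstimate, eif_inference, solve_fluctuation

__all__ = [
    "InteractionEstimate",
    "InteractionTargetingData",
    "interaction_delta_method",
    "combined_clever_covariate",
    "tmle_interaction_direct",
    "target_interaction_direct",
    "gcomp_interaction",
    "gcomp_single_shift",
    "gcomp_threeway",
]


@dataclass
class InteractionEstimate:
    """An interaction contrast with EIF-based inference."""

    psi: float
    se: float
    ci_lo: float
    ci_hi: float
    p_value: float
    eif: np.ndarray
    n: int
    approach: str  # {"delta", "direct"}
    pair: tuple[str, str]
    deltas: dict[str, float] = field(default_factory=dict)
    components: dict[str, ShiftEstimate] = field(default_factory=dict)
    condition: str = "Interaction"
    fold: object = None
    epsilon: float = 0.0
    converged: bool = True

    @property
    def variance(self) -> float:
        return self.se**2


def interaction_delta_method(
    joint: ShiftEstimate,
    marginal_i: ShiftEstimate,
    marginal_j: ShiftEstimate,
    baseline: ShiftEstimate,
    pair: tuple[str, str] | None = None,
    fold: object = None,
) -> InteractionEstimate:
    """Combine four shift-mean estimates into the interaction contrast.

    All four must be estimated on the same rows: the combined influence
    function D = D_joint - D_i - D_j + D_baseline accounts for the
    covariances among the components.
    """
    lengths = {len(e.eif) for e in (joint, marginal_i, marginal_j, baseline)}
    if len(lengths) != 1:
        raise ValueError("component EIF vectors are misaligned")
    psi = joint.psi - marginal_i.psi - marginal_j.psi + baseline.psi
    eif = joint.eif - marginal_i.eif - marginal_j.eif + baseline.eif
    se, lo, hi, p = eif_inference(eif, psi)
    deltas = dict(joint.deltas)
    if pair is None:
        pair = tuple(deltas)[:2]
    return InteractionEstimate(
        psi=psi, se=se, ci_lo=lo, ci_hi=hi, p_value=p, eif=eif,
        n=joint.n, approach="delta", pair=tuple(pair), deltas=deltas,
        components={
            "joint": joint, "marginal_i": marginal_i,
            "marginal_j": marginal_j, "baseline": baseline,
        },
        fold=fold,
        converged=all(e.converged for e in (joint, marginal_i, marginal_j)),
    )


def combined_clever_covariate(
    h_joint: np.ndarray, h_i: np.ndarray, h_j: np.ndarray
) -> np.ndarray:
    """H* = H_joint - H_i - H_j + 1, elementwise."""
    h_joint, h_i, h_j = (np.asarray(h) for h in (h_joint, h_i, h_j))
    if not (h_joint.shape == h_i.shape == h_j.shape):
        raise ValueError("clever-covariate length mismatch")
    return h_joint - h_i - h_j + 1.0


@dataclass
class InteractionTargetingData:
    """Arrays for the direct (single-step) interaction TMLE.

    The combined covariate H* is evaluated both at the observed
    exposures (for the fluctuation) and at each of the four exposure
    configurations (because the updated regression is a function of
    (a, w) that includes eps * H*(a, w)).
    """

    y: np.ndarray
    q_obs: np.ndarray
    q_joint: np.ndarray
    q_i: np.ndarray
    q_j: np.ndarray
    hstar_obs: np.ndarray
    hstar_joint: np.ndarray
    hstar_i: np.ndarray
    hstar_j: np.ndarray

    _FIELDS = ("y", "q_obs", "q_joint", "q_i", "q_j",
               "hstar_obs", "hstar_joint", "hstar_i", "hstar_j")

    @staticmethod
    def stack(parts: list["InteractionTargetingData"]) -> "InteractionTargetingData":
        return InteractionTargetingData(
            *(np.concatenate([getattr(p, f) for p in parts])
              for f in InteractionTargetingData._FIELDS)
        )


def target_interaction_direct(
    td: InteractionTargetingData,
    y_lo: float,
    y_hi: float,
    fluctuation: str = "logistic",
) -> tuple[float, np.ndarray, float, bool]:
    """One fluctuation with H*, then the four-configuration plug-in.

    psi = mean[Q*(joint) - Q*(i) - Q*(j) + Q*(obs)];
    EIF = H*(Y - Q*(obs)) + that contrast - psi.  The baseline mean's
    influence is carried by the "+1" term inside H*.
    """
    scale = y_hi - y_lo
    if fluctuation == "logistic":
        y01 = (td.y - y_lo) / scale

        def q01(q):
            return np.clip((q - y_lo) / scale, *PROB_BOUNDS)

        eps, ok = solve_fluctuation(y01, logit(q01(td.q_obs)), td.hstar_obs)
        qs_obs = expit(logit(q01(td.q_obs)) + eps * td.hstar_obs)
        qs_joint = expit(logit(q01(td.q_joint)) + eps * td.hstar_joint)
        qs_i = expit(logit(q01(td.q_i)) + eps * td.hstar_i)
        qs_j = expit(logit(q01(td.q_j)) + eps * td.hstar_j)
        contrast01 = qs_joint - qs_i - qs_j + qs_obs
        psi01 = float(np.mean(contrast01))
        eif01 = td.hstar_obs * (y01 - qs_obs) + contrast01 - psi01
        # the offsets y_lo cancel in the double difference
        return scale * psi01, scale * eif01, eps, ok
    if fluctuation == "linear":
        denom = float(np.sum(td.hstar_obs**2))
        eps = (
            float(np.sum(td.hstar_obs * (td.y - td.q_obs)) / denom)
            if denom > 0 else 0.0
        )
        qs_obs = td.q_obs + eps * td.hstar_obs
        contrast = (
            (td.q_joint + eps * td.hstar_joint)
            - (td.q_i + eps * td.hstar_i)
            - (td.q_j + eps * td.hstar_j)
            + qs_obs
        )
        psi = float(np.mean(contrast))
        eif = td.hstar_obs * (td.y - qs_obs) + contrast - psi
        return psi, eif, eps, True
    raise ValueError(f"unknown fluctuation {fluctuation!r}")


def interaction_targeting_data(
    data: MixtureDataset,
    joint_spec: ShiftSpec,
    spec_i: ShiftSpec,
    spec_j: ShiftSpec,
    Q: OutcomeModel,
    g_joint: RatioModel,
    g_i: RatioModel,
    g_j: RatioModel,
) -> InteractionTargetingData:
    configs = {
        "obs": data.A,
        "joint": apply_shift(data, joint_spec, "post-intervention"),
        "i": apply_shift(data, spec_i, "post-intervention"),
        "j": apply_shift(data, spec_j, "post-intervention"),
    }
    # record positivity diagnostics on the observed rows
    for g, spec in ((g_joint, joint_spec), (g_i, spec_i), (g_j, spec_j)):
        clever_covariate(g, data, spec)
    q = {k: Q.predict(data.W, A) for k, A in configs.items()}
    hstar = {
        k: combined_clever_covariate(
            g_joint.predict_ratio(data.W, A),
            g_i.predict_ratio(data.W, A),
            g_j.predict_ratio(data.W, A),
        )
        for k, A in configs.items()
    }
    return InteractionTargetingData(
        y=data.Y,
        q_obs=q["obs"], q_joint=q["joint"], q_i=q["i"], q_j=q["j"],
        hstar_obs=hstar["obs"], hstar_joint=hstar["joint"],
        hstar_i=hstar["i"], hstar_j=hstar["j"],
    )


def tmle_interaction_direct(
    data: MixtureDataset,
    pair: tuple[str, str],
    deltas: tuple[float, float],
    Q: OutcomeModel,
    g_joint: RatioModel,
    g_i: RatioModel,
    g_j: RatioModel,
    fluctuation: str = "logistic",
    fold: object = None,
) -> InteractionEstimate:
    """Single-step TMLE of the interaction with the combined covariate H*."""
    i, j = pair
    di, dj = deltas
    joint_spec = ShiftSpec((i, j), (di, dj))
    td = interaction_targeting_data(
        data, joint_spec, ShiftSpec((i,), (di,)), ShiftSpec((j,), (dj,)),
        Q, g_joint, g_i, g_j,
    )
    psi, eif, eps, ok = target_interaction_direct(td, Q.y_lo, Q.y_hi, fluctuation)
    se, lo, hi, p = eif_inference(eif, psi)
    return InteractionEstimate(
        psi=psi, se=se, ci_lo=lo, ci_hi=hi, p_value=p, eif=eif,
        n=data.n, approach="direct", pair=(i, j), deltas={i: di, j: dj},
        fold=fold, epsilon=eps, converged=ok,
    )


# ---------------------------------------------------------------------------
# g-computation contrasts (discovery stage; no targeting, no SE)
# ---------------------------------------------------------------------------

def _shifted_pred(Q: OutcomeModel, data: MixtureDataset, spec: ShiftSpec) -> np.ndarray:
    A = apply_shift(data, spec, "post-intervention")
    return Q.predict(data.W, A)


def gcomp_single_shift(
    Q: OutcomeModel, data: MixtureDataset, exposure: str, delta: float
) -> float:
    """Plug-in single-shift effect mean[Q(A_i + delta) - Q(A)]."""
    spec = ShiftSpec((exposure,), (delta,))
    return float(np.mean(_shifted_pred(Q, data, spec)
                         - Q.predict(data.W, data.A)))


def gcomp_interaction(
    Q: OutcomeModel,
    data: MixtureDataset,
    pair: tuple[str, str],
    delta_i: float,
    delta_j: float,
) -> float:
    """Plug-in interaction contrast for one exposure pair.

    mean[Q(joint shift) - Q(i shift) - Q(j shift) + Q(observed)] using
    post-intervention exposures; equals the TMLE's initial (untargeted)
    plug-in value for the same outcome regression and shifts.  The
    contrast is formed row-wise so additive structure cancels exactly.
    """
    i, j = pair
    contrast = (
        _shifted_pred(Q, data, ShiftSpec((i, j), (delta_i, delta_j)))
        - _shifted_pred(Q, data, ShiftSpec((i,), (delta_i,)))
        - _shifted_pred(Q, data, ShiftSpec((j,), (delta_j,)))
        + Q.predict(data.W, data.A)
    )
    return float(np.mean(contrast))


def gcomp_threeway(
    Q: OutcomeModel,
    data: MixtureDataset,
    triple: tuple[str, str, str],
    deltas: tuple[float, float, float],
) -> float:
    """Third-order finite-difference interaction for an exposure triple.

    The inclusion-exclusion contrast (triple shift, minus pairwise
    shifts, plus single shifts, minus baseline) annihilates all additive
    and pairwise-product structure; a pure triple product gamma *
    a_i a_j a_k yields gamma * d_i d_j d_k exactly.
    """
    names = tuple(triple)
    d = dict(zip(names, deltas))
    contrast = np.zeros(data.n)
    for r in range(4):
        sign = (-1.0) ** (3 - r)
        for subset in combinations(names, r):
            spec = ShiftSpec(subset, tuple(d[s] for s in subset))
            contrast += sign * _shifted_pred(Q, data, spec)
    return float(np.mean(contrast))
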