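"""Targeted maximum likelihood estimation of shift-intervention means.

For a shift spec delta, the target is psi = E_delta[Y], the mean outcome
had every targeted exposure been shifted by delta.  Its efficient
influence function is

    D(O) = H_delta(A, W) (Y - Qbar(A, W)) + Qbar(A + delta, W) - psi,

with clever covariate H_delta(A, W) = g0(A - delta | W) / g0(A | W).
The initial outcome regression is fluctuated along a one-dimensional
submodel (logistic on the outcome rescaled to [0, 1] by default, or
linear) so the empirical mean of the EIF is zero; the standard error is
the EIF's sample standard deviation over sqrt(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .data import MixtureDataset, ShiftSpec, apply_shift
from .nuisance import PROB_BOUNDS, OutcomeModel, RatioModel, clever_covariate

__all__ = [
    "ShiftEstimate",
    "ShiftTargetingData",
    "eif_inference",
    "baseline_mean",
    "tmle_shift_mean",
    "target_shift_mean",
    "solve_fluctuation",
]

EPS_BOUND = 10.0  # |epsilon| beyond this on the logit scale is flagged
Z_95 = 1.96


@dataclass
class ShiftEstimate:
    """A shift-mean (or baseline-mean) estimate with EIF-based inference."""

    psi: float
    se: float
    ci_lo: float
    ci_hi: float
    p_value: float
    eif: np.ndarray
    n: int
    deltas: dict[str, float] = field(default_factory=dict)
    condition: str = ""
    fold: object = None
    epsilon: float = 0.0
    converged: bool = True

    @property
    def variance(self) -> float:
        return self.se**2


@dataclass
class ShiftTargetingData:
    """Natural-scale ingredients of one fold's targeting step.

    Kept on the natural outcome scale so validation folds can be stacked
    and re-targeted jointly (pooled TMLE) with common scaling constants.
    """

    y: np.ndarray
    q_obs: np.ndarray
    q_shift: np.ndarray
    h_obs: np.ndarray
    h_shift: np.ndarray

    @staticmethod
    def stack(parts: list["ShiftTargetingData"]) -> "ShiftTargetingData":
        return ShiftTargetingData(
            *(np.concatenate([getattr(p, f) for p in parts])
              for f in ("y", "q_obs", "q_shift", "h_obs", "h_shift"))
        )


def eif_inference(
    eif: np.ndarray, psi: float, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """Wald inference from an influence-function vector.

    se = sqrt(Var_hat(D) / n) with the n-1 variance denominator; the CI
    uses the normal quantile (1.96 at the default 95% level) and the
    p-value is the two-sided test of psi = 0.
    """
    eif = np.asarray(eif, dtype=float)
    n = eif.shape[0]
    if n < 2:
        raise ValueError("need at least two observations for inference")
    se = float(np.sqrt(np.var(eif, ddof=1) / n))
    z = Z_95 if abs(alpha - 0.05) < 1e-12 else float(norm.ppf(1 - alpha / 2))
    ci_lo, ci_hi = psi - z * se, psi + z * se
    if se == 0.0:
        p = 0.0 if psi != 0.0 else 1.0
    else:
        p = float(2 * norm.sf(abs(psi) / se))
    return se, ci_lo, ci_hi, p


def baseline_mean(
    data: MixtureDataset, condition: str = "Baseline", fold: object = None
) -> ShiftEstimate:
    """The unshifted mean outcome E[Y]: sample mean with EIF Y - ybar."""
    if data.n < 2:
        raise ValueError("need at least two observations")
    ybar = float(np.mean(data.Y))
    eif = data.Y - ybar
    se, lo, hi, p = eif_inference(eif, ybar)
    return ShiftEstimate(
        psi=ybar, se=se, ci_lo=lo, ci_hi=hi, p_value=p, eif=eif,
        n=data.n, deltas={}, condition=condition, fold=fold,
    )


def solve_fluctuation(
    y01: np.ndarray, logit_q: np.ndarray, h: np.ndarray
) -> tuple[float, bool]:
    """Maximum-likelihood epsilon of the logistic fluctuation submodel.

    Solves the score equation mean(h * (y01 - expit(logit_q + eps h))) = 0,
    which is monotone decreasing in eps.  A root outside |eps| <= 10 is
    flagged as non-convergent.
    """
    if float(np.sum(h * h)) < 1e-12:
        return 0.0, True

    def score(eps: float) -> float:
        return float(np.mean(h * (y01 - expit(logit_q + eps * h))))

    lo, hi = -EPS_BOUND, EPS_BOUND
    s_lo, s_hi = score(lo), score(hi)
    if s_lo < 0 or s_hi > 0:  # no sign change inside the bound
        warnings.warn("fluctuation epsilon outside convergence bound", RuntimeWarning)
        return (lo if abs(s_lo) < abs(s_hi) else hi), False
    eps = brentq(score, lo, hi, xtol=1e-14)
    return float(eps), True


def target_shift_mean(
    td: ShiftTargetingData,
    y_lo: float,
    y_hi: float,
    fluctuation: str = "logistic",
) -> tuple[float, np.ndarray, float, bool]:
    """Run the targeting step on prepared arrays.

    Returns (psi, eif, epsilon, converged) on the natural outcome scale.
    """
    scale = y_hi - y_lo
    if fluctuation == "logistic":
        y01 = (td.y - y_lo) / scale
        q01_obs = np.clip((td.q_obs - y_lo) / scale, *PROB_BOUNDS)
        q01_shift = np.clip((td.q_shift - y_lo) / scale, *PROB_BOUNDS)
        eps, ok = solve_fluctuation(y01, logit(q01_obs), td.h_obs)
        qstar_obs = expit(logit(q01_obs) + eps * td.h_obs)
        qstar_shift = expit(logit(q01_shift) + eps * td.h_shift)
        psi01 = float(np.mean(qstar_shift))
        eif01 = td.h_obs * (y01 - qstar_obs) + qstar_shift - psi01
        return y_lo + scale * psi01, scale * eif01, eps, ok
    if fluctuation == "linear":
        denom = float(np.sum(td.h_obs**2))
        eps = float(np.sum(td.h_obs * (td.y - td.q_obs)) / denom) if denom > 0 else 0.0
        qstar_obs = td.q_obs + eps * td.h_obs
        qstar_shift = td.q_shift + eps * td.h_shift
        psi = float(np.mean(qstar_shift))
        eif = td.h_obs * (td.y - qstar_obs) + qstar_shift - psi
        return psi, eif, eps, True
    raise ValueError(f"unknown fluctuation {fluctuation!r}")


def shift_targeting_data(
    data: MixtureDataset,
    spec: ShiftSpec,
    Q: OutcomeModel,
    g: RatioModel,
) -> ShiftTargetingData:
    """Evaluate nuisances at observed and post-intervention exposures."""
    A_shift = apply_shift(data, spec, "post-intervention")
    h_obs = clever_covariate(g, data, spec)
    # the updated regression is a function of (a, w); evaluating it at the
    # post-intervention exposures requires the clever covariate there too
    h_shift = g.predict_ratio(data.W, A_shift)
    return ShiftTargetingData(
        y=data.Y,
        q_obs=Q.predict(data.W, data.A),
        q_shift=Q.predict(data.W, A_shift),
        h_obs=h_obs,
        h_shift=h_shift,
    )


def tmle_shift_mean(
    data: MixtureDataset,
    spec: ShiftSpec,
    Q: OutcomeModel,
    g: RatioModel,
    fluctuation: str = "logistic",
    condition: str = "",
    fold: object = None,
) -> ShiftEstimate:
    """TMLE of the shift mean E_delta[Y] on ``data``.

    Nuisances may have been fitted on held-out rows (CV-TMLE); the
    targeting step and inference use only ``data``.
    """
    td = shift_targeting_data(data, spec, Q, g)
    psi, eif, eps, ok = target_shift_mean(td, Q.y_lo, Q.y_hi, fluctuation)
    se, lo, hi, p = eif_inference(eif, psi)
    return ShiftEstimate(
        psi=psi, se=se, ci_lo=lo, ci_hi=hi, p_value=p, eif=eif,
        n=data.n, deltas=spec.as_mapping(),
        condition=condition or "+".join(spec.targets),
        fold=fold, epsilon=eps, converged=ok,
    )
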