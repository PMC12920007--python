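"""K-fold discovery-estimation of data-adaptive shift parameters.

Because the estimand ("the top synergy pair") is chosen from the data,
estimating it on the same rows used to choose it gives anti-conservative
inference.  The engine therefore splits the sample into K folds; within
each fold the training rows rank candidate exposure pairs (and single
exposures) by fast g-computation contrasts, and the held-out validation
rows estimate the discovered parameters by TMLE (CV-TMLE).  Shift
magnitudes are shrunk adaptively on the training fold whenever the
density ratio exceeds a positivity ceiling; fold estimates are combined
by a single pooled targeting step over the stacked validation folds and
reported with the average feasible shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import MixtureDataset, ShiftSpec
from .interaction import (
    InteractionEstimate,
    InteractionTargetingData,
    gcomp_interaction,
    gcomp_single_shift,
    interaction_delta_method,
    interaction_targeting_data,
    target_interaction_direct,
)
from .nuisance import OutcomeModel, RatioModel, fit_outcome_regression, fit_ratio
from .tmle import (
    ShiftEstimate,
    ShiftTargetingData,
    baseline_mean,
    eif_inference,
    shift_targeting_data,
    target_shift_mean,
)

__all__ = [
    "AnalysisConfig",
    "FoldPlan",
    "RankedPairs",
    "BlockResult",
    "PooledResult",
    "PositivityError",
    "make_folds",
    "rank_pairs",
    "rank_marginals",
    "adapt_delta",
    "run_discovery_estimation",
    "pool_folds",
    "rank_consistency",
    "child_seed",
]

BLOCK_KINDS = ("marginal_pos", "marginal_neg", "synergy", "antagonism")
BLOCK_LABELS = {
    "marginal_pos": "Positive Marginal",
    "marginal_neg": "Negative Marginal",
    "synergy": "Synergy",
    "antagonism": "Antagonism",
}


class PositivityError(RuntimeError):
    """Raised when no feasible shift satisfies the ratio ceiling."""


def child_seed(seed: int, *keys: int) -> int:
    """Counter-based fan-out of one global seed into independent streams."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class AnalysisConfig:
    """Configuration of the discovery-estimation engine.

    ``delta`` is a scalar shift applied to every exposure, or a mapping
    from exposure name to shift.  ``targets`` selects which result
    blocks to estimate.  ``q_roster``/``ratio_roster`` of None means the
    package defaults (intercept-only, main-terms GLM, random forest,
    gradient boosting).
    """

    k_folds: int = 3
    top_s: int = 1
    delta: float | dict[str, float] = 0.5
    lam: float = 50.0
    approach: str = "delta"  # {"delta", "direct"}
    density_method: str = "classifier"  # {"classifier", "direct"}
    fluctuation: str = "logistic"
    q_roster: Sequence[str] | None = None
    ratio_roster: Sequence[str] | None = None
    v_folds: int = 3
    targets: tuple[str, ...] = BLOCK_KINDS
    estimate: bool = True
    seed: int = 0

    def delta_for(self, exposure: str) -> float:
        if isinstance(self.delta, dict):
            return float(self.delta[exposure])
        return float(self.delta)

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("need at least K=2 folds (no held-out fold otherwise)")
        if self.top_s < 1:
            raise ValueError("top_s must be >= 1")
        if self.approach not in ("delta", "direct"):
            raise ValueError(f"unknown approach {self.approach!r}")
        unknown = set(self.targets) - set(BLOCK_KINDS)
        if unknown:
            raise ValueError(f"unknown target block(s): {sorted(unknown)}")


@dataclass(frozen=True)
class FoldPlan:
    """Validation folds are pairwise disjoint and cover all rows."""

    K: int
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]  # (train_idx, val_idx)
    seed: int

    def __iter__(self):
        return iter(self.folds)


def make_folds(n: int, K: int, seed: int) -> FoldPlan:
    """Split 1..n into K approximately equal validation folds."""
    if K > n:
        raise ValueError("K cannot exceed n")
    if K < 2:
        raise ValueError("need at least K=2 folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_folds = np.array_split(order, K)
    folds = []
    for val in val_folds:
        val = np.sort(val)
        train = np.setdiff1d(np.arange(n), val)
        folds.append((train, val))
    return FoldPlan(K=K, folds=tuple(folds), seed=seed)


@dataclass
class RankedPairs:
    """Per-fold g-computation values and the signed top-s sets."""

    values: list[tuple[tuple[str, str], float]]  # all pairs, descending
    synergy: list[tuple[tuple[str, str], float]]  # positive values only
    antagonism: list[tuple[tuple[str, str], float]]  # negative, ascending
    s: int


def rank_pairs(
    train: MixtureDataset,
    Q: OutcomeModel,
    deltas: Callable[[str], float] | dict[str, float] | float,
    s: int = 1,
) -> RankedPairs:
    """Rank all unordered exposure pairs by the g-computation contrast.

    A pair enters the synergy set only with a positive value and the
    antagonism set only with a negative one; ties break lexicographically
    by pair name.
    """
    if train.n_exposures < 2:
        raise ValueError("need at least two exposures to rank pairs")
    dfun = _delta_fun(deltas)
    vals = []
    for i, j in combinations(train.exposure_names, 2):
        vals.append(((i, j), gcomp_interaction(Q, train, (i, j), dfun(i), dfun(j))))
    descending = sorted(vals, key=lambda t: (-t[1], t[0]))
    ascending = sorted(vals, key=lambda t: (t[1], t[0]))
    tol = _sign_tolerance(v for _, v in vals)
    synergy = [(p, v) for p, v in descending if v > tol][:s]
    antagonism = [(p, v) for p, v in ascending if v < -tol][:s]
    return RankedPairs(values=descending, synergy=synergy,
                       antagonism=antagonism, s=s)


def _sign_tolerance(values) -> float:
    # numerical dust from float cancellation must not count as a signed
    # interaction
    vmax = max((abs(v) for v in values), default=0.0)
    return 1e-10 * max(1.0, vmax)


def rank_marginals(
    train: MixtureDataset,
    Q: OutcomeModel,
    deltas: Callable[[str], float] | dict[str, float] | float,
    s: int = 1,
) -> dict[str, list[tuple[str, float]]]:
    """Rank single exposures by their g-computation shift effect."""
    dfun = _delta_fun(deltas)
    vals = [(e, gcomp_single_shift(Q, train, e, dfun(e)))
            for e in train.exposure_names]
    pos = sorted(vals, key=lambda t: (-t[1], t[0]))
    neg = sorted(vals, key=lambda t: (t[1], t[0]))
    tol = _sign_tolerance(v for _, v in vals)
    return {
        "marginal_pos": [(e, v) for e, v in pos if v > tol][:s],
        "marginal_neg": [(e, v) for e, v in neg if v < -tol][:s],
    }


def _delta_fun(deltas) -> Callable[[str], float]:
    if callable(deltas):
        return deltas
    if isinstance(deltas, dict):
        return lambda e: float(deltas[e])
    return lambda e: float(deltas)


def adapt_delta(
    train: MixtureDataset,
    spec: ShiftSpec,
    ratio_factory: Callable[[MixtureDataset, ShiftSpec], RatioModel],
    lam: float = 50.0,
    shrink: float = 0.9,
    min_frac: float = 0.01,
) -> tuple[ShiftSpec, RatioModel]:
    """Shrink |delta| on a geometric grid until max_i H_delta < lam.

    Ratios below 1 are never penalized (moving mass into denser regions
    poses no positivity risk).  Returns the feasible spec together with
    the ratio model fitted for it.  Raises PositivityError if even
    1% of the requested shift violates the ceiling.
    """
    if lam <= 1:
        raise ValueError("ceiling lam must exceed 1")
    initial = spec.magnitude
    current = spec
    g = ratio_factory(train, current)
    while True:
        raw_max = float(np.max(g.raw_ratio(train.W, train.A)))
        g.max_ratio_ = raw_max
        if raw_max < lam:
            return current, g
        current = current.scaled(shrink)
        if current.magnitude < min_frac * initial:
            raise PositivityError(
                f"positivity: no feasible shift above {min_frac:.0%} of the "
                f"requested magnitude satisfies the ceiling {lam}"
            )
        if g.method == "direct-density":
            g = g.with_spec(current)
        else:
            g = ratio_factory(train, current)


# ---------------------------------------------------------------------------
# fold-level estimation blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockResult:
    """One discovered parameter estimated on one validation fold."""

    kind: str
    rank: int
    fold: int
    variables: tuple[str, ...]
    deltas: dict[str, float]
    n: int
    estimates: dict[str, object] = field(default_factory=dict)
    shift_tds: dict[str, ShiftTargetingData] = field(default_factory=dict)
    interaction_td: InteractionTargetingData | None = None
    val_idx: np.ndarray | None = None
    error: str | None = None


@dataclass
class PooledResult:
    """Fold-level and pooled estimates plus discovery diagnostics."""

    config: AnalysisConfig
    fold_plan: FoldPlan
    fold_blocks: list[BlockResult]
    pooled_blocks: list[BlockResult]
    fold_rankings: dict[str, list[list[tuple, ...]]]
    rank_tables: dict[str, pd.DataFrame]
    delta_bars: dict[tuple[str, int], dict[str, float]]
    q_learners: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Tidy results table (fold rows then pooled rows per block)."""
        rows = []
        for blk in self.fold_blocks + self.pooled_blocks:
            fold_label = "Pooled" if blk.fold < 0 else str(blk.fold + 1)
            prefix = f"Rank {blk.rank} {BLOCK_LABELS[blk.kind]}"
            if blk.error is not None:
                rows.append(_row(f"{prefix} [failed: {blk.error}]", None,
                                 fold_label, blk.n, blk.deltas))
                continue
            for cond, est in blk.estimates.items():
                rows.append(_row(f"{prefix} {cond}", est, fold_label,
                                 est.n, _row_deltas(est)))
        return pd.DataFrame(
            rows,
            columns=["Condition", "Psi", "Variance", "SE", "Lower CI",
                     "Upper CI", "P-value", "Fold", "N", "Delta"],
        )

    def pooled_estimate(self, kind: str, rank: int = 1, condition: str | None = None):
        for blk in self.pooled_blocks:
            if blk.kind == kind and blk.rank == rank and blk.error is None:
                if condition is None:
                    condition = ("Interaction"
                                 if kind in ("synergy", "antagonism") else "Marginal")
                return blk.estimates.get(condition)
        return None

    def top_pair_per_fold(self, kind: str = "synergy") -> list[tuple | None]:
        out = []
        for ranked in self.fold_rankings.get(kind, []):
            out.append(ranked[0][0] if ranked else None)
        return out


def _row(condition, est, fold_label, n, deltas):
    if est is None:
        return {"Condition": condition, "Psi": np.nan, "Variance": np.nan,
                "SE": np.nan, "Lower CI": np.nan, "Upper CI": np.nan,
                "P-value": np.nan, "Fold": fold_label, "N": n,
                "Delta": _fmt_deltas(deltas)}
    return {
        "Condition": condition, "Psi": est.psi, "Variance": est.variance,
        "SE": est.se, "Lower CI": est.ci_lo, "Upper CI": est.ci_hi,
        "P-value": est.p_value, "Fold": fold_label, "N": n,
        "Delta": _fmt_deltas(deltas),
    }


def _row_deltas(est) -> dict[str, float]:
    return dict(getattr(est, "deltas", {}) or {})


def _fmt_deltas(deltas: dict[str, float]) -> str:
    return ";".join(f"{v:.6g}" for v in deltas.values()) if deltas else "0"


def rank_consistency(
    fold_rankings: list[list[tuple[tuple, float]]], K: int | None = None
) -> pd.DataFrame:
    """How often each pair (or exposure) occupies the top-s across folds.

    A candidate is flagged robust when it appears in more than half the
    folds, the working rule for calling a discovery stable.
    """
    if K is None:
        K = len(fold_rankings)
    if K < 2:
        raise ValueError("need at least two folds")
    counts: dict[object, list[int]] = {}
    for ranked in fold_rankings:
        for pos, (entity, _val) in enumerate(ranked, start=1):
            counts.setdefault(entity, []).append(pos)
    rows = [
        {
            "variables": ("+".join(e) if isinstance(e, tuple) else e),
            "frequency": len(ranks),
            "mean_rank": float(np.mean(ranks)),
            "robust": len(ranks) > K / 2,
        }
        for e, ranks in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["variables", "frequency", "mean_rank", "robust"])
    return df.sort_values(["frequency", "mean_rank"],
                          ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def _global_scale(data: MixtureDataset) -> tuple[float, float]:
    if data.binary_outcome:
        return 0.0, 1.0
    rng_y = float(np.max(data.Y) - np.min(data.Y))
    m = 0.1 * rng_y
    return float(np.min(data.Y) - m), float(np.max(data.Y) + m)


def _estimate_from_td(
    td: ShiftTargetingData, y_lo, y_hi, fluctuation, deltas, condition, fold
) -> ShiftEstimate:
    psi, eif, eps, ok = target_shift_mean(td, y_lo, y_hi, fluctuation)
    se, lo, hi, p = eif_inference(eif, psi)
    return ShiftEstimate(psi=psi, se=se, ci_lo=lo, ci_hi=hi, p_value=p,
                         eif=eif, n=len(td.y), deltas=deltas,
                         condition=condition, fold=fold, epsilon=eps,
                         converged=ok)


def _estimate_pair_block(
    kind, rank, k, pair, train, val, Q, config, seed
) -> BlockResult:
    i, j = pair
    di, dj = config.delta_for(i), config.delta_for(j)
    joint_spec = ShiftSpec((i, j), (di, dj))

    def factory(ds, spec):
        return fit_ratio(ds, spec, config.density_method, config.ratio_roster,
                         seed, ceiling=config.lam)

    joint_spec, g_joint = adapt_delta(train, joint_spec, factory, config.lam)
    di, dj = joint_spec.deltas
    spec_i, spec_j = ShiftSpec((i,), (di,)), ShiftSpec((j,), (dj,))
    g_i = factory(train, spec_i)
    g_j = factory(train, spec_j)

    blk = BlockResult(kind=kind, rank=rank, fold=k, variables=(i, j),
                      deltas={i: di, j: dj}, n=val.n)
    tds = {
        f"Var 1 ({i})": shift_targeting_data(val, spec_i, Q, g_i),
        f"Var 2 ({j})": shift_targeting_data(val, spec_j, Q, g_j),
        "Joint": shift_targeting_data(val, joint_spec, Q, g_joint),
    }
    ests: dict[str, object] = {}
    for (cond, td), deltas in zip(
        tds.items(), ({i: di}, {j: dj}, {i: di, j: dj})
    ):
        ests[cond] = _estimate_from_td(td, Q.y_lo, Q.y_hi, config.fluctuation,
                                       deltas, cond, k)
    base = baseline_mean(val, fold=k)
    if config.approach == "delta":
        inter = interaction_delta_method(
            ests["Joint"], ests[f"Var 1 ({i})"], ests[f"Var 2 ({j})"], base,
            pair=pair, fold=k,
        )
        inter.condition = "Interaction"
    else:
        itd = interaction_targeting_data(val, joint_spec, spec_i, spec_j,
                                         Q, g_joint, g_i, g_j)
        psi, eif, eps, ok = target_interaction_direct(
            itd, Q.y_lo, Q.y_hi, config.fluctuation)
        se, lo, hi, p = eif_inference(eif, psi)
        inter = InteractionEstimate(
            psi=psi, se=se, ci_lo=lo, ci_hi=hi, p_value=p, eif=eif, n=val.n,
            approach="direct", pair=pair, deltas={i: di, j: dj}, fold=k,
            epsilon=eps, converged=ok,
        )
        blk.interaction_td = itd
    ests["Interaction"] = inter
    blk.estimates = ests
    blk.shift_tds = tds
    return blk


def _estimate_marginal_block(
    kind, rank, k, exposure, train, val, Q, config, seed
) -> BlockResult:
    delta = config.delta_for(exposure)
    spec = ShiftSpec((exposure,), (delta,))

    def factory(ds, s):
        return fit_ratio(ds, s, config.density_method, config.ratio_roster,
                         seed, ceiling=config.lam)

    spec, g = adapt_delta(train, spec, factory, config.lam)
    blk = BlockResult(kind=kind, rank=rank, fold=k, variables=(exposure,),
                      deltas=spec.as_mapping(), n=val.n)
    td = shift_targeting_data(val, spec, Q, g)
    blk.estimates = {"Marginal": _estimate_from_td(
        td, Q.y_lo, Q.y_hi, config.fluctuation, spec.as_mapping(),
        f"Marginal ({exposure})", k)}
    blk.shift_tds = {"Marginal": td}
    return blk


def run_discovery_estimation(
    data: MixtureDataset, config: AnalysisConfig
) -> PooledResult:
    """Run the full K-fold discovery-estimation pipeline.

    Per fold: fit the outcome regression on the training rows, rank
    pairs (and single exposures) by g-computation, adapt the shift for
    positivity, then TMLE the discovered parameters on the validation
    rows.  Fold estimates are pooled by rank with a single targeting
    step over the stacked validation folds.
    """
    config.validate()
    plan = make_folds(data.n, config.k_folds, config.seed)
    y_lo, y_hi = _global_scale(data)

    fold_blocks: list[BlockResult] = []
    fold_rankings: dict[str, list[list]] = {kind: [] for kind in BLOCK_KINDS}
    q_learners = []
    want_pairs = {"synergy", "antagonism"} & set(config.targets)
    want_marg = {"marginal_pos", "marginal_neg"} & set(config.targets)

    for k, (tr_idx, va_idx) in enumerate(plan):
        assert len(np.intersect1d(tr_idx, va_idx)) == 0
        train, val = data.subset(tr_idx), data.subset(va_idx)
        seed_k = child_seed(config.seed, 1, k)
        Q = fit_outcome_regression(train, config.q_roster, config.v_folds, seed_k)
        q_learners.append(Q.learner_name)

        if want_pairs:
            ranked = rank_pairs(train, Q, config.delta_for, config.top_s)
            fold_rankings["synergy"].append(ranked.synergy)
            fold_rankings["antagonism"].append(ranked.antagonism)
        if want_marg:
            margs = rank_marginals(train, Q, config.delta_for, config.top_s)
            fold_rankings["marginal_pos"].append(margs["marginal_pos"])
            fold_rankings["marginal_neg"].append(margs["marginal_neg"])

        if not config.estimate:
            continue
        for kind in config.targets:
            ranking = fold_rankings[kind][-1]
            for r, (entity, _val) in enumerate(ranking, start=1):
                try:
                    if kind in ("synergy", "antagonism"):
                        blk = _estimate_pair_block(
                            kind, r, k, entity, train, val, Q, config, seed_k)
                    else:
                        blk = _estimate_marginal_block(
                            kind, r, k, entity, train, val, Q, config, seed_k)
                except PositivityError as exc:
                    blk = BlockResult(kind=kind, rank=r, fold=k,
                                      variables=(entity if isinstance(entity, tuple)
                                                 else (entity,)),
                                      deltas={}, n=val.n, error=str(exc))
                blk.val_idx = va_idx
                fold_blocks.append(blk)

    rank_tables = {
        kind: rank_consistency(fold_rankings[kind], plan.K)
        for kind in config.targets
        if fold_rankings.get(kind)
    }
    pooled_blocks, delta_bars = ([], {})
    if config.estimate:
        pooled_blocks, delta_bars = pool_folds(
            fold_blocks, data, config, y_lo, y_hi)
    return PooledResult(
        config=config, fold_plan=plan, fold_blocks=fold_blocks,
        pooled_blocks=pooled_blocks, fold_rankings=fold_rankings,
        rank_tables=rank_tables, delta_bars=delta_bars, q_learners=q_learners,
    )


def pool_folds(
    fold_blocks: list[BlockResult],
    data: MixtureDataset,
    config: AnalysisConfig,
    y_lo: float | None = None,
    y_hi: float | None = None,
) -> tuple[list[BlockResult], dict[tuple[str, int], dict[str, float]]]:
    """Pool fold estimates by rank via one stacked targeting step.

    Alignment is by rank, not pair identity: the rank-1 synergy slot may
    hold different pairs in different folds, in which case the pooled row
    averages over the discovered pairs (provenance is retained in the
    fold rows).  Each stacked row keeps its own fold's nuisance
    predictions and clever covariates; a single fluctuation is then run
    on the stacked arrays and the pooled shift is the average of the
    fold-specific feasible shifts.
    """
    if y_lo is None or y_hi is None:
        y_lo, y_hi = _global_scale(data)
    groups: dict[tuple[str, int], list[BlockResult]] = {}
    for blk in fold_blocks:
        groups.setdefault((blk.kind, blk.rank), []).append(blk)

    pooled_blocks: list[BlockResult] = []
    delta_bars: dict[tuple[str, int], dict[str, float]] = {}
    for (kind, rank), blks in sorted(groups.items()):
        ok_blks = [b for b in blks if b.error is None]
        if not ok_blks or len(ok_blks) < len(blks):
            missing = [b.fold + 1 for b in blks if b.error is not None]
            pooled_blocks.append(BlockResult(
                kind=kind, rank=rank, fold=-1,
                variables=tuple(sorted({v for b in blks for v in b.variables})),
                deltas={}, n=sum(b.n for b in blks),
                error=f"positivity failure in fold(s) {missing}"))
            continue
        n_total = sum(b.n for b in ok_blks)
        # average shift, position-wise across folds (pairs may differ)
        dbar = {}
        positions = max(len(b.deltas) for b in ok_blks)
        for pos in range(positions):
            vals = [list(b.deltas.values())[pos] for b in ok_blks]
            names = sorted({list(b.deltas)[pos] for b in ok_blks})
            dbar["/".join(names)] = float(np.mean(vals))
        delta_bars[(kind, rank)] = dbar

        blk = BlockResult(
            kind=kind, rank=rank, fold=-1,
            variables=tuple(sorted({v for b in ok_blks for v in b.variables})),
            deltas=dbar, n=n_total,
        )
        ests: dict[str, object] = {}
        cond_keys = _aligned_conditions(ok_blks)
        shift_ests: dict[str, ShiftEstimate] = {}
        for slot, labels in cond_keys.items():
            tds = [b.shift_tds[lab] for b, lab in zip(ok_blks, labels)]
            td = ShiftTargetingData.stack(tds)
            label = slot if len(set(labels)) > 1 else labels[0]
            est = _estimate_from_td(td, y_lo, y_hi, config.fluctuation,
                                    dbar, label, "pooled")
            shift_ests[slot] = est
            ests[label] = est
        if kind in ("synergy", "antagonism"):
            # stacked in fold order so the baseline EIF aligns row-wise
            # with the stacked shift-mean EIFs
            base = baseline_mean(
                data.subset(np.concatenate([b.val_idx for b in ok_blks])),
                fold="pooled")
            if config.approach == "delta":
                inter = interaction_delta_method(
                    shift_ests["Joint"], shift_ests["Var 1"],
                    shift_ests["Var 2"], base, pair=blk.variables[:2],
                    fold="pooled")
                inter.condition = "Interaction"
            else:
                itd = InteractionTargetingData.stack(
                    [b.interaction_td for b in ok_blks])
                psi, eif, eps, okf = target_interaction_direct(
                    itd, y_lo, y_hi, config.fluctuation)
                se, lo, hi, p = eif_inference(eif, psi)
                inter = InteractionEstimate(
                    psi=psi, se=se, ci_lo=lo, ci_hi=hi, p_value=p, eif=eif,
                    n=n_total, approach="direct", pair=blk.variables[:2],
                    deltas=dbar, fold="pooled", epsilon=eps, converged=okf)
            ests["Interaction"] = inter
        blk.estimates = ests
        pooled_blocks.append(blk)
    return pooled_blocks, delta_bars


def _aligned_conditions(blks: list[BlockResult]) -> dict[str, list[str]]:
    """Map rank-aligned slots ("Var 1", "Var 2", "Joint", "Marginal") to
    each fold's concrete condition label."""
    slots: dict[str, list[str]] = {}
    for b in blks:
        for lab in b.shift_tds:
            slot = lab.split(" (")[0]
            slots.setdefault(slot, []).append(lab)
    return {s: labs for s, labs in slots.items() if len(labs) == len(blks)}
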