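"""Model/Results interface over the discovery-estimation engine.

``ShiftInteractionModel`` holds the validated data and configuration;
``fit()`` runs the K-fold discovery-estimation pipeline and returns a
``ShiftInteractionResults`` carrying the fold-level and pooled
estimates, their EIF-based standard errors, the rank-consistency
diagnostics, and a run manifest sufficient to reproduce the fit.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .data import MixtureDataset, validate_dataset
from .discovery import (
    AnalysisConfig,
    BLOCK_LABELS,
    PooledResult,
    run_discovery_estimation,
)

__all__ = ["ShiftInteractionModel", "ShiftInteractionResults"]


class ShiftInteractionModel:
    """Data-adaptive shift-interaction analysis of an exposure mixture."""

    def __init__(self, data: MixtureDataset, config: AnalysisConfig | None = None,
                 **config_kwargs):
        if config is None:
            config = AnalysisConfig(**config_kwargs)
        elif config_kwargs:
            config = dataclasses.replace(config, **config_kwargs)
        config.validate()
        self.data = data
        self.config = config

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        exposures: Iterable[str],
        confounders: Iterable[str],
        outcome: str = "Y",
        **config_kwargs,
    ) -> "ShiftInteractionModel":
        data = validate_dataset(df, confounders, exposures, outcome)
        return cls(data, **config_kwargs)

    def fit(self, seed: int | None = None) -> "ShiftInteractionResults":
        config = self.config
        if seed is not None:
            config = dataclasses.replace(config, seed=seed)
        raw = run_discovery_estimation(self.data, config)
        return ShiftInteractionResults(self, raw)


class ShiftInteractionResults:
    """Fitted discovery-estimation results."""

    def __init__(self, model: ShiftInteractionModel, raw: PooledResult):
        self.model = model
        self.raw = raw
        self.results_table = raw.table()
        self.rank_tables = raw.rank_tables

    # -- accessors -------------------------------------------------------
    def pooled_estimate(self, kind: str, rank: int = 1, condition: str | None = None):
        return self.raw.pooled_estimate(kind, rank, condition)

    @property
    def delta_bars(self) -> Mapping:
        return self.raw.delta_bars

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self.model.config)
        cfg["targets"] = list(cfg["targets"])
        fold_deltas = {}
        for blk in self.raw.fold_blocks:
            key = f"{blk.kind}:rank{blk.rank}"
            fold_deltas.setdefault(key, []).append(
                {"fold": blk.fold + 1, "deltas": blk.deltas,
                 "variables": list(blk.variables), "error": blk.error})
        return {
            "package": "mixshift",
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "config": cfg,
            "seed_scheme": ("SeedSequence([seed, stream, counter]) -> "
                            "first state word mod 2^31"),
            "q_learners_selected": self.raw.q_learners,
            "fold_deltas": fold_deltas,
            "delta_bar": {f"{k}:rank{r}": v
                          for (k, r), v in self.raw.delta_bars.items()},
            "n": self.model.data.n,
            "exposures": list(self.model.data.exposure_names),
            "confounders": list(self.model.data.confounder_names),
            "outcome": self.model.data.outcome_name,
        }

    def save(self, results_csv: str, manifest_json: str | None = None) -> None:
        self.results_table.to_csv(results_csv, index=False, float_format="%.17g")
        if manifest_json is not None:
            with open(manifest_json, "w") as fh:
                json.dump(self.manifest(), fh, indent=2, default=str)

    def summary(self) -> str:
        """Human-readable summary of the pooled estimates."""
        lines = [
            "Stochastic-shift interaction analysis",
            "=" * 72,
            f"n = {self.model.data.n}, exposures = "
            f"{len(self.model.data.exposure_names)}, "
            f"K = {self.model.config.k_folds} folds, "
            f"approach = {self.model.config.approach}, "
            f"delta = {self.model.config.delta}",
            "-" * 72,
        ]
        header = (f"{'Condition':<34}{'Psi':>9}{'SE':>8}"
                  f"{'95% CI':>19}{'P':>7}")
        lines.append(header)
        for blk in self.raw.pooled_blocks:
            label = f"Rank {blk.rank} {BLOCK_LABELS[blk.kind]}"
            if blk.error is not None:
                lines.append(f"{label:<34}  {blk.error}")
                continue
            for cond, est in blk.estimates.items():
                name = f"{label} {cond}"
                lines.append(
                    f"{name:<34}{est.psi:>9.3f}{est.se:>8.3f}"
                    f"  ({est.ci_lo:>7.3f}, {est.ci_hi:>7.3f})"
                    f"{est.p_value:>7.2f}"
                )
        lines.append("-" * 72)
        for kind, tab in self.rank_tables.items():
            if len(tab):
                top = tab.iloc[0]
                lines.append(
                    f"top {BLOCK_LABELS[kind].lower()}: {top['variables']} "
                    f"(in {int(top['frequency'])}/{self.model.config.k_folds} "
                    f"folds, mean rank {top['mean_rank']:.1f}"
                    f"{', robust' if top['robust'] else ''})")
        return "\n".join(lines)

    def plot_estimates(self, ax=None):
        """Forest-style plot of the pooled estimates with 95% CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        labels, psis, los, his = [], [], [], []
        for blk in self.raw.pooled_blocks:
            if blk.error is not None:
                continue
            for cond, est in blk.estimates.items():
                labels.append(f"{BLOCK_LABELS[blk.kind]} {cond}")
                psis.append(est.psi)
                los.append(est.ci_lo)
                his.append(est.ci_hi)
        ypos = np.arange(len(labels))[::-1]
        ax.errorbar(psis, ypos,
                    xerr=[np.array(psis) - np.array(los),
                          np.array(his) - np.array(psis)],
                    fmt="o", capsize=3)
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(ypos)
        ax.set_yticklabels(labels)
        ax.set_xlabel("Psi (pooled TMLE, 95% CI)")
        return ax
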