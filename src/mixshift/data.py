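"""Observational mixture data containers and stochastic shift specifications.

The unit of analysis is a triple O = (W, A, Y): baseline confounders W,
a vector of continuous exposures A, and an outcome Y (continuous or binary).
A stochastic shift intervention replaces each targeted exposure by its
observed value plus a signed shift delta; the post-intervention exposure
density is the observed conditional density translated by delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixtureDataset",
    "ShiftSpec",
    "validate_dataset",
    "apply_shift",
]


@dataclass(frozen=True)
class MixtureDataset:
    """Validated (W, A, Y) triples with column metadata.

    Attributes
    ----------
    W : ndarray, shape (n, q)
        Confounder matrix.
    A : ndarray, shape (n, p)
        Exposure matrix; columns are named and names are unique.
    Y : ndarray, shape (n,)
        Outcome vector; flagged binary iff every value is 0 or 1.
    """

    W: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    confounder_names: tuple[str, ...]
    exposure_names: tuple[str, ...]
    outcome_name: str = "Y"
    binary_outcome: bool = field(default=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        A = np.asarray(self.A, dtype=float)
        Y = np.asarray(self.Y, dtype=float).ravel()
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "confounder_names", tuple(self.confounder_names))
        object.__setattr__(self, "exposure_names", tuple(self.exposure_names))
        n = Y.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one row")
        if W.ndim != 2 or A.ndim != 2:
            raise ValueError("W and A must be two-dimensional")
        if W.shape[0] != n or A.shape[0] != n:
            raise ValueError("W, A and Y must share the same row count")
        if W.shape[1] != len(self.confounder_names):
            raise ValueError("confounder_names does not match W columns")
        if A.shape[1] != len(self.exposure_names):
            raise ValueError("exposure_names does not match A columns")
        if len(set(self.exposure_names)) != len(self.exposure_names):
            raise ValueError("duplicate exposure name")
        for name, arr in (("W", W), ("A", A), ("Y", Y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite value in {name}")
        object.__setattr__(
            self, "binary_outcome", bool(np.all(np.isin(Y, (0.0, 1.0))))
        )

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.A.shape[1]

    def exposure_index(self, name: str) -> int:
        try:
            return self.exposure_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown exposure {name!r}") from exc

    def exposure(self, name: str) -> np.ndarray:
        return self.A[:, self.exposure_index(name)]

    def subset(self, idx: np.ndarray | Sequence[int]) -> "MixtureDataset":
        idx = np.asarray(idx)
        return MixtureDataset(
            W=self.W[idx],
            A=self.A[idx],
            Y=self.Y[idx],
            confounder_names=self.confounder_names,
            exposure_names=self.exposure_names,
            outcome_name=self.outcome_name,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.W, columns=list(self.confounder_names))
        for j, name in enumerate(self.exposure_names):
            df[name] = self.A[:, j]
        df[self.outcome_name] = self.Y
        return df


@dataclass(frozen=True)
class ShiftSpec:
    """Which exposures are shifted and by how much.

    The post-intervention exposure is ``observed + delta``; a regulatory
    reduction of one unit is requested as ``delta=-1``.  Non-target
    exposures implicitly carry ``delta=0``.
    """

    targets: tuple[str, ...]
    deltas: tuple[float, ...]
    convention: str = "additive"

    def __post_init__(self) -> None:
        targets = tuple(self.targets)
        deltas = tuple(float(d) for d in np.atleast_1d(np.asarray(self.deltas, dtype=float)))
        if len(targets) != len(deltas):
            raise ValueError("targets and deltas must align")
        if len(set(targets)) != len(targets):
            raise ValueError("duplicate shift target")
        if not all(np.isfinite(d) for d in deltas):
            raise ValueError("shift delta must be finite")
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "deltas", deltas)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ShiftSpec":
        return cls(tuple(mapping.keys()), tuple(mapping.values()))

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.targets, self.deltas))

    def delta_for(self, name: str) -> float:
        return self.as_mapping().get(name, 0.0)

    def scaled(self, factor: float) -> "ShiftSpec":
        """Return a copy with every delta multiplied by ``factor``."""
        return ShiftSpec(self.targets, tuple(d * factor for d in self.deltas),
                         self.convention)

    def negated(self) -> "ShiftSpec":
        return self.scaled(-1.0)

    def validate_for(self, dataset: MixtureDataset) -> None:
        for t in self.targets:
            if t not in dataset.exposure_names:
                raise KeyError(f"unknown shift target {t!r}")

    @property
    def magnitude(self) -> float:
        """Common |delta| scale (max absolute shift across targets)."""
        return float(max(abs(d) for d in self.deltas)) if self.deltas else 0.0


def validate_dataset(
    table: pd.DataFrame,
    confounders: Iterable[str],
    exposures: Iterable[str],
    outcome: str,
) -> MixtureDataset:
    """Validate a raw table with declared column roles.

    Raises on a missing column, a non-finite value, or a duplicate
    exposure name.  The binary-outcome flag is set iff every outcome
    value is 0 or 1.
    """
    confounders = list(confounders)
    exposures = list(exposures)
    missing = [c for c in confounders + exposures + [outcome] if c not in table.columns]
    if missing:
        raise KeyError(f"missing column(s): {missing}")
    if len(set(exposures)) != len(exposures):
        raise ValueError("duplicate exposure name")
    return MixtureDataset(
        W=table[confounders].to_numpy(dtype=float),
        A=table[exposures].to_numpy(dtype=float),
        Y=table[outcome].to_numpy(dtype=float),
        confounder_names=tuple(confounders),
        exposure_names=tuple(exposures),
        outcome_name=outcome,
    )


def apply_shift(
    dataset: MixtureDataset,
    spec: ShiftSpec,
    mode: str = "post-intervention",
    A: np.ndarray | None = None,
) -> np.ndarray:
    """Return the exposure matrix under a shift specification.

    ``mode="post-intervention"`` adds each target's delta (the exposure
    values at which the outcome regression is evaluated after
    intervening); ``mode="density-argument"`` subtracts it (the argument
    at which the observed conditional density is evaluated to obtain the
    shifted density).  Non-target columns are returned unchanged.
    """
    if mode not in ("post-intervention", "density-argument"):
        raise ValueError(f"unknown mode {mode!r}")
    spec.validate_for(dataset)
    out = np.array(dataset.A if A is None else A, dtype=float, copy=True)
    sign = 1.0 if mode == "post-intervention" else -1.0
    for name, delta in zip(spec.targets, spec.deltas):
        out[:, dataset.exposure_index(name)] += sign * delta
    return out
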