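"""Sensitivity summary statistics and the distance to observed data.

The summary statistic of one simulated candidate is the vector of per-node
sensitivities to a beta perturbation,

    eps(N) = ln( SS_high(N) / SS_low(N) ) / ln( beta_high / beta_low ),

where SS_low / SS_high are the steady states with the perturbed nodes'
independent activity at the low / high level.  Simulated and observed
vectors are both scaled to max-abs 1 before comparison by Euclidean
distance, which makes the comparison independent of the logarithm base of
the observed fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grn_model import (
    DirectedGRN,
    GRNError,
    ModelParameters,
    SolverConfig,
    steady_state,
)
from .orientations import Orientation, PerturbationCondition

__all__ = [
    "SensitivityVector",
    "ObservedVector",
    "AlignmentError",
    "sensitivity_vector",
    "scale_vector",
    "euclidean_distance",
]


class AlignmentError(GRNError):
    """Two node-indexed vectors do not share the same node set."""


@dataclass(frozen=True)
class SensitivityVector:
    """Per-node sensitivity values for one (orientation, condition) pair."""

    values: Mapping[str, float]
    condition: PerturbationCondition
    orientation: Orientation | None = None

    def as_array(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.values[n] for n in nodes], dtype=float)


@dataclass(frozen=True)
class ObservedVector:
    """Scaled observed per-node values (e.g. Log2FC), max-abs <= 1."""

    values: Mapping[str, float]
    label: str = "observed"

    def __post_init__(self) -> None:
        vals = list(self.values.values())
        if any(not math.isfinite(v) for v in vals):
            raise GRNError(f"observed vector {self.label!r} has non-finite values")
        if vals and max(abs(v) for v in vals) > 1 + 1e-12:
            raise GRNError(
                f"observed vector {self.label!r} is not scaled to max-abs <= 1; "
                "apply scale_vector first (ObservedVector.from_raw does this)"
            )

    @classmethod
    def from_raw(cls, values: Mapping[str, float], label: str = "observed") -> "ObservedVector":
        """Scale raw per-node values to max-abs 1 and wrap them."""
        nodes = list(values)
        scaled = scale_vector(np.array([values[n] for n in nodes], dtype=float))
        return cls(dict(zip(nodes, scaled.tolist())), label=label)

    def as_array(self, nodes: Sequence[str]) -> np.ndarray:
        missing = [n for n in nodes if n not in self.values]
        extra = [n for n in self.values if n not in set(nodes)]
        if missing or extra:
            raise AlignmentError(
                f"observed vector {self.label!r} does not align with the network: "
                f"missing {missing or 'none'}, extra {extra or 'none'}"
            )
        return np.array([self.values[n] for n in nodes], dtype=float)


def sensitivity_vector(
    grn: DirectedGRN,
    params: ModelParameters,
    condition: PerturbationCondition,
    config: SolverConfig | None = None,
    orientation: Orientation | None = None,
    ss_memo: dict | None = None,
) -> SensitivityVector:
    """Log-log response of every node to the condition's beta switch.

    Both steady states use the same solver configuration.  When several
    nodes are perturbed together they all switch beta at once and the
    denominator stays ``ln(beta_high / beta_low)``.  A zero steady state
    makes the log ratio undefined and raises; under the standard strictly
    positive parametrization this cannot happen.

    ``ss_memo`` (keyed by the beta-override profile) lets a caller reuse
    steady states shared between conditions of the same network — e.g. the
    unperturbed baseline, identical across all single-node conditions.
    """
    unknown = [n for n in condition.perturbed if n not in grn.nodes]
    if unknown:
        raise AlignmentError(f"perturbed nodes not in network: {unknown}")
    low = {n: condition.beta_low for n in condition.perturbed}
    high = {n: condition.beta_high for n in condition.perturbed}

    def _solve(overrides: Mapping[str, float]):
        betas = dict(params.beta)
        betas.update(overrides)
        key = tuple(sorted(betas.items()))
        if ss_memo is not None and key in ss_memo:
            return ss_memo[key]
        state = steady_state(grn, params.with_beta(overrides), config)
        if ss_memo is not None:
            ss_memo[key] = state
        return state

    ss_low = _solve(low)
    ss_high = _solve(high)
    denom = math.log(condition.beta_high / condition.beta_low)
    values = {}
    for node in grn.nodes:
        lo, hi = ss_low[node], ss_high[node]
        if lo <= 0.0 or hi <= 0.0:
            raise GRNError(
                f"steady state of node {node!r} is zero; sensitivity log-ratio undefined"
            )
        values[node] = math.log(hi / lo) / denom
    return SensitivityVector(values, condition=condition, orientation=orientation)


def scale_vector(v: np.ndarray) -> np.ndarray:
    """Divide by the maximum absolute component; all-zero vectors pass through.

    Sign- and ratio-preserving, idempotent, and the scaled vector lies in
    [-1, 1].
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise GRNError("cannot scale a vector with non-finite values")
    m = np.max(np.abs(v)) if v.size else 0.0
    if m == 0.0:
        return v.copy()
    return v / m


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Plain l2 distance between two aligned vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"vector shapes differ: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
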