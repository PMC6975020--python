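"""Rejection ABC over link orientations.

The parameter of interest Theta is the direction of every edge of an
undirected network.  The prior is uniform: every one of the 2**L
orientations is simulated under every perturbation condition, its scaled
sensitivity vector is compared to the scaled observed vector by Euclidean
distance, and only the closest fraction of candidates is accepted.  The
posterior probability that an edge points in its canonical forward
direction is the proportion of accepted candidates that orient it forward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .grn_model import (
    ConvergenceError,
    GRNError,
    ModelParameters,
    SolverConfig,
    UndirectedGRN,
)
from .orientations import (
    DEFAULT_EDGE_CAP,
    Orientation,
    PerturbationCondition,
    apply_orientation,
    enumerate_orientations,
    perturbation_conditions,
)
from .sensitivity import ObservedVector, euclidean_distance, scale_vector, sensitivity_vector

__all__ = [
    "ABCConfig",
    "Candidate",
    "ABCResult",
    "simulate_candidates",
    "reject",
    "link_posteriors",
    "run_abc",
    "percent_accepted",
]


@dataclass(frozen=True)
class ABCConfig:
    """Everything that fixes one exhaustive ABC run (no randomness anywhere)."""

    beta_low: float = 0.01
    beta_high: float = 0.1
    max_subset_size: int = 1
    acyclic_only: bool = False
    top_fraction: float | None = 0.1  # percent of candidates kept
    distance_threshold: float | None = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    edge_cap: int = DEFAULT_EDGE_CAP

    def __post_init__(self) -> None:
        if (self.top_fraction is None) == (self.distance_threshold is None):
            raise GRNError(
                "exactly one of top_fraction and distance_threshold must be set"
            )
        if self.top_fraction is not None and not 0 < self.top_fraction <= 100:
            raise GRNError(f"top_fraction must be in (0, 100], got {self.top_fraction}")


@dataclass(frozen=True)
class Candidate:
    """One simulated (orientation, perturbation) pair with its distance."""

    orientation: Orientation
    orientation_index: int
    condition: PerturbationCondition
    condition_index: int
    summary: tuple[float, ...]  # scaled sensitivity vector, network node order
    distance: float

    @property
    def sort_key(self) -> tuple[float, int, int]:
        return (self.distance, self.orientation_index, self.condition_index)


@dataclass(frozen=True)
class ABCResult:
    """Accepted candidates, realized threshold and per-edge posteriors.

    ``link_posteriors`` maps each undirected edge (as its canonical
    ``(source, target)`` pair) to the posterior probability that it points
    forward; the reverse direction has probability one minus that, exactly.
    ``diagnostics`` reports enumeration, convergence-failure and
    unique-orientation tallies.
    """

    accepted: tuple[Candidate, ...]
    acceptance_threshold: float
    total_candidates: int
    link_posteriors: Mapping[tuple[str, str], float]
    diagnostics: Mapping[str, int]
    config: ABCConfig

    @property
    def acceptance_fraction(self) -> float:
        return percent_accepted(len(self.accepted), self.total_candidates)


def percent_accepted(n_accepted: int, n_total: int) -> float:
    """Acceptance rate as a percentage of the pooled candidate set."""
    if n_total <= 0:
        raise GRNError("total candidate count must be positive")
    return 100.0 * n_accepted / n_total


def simulate_candidates(
    grn: UndirectedGRN,
    observed: ObservedVector,
    config: ABCConfig,
    params: ModelParameters | None = None,
) -> Iterator[Candidate | tuple[Orientation, PerturbationCondition, ConvergenceError]]:
    """Stream one candidate per (orientation, condition) pair.

    Orientations iterate in bit-vector order, conditions in subset order;
    the stream is fully deterministic.  A solver convergence failure yields
    the failing pair together with the error instead of a candidate, so the
    caller can count it without aborting the run.
    """
    observed_arr = observed.as_array(grn.nodes)  # validates alignment
    conditions = list(
        perturbation_conditions(
            grn.nodes,
            max_subset_size=config.max_subset_size,
            beta_low=config.beta_low,
            beta_high=config.beta_high,
        )
    )
    for orientation in enumerate_orientations(
        grn, acyclic_only=config.acyclic_only, edge_cap=config.edge_cap
    ):
        directed = apply_orientation(grn, orientation)
        link_params = params if params is not None else ModelParameters.defaults(
            directed, beta=config.beta_low
        )
        ss_memo: dict = {}  # baseline steady state is shared across conditions
        for cond_index, condition in enumerate(conditions):
            try:
                sens = sensitivity_vector(
                    directed,
                    link_params,
                    condition,
                    config.solver,
                    orientation=orientation,
                    ss_memo=ss_memo,
                )
            except ConvergenceError as err:
                yield (orientation, condition, err)
                continue
            summary = scale_vector(sens.as_array(grn.nodes))
            yield Candidate(
                orientation=orientation,
                orientation_index=orientation.index,
                condition=condition,
                condition_index=cond_index,
                summary=tuple(summary.tolist()),
                distance=euclidean_distance(summary, observed_arr),
            )


def reject(
    candidates: Sequence[Candidate],
    top_fraction: float | None = None,
    distance_threshold: float | None = None,
) -> tuple[list[Candidate], float]:
    """Keep the best candidates; returns (accepted, realized threshold).

    Fraction mode keeps the ``ceil(total * fraction / 100)`` smallest
    distances and extends the cut to include every candidate tied with the
    cut distance, so at least one candidate is always accepted and the
    result does not depend on the ordering of ties.  Threshold mode keeps
    every candidate with distance <= threshold.
    """
    if (top_fraction is None) == (distance_threshold is None):
        raise GRNError("give exactly one of top_fraction / distance_threshold")
    if not candidates:
        raise GRNError("cannot reject from an empty candidate set")
    ranked = sorted(candidates, key=lambda c: c.sort_key)
    if top_fraction is not None:
        if not 0 < top_fraction <= 100:
            raise GRNError(f"top_fraction must be in (0, 100], got {top_fraction}")
        k = math.ceil(len(ranked) * top_fraction / 100.0)
        cut = ranked[k - 1].distance
        accepted = [c for c in ranked if c.distance <= cut]
        return accepted, cut
    accepted = [c for c in ranked if c.distance <= distance_threshold]
    return accepted, float(distance_threshold)


def link_posteriors(
    accepted: Sequence[Candidate], grn: UndirectedGRN
) -> dict[tuple[str, str], float]:
    """Per-edge probability of the canonical forward direction.

    Counts pooled accepted candidates: an orientation accepted under k
    perturbation conditions contributes k times, mirroring a rejection
    scheme that thresholds the pooled simulated dataset.
    """
    if not accepted:
        raise GRNError("cannot compute posteriors from an empty accepted set")
    posteriors = {}
    for ell, (u, v, _sign) in enumerate(grn.edges):
        forward = sum(1 for c in accepted if c.orientation.bits[ell] == 1)
        posteriors[(u, v)] = forward / len(accepted)
    return posteriors


def run_abc(
    grn: UndirectedGRN,
    observed: ObservedVector,
    config: ABCConfig | None = None,
    params: ModelParameters | None = None,
) -> ABCResult:
    """Exhaustive rejection ABC over the orientations of ``grn``.

    Fully deterministic: repeated runs with the same inputs give
    bit-identical results.  Candidates whose steady state fails to converge
    (possible only for cyclic orientations) are excluded from the ranking
    and counted in ``diagnostics["n_nonconverged"]``.
    """
    if config is None:
        config = ABCConfig()
    candidates: list[Candidate] = []
    n_nonconverged = 0
    n_enumerated = 0
    for item in simulate_candidates(grn, observed, config, params=params):
        n_enumerated += 1
        if isinstance(item, Candidate):
            candidates.append(item)
        else:
            n_nonconverged += 1
    if not candidates:
        raise GRNError("no candidate converged; nothing to rank")
    accepted, threshold = reject(
        candidates,
        top_fraction=config.top_fraction,
        distance_threshold=config.distance_threshold,
    )
    posteriors = link_posteriors(accepted, grn)
    diagnostics = {
        "n_enumerated": n_enumerated,
        "n_ranked": len(candidates),
        "n_nonconverged": n_nonconverged,
        "n_accepted": len(accepted),
        "n_unique_accepted_orientations": len(
            {c.orientation_index for c in accepted}
        ),
    }
    return ABCResult(
        accepted=tuple(accepted),
        acceptance_threshold=threshold,
        total_candidates=len(candidates),
        link_posteriors=posteriors,
        diagnostics=diagnostics,
        config=config,
    )
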