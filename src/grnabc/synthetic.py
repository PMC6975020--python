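"""Ground-truth networks and synthetic observed data for closed-loop tests.

Emulates the two-condition design the inference assumes: an unperturbed
("axenic") culture where every node sits at its baseline steady state, and
a perturbed ("mixed") culture where the presence of other strains raises
the independent activity beta of a chosen node subset tenfold.  Replicate
samples add multiplicative log-normal noise to the steady states, matching
positive, right-skewed TPM/LFQ-like abundances.  The exact noiseless
Log2FC vector is returned alongside so tests can separate method error
from sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn_model import (
    DirectedGRN,
    GRNError,
    Link,
    ModelParameters,
    Sign,
    SolverConfig,
    steady_state,
)
from .sensitivity import ObservedVector, scale_vector

__all__ = [
    "SyntheticSpec",
    "generate_ground_truth",
    "simulate_observed",
    "average_observations",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic benchmark instance.

    Defaults mirror a small two-condition culture experiment: quadruplicate
    samples per condition, ~5% multiplicative noise on abundances, a
    quarter of links inhibitory, and the perturbation applied to the first
    node in topological order (the most upstream regulator) unless a subset
    is given.
    """

    n_nodes: int
    n_links: int
    seed: int
    inhibition_fraction: float = 0.25
    noise_sd: float = 0.05
    replicates: int = 4
    perturbed_nodes: tuple[str, ...] | None = None
    beta_low: float = 0.01
    beta_high: float = 0.1

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise GRNError("need at least 2 nodes")
        if not self.n_nodes - 1 <= self.n_links <= self.n_nodes * (self.n_nodes - 1) // 2:
            raise GRNError(
                f"n_links must be in [{self.n_nodes - 1}, "
                f"{self.n_nodes * (self.n_nodes - 1) // 2}] for a connected simple DAG"
            )
        if not 0 <= self.inhibition_fraction <= 1:
            raise GRNError("inhibition_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise GRNError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise GRNError("need at least one replicate per condition")


def _node_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_ground_truth(spec: SyntheticSpec) -> DirectedGRN:
    """A random connected DAG with exactly ``spec.n_links`` signed links.

    Construction fixes a topological order, wires each node to a random
    earlier parent (guaranteeing connectivity), then adds extra forward
    links uniformly at random — acyclic by construction and fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = _node_names(spec.n_nodes)
    order = rng.permutation(spec.n_nodes)
    topo = [names[i] for i in order]
    pairs: list[tuple[str, str]] = []
    for k in range(1, spec.n_nodes):
        parent = topo[int(rng.integers(0, k))]
        pairs.append((parent, topo[k]))
    remaining = [
        (topo[i], topo[j])
        for i in range(spec.n_nodes)
        for j in range(i + 1, spec.n_nodes)
        if (topo[i], topo[j]) not in set(pairs)
    ]
    n_extra = spec.n_links - len(pairs)
    if n_extra:
        extra_idx = rng.choice(len(remaining), size=n_extra, replace=False)
        pairs.extend(remaining[int(i)] for i in sorted(extra_idx))
    signs = rng.random(len(pairs)) < spec.inhibition_fraction
    links = [
        Link(u, v, Sign.INHIBITION if inhib else Sign.ACTIVATION)
        for (u, v), inhib in zip(pairs, signs)
    ]
    return DirectedGRN(names, links)


def _topo_first_node(grn: DirectedGRN) -> str:
    targets = {l.target for l in grn.links}
    for node in grn.nodes:
        if node not in targets:
            return node
    raise GRNError("network has no source node; is it acyclic?")


def simulate_observed(
    grn: DirectedGRN,
    spec: SyntheticSpec,
    solver: SolverConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Two-condition expression tables plus the exact Log2FC vector.

    Returns ``(axenic, mixed, exact_log2fc)``: the axenic table holds noisy
    replicates of the baseline steady state (all beta at beta_low), the
    mixed table replicates of the perturbed steady state (perturbed nodes
    at beta_high).  Noise multiplies each entry by ``exp(N(0, noise_sd**2))``.
    """
    perturbed = spec.perturbed_nodes
    if perturbed is None:
        perturbed = (_topo_first_node(grn),)
    unknown = [n for n in perturbed if n not in grn.nodes]
    if unknown:
        raise GRNError(f"perturbed nodes not in network: {unknown}")

    params = ModelParameters.defaults(grn, beta=spec.beta_low)
    ss_axenic = steady_state(grn, params, solver)
    ss_mixed = steady_state(
        grn, params.with_beta({n: spec.beta_high for n in perturbed}), solver
    )
    base_ax = ss_axenic.as_array(grn.nodes)
    base_mx = ss_mixed.as_array(grn.nodes)
    exact = {
        n: math.log2(ss_mixed[n] / ss_axenic[n]) for n in grn.nodes
    }

    rng = np.random.default_rng(spec.seed + 1)
    n, r = len(grn.nodes), spec.replicates
    noise_ax = np.exp(rng.normal(0.0, spec.noise_sd, size=(n, r)))
    noise_mx = np.exp(rng.normal(0.0, spec.noise_sd, size=(n, r)))
    axenic = pd.DataFrame(
        base_ax[:, None] * noise_ax,
        index=grn.nodes,
        columns=[f"axenic_{k + 1}" for k in range(r)],
    )
    mixed = pd.DataFrame(
        base_mx[:, None] * noise_mx,
        index=grn.nodes,
        columns=[f"mixed_{k + 1}" for k in range(r)],
    )
    return axenic, mixed, exact


def average_observations(table: pd.DataFrame, label: str = "averaged") -> ObservedVector:
    """Condense an observations x components matrix into one scaled vector.

    Column means (one per measured component) scaled to max-abs 1 — the
    protocol used to collapse population-resolved single-cell measurements
    into the averaged per-component vector the inference consumes.
    """
    if table.shape[0] < 1:
        raise GRNError("need at least one observation row")
    arr = table.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = [
            (str(table.index[i]), str(table.columns[j]))
            for i in range(table.shape[0])
            for j in range(table.shape[1])
            if not isinstance(table.iat[i, j], (int, float, np.integer, np.floating))
        ]
        raise GRNError(f"non-numeric cells at (row, column): {bad[:5]}")
    if not np.all(np.isfinite(arr)):
        loc = np.argwhere(~np.isfinite(arr))[0]
        raise GRNError(
            f"non-finite value at row {table.index[loc[0]]!r}, "
            f"column {table.columns[loc[1]]!r}"
        )
    means = arr.mean(axis=0)
    scaled = scale_vector(means)
    return ObservedVector(dict(zip(table.columns, scaled.tolist())), label=label)
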