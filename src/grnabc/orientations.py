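"""Exhaustive orientation of undirected networks and perturbation designs.

An undirected network with L edges has 2**L fully directed versions.  Each
is encoded as a bit vector over the edges in input order: bit 1 keeps the
edge's canonical forward direction (first endpoint -> second endpoint),
bit 0 reverses it.  Orientations are streamed in integer order of the bit
vector, never materialized.

Perturbation conditions are the node subsets whose independent activity
beta is switched from a low to a high level; by default all single-node
perturbations, configurable up to all non-empty subsets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

from .grn_model import DirectedGRN, GRNError, Link, UndirectedGRN, _topological_order

__all__ = [
    "Orientation",
    "PerturbationCondition",
    "OrientationSizeError",
    "enumerate_orientations",
    "apply_orientation",
    "orientation_bits",
    "is_acyclic",
    "perturbation_conditions",
]

#: refuse to enumerate beyond this many edges unless explicitly overridden
DEFAULT_EDGE_CAP = 24


class OrientationSizeError(GRNError):
    """Edge count exceeds the enumeration cap."""


@dataclass(frozen=True)
class Orientation:
    """One direction assignment for every edge of an undirected network."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise GRNError("orientation bits must be 0 or 1")

    @property
    def L(self) -> int:
        return len(self.bits)

    @property
    def index(self) -> int:
        """Integer encoding; bit ell is the direction of edge ell."""
        return sum(b << i for i, b in enumerate(self.bits))

    @classmethod
    def from_index(cls, k: int, L: int) -> "Orientation":
        return cls(tuple((k >> i) & 1 for i in range(L)))


@dataclass(frozen=True)
class PerturbationCondition:
    """Node subset whose independent activity is raised beta_low -> beta_high."""

    perturbed: tuple[str, ...]
    beta_low: float = 0.01
    beta_high: float = 0.1

    def __post_init__(self) -> None:
        if not self.perturbed:
            raise GRNError("a perturbation condition needs at least one node")
        if len(set(self.perturbed)) != len(self.perturbed):
            raise GRNError("perturbed nodes must be distinct")
        if not (0 < self.beta_low < self.beta_high):
            raise GRNError(
                f"need beta_high > beta_low > 0, got {self.beta_low}, {self.beta_high}"
            )

    @property
    def label(self) -> str:
        return "+".join(self.perturbed)


def is_acyclic(grn: DirectedGRN) -> bool:
    """True iff the directed network has no directed cycle."""
    return _topological_order(grn) is not None


def apply_orientation(grn: UndirectedGRN, orientation: Orientation) -> DirectedGRN:
    """Direct every edge of ``grn`` according to the orientation bits."""
    if orientation.L != grn.n_edges:
        raise GRNError(
            f"orientation has {orientation.L} bits but network has {grn.n_edges} edges"
        )
    links = []
    for (u, v, sign), bit in zip(grn.edges, orientation.bits):
        links.append(Link(u, v, sign) if bit else Link(v, u, sign))
    return DirectedGRN(grn.nodes, links)


def orientation_bits(grn: UndirectedGRN, directed: DirectedGRN) -> Orientation:
    """Recover the bit vector of a directed version of ``grn``."""
    directed_pairs = {(l.source, l.target) for l in directed.links}
    bits = []
    for u, v, _sign in grn.edges:
        if (u, v) in directed_pairs:
            bits.append(1)
        elif (v, u) in directed_pairs:
            bits.append(0)
        else:
            raise GRNError(f"directed network has no link between {u!r} and {v!r}")
    return Orientation(tuple(bits))


def enumerate_orientations(
    grn: UndirectedGRN,
    acyclic_only: bool = False,
    edge_cap: int = DEFAULT_EDGE_CAP,
) -> Iterator[Orientation]:
    """Stream all 2**L orientations in integer bit-vector order.

    With ``acyclic_only`` the stream is filtered to orientations whose
    directed network is a DAG.  Enumeration refuses to start above
    ``edge_cap`` edges (2**L blows up quickly); raise the cap explicitly
    for larger runs.
    """
    L = grn.n_edges
    if L > edge_cap:
        raise OrientationSizeError(
            f"{L} edges would enumerate 2^{L} orientations; "
            f"raise edge_cap (currently {edge_cap}) to override"
        )
    for k in range(1 << L):
        orientation = Orientation.from_index(k, L)
        if acyclic_only and not is_acyclic(apply_orientation(grn, orientation)):
            continue
        yield orientation


def perturbation_conditions(
    nodes: Sequence[str],
    max_subset_size: int = 1,
    beta_low: float = 0.01,
    beta_high: float = 0.1,
) -> Iterator[PerturbationCondition]:
    """All non-empty node subsets of size <= ``max_subset_size``.

    Ordered by subset size, then lexicographically by position in ``nodes``
    — a deterministic, seedless enumeration.
    """
    n = len(nodes)
    if not 1 <= max_subset_size <= n:
        raise GRNError(
            f"max_subset_size must be in [1, {n}], got {max_subset_size}"
        )
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(nodes, size):
            yield PerturbationCondition(subset, beta_low=beta_low, beta_high=beta_high)
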