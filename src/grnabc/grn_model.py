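"""Signed gene regulatory networks and their steady-state Hill-kinetics model.

Nodes are genes/proteins whose activity :math:`X` evolves as

.. math::

    dY/dt = -\\delta_Y Y + \\Big(\\beta_Y + \\sum_i Act_i(X_i)\\Big)
            \\cdot \\prod_j Inh_j(X_j)

where each incoming activating link contributes a saturating Hill term
``alpha * x**eta / (x**eta + gamma**eta)`` and each inhibiting link a
reciprocal term ``alpha * gamma**eta / (x**eta + gamma**eta)``.  Activations
are summed on top of the node's independent (zero-order) activity ``beta``;
inhibitions multiply the whole production term.  The standard
parametrization is ``beta = 0.01`` and unity for everything else, which
keeps the system non-stiff and its steady state unique in practice.

The steady state is obtained either by exact substitution in topological
order (acyclic networks) or by explicit fixed-step 4th-order Runge-Kutta
integration until the largest time derivative falls below a tolerance.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Sign",
    "Link",
    "UndirectedGRN",
    "DirectedGRN",
    "ModelParameters",
    "ActivityState",
    "SolverConfig",
    "GRNError",
    "ParameterError",
    "ConvergenceError",
    "hill_activation",
    "hill_inhibition",
    "assemble_rhs",
    "steady_state",
]


class GRNError(ValueError):
    """Structural problem with a network, its parameters or its inputs."""


class ParameterError(GRNError):
    """A model parameter is outside its admissible domain."""


class ConvergenceError(RuntimeError):
    """Integration hit the time horizon before the derivative tolerance.

    Carries the last state reached and the residual (max absolute
    derivative) so callers can diagnose or report the failure.
    """

    def __init__(self, message: str, state: "ActivityState", residual: float):
        super().__init__(message)
        self.state = state
        self.residual = residual


class Sign(enum.Enum):
    """Link sign: activating (solid arrow) or inhibiting (dashed arrow)."""

    ACTIVATION = "+"
    INHIBITION = "-"

    @classmethod
    def parse(cls, token: str) -> "Sign":
        token = token.strip()
        for s in cls:
            if token == s.value:
                return s
        if token.lower() in ("activation", "act"):
            return cls.ACTIVATION
        if token.lower() in ("inhibition", "inh"):
            return cls.INHIBITION
        raise GRNError(f"unknown link sign {token!r} (expected '+' or '-')")


@dataclass(frozen=True)
class Link:
    """A directed, signed regulatory interaction ``source -> target``."""

    source: str
    target: str
    sign: Sign

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise GRNError("link endpoints must be non-empty node names")
        if self.source == self.target:
            raise GRNError(f"self-loop on node {self.source!r} is not allowed")


def _check_nodes(nodes: Sequence[str]) -> tuple[str, ...]:
    nodes = tuple(nodes)
    if any(not n for n in nodes):
        raise GRNError("node names must be non-empty")
    if len(set(nodes)) != len(nodes):
        dupes = sorted({n for n in nodes if list(nodes).count(n) > 1})
        raise GRNError(f"duplicate node names: {dupes}")
    return nodes


@dataclass(frozen=True)
class UndirectedGRN:
    """An undirected signed network.

    Edge order is significant: it fixes the canonical "forward" direction of
    every edge (first endpoint -> second endpoint), which is the reference
    for orientation bit vectors and posterior link probabilities.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, Sign], ...]

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str, Sign]]):
        object.__setattr__(self, "nodes", _check_nodes(list(nodes)))
        node_set = set(self.nodes)
        seen_pairs: set[frozenset[str]] = set()
        clean = []
        for u, v, sign in edges:
            if u == v:
                raise GRNError(f"self-loop on node {u!r} is not allowed")
            if u not in node_set or v not in node_set:
                raise GRNError(f"edge ({u!r}, {v!r}) references unknown node")
            pair = frozenset((u, v))
            if pair in seen_pairs:
                raise GRNError(f"duplicate edge between {u!r} and {v!r}")
            seen_pairs.add(pair)
            clean.append((u, v, sign if isinstance(sign, Sign) else Sign.parse(sign)))
        object.__setattr__(self, "edges", tuple(clean))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class DirectedGRN:
    """A fully oriented signed network (one orientation of an UndirectedGRN)."""

    nodes: tuple[str, ...]
    links: tuple[Link, ...]

    def __init__(self, nodes: Iterable[str], links: Iterable[Link]):
        object.__setattr__(self, "nodes", _check_nodes(list(nodes)))
        node_set = set(self.nodes)
        seen_pairs: set[frozenset[str]] = set()
        clean = []
        for link in links:
            if link.source not in node_set or link.target not in node_set:
                raise GRNError(
                    f"link {link.source!r}->{link.target!r} references unknown node"
                )
            pair = frozenset((link.source, link.target))
            if pair in seen_pairs:
                raise GRNError(
                    f"more than one link between {link.source!r} and {link.target!r}"
                )
            seen_pairs.add(pair)
            clean.append(link)
        object.__setattr__(self, "links", tuple(clean))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def undirected(self) -> UndirectedGRN:
        return UndirectedGRN(
            self.nodes, [(l.source, l.target, l.sign) for l in self.links]
        )


#: standard parametrization: unity everywhere except the independent activity
DEFAULT_BETA = 0.01
DEFAULT_DELTA = 1.0
DEFAULT_ALPHA = 1.0
DEFAULT_GAMMA = 1.0
DEFAULT_ETA = 1.0

LinkKey = tuple[str, str]


@dataclass(frozen=True)
class ModelParameters:
    """Per-node (beta, delta) and per-link (alpha, gamma, eta) parameters.

    ``beta`` is the node's independent zero-order activity — the parameter
    the perturbation scheme switches from 0.01 to 0.1.  ``delta`` is the
    first-order decay rate.  ``alpha``, ``gamma`` and ``eta`` scale and
    shape each link's Hill transfer function.  All values are strictly
    positive; link maps are keyed by ``(source, target)``.
    """

    beta: Mapping[str, float]
    delta: Mapping[str, float]
    alpha: Mapping[LinkKey, float]
    gamma: Mapping[LinkKey, float]
    eta: Mapping[LinkKey, float]

    def __post_init__(self) -> None:
        for name, mapping in (
            ("beta", self.beta),
            ("delta", self.delta),
            ("alpha", self.alpha),
            ("gamma", self.gamma),
            ("eta", self.eta),
        ):
            for key, value in mapping.items():
                if not (math.isfinite(value) and value > 0):
                    raise ParameterError(
                        f"{name}[{key!r}] must be finite and > 0, got {value!r}"
                    )

    @classmethod
    def defaults(
        cls,
        grn: DirectedGRN,
        beta: float = DEFAULT_BETA,
        delta: float = DEFAULT_DELTA,
        alpha: float = DEFAULT_ALPHA,
        gamma: float = DEFAULT_GAMMA,
        eta: float = DEFAULT_ETA,
    ) -> "ModelParameters":
        """Standard parametrization for every node and link of ``grn``."""
        keys = [(l.source, l.target) for l in grn.links]
        return cls(
            beta={n: beta for n in grn.nodes},
            delta={n: delta for n in grn.nodes},
            alpha={k: alpha for k in keys},
            gamma={k: gamma for k in keys},
            eta={k: eta for k in keys},
        )

    def with_beta(self, overrides: Mapping[str, float]) -> "ModelParameters":
        """Copy with the independent activity of some nodes replaced."""
        beta = dict(self.beta)
        for node, value in overrides.items():
            if node not in beta:
                raise ParameterError(f"beta override for unknown node {node!r}")
            beta[node] = value
        return replace(self, beta=beta)

    def validate_for(self, grn: DirectedGRN) -> None:
        missing_nodes = [n for n in grn.nodes if n not in self.beta or n not in self.delta]
        if missing_nodes:
            raise ParameterError(f"missing node parameters for {missing_nodes}")
        for link in grn.links:
            key = (link.source, link.target)
            if key not in self.alpha or key not in self.gamma or key not in self.eta:
                raise ParameterError(
                    f"missing link parameters for {link.source}->{link.target}"
                )


@dataclass(frozen=True)
class ActivityState:
    """Non-negative steady-state (or instantaneous) activity per node."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for node, value in self.values.items():
            if not math.isfinite(value) or value < 0:
                raise GRNError(f"activity of {node!r} must be finite and >= 0")

    def as_array(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.values[n] for n in nodes], dtype=float)

    def __getitem__(self, node: str) -> float:
        return self.values[node]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the steady-state computation.

    ``method="auto"`` uses exact topological substitution on acyclic
    networks and fixed-step RK4 otherwise; ``"rk4"`` forces integration,
    ``"topological"`` forces substitution (errors on cycles).
    """

    step: float = 0.01
    tol: float = 1e-9
    t_max: float = 1e4
    method: str = "auto"

    def __post_init__(self) -> None:
        if self.step <= 0 or self.tol <= 0 or self.t_max <= 0:
            raise ParameterError("step, tol and t_max must be positive")
        if self.method not in ("auto", "rk4", "topological"):
            raise ParameterError(f"unknown solver method {self.method!r}")


def _require_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ParameterError(f"{name} must be finite and > 0, got {value!r}")


def hill_activation(x: float, alpha: float, gamma: float, eta: float) -> float:
    """Saturating activation ``alpha * x**eta / (x**eta + gamma**eta)``.

    Monotone increasing from 0 at ``x = 0`` towards the plateau ``alpha``;
    half-maximal at ``x = gamma``; ``eta`` sets the steepness.
    """
    _require_positive("alpha", alpha)
    _require_positive("gamma", gamma)
    _require_positive("eta", eta)
    if not math.isfinite(x) or x < 0:
        raise ParameterError(f"input activity must be finite and >= 0, got {x!r}")
    if x == 0.0:
        return 0.0
    xe = x**eta
    return alpha * xe / (xe + gamma**eta)


def hill_inhibition(x: float, alpha: float, gamma: float, eta: float) -> float:
    """Reciprocal inhibition ``alpha * gamma**eta / (x**eta + gamma**eta)``.

    Monotone decreasing from ``alpha`` at ``x = 0``; half-maximal at
    ``x = gamma``.
    """
    _require_positive("alpha", alpha)
    _require_positive("gamma", gamma)
    _require_positive("eta", eta)
    if not math.isfinite(x) or x < 0:
        raise ParameterError(f"input activity must be finite and >= 0, got {x!r}")
    ge = gamma**eta
    return alpha * ge / (x**eta + ge)


class _Compiled:
    """Index-array form of (network, parameters) for vectorized evaluation."""

    def __init__(self, grn: DirectedGRN, params: ModelParameters):
        params.validate_for(grn)
        self.nodes = grn.nodes
        index = {n: i for i, n in enumerate(grn.nodes)}
        self.beta = np.array([params.beta[n] for n in grn.nodes])
        self.delta = np.array([params.delta[n] for n in grn.nodes])

        act, inh = [], []
        for link in grn.links:
            key = (link.source, link.target)
            row = (
                index[link.source],
                index[link.target],
                params.alpha[key],
                params.gamma[key],
                params.eta[key],
            )
            (act if link.sign is Sign.ACTIVATION else inh).append(row)

        def _arrays(rows):
            if not rows:
                return (
                    np.zeros(0, dtype=int),
                    np.zeros(0, dtype=int),
                    np.zeros(0),
                    np.zeros(0),
                    np.zeros(0),
                )
            src, tgt, alpha, gamma, eta = zip(*rows)
            return (
                np.array(src, dtype=int),
                np.array(tgt, dtype=int),
                np.array(alpha),
                np.array(gamma),
                np.array(eta),
            )

        (self.act_src, self.act_tgt, self.act_alpha, self.act_gamma, self.act_eta) = _arrays(act)
        (self.inh_src, self.inh_tgt, self.inh_alpha, self.inh_gamma, self.inh_eta) = _arrays(inh)
        self.n = len(grn.nodes)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        production = self.beta.copy()
        if self.act_src.size:
            xe = x[self.act_src] ** self.act_eta
            terms = self.act_alpha * xe / (xe + self.act_gamma**self.act_eta)
            np.add.at(production, self.act_tgt, terms)
        if self.inh_src.size:
            ge = self.inh_gamma**self.inh_eta
            factors = self.inh_alpha * ge / (x[self.inh_src] ** self.inh_eta + ge)
            inhibition = np.ones(self.n)
            np.multiply.at(inhibition, self.inh_tgt, factors)
            production = production * inhibition
        return -self.delta * x + production


def assemble_rhs(
    grn: DirectedGRN, params: ModelParameters
) -> Callable[[ActivityState], dict[str, float]]:
    """Build the time-derivative function of the ODE system.

    Returns a callable mapping an :class:`ActivityState` to the per-node
    derivatives ``dX/dt``.  Incoming activations are summed on top of beta;
    incoming inhibitions multiply the summed production term; a node with no
    inputs reduces to the linear source-decay ODE.
    """
    compiled = _Compiled(grn, params)

    def rhs(state: ActivityState) -> dict[str, float]:
        x = state.as_array(compiled.nodes)
        dx = compiled.rhs(x)
        return dict(zip(compiled.nodes, dx.tolist()))

    return rhs


def _topological_order(grn: DirectedGRN) -> list[int] | None:
    """Kahn's algorithm; None if the directed graph has a cycle."""
    index = {n: i for i, n in enumerate(grn.nodes)}
    indegree = [0] * len(grn.nodes)
    out: list[list[int]] = [[] for _ in grn.nodes]
    for link in grn.links:
        s, t = index[link.source], index[link.target]
        out[s].append(t)
        indegree[t] += 1
    queue = [i for i, d in enumerate(indegree) if d == 0]
    order = []
    while queue:
        i = queue.pop()
        order.append(i)
        for j in out[i]:
            indegree[j] -= 1
            if indegree[j] == 0:
                queue.append(j)
    return order if len(order) == len(grn.nodes) else None


def _solve_topological(compiled: _Compiled, order: list[int]) -> np.ndarray:
    x = np.zeros(compiled.n)
    # incoming links grouped per target for scalar substitution
    act_by_tgt: dict[int, list[int]] = {}
    for k, t in enumerate(compiled.act_tgt):
        act_by_tgt.setdefault(int(t), []).append(k)
    inh_by_tgt: dict[int, list[int]] = {}
    for k, t in enumerate(compiled.inh_tgt):
        inh_by_tgt.setdefault(int(t), []).append(k)
    for i in order:
        production = compiled.beta[i]
        for k in act_by_tgt.get(i, ()):
            xs = x[compiled.act_src[k]]
            xe = xs ** compiled.act_eta[k]
            production += compiled.act_alpha[k] * xe / (xe + compiled.act_gamma[k] ** compiled.act_eta[k])
        for k in inh_by_tgt.get(i, ()):
            xs = x[compiled.inh_src[k]]
            ge = compiled.inh_gamma[k] ** compiled.inh_eta[k]
            production *= compiled.inh_alpha[k] * ge / (xs ** compiled.inh_eta[k] + ge)
        x[i] = production / compiled.delta[i]
    return x


def _solve_rk4(
    compiled: _Compiled, config: SolverConfig, nodes: Sequence[str]
) -> np.ndarray:
    h = config.step
    x = compiled.beta / compiled.delta  # no-interaction fixed point
    t = 0.0
    check_every = 10
    n_steps = int(math.ceil(config.t_max / h))
    rhs = compiled.rhs
    for step in range(n_steps):
        k1 = rhs(x)
        k2 = rhs(np.maximum(x + 0.5 * h * k1, 0.0))
        k3 = rhs(np.maximum(x + 0.5 * h * k2, 0.0))
        k4 = rhs(np.maximum(x + h * k3, 0.0))
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        x = np.maximum(x, 0.0)
        t += h
        if step % check_every == 0:
            residual = float(np.max(np.abs(rhs(x))))
            if residual < config.tol:
                return x
    residual = float(np.max(np.abs(rhs(x))))
    if residual < config.tol:
        return x
    state = ActivityState(dict(zip(nodes, np.maximum(x, 0.0).tolist())))
    raise ConvergenceError(
        f"no steady state within t_max={config.t_max}: residual {residual:.3e} "
        f"exceeds tol {config.tol:.1e}",
        state=state,
        residual=residual,
    )


def steady_state(
    grn: DirectedGRN,
    params: ModelParameters | None = None,
    config: SolverConfig | None = None,
) -> ActivityState:
    """Steady-state activity of every node.

    Acyclic networks are solved exactly: in topological order each node's
    fixed point is ``(beta + sum of activations) * product of inhibitions /
    delta``, a pure substitution because upstream activities are already
    settled.  Cyclic networks are integrated with fixed-step RK4 from the
    no-interaction fixed point ``beta/delta`` until the largest absolute
    derivative drops below ``config.tol``; hitting ``t_max`` first raises
    :class:`ConvergenceError` with the last state attached.
    """
    if params is None:
        params = ModelParameters.defaults(grn)
    if config is None:
        config = SolverConfig()
    compiled = _Compiled(grn, params)
    order = _topological_order(grn)
    if config.method == "topological" and order is None:
        raise GRNError("topological solver requested for a cyclic network")
    use_topo = config.method == "topological" or (config.method == "auto" and order is not None)
    if use_topo:
        x = _solve_topological(compiled, order)
    else:
        x = _solve_rk4(compiled, config, grn.nodes)
    x = np.where(x < 0, 0.0, x)
    return ActivityState(dict(zip(grn.nodes, x.tolist())))
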