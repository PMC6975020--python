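"""Naive reference implementation of the whole ABC pipeline.

Direct loops and scalar math only, no streaming, no shared code paths with
the package beyond the domain types: steady states come from a damped
fixed-point iteration (not topological substitution, not RK4), and
enumeration materializes every orientation.  Used as the independent
oracle for candidate-for-candidate equivalence on small fixtures.
"""

from __future__ import annotations

import itertools
import math

from grnabc import Sign, UndirectedGRN


def naive_steady_state(nodes, links, beta, tol=1e-13, max_iter=100_000):
    """Damped fixed-point iteration on x = production(x) / delta."""
    x = {n: beta[n] for n in nodes}  # delta = 1 everywhere
    for _ in range(max_iter):
        new = {}
        for node in nodes:
            production = beta[node]
            for (src, tgt, sign) in links:
                if tgt == node and sign is Sign.ACTIVATION:
                    production += x[src] / (x[src] + 1.0)  # alpha=gamma=eta=1
            for (src, tgt, sign) in links:
                if tgt == node and sign is Sign.INHIBITION:
                    production *= 1.0 / (x[src] + 1.0)
            new[node] = 0.5 * x[node] + 0.5 * production
        shift = max(abs(new[n] - x[n]) for n in nodes)
        x = new
        if shift < tol:
            return x
    raise RuntimeError("naive fixed point did not converge")


def _has_cycle(nodes, links):
    adjacency = {n: [] for n in nodes}
    for src, tgt, _ in links:
        adjacency[src].append(tgt)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in nodes}

    def visit(n):
        color[n] = GRAY
        for m in adjacency[n]:
            if color[m] == GRAY:
                return True
            if color[m] == WHITE and visit(m):
                return True
        color[n] = BLACK
        return False

    return any(color[n] == WHITE and visit(n) for n in nodes)


def naive_run_abc(
    grn: UndirectedGRN,
    observed: dict[str, float],
    top_fraction: float = 0.1,
    max_subset_size: int = 1,
    acyclic_only: bool = False,
    beta_low: float = 0.01,
    beta_high: float = 0.1,
):
    """Returns (accepted, posteriors); accepted items are
    (bits, perturbed subset, distance)."""
    nodes = list(grn.nodes)
    edges = list(grn.edges)

    obs = [observed[n] for n in nodes]
    m = max(abs(v) for v in obs)
    obs = [v / m if m else v for v in obs]

    subsets = []
    for size in range(1, max_subset_size + 1):
        subsets.extend(itertools.combinations(nodes, size))

    candidates = []
    for bits in itertools.product((0, 1), repeat=len(edges)):
        links = [
            (u, v, s) if bit else (v, u, s) for (u, v, s), bit in zip(edges, bits)
        ]
        if acyclic_only and _has_cycle(nodes, links):
            continue
        for perturbed in subsets:
            beta_lo = {n: beta_low for n in nodes}
            beta_hi = dict(beta_lo)
            for p in perturbed:
                beta_hi[p] = beta_high
            ss_lo = naive_steady_state(nodes, links, beta_lo)
            ss_hi = naive_steady_state(nodes, links, beta_hi)
            denom = math.log(beta_high / beta_low)
            eps = [math.log(ss_hi[n] / ss_lo[n]) / denom for n in nodes]
            m = max(abs(v) for v in eps)
            if m:
                eps = [v / m for v in eps]
            dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(eps, obs)))
            candidates.append((bits, perturbed, dist))

    k = math.ceil(len(candidates) * top_fraction / 100.0)
    ranked = sorted(candidates, key=lambda c: c[2])
    cut = ranked[k - 1][2]
    accepted = [c for c in candidates if c[2] <= cut]

    posteriors = {}
    for ell, (u, v, _s) in enumerate(edges):
        forward = sum(1 for bits, _p, _d in accepted if bits[ell] == 1)
        posteriors[(u, v)] = forward / len(accepted)
    return accepted, posteriors
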