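"""Undirected network reconstruction from expression tables.

Links between genes are called where both the Pearson correlation and the
partial correlation (conditioning on all remaining genes) exceed a
stringent threshold in absolute value, |r| >= 0.99 by default.  Partial
correlation prunes indirect links that plain correlation would attribute
to chains of regulation; the sign of the plain correlation is kept as the
link sign (positive -> activation, negative -> inhibition).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .grn_model import GRNError, Sign, UndirectedGRN

__all__ = [
    "ExpressionTable",
    "pearson_correlation_matrix",
    "partial_correlation_matrix",
    "threshold_links",
    "connected_components",
    "log2fc",
    "filter_genes",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Genes x samples abundance matrix (TPM- or LFQ-like, non-negative).

    ``condition_map`` assigns each sample label to an experimental
    condition (e.g. "axenic" / "mixed"); it may cover a subset of samples
    when only some are used for fold changes.
    """

    values: pd.DataFrame
    condition_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise GRNError("an expression table needs at least 2 samples")
        if self.values.isna().any().any():
            raise GRNError("expression table contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise GRNError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise GRNError(f"duplicate gene identifiers: {dupes}")
        unknown = set(self.condition_map) - set(self.values.columns)
        if unknown:
            raise GRNError(f"condition map references unknown samples: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_map.get(s) == condition]


def filter_genes(
    table: ExpressionTable,
    keep: Sequence[str] | None = None,
    pvalues: Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> ExpressionTable:
    """Restrict the table to a pre-computed gene list and/or a p-value cut.

    Differential-expression testing itself happens upstream; this only
    applies its outcome (a gene list, or per-gene p-values thresholded at
    ``alpha``).
    """
    genes = list(table.genes)
    if keep is not None:
        keep_set = set(keep)
        genes = [g for g in genes if g in keep_set]
    if pvalues is not None:
        genes = [g for g in genes if pvalues.get(g, math.inf) <= alpha]
    if not genes:
        raise GRNError("gene filter removed every gene")
    return ExpressionTable(table.values.loc[genes], condition_map=dict(table.condition_map))


def _drop_constant(table: ExpressionTable) -> pd.DataFrame:
    values = table.values
    sd = values.std(axis=1, ddof=1)
    constant = list(values.index[sd == 0])
    if constant:
        log.warning(
            "excluding %d constant gene(s) with undefined correlation: %s",
            len(constant),
            constant,
        )
        values = values.drop(index=constant)
    if values.shape[0] < 2:
        raise GRNError("fewer than 2 non-constant genes; no correlations to compute")
    return values


def pearson_correlation_matrix(table: ExpressionTable) -> pd.DataFrame:
    """Pearson correlation of genes across samples; diagonal exactly 1.

    Constant genes have no defined correlation and are excluded with a
    logged warning.
    """
    values = _drop_constant(table)
    if values.shape[1] < 3:
        log.warning("correlations from %d samples are hardly meaningful", values.shape[1])
    corr = np.corrcoef(values.to_numpy())
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def _shrinkage_intensity(values: np.ndarray) -> float:
    """Analytic shrinkage of the correlation matrix toward the identity.

    The data-driven intensity is the ratio of the summed sampling variances
    of the off-diagonal correlations to their summed squares, clipped to
    [0, 1] — large when correlations are noisy, zero when they are well
    determined.
    """
    p, n = values.shape
    if n < 3:
        return 1.0
    x = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1, keepdims=True)
    # w[k,i,j] = x[i,k] * x[j,k]; moments over samples k
    w_mean = (x @ x.T) / n
    r = w_mean * n / (n - 1)
    w2_mean = (x**2) @ (x.T**2) / n
    var_r = n / (n - 1) ** 3 * (w2_mean - w_mean**2) * n
    off = ~np.eye(p, dtype=bool)
    denom = float(np.sum(r[off] ** 2))
    if denom == 0.0:
        return 0.0
    lam = float(np.sum(var_r[off])) / denom
    return min(1.0, max(0.0, lam))


def partial_correlation_matrix(
    table: ExpressionTable, shrinkage: float | str | None = "auto"
) -> pd.DataFrame:
    """Partial correlations of each gene pair given all remaining genes.

    Computed from the (pseudo-)inverse Omega of the correlation matrix as
    ``-Omega_ij / sqrt(Omega_ii * Omega_jj)``.  With ``shrinkage="auto"``
    the correlation matrix is shrunk toward the identity with the analytic
    data-driven intensity whenever it is rank-deficient or numerically
    singular (fewer samples than genes, exactly collinear genes); a float
    forces that intensity, ``None`` disables shrinkage and falls back to
    the pseudo-inverse.  The applied intensity is logged.
    """
    values = _drop_constant(table)
    p, n = values.shape
    corr = pearson_correlation_matrix(table)
    genes = corr.index
    r = corr.to_numpy()

    if p == 2:  # nothing to condition on
        return corr.copy()

    lam = 0.0
    needs = n - 1 < p or np.linalg.cond(r) > 1e12
    if isinstance(shrinkage, (int, float)):
        lam = float(shrinkage)
    elif shrinkage == "auto" and needs:
        lam = _shrinkage_intensity(values.to_numpy())
    if lam > 0:
        log.info("shrinking correlation matrix toward identity, intensity %.4g", lam)
        r = (1 - lam) * r + lam * np.eye(p)
    try:
        omega = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        log.warning("correlation matrix singular; using pseudo-inverse")
        omega = np.linalg.pinv(r)
    d = np.sqrt(np.abs(np.diag(omega)))
    pcor = -omega / np.outer(d, d)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pcor, 1.0)
    return pd.DataFrame(pcor, index=genes, columns=genes)


def threshold_links(
    cor: pd.DataFrame, pcor: pd.DataFrame, r_threshold: float = 0.99
) -> UndirectedGRN:
    """Call a link where |correlation| and |partial correlation| both pass.

    The link sign follows the plain correlation: positive -> activation,
    negative -> inhibition.  Edge canonical order follows gene order in the
    matrix, so the output is independent of how ties are stored.
    """
    if list(cor.index) != list(pcor.index):
        raise GRNError("correlation and partial-correlation matrices are not aligned")
    genes = list(cor.index)
    edges = []
    c = cor.to_numpy()
    pc = pcor.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if abs(c[i, j]) >= r_threshold and abs(pc[i, j]) >= r_threshold:
                sign = Sign.ACTIVATION if c[i, j] > 0 else Sign.INHIBITION
                edges.append((genes[i], genes[j], sign))
    return UndirectedGRN(genes, edges)


def connected_components(grn: UndirectedGRN) -> list[UndirectedGRN]:
    """Standalone subnetworks, largest first; isolated nodes are dropped."""
    g = nx.Graph()
    g.add_nodes_from(grn.nodes)
    g.add_edges_from((u, v) for u, v, _ in grn.edges)
    comps = [c for c in nx.connected_components(g) if len(c) > 1]
    out = []
    for comp in comps:
        nodes = [n for n in grn.nodes if n in comp]
        edges = [(u, v, s) for u, v, s in grn.edges if u in comp]
        out.append(UndirectedGRN(nodes, edges))
    out.sort(key=lambda c: (-c.n_nodes, c.nodes[0]))
    return out


def log2fc(
    table: ExpressionTable,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.0,
) -> dict[str, float]:
    """Per-gene log2 fold change of condition_b over condition_a means.

    ``log2((mean_b + pseudocount) / (mean_a + pseudocount))``.  The default
    pseudocount of 0 makes a zero mean a hard error rather than silently
    distorting the ratio; pass a positive pseudocount to allow zeros.
    """
    samples_a = table.samples_for(condition_a)
    samples_b = table.samples_for(condition_b)
    if not samples_a:
        raise GRNError(f"condition {condition_a!r} has no samples")
    if not samples_b:
        raise GRNError(f"condition {condition_b!r} has no samples")
    mean_a = table.values[samples_a].mean(axis=1)
    mean_b = table.values[samples_b].mean(axis=1)
    out = {}
    for gene in table.genes:
        a = mean_a[gene] + pseudocount
        b = mean_b[gene] + pseudocount
        if a <= 0 or b <= 0:
            raise GRNError(
                f"gene {gene!r} has a zero condition mean; "
                "set a positive pseudocount to compute its fold change"
            )
        out[gene] = math.log2(b / a)
    return out
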