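"""Readers and writers for the plain-text formats binding the stages.

Edge lists are TSV with one edge per line, ``source<TAB>target<TAB>sign``,
sign ``+`` (activation) or ``-`` (inhibition); a header line is detected by
its third column not being a sign token.  Observed vectors are two-column
TSV ``node<TAB>value``.  Expression tables are TSV/CSV with gene ids in the
first column and sample labels in the header.  Parsing is strict: malformed
lines fail with their line number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .abc_rejection import ABCConfig, ABCResult
from .grn_model import DirectedGRN, GRNError, Link, Sign, SolverConfig, UndirectedGRN
from .sensitivity import ObservedVector
from .undirected import ExpressionTable

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_directed_edge_list",
    "write_directed_edge_list",
    "read_observed",
    "write_observed",
    "read_expression_table",
    "write_expression_table",
    "read_condition_map",
    "read_single_cell_csv",
    "write_abc_result",
    "write_dot",
    "RunConfig",
]

_SIGN_TOKENS = {"+", "-", "activation", "inhibition", "act", "inh"}


def _parse_edge_lines(path: str | Path) -> list[tuple[int, str, str, Sign]]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GRNError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            u, v, sign_token = (p.strip() for p in parts)
            if lineno == 1 and sign_token.lower() not in _SIGN_TOKENS:
                continue  # header line
            try:
                sign = Sign.parse(sign_token)
            except GRNError as err:
                raise GRNError(f"{path}:{lineno}: {err}") from None
            rows.append((lineno, u, v, sign))
    if not rows:
        raise GRNError(f"{path}: no edges found")
    return rows


def read_edge_list(path: str | Path) -> UndirectedGRN:
    """Read an undirected signed network; node order is first appearance."""
    rows = _parse_edge_lines(path)
    nodes: list[str] = []
    seen_pairs: dict[frozenset, int] = {}
    edges = []
    for lineno, u, v, sign in rows:
        if u == v:
            raise GRNError(f"{path}:{lineno}: self-loop on {u!r}")
        pair = frozenset((u, v))
        if pair in seen_pairs:
            raise GRNError(
                f"{path}:{lineno}: duplicate edge between {u!r} and {v!r} "
                f"(first at line {seen_pairs[pair]})"
            )
        seen_pairs[pair] = lineno
        for n in (u, v):
            if n not in nodes:
                nodes.append(n)
        edges.append((u, v, sign))
    return UndirectedGRN(nodes, edges)


def write_edge_list(grn: UndirectedGRN, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsign\n")
        for u, v, sign in grn.edges:
            fh.write(f"{u}\t{v}\t{sign.value}\n")


def read_directed_edge_list(path: str | Path) -> DirectedGRN:
    """Read a directed network: each line's direction is source -> target."""
    rows = _parse_edge_lines(path)
    nodes: list[str] = []
    links = []
    for lineno, u, v, sign in rows:
        try:
            link = Link(u, v, sign)
        except GRNError as err:
            raise GRNError(f"{path}:{lineno}: {err}") from None
        for n in (u, v):
            if n not in nodes:
                nodes.append(n)
        links.append(link)
    try:
        return DirectedGRN(nodes, links)
    except GRNError as err:
        raise GRNError(f"{path}: {err}") from None


def write_directed_edge_list(grn: DirectedGRN, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsign\n")
        for link in grn.links:
            fh.write(f"{link.source}\t{link.target}\t{link.sign.value}\n")


def read_observed(path: str | Path, label: str | None = None) -> ObservedVector:
    """Read a two-column ``node<TAB>value`` TSV and scale it to max-abs 1."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GRNError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            node, token = parts[0].strip(), parts[1].strip()
            if lineno == 1:
                try:
                    float(token)
                except ValueError:
                    continue  # header line
            if node in values:
                raise GRNError(f"{path}:{lineno}: duplicate node {node!r}")
            try:
                values[node] = float(token)
            except ValueError:
                raise GRNError(f"{path}:{lineno}: not a number: {token!r}") from None
    if not values:
        raise GRNError(f"{path}: no values found")
    return ObservedVector.from_raw(values, label=label or Path(path).stem)


def write_observed(values: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tvalue\n")
        for node, value in values.items():
            fh.write(f"{node}\t{value:.10g}\n")


def read_expression_table(
    path: str | Path, condition_map: Mapping[str, str] | None = None
) -> ExpressionTable:
    """Read a genes x samples TSV/CSV (delimiter chosen by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.shape[1] < 2:
        raise GRNError(f"{path}: expected at least 2 sample columns")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise GRNError(f"{path}: non-numeric sample columns {non_numeric}")
    return ExpressionTable(df, condition_map=dict(condition_map or {}))


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    table.values.to_csv(path, sep=sep, index_label="gene")


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Sample -> condition mapping from YAML or a two-column TSV."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml", ".json")):
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise GRNError(f"{path}: expected a mapping of sample -> condition")
        return {str(k): str(v) for k, v in data.items()}
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise GRNError(f"{path}:{lineno}: expected 2 tab-separated columns")
        if lineno == 1 and parts[0].strip().lower() in ("sample", "samples"):
            continue
        mapping[parts[0].strip()] = parts[1].strip()
    if not mapping:
        raise GRNError(f"{path}: no sample conditions found")
    return mapping


def read_single_cell_csv(path: str | Path) -> pd.DataFrame:
    """Observations x components CSV with a header row of component names."""
    df = pd.read_csv(path)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise GRNError(f"{path}: empty table")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise GRNError(f"{path}: non-numeric component columns {non_numeric}")
    return df


def _majority_direction(
    grn: UndirectedGRN, posteriors: Mapping[tuple[str, str], float]
) -> list[tuple[str, str, Sign, float]]:
    """Each edge in its majority direction with that direction's posterior."""
    rows = []
    for u, v, sign in grn.edges:
        p = posteriors[(u, v)]
        if p >= 0.5:
            rows.append((u, v, sign, p))
        else:
            rows.append((v, u, sign, 1.0 - p))
    return rows


def write_abc_result(
    result: ABCResult,
    grn: UndirectedGRN,
    json_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Write the full JSON result and a majority-direction TSV summary.

    The JSON carries full provenance (config echo, counts, realized
    threshold) so a run can be regenerated exactly from it plus the inputs.
    """
    config = dataclasses.asdict(result.config)
    payload = {
        "config": config,
        "total_candidates": result.total_candidates,
        "acceptance_threshold": result.acceptance_threshold,
        "acceptance_fraction_pct": result.acceptance_fraction,
        "diagnostics": dict(result.diagnostics),
        "link_posteriors": [
            {"source": u, "target": v, "sign": sign.value,
             "posterior_forward": result.link_posteriors[(u, v)]}
            for u, v, sign in grn.edges
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("source\ttarget\tsign\tposterior\n")
            for u, v, sign, p in _majority_direction(grn, result.link_posteriors):
                fh.write(f"{u}\t{v}\t{sign.value}\t{p:.6f}\n")


def write_dot(
    grn: UndirectedGRN,
    posteriors: Mapping[tuple[str, str], float],
    path: str | Path,
) -> None:
    """Graphviz export: solid edges for activation, dashed for inhibition."""
    lines = ["digraph grn {"]
    for u, v, sign, p in _majority_direction(grn, posteriors):
        style = "solid" if sign is Sign.ACTIVATION else "dashed"
        lines.append(f'  "{u}" -> "{v}" [style={style}, label="{100 * p:.1f}%"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline run (YAML round-trippable)."""

    solver_step: float = 0.01
    solver_tol: float = 1e-9
    solver_t_max: float = 1e4
    beta_low: float = 0.01
    beta_high: float = 0.1
    max_subset_size: int = 1
    acyclic_only: bool = False
    r_threshold: float = 0.99
    top_fraction: float | None = 0.1
    distance_threshold: float | None = None
    pseudocount: float = 0.0
    seed: int = 0

    def abc_config(self) -> ABCConfig:
        return ABCConfig(
            beta_low=self.beta_low,
            beta_high=self.beta_high,
            max_subset_size=self.max_subset_size,
            acyclic_only=self.acyclic_only,
            top_fraction=self.top_fraction,
            distance_threshold=self.distance_threshold,
            solver=SolverConfig(
                step=self.solver_step, tol=self.solver_tol, t_max=self.solver_t_max
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise GRNError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)
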