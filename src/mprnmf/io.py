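"""Readers, writers and the run configuration.

All external formats are plain text: TSV for expression matrices, edge
lists, pair lists and predictions; GMT as an alternative annotation input;
YAML for the flat run configuration; JSON for reports and metadata.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import EntityNetwork, ExpressionMatrix, ParseError, ValidationError

logger = logging.getLogger("mprnmf")

DEFAULT_K_GRID = tuple(range(40, 65, 4))
DEFAULT_ALPHA_GRID = tuple(round(0.1 + 0.2 * i, 10) for i in range(10))
DEFAULT_THRESHOLD_GRID = tuple(round(0.01 * i, 10) for i in range(101))


@dataclass
class RunConfig:
    """Flat parameter record for a reproducible run.

    ``k`` is the factorization rank (number of latent function groups),
    ``alpha`` the shared weight of the per-view coupling regularizers.
    Defaults for ``iterations``, ``k_grid`` and the alpha sweep follow the
    method's published protocol (100 rounds; k from 40 to 64 in steps of 4;
    alpha from 0.1 to 2 in steps of 0.2).
    """

    k: int = 52
    alpha: float = 1.0
    iterations: int = 100
    seed: int = 0
    coexpr_threshold: float = 0.5
    view_list: tuple[str, ...] = ("expression", "disease")
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    tau: int = 10
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    use_absolute_correlation: bool = False
    log_transform_expression: bool = False
    update_variant: str = "standard"
    scale_scores: bool = True
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be a positive integer")
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not 0 <= self.coexpr_threshold <= 1:
            raise ValidationError("coexpr_threshold must lie in [0, 1]")
        if len(set(self.view_list)) != len(self.view_list):
            raise ValidationError("view names must be unique")
        grid = tuple(self.threshold_grid)
        if any(t < 0 or t > 1 for t in grid):
            raise ValidationError("threshold_grid values must lie in [0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("threshold_grid must be strictly increasing")
        if any(k < 1 for k in self.k_grid):
            raise ValidationError("k_grid entries must be positive")
        if self.tau < 1:
            raise ValidationError("tau must be positive")
        if self.update_variant not in ("standard", "sqrt"):
            raise ValidationError("update_variant must be 'standard' or 'sqrt'")

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields replaced (CLI-flag semantics)."""
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key-value YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("view_list", "threshold_grid", "k_grid", "alpha_grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {}
    for name in RunConfig.__dataclass_fields__:
        value = getattr(config, name)
        if isinstance(value, tuple):
            value = list(value)
        data[name] = value
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix: header of sample IDs, first column IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate entity IDs {dupes}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric value {raw!r} at row {ids[i]!r}, "
                    f"column {col!r}"
                ) from None
    return ExpressionMatrix(ids=ids, samples=[str(c) for c in df.columns], values=values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.ids, columns=expr.samples)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> EntityNetwork:
    """Read a TSV edge list ``idA idB [weight]`` into an undirected network.

    Duplicate pairs in either orientation keep the maximum weight; self-loops
    are dropped with a warning; a missing weight column means 1.0.
    """
    ids: list[str] = []
    index: dict[str, int] = {}
    edges: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns")
            a, b = parts[0].strip(), parts[1].strip()
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
            else:
                w = 1.0
            if w < 0:
                raise ValidationError(f"{path}:{lineno}: negative weight {w}")
            for node in (a, b):
                if node not in index:
                    index[node] = len(ids)
                    ids.append(node)
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            i, j = sorted((index[a], index[b]))
            edges[(i, j)] = max(edges.get((i, j), 0.0), w)
    W = np.zeros((len(ids), len(ids)))
    for (i, j), w in edges.items():
        W[i, j] = W[j, i] = w
    return EntityNetwork(ids=ids, W=W)


def write_edge_list(net: EntityNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(net.n):
            for j in range(i + 1, net.n):
                if net.W[i, j] > 0:
                    fh.write(f"{net.ids[i]}\t{net.ids[j]}\t{net.W[i, j]:.10g}\n")


# ---------------------------------------------------------------------------
# Pair lists (disease links, annotations)
# ---------------------------------------------------------------------------

def read_pair_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV into a deduplicated (entity, label) pair list.

    First-seen order is preserved so downstream matrix construction has a
    deterministic index map.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            pair = (parts[0].strip(), parts[1].strip())
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    return pairs


def write_pair_list(pairs: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> list[tuple[str, str]]:
    """Read GMT annotation sets as (entity, term) pairs.

    Set name = term; the description column is ignored; members = entities.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT rows need >= 3 columns")
            term = parts[0].strip()
            for member in parts[2:]:
                member = member.strip()
                if member and (member, term) not in seen:
                    seen.add((member, term))
                    pairs.append((member, term))
    return pairs


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(
    scores: list[tuple[str, str, float]], path: str | Path
) -> None:
    """Write ranked (lncRNA, GO term, score) records, best first."""
    for lnc, term, s in scores:
        if not math.isfinite(s):
            raise ValidationError(f"non-finite score for ({lnc}, {term}): {s}")
    ranked = sorted(scores, key=lambda rec: -rec[2])
    with open(path, "w") as fh:
        fh.write("lncRNA\tGO_term\tscore\n")
        for lnc, term, s in ranked:
            fh.write(f"{lnc}\t{term}\t{s:.6g}\n")


def read_predictions(path: str | Path) -> list[tuple[str, str, float]]:
    records: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("lncRNA"):
            raise ParseError(f"{path}: missing predictions header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            records.append((parts[0], parts[1], float(parts[2])))
    return records
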