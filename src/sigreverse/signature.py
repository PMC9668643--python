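"""Disease query-signature extraction.

A disease signature is the ordered pair of "tag" gene lists used to query a
perturbagen compendium: the top-N genes up-regulated in disease (descending
log2 fold change) and the top-N down-regulated (ascending log2 fold
change), after filtering on adjusted p-value and an absolute fold-change
threshold. Defaults mirror the standard workflow: adjusted p < 0.05,
|log2FC| >= 1, N = 100 per direction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError, ParseError, SignatureError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureParams:
    """Thresholds controlling signature extraction."""

    adj_p_max: float = 0.05
    lfc_min: float = 1.0
    top_n: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.adj_p_max < 1:
            raise ConfigurationError(f"adj_p_max must be in (0,1): {self.adj_p_max}")
        if self.lfc_min < 0:
            raise ConfigurationError(f"lfc_min must be >= 0: {self.lfc_min}")
        if self.top_n < 1:
            raise ConfigurationError(f"top_n must be >= 1: {self.top_n}")


@dataclass
class DiseaseSignature:
    """Ordered up- and down-regulated tag gene lists.

    ``up_tags`` are ordered by descending log2FC (strongest up-regulation
    first); ``down_tags`` by ascending log2FC (strongest down-regulation
    first). The two lists are disjoint and duplicate-free.
    """

    up_tags: list[str] = field(default_factory=list)
    down_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.up_tags)) != len(self.up_tags):
            raise SignatureError("duplicate genes in up_tags")
        if len(set(self.down_tags)) != len(self.down_tags):
            raise SignatureError("duplicate genes in down_tags")
        overlap = set(self.up_tags) & set(self.down_tags)
        if overlap:
            raise SignatureError(f"genes in both directions: {sorted(overlap)[:5]}")


def _select_direction(
    table: pd.DataFrame, params: SignatureParams, direction: str
) -> list[str]:
    passing = table[table["adj_pvalue"] < params.adj_p_max]
    if direction == "up":
        passing = passing[passing["log2fc"] >= params.lfc_min]
        ordered = passing.sort_values(
            ["log2fc", "adj_pvalue", "gene_id"], ascending=[False, True, True]
        )
    else:
        passing = passing[passing["log2fc"] <= -params.lfc_min]
        ordered = passing.sort_values(
            ["log2fc", "adj_pvalue", "gene_id"], ascending=[True, True, True]
        )
    genes = ordered["gene_id"].tolist()
    if not genes:
        raise SignatureError(f"no gene passes the filters in direction {direction!r}")
    if len(genes) < params.top_n:
        log.warning(
            "only %d genes pass in direction %s (requested top %d)",
            len(genes),
            direction,
            params.top_n,
        )
    return genes[: params.top_n]


def extract_signature(
    table: pd.DataFrame, params: SignatureParams | None = None
) -> DiseaseSignature:
    """Filter a differential-expression table and cut the top-N per direction.

    Genes qualify upward when ``adj_pvalue < adj_p_max`` and
    ``log2fc >= lfc_min`` (downward: ``log2fc <= -lfc_min``); each
    direction is ranked by log2 fold change (p-value, then gene ID break
    ties) and truncated to ``top_n``. Fewer than ``top_n`` passing genes
    yields a shorter list with a warning; zero passing genes in a
    direction raises :class:`SignatureError`.
    """
    params = params or SignatureParams()
    if table.empty:
        raise SignatureError("empty differential-expression table")
    return DiseaseSignature(
        up_tags=_select_direction(table, params, "up"),
        down_tags=_select_direction(table, params, "down"),
    )


def write_signature(signature: DiseaseSignature, path: str | Path) -> None:
    """Write a two-column TSV (gene_id, direction), preserving tag order."""
    with open(path, "w") as fh:
        for gene in signature.up_tags:
            fh.write(f"{gene}\tup\n")
        for gene in signature.down_tags:
            fh.write(f"{gene}\tdown\n")


def read_signature(path: str | Path) -> DiseaseSignature:
    """Read the TSV written by :func:`write_signature` (direction tokens are
    case-insensitive)."""
    up: list[str] = []
    down: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            gene, direction = parts[0], parts[1].strip().lower()
            if direction == "up":
                up.append(gene)
            elif direction == "down":
                down.append(gene)
            else:
                raise ParseError(
                    f"{path}:{lineno}: direction must be up/down, got {parts[1]!r}"
                )
    return DiseaseSignature(up_tags=up, down_tags=down)


def write_signature_gmt(
    signature: DiseaseSignature, path: str | Path, name: str = "QUERY"
) -> None:
    """Export the signature as a paired two-line GMT (<name>_UP, <name>_DN)
    for interoperability with connectivity-map style query tools."""
    with open(path, "w") as fh:
        fh.write("\t".join([f"{name}_UP", "up-regulated tags"] + signature.up_tags))
        fh.write("\n")
        fh.write("\t".join([f"{name}_DN", "down-regulated tags"] + signature.down_tags))
        fh.write("\n")
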