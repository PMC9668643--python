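"""Pre-ranked gene-set enrichment (GSEA-Preranked semantics).

Genes are ranked by a signed metric (default: the moderated t-statistic of
the differential-expression stage, which folds both significance and fold
change into one number). For each gene set the weighted running-sum
enrichment score (exponent 1) is computed: walking down the ranked list,
hits increment the sum by |metric|/Σ_hits|metric| and misses decrement it by
1/(N − N_hits); ES is the signed maximum deviation from zero. Significance
comes from a gene-set permutation null: random same-size sets drawn from the
ranked universe, NES = ES / mean(|null ES| of matching sign), p by the
plus-one estimator over same-sign null scores.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError, ParseError

log = logging.getLogger(__name__)

RESULT_COLUMNS = ("set_name", "es", "nes", "pvalue", "n_hits")


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (unique names, non-empty sets)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise InputError(f"gene set {name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, tab-separated set name, description, genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 gene"
                )
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = parts[2:]
            descriptions[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + list(members)) + "\n")


def rank_genes(
    dge_table: pd.DataFrame, metric: str = "tstat"
) -> pd.Series:
    """Build a ranked list (metric descending, ties by gene ID) from a
    differential-expression table.

    ``metric`` is ``"tstat"`` (default, the signed moderated t) or
    ``"log2fc"``.
    """
    if metric not in ("tstat", "log2fc"):
        raise InputError(f"unknown ranking metric {metric!r}")
    tbl = dge_table[["gene_id", metric]].copy()
    if tbl["gene_id"].duplicated().any():
        raise InputError("duplicate gene IDs in differential-expression table")
    if not np.isfinite(tbl[metric]).all():
        raise InputError("ranking metric contains non-finite values")
    tbl = tbl.sort_values([metric, "gene_id"], ascending=[False, True])
    return pd.Series(tbl[metric].to_numpy(), index=tbl["gene_id"].to_numpy())


def _es_from_hits(
    pos: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Weighted running-sum ES from sorted 1-based hit positions and their
    |metric| weights; vectorized over leading axes.

    The running sum only changes at hits (up by w/W) and between them
    (down by 1/(N−t) per miss), so its extremes occur just before or just
    after a hit — those 2t candidate values are evaluated directly.
    """
    pos = np.asarray(pos, dtype=float)
    w = np.asarray(weights, dtype=float)
    t = pos.shape[-1]
    if t == n:  # no misses: the sum climbs monotonically to exactly 1
        return np.ones(pos.shape[:-1]) if pos.ndim > 1 else np.float64(1.0)
    W = w.sum(axis=-1, keepdims=True)
    # all-zero weights would make hit increments 0/0; fall back to equal steps
    zero = W == 0
    if np.any(zero):
        w = np.where(np.broadcast_to(zero, w.shape), 1.0, w)
        W = w.sum(axis=-1, keepdims=True)
    cum = np.cumsum(w, axis=-1) / W
    j = np.arange(1, t + 1, dtype=float)
    miss = (pos - j) / (n - t)  # misses seen before/at the j-th hit
    after = cum - miss
    before = after - w / W
    pos_ext = np.maximum(after.max(axis=-1), 0.0)
    neg_ext = np.minimum(before.min(axis=-1), 0.0)
    return np.where(pos_ext >= -neg_ext, pos_ext, neg_ext)


def preranked_es(ranked: pd.Series, gene_set) -> float:
    """Enrichment score of one gene set in a ranked list, in [−1, 1].

    Raises
    ------
    InputError
        If the set has no overlap with the ranked universe.
    """
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ranked.index), bool, len(ranked))
    if not mask.any():
        raise InputError("gene set has no overlap with the ranked list")
    pos = np.nonzero(mask)[0] + 1
    weights = np.abs(ranked.to_numpy()[mask])
    return float(_es_from_hits(pos, weights, len(ranked)))


def preranked_gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene-set collection.

    Per set: ES as in :func:`preranked_es`; a null of ``n_perm`` random
    same-size gene sets; NES = ES / mean(|null| of matching sign); p the
    plus-one fraction of same-sign null scores at least as extreme. Sets
    with no overlap are skipped with a warning. Records are sorted by NES
    descending.
    """
    if n_perm < 100:
        raise InputError(f"n_perm must be >= 100, got {n_perm}")
    if len(collection) == 0:
        raise InputError("empty gene-set collection")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    absmetric = np.abs(ranked.to_numpy())
    index = pd.Index(ranked.index)

    rows = []
    for name, members in collection:
        idx = index.get_indexer(list(members))
        idx = idx[idx >= 0]
        if idx.size == 0:
            log.warning("gene set %s has no overlap with the ranking; skipped", name)
            continue
        t = idx.size
        pos = np.sort(idx) + 1
        es = float(_es_from_hits(pos, absmetric[np.sort(idx)], n))
        if t == n:
            rows.append((name, es, 1.0, 1.0 / (n_perm + 1), t))
            continue
        null_pos = np.argpartition(rng.random((n_perm, n)), t - 1, axis=1)[:, :t]
        null_pos.sort(axis=1)
        null = _es_from_hits(null_pos + 1, absmetric[null_pos], n)
        if es > 0:
            same = null[null > 0]
        elif es < 0:
            same = -null[null < 0]
        else:
            rows.append((name, 0.0, 0.0, 1.0, t))
            continue
        if same.size == 0:
            log.warning("set %s: no same-sign null scores; NES undefined", name)
            rows.append((name, es, np.nan, 1.0, t))
            continue
        nes = es / same.mean() if es > 0 else -abs(es) / same.mean()
        p = (1 + int(np.count_nonzero(same >= abs(es)))) / (same.size + 1)
        rows.append((name, es, nes, p, t))

    records = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    return records.sort_values(
        "nes", ascending=False, na_position="last"
    ).reset_index(drop=True)
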