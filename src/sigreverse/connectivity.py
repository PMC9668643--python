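"""Connectivity scoring of a disease signature against a perturbagen compendium.

This is a local reimplementation of the connectivity-map query: for every
perturbagen (a drug whose transcriptional effect is stored as a full ranking
of the gene universe, rank 1 = most up-regulated by the drug) the query's up-
and down-tags are scored by a Kolmogorov–Smirnov enrichment statistic against
the ranking, combined into a bidirectional raw connectivity in [−1, 1], and
normalized to a signed percentile τ in [−100, +100] against the perturbagen's
stored reference-query ("touchstone") scores. A strongly negative τ means the
drug's profile reverses the disease signature — the repurposing candidates of
interest — while a strongly positive τ marks a mimic.

KS enrichment uses the classic tag-set construction: with sorted hit ranks
r(1) < … < r(t) in a profile of n genes,

    a = max_i [ i/t − r(i)/n ],   b = max_i [ r(i)/n − (i−1)/t ],
    ES = a if a >= b else −b,

and the bidirectional raw score is (ES_up − ES_down)/2, set to 0 when both
directions agree in sign.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import bh_adjust
from .exceptions import ConfigurationError, InputError
from .signature import DiseaseSignature

log = logging.getLogger(__name__)

#: minimum number of stored reference scores accepted for a tau computation
MIN_REFERENCE_SCORES = 20
#: warn when a query direction retains fewer matched tags than this
MIN_TAGS_WARN = 10

RESULT_COLUMNS = (
    "perturbagen_id",
    "es_up",
    "es_down",
    "raw_score",
    "tau",
    "pvalue",
    "fdr",
    "rank",
)


@dataclass
class PerturbagenProfile:
    """A single perturbagen: an identifier plus a full gene ranking
    (position 0 of ``ranking`` holds the gene most up-regulated by the drug)."""

    perturbagen_id: str
    ranking: np.ndarray  # array of gene-ID strings, a permutation of the universe

    def __post_init__(self) -> None:
        self.ranking = np.asarray(self.ranking)
        if len(np.unique(self.ranking)) != len(self.ranking):
            raise InputError(
                f"profile {self.perturbagen_id}: ranking contains duplicate genes"
            )


@dataclass
class PerturbagenCompendium:
    """A collection of perturbagen rankings over a shared gene universe.

    ``rankings[p, j]`` is the index (into ``universe``) of the gene at rank
    j+1 of perturbagen p. ``reference_scores[p]`` holds the cached raw
    connectivity scores of stored reference queries against perturbagen p,
    used for τ percentile normalization.
    """

    universe: np.ndarray  # gene-ID strings
    perturbagen_ids: list[str]
    rankings: np.ndarray  # int array (n_perturbagens, n_genes)
    reference_scores: np.ndarray | None = None  # (n_perturbagens, n_ref)

    def __post_init__(self) -> None:
        self.universe = np.asarray(self.universe)
        self.rankings = np.asarray(self.rankings)
        n = len(self.universe)
        if self.rankings.ndim != 2 or self.rankings.shape[1] != n:
            raise InputError("rankings must be (n_perturbagens, n_genes)")
        if self.rankings.shape[0] != len(self.perturbagen_ids):
            raise InputError("one ranking per perturbagen ID required")
        if len(set(self.perturbagen_ids)) != len(self.perturbagen_ids):
            raise InputError("duplicate perturbagen IDs")
        # each row must be a permutation of 0..n-1
        if not (np.sort(self.rankings, axis=1) == np.arange(n)).all():
            raise InputError("every ranking must be a permutation of the universe")
        if self.reference_scores is not None:
            self.reference_scores = np.asarray(self.reference_scores, dtype=float)
            if self.reference_scores.shape[0] != self.rankings.shape[0]:
                raise InputError("one reference-score row per perturbagen required")

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def n_perturbagens(self) -> int:
        return self.rankings.shape[0]

    def profile(self, i: int) -> PerturbagenProfile:
        return PerturbagenProfile(
            self.perturbagen_ids[i], self.universe[self.rankings[i]]
        )

    def inverse_ranks(self) -> np.ndarray:
        """1-based position of every universe gene in every profile,
        shape (n_perturbagens, n_genes)."""
        inv = np.empty_like(self.rankings)
        rows = np.arange(self.n_perturbagens)[:, None]
        inv[rows, self.rankings] = np.arange(1, self.n_genes + 1)
        return inv


def _es_from_sorted_positions(pos: np.ndarray, n: int) -> np.ndarray:
    """KS enrichment score from sorted 1-based hit positions.

    ``pos`` has the hit positions along the last axis, strictly increasing;
    broadcasting over leading axes gives vectorized scoring. Ties between
    the positive and negative deviation resolve to the positive branch.
    """
    pos = np.asarray(pos, dtype=float)
    t = pos.shape[-1]
    i = np.arange(1, t + 1, dtype=float)
    a = np.max(i / t - pos / n, axis=-1)
    b = np.max(pos / n - (i - 1) / t, axis=-1)
    return np.where(a >= b, a, -b)


def _match_tags(tags, universe_index: pd.Index, label: str = "tags") -> np.ndarray:
    """Indices of tags in the universe; drops unmatched tags with a warning,
    errors when nothing matches."""
    tags = list(tags)
    idx = universe_index.get_indexer(tags)
    missing = [t for t, j in zip(tags, idx) if j < 0]
    if missing:
        log.warning("%d %s not in universe (dropped): %s", len(missing), label,
                    missing[:5])
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise InputError(f"no {label} found in the profile universe: {missing[:10]}")
    if idx.size < MIN_TAGS_WARN:
        log.warning("only %d matched %s (< %d)", idx.size, label, MIN_TAGS_WARN)
    return idx


def ks_enrichment(tags, profile: PerturbagenProfile) -> float:
    """KS enrichment of a tag gene set in a perturbagen's ranking, in [−1, 1].

    Positive when the tags concentrate near the top of the ranking (the
    drug up-regulates them), negative near the bottom.
    """
    index = pd.Index(profile.ranking)
    idx = _match_tags(tags, index, "tags")
    pos = np.sort(idx + 1)  # 1-based ranks
    return float(_es_from_sorted_positions(pos, len(profile.ranking)))


def raw_connectivity(
    signature: DiseaseSignature, profile: PerturbagenProfile
) -> tuple[float, float, float]:
    """Bidirectional raw connectivity of a query signature with one profile.

    Returns ``(es_up, es_down, raw_score)`` where ``raw_score`` is
    ``(es_up − es_down)/2`` and 0 when both enrichment scores share a
    strict sign (the null convention of the connectivity map).
    """
    es_up = ks_enrichment(signature.up_tags, profile)
    es_down = ks_enrichment(signature.down_tags, profile)
    return es_up, es_down, float(_combine(es_up, es_down))


def _combine(es_up, es_down):
    """Same-sign null rule + bidirectional combination; works on arrays."""
    same_sign = np.sign(es_up) == np.sign(es_down)
    strict = (es_up != 0) & (es_down != 0)
    raw = (np.asarray(es_up) - np.asarray(es_down)) / 2.0
    return np.where(same_sign & strict, 0.0, raw)


def tau_normalize(raw_score: float, reference_scores) -> float:
    """Signed percentile of |raw_score| against stored reference scores.

    τ = sign(raw) × 100 × #{reference r : |r| < |raw|} / n_ref, hence in
    [−100, 100]; τ = 0 when raw_score = 0. Requires at least
    ``MIN_REFERENCE_SCORES`` stored scores.
    """
    refs = np.asarray(reference_scores, dtype=float)
    if refs.size < MIN_REFERENCE_SCORES:
        raise ConfigurationError(
            f"tau needs >= {MIN_REFERENCE_SCORES} reference scores, got {refs.size}"
        )
    if raw_score == 0:
        return 0.0
    frac = np.count_nonzero(np.abs(refs) < abs(raw_score)) / refs.size
    return float(np.sign(raw_score) * 100.0 * frac)


def _random_query_scores(
    n_genes: int, t_up: int, t_down: int, n_perm: int, rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """Raw connectivity scores of random disjoint same-size queries against a
    fixed profile.

    The hit positions of a uniformly random tag set in any fixed permutation
    are a uniformly random subset of ranks, so the profile itself is not
    needed — only the universe size and tag sizes.
    """
    if t_up + t_down > n_genes:
        raise InputError("tag sizes exceed the universe")
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        r = rng.random((m, n_genes))
        take = np.argpartition(r, t_up + t_down - 1, axis=1)[:, : t_up + t_down]
        pos_up = np.sort(take[:, :t_up], axis=1) + 1.0
        pos_dn = np.sort(take[:, t_up:], axis=1) + 1.0
        es_up = _es_from_sorted_positions(pos_up, n_genes)
        es_dn = _es_from_sorted_positions(pos_dn, n_genes)
        out[done : done + m] = _combine(es_up, es_dn)
        done += m
    return out


def permutation_pvalue(
    signature: DiseaseSignature,
    profile: PerturbagenProfile,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for one query/profile pair.

    Draws ``n_perm`` random signatures with the query's tag-list sizes
    (tags sampled uniformly without replacement from the universe) and
    reports the plus-one estimator
    ``(1 + #{|raw_perm| >= |raw|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise InputError(f"n_perm must be >= 100, got {n_perm}")
    _, _, raw = raw_connectivity(signature, profile)
    index = pd.Index(profile.ranking)
    t_up = _match_tags(signature.up_tags, index, "up-tags").size
    t_dn = _match_tags(signature.down_tags, index, "down-tags").size
    rng = np.random.default_rng(seed)
    null = _random_query_scores(len(profile.ranking), t_up, t_dn, n_perm, rng)
    return (1 + int(np.count_nonzero(np.abs(null) >= abs(raw)))) / (n_perm + 1)


def score_compendium(
    signature: DiseaseSignature,
    compendium: PerturbagenCompendium,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every perturbagen and rank by τ ascending (best reverser first).

    Returns a DataFrame with one row per perturbagen and columns
    ``perturbagen_id, es_up, es_down, raw_score, tau, pvalue, fdr, rank``.
    The permutation null is shared across perturbagens: for fixed universe
    and tag sizes the null raw-score distribution does not depend on the
    particular profile permutation, so one pool of ``n_perm`` random-query
    scores serves all of them. FDR is Benjamini–Hochberg over all
    perturbagen p-values; ties in τ break by raw score ascending, then by
    perturbagen ID.
    """
    if compendium.n_perturbagens == 0:
        raise InputError("empty compendium")
    if compendium.reference_scores is None:
        raise ConfigurationError("compendium carries no reference scores for tau")
    index = pd.Index(compendium.universe)
    up_idx = _match_tags(signature.up_tags, index, "up-tags")
    dn_idx = _match_tags(signature.down_tags, index, "down-tags")

    inv = compendium.inverse_ranks()
    pos_up = np.sort(inv[:, up_idx], axis=1)
    pos_dn = np.sort(inv[:, dn_idx], axis=1)
    es_up = _es_from_sorted_positions(pos_up, compendium.n_genes)
    es_dn = _es_from_sorted_positions(pos_dn, compendium.n_genes)
    raw = _combine(es_up, es_dn)

    rng = np.random.default_rng(seed)
    null = np.abs(
        _random_query_scores(
            compendium.n_genes, up_idx.size, dn_idx.size, n_perm, rng
        )
    )
    null.sort()
    # number of null scores >= |raw| via binary search on the sorted pool
    n_ge = n_perm - np.searchsorted(null, np.abs(raw), side="left")
    pvals = (1 + n_ge) / (n_perm + 1)

    taus = np.array(
        [
            tau_normalize(raw[i], compendium.reference_scores[i])
            for i in range(compendium.n_perturbagens)
        ]
    )
    records = pd.DataFrame(
        {
            "perturbagen_id": compendium.perturbagen_ids,
            "es_up": es_up,
            "es_down": es_dn,
            "raw_score": raw,
            "tau": taus,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        }
    )
    records = records.sort_values(
        ["tau", "raw_score", "perturbagen_id"], ascending=True
    ).reset_index(drop=True)
    records["rank"] = np.arange(1, len(records) + 1)
    return records


def truncate_candidates(records: pd.DataFrame, k: int = 150) -> pd.DataFrame:
    """Keep the first min(k, len) records of a ranked result table."""
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    return records.head(min(k, len(records))).reset_index(drop=True)
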