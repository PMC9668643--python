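"""Synthetic inputs with planted ground truth.

Generates everything the real pipeline would obtain from public resources:
a two-group log2-scale expression matrix with a planted subset of truly
up/down-regulated genes (emulating case/control skin-biopsy microarray
series at desk scale), a perturbagen compendium of full gene rankings with
planted reversers and mimics of a given query signature (emulating a
connectivity-map compendium), and a collection of gene sets with one
positive-control set enriched in the planted up-regulated genes (emulating
the 50 hallmark pathway sets).

Everything is a pure function of (config, seed): each generator derives its
own RNG stream from the config seed, so generators are independently
reproducible and can recompute each other's planted gene choices.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import PerturbagenCompendium, _combine, _es_from_sorted_positions
from .dge import ExpressionMatrix
from .exceptions import ConfigurationError, InputError
from .enrichment import GeneSetCollection
from .signature import DiseaseSignature

log = logging.getLogger(__name__)

# per-generator RNG stream keys (mixed with config.seed in a SeedSequence)
_KEY_PLANT = 17
_KEY_EXPR = 23
_KEY_COMP = 29
_KEY_SETS = 43

#: baseline log2 intensity distribution for simulated probes
BASELINE_MEAN = 8.0
BASELINE_SD = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults are desk scale: 5,000 genes, 20+20 samples, 500 perturbagens
    (the real series have tens of samples per group and 10⁴–10⁵ probes).
    ``effect_size`` is the log2-units mean shift of planted genes in the
    disease group; ``noise_sd`` the per-gene Gaussian standard deviation;
    ``profile_noise`` the fraction of adjacent-transposition swaps applied
    to each perturbagen ranking.
    """

    n_genes: int = 5000
    n_control: int = 20
    n_disease: int = 20
    n_up_planted: int = 150
    n_down_planted: int = 150
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_perturbagens: int = 500
    n_reversers: int = 10
    n_mimics: int = 10
    profile_noise: float = 0.02
    n_gene_sets: int = 50
    genes_per_set: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_genes >= 1, "n_genes >= 1"),
            (self.n_control >= 1, "n_control >= 1"),
            (self.n_disease >= 1, "n_disease >= 1"),
            (self.n_up_planted >= 0, "n_up_planted >= 0"),
            (self.n_down_planted >= 0, "n_down_planted >= 0"),
            (
                self.n_up_planted + self.n_down_planted <= self.n_genes,
                "n_up_planted + n_down_planted <= n_genes",
            ),
            (self.noise_sd > 0, "noise_sd > 0"),
            (self.n_perturbagens >= 0, "n_perturbagens >= 0"),
            (
                self.n_reversers + self.n_mimics <= self.n_perturbagens,
                "n_reversers + n_mimics <= n_perturbagens",
            ),
            (0 <= self.profile_noise <= 1, "0 <= profile_noise <= 1"),
            (self.n_gene_sets >= 0, "n_gene_sets >= 0"),
            (
                self.genes_per_set <= self.n_genes,
                "genes_per_set <= n_genes",
            ),
            (self.genes_per_set >= 1, "genes_per_set >= 1"),
        ]
        for ok, constraint in checks:
            if not ok:
                raise ConfigurationError(f"violated constraint: {constraint}")


def gene_universe(config: SimulationConfig) -> np.ndarray:
    """Synthetic gene identifiers G000001 … G<n_genes> (unique, uppercase)."""
    width = max(6, len(str(config.n_genes)))
    return np.array([f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)])


def _rng(config: SimulationConfig, key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, key])


def planted_genes(config: SimulationConfig) -> pd.DataFrame:
    """Planted-truth table: gene_id and true direction ('up'/'down').

    Planted positions are drawn from a dedicated seeded stream so every
    generator recovers the same choice.
    """
    rng = _rng(config, _KEY_PLANT)
    n_plant = config.n_up_planted + config.n_down_planted
    genes = gene_universe(config)
    chosen = rng.choice(config.n_genes, size=n_plant, replace=False)
    directions = ["up"] * config.n_up_planted + ["down"] * config.n_down_planted
    return pd.DataFrame({"gene_id": genes[chosen], "direction": directions})


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a two-group log2-scale expression matrix.

    Per-gene baselines are Gaussian around typical microarray log2
    intensities; every value adds Gaussian noise with sd ``noise_sd``;
    planted up (down) genes get their disease-group mean shifted by
    +effect_size (−effect_size). Returns the matrix and the planted-truth
    table.
    """
    rng = _rng(config, _KEY_EXPR)
    genes = gene_universe(config)
    truth = planted_genes(config)
    n_samples = config.n_control + config.n_disease
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, config.n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, (config.n_genes, n_samples)
    )

    gene_pos = pd.Index(genes).get_indexer(truth["gene_id"])
    disease_cols = slice(config.n_control, n_samples)
    up_pos = gene_pos[(truth["direction"] == "up").to_numpy()]
    down_pos = gene_pos[(truth["direction"] == "down").to_numpy()]
    values[up_pos, disease_cols] += config.effect_size
    values[down_pos, disease_cols] -= config.effect_size

    sample_ids = [f"normal_{i:02d}" for i in range(1, config.n_control + 1)] + [
        f"disease_{i:02d}" for i in range(1, config.n_disease + 1)
    ]
    groups = pd.Series(
        ["normal"] * config.n_control + ["disease"] * config.n_disease,
        index=sample_ids,
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids), groups
    )
    return matrix, truth


def _apply_profile_noise(
    rankings: np.ndarray, fraction: float, rng: np.random.Generator
) -> None:
    """Perturb each ranking in place with round(fraction × n_genes) random
    adjacent transpositions (swap of positions j, j+1)."""
    n = rankings.shape[1]
    n_swaps = int(round(fraction * n))
    if n_swaps == 0 or n < 2:
        return
    for row in rankings:
        sites = rng.integers(0, n - 1, n_swaps)
        for j in sites:
            row[j], row[j + 1] = row[j + 1], row[j]


def generate_compendium(
    config: SimulationConfig,
    signature: DiseaseSignature,
    n_ref: int = 100,
) -> tuple[PerturbagenCompendium, pd.DataFrame]:
    """Simulate a perturbagen compendium with planted reversers and mimics.

    Reversers place the query's up-tags at the bottom of their ranking and
    down-tags at the top (so the drug counteracts the signature); mimics
    the opposite; the remaining perturbagens are uniform random
    permutations. ``profile_noise`` then applies that fraction of random
    adjacent swaps per profile. Reference ("touchstone") scores for τ are
    cached per perturbagen by scoring ``n_ref`` random queries with the
    signature's tag sizes. Returns the compendium and a truth table
    (perturbagen_id, role ∈ {reverser, mimic, null}).
    """
    rng = _rng(config, _KEY_COMP)
    genes = gene_universe(config)
    index = pd.Index(genes)
    up_idx = index.get_indexer(signature.up_tags)
    dn_idx = index.get_indexer(signature.down_tags)
    missing = [
        t
        for t, j in zip(list(signature.up_tags) + list(signature.down_tags),
                        list(up_idx) + list(dn_idx))
        if j < 0
    ]
    if missing:
        raise InputError(f"signature genes not in universe: {missing[:10]}")

    n, p = config.n_genes, config.n_perturbagens
    width = max(4, len(str(p)))
    ids = [f"D{i:0{width}d}" for i in range(1, p + 1)]
    roles = np.array(["null"] * p, dtype=object)
    special = rng.choice(p, size=config.n_reversers + config.n_mimics, replace=False)
    roles[special[: config.n_reversers]] = "reverser"
    roles[special[config.n_reversers :]] = "mimic"

    tag_idx = np.concatenate([up_idx, dn_idx])
    rest = np.setdiff1d(np.arange(n), tag_idx)
    rankings = np.empty((p, n), dtype=np.int64)
    for i in range(p):
        if roles[i] == "null":
            rankings[i] = rng.permutation(n)
        else:
            middle = rng.permutation(rest)
            if roles[i] == "reverser":
                rankings[i] = np.concatenate([dn_idx, middle, up_idx])
            else:
                rankings[i] = np.concatenate([up_idx, middle, dn_idx])
    _apply_profile_noise(rankings, config.profile_noise, rng)

    compendium = PerturbagenCompendium(
        universe=genes, perturbagen_ids=ids, rankings=rankings
    )
    compendium.reference_scores = _reference_scores(
        compendium, len(up_idx), len(dn_idx), n_ref, rng
    )
    truth = pd.DataFrame({"perturbagen_id": ids, "role": roles})
    return compendium, truth


def _reference_scores(
    compendium: PerturbagenCompendium,
    t_up: int,
    t_down: int,
    n_ref: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw connectivity of ``n_ref`` random reference queries against every
    perturbagen — the stored touchstone used for τ percentiles."""
    n = compendium.n_genes
    inv = compendium.inverse_ranks()
    scores = np.empty((compendium.n_perturbagens, n_ref))
    for r in range(n_ref):
        q = rng.choice(n, size=t_up + t_down, replace=False)
        pos_up = np.sort(inv[:, q[:t_up]], axis=1)
        pos_dn = np.sort(inv[:, q[t_up:]], axis=1)
        es_up = _es_from_sorted_positions(pos_up, n)
        es_dn = _es_from_sorted_positions(pos_dn, n)
        scores[:, r] = _combine(es_up, es_dn)
    return scores


def generate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """Simulate a gene-set collection (hallmark-like: 50 sets by default).

    Sets are sampled without replacement within each set. When genes are
    planted, the first set (``SET_PLANTED_UP``) is built from the planted
    up-regulated genes (padded with random others if needed) as a
    positive control for downstream enrichment.
    """
    rng = _rng(config, _KEY_SETS)
    genes = gene_universe(config)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}

    n_random = config.n_gene_sets
    if config.n_up_planted > 0 and config.n_gene_sets > 0:
        planted_up = planted_genes(config).query("direction == 'up'")["gene_id"]
        core = planted_up.tolist()[: config.genes_per_set]
        if len(core) < config.genes_per_set:
            pool = np.setdiff1d(genes, np.array(core))
            pad = rng.choice(pool, config.genes_per_set - len(core), replace=False)
            core = core + pad.tolist()
        sets["SET_PLANTED_UP"] = core
        descriptions["SET_PLANTED_UP"] = "positive control: planted up genes"
        n_random -= 1

    for i in range(1, n_random + 1):
        name = f"SET_{i:04d}"
        members = rng.choice(genes, config.genes_per_set, replace=False)
        assert len(set(members)) == config.genes_per_set
        sets[name] = members.tolist()
        descriptions[name] = "random synthetic set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
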