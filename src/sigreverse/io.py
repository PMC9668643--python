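"""File I/O, validation-annotation summary, and pipeline orchestration.

File dialects: matrices and compendia are tab-separated, report tables
comma-separated, UTF-8, "." decimal. Every report written by the pipeline
carries a header comment line with the seed and a hash of the run
configuration so outputs are traceable to their run.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .connectivity import (
    PerturbagenCompendium,
    score_compendium,
    truncate_candidates,
)
from .dge import ExpressionMatrix, auto_log_check, differential_expression
from .enrichment import preranked_gsea, rank_genes, read_gmt
from .exceptions import (
    ConfigurationError,
    InputError,
    ParseError,
    SigReverseError,
)
from .signature import DiseaseSignature, SignatureParams, extract_signature

log = logging.getLogger(__name__)

#: accepted (case-insensitive) sample group labels → canonical group
GROUP_SYNONYMS = {"normal": "normal", "disease": "disease", "psoriasis": "disease"}

VALIDATION_STATUSES = ("validated", "contradicted", "untested")


# ---------------------------------------------------------------------------
# expression matrix + metadata

def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the matrix as TSV (first column gene ID) and a sample-metadata
    TSV with columns sample_id, group."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": [matrix.groups[s] for s in matrix.sample_ids]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_expression(
    matrix_path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """Read and validate a matrix TSV plus its sample-metadata TSV.

    Group labels are case-insensitive; "Psoriasis" maps to disease. Errors
    carry row/column coordinates where applicable.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{matrix_path}: duplicate gene IDs: {dup[:5]}")
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"{matrix_path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        if coerced.isna().any():
            gene = raw.index[coerced.isna().to_numpy()][0]
            raise ParseError(
                f"{matrix_path}: missing value at gene {gene!r}, sample {col!r}"
            )
        raw[col] = coerced

    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    if not {"sample_id", "group"} <= set(meta.columns):
        raise ParseError(f"{metadata_path}: need columns sample_id, group")
    groups = {}
    for _, row in meta.iterrows():
        label = str(row["group"]).strip().lower()
        if label not in GROUP_SYNONYMS:
            raise ParseError(
                f"{metadata_path}: unknown group {row['group']!r} "
                f"for sample {row['sample_id']!r}"
            )
        groups[str(row["sample_id"])] = GROUP_SYNONYMS[label]
    extra = [s for s in groups if s not in raw.columns]
    if extra:
        raise InputError(f"metadata samples absent from the matrix: {extra}")
    missing = [s for s in raw.columns if s not in groups]
    if missing:
        raise InputError(f"matrix samples missing from metadata: {missing}")
    return ExpressionMatrix(raw, pd.Series(groups))


# ---------------------------------------------------------------------------
# compendium

def write_compendium(
    compendium: PerturbagenCompendium,
    profiles_path: str | Path,
    references_path: str | Path | None = None,
) -> None:
    """Write profiles as TSV (one row per perturbagen: ID then the full gene
    ranking) and, optionally, the cached reference scores as a long CSV."""
    with open(profiles_path, "w") as fh:
        for i, pid in enumerate(compendium.perturbagen_ids):
            genes = compendium.universe[compendium.rankings[i]]
            fh.write(pid + "\t" + "\t".join(genes) + "\n")
    if references_path is not None:
        if compendium.reference_scores is None:
            raise InputError("compendium has no reference scores to write")
        n_ref = compendium.reference_scores.shape[1]
        frame = pd.DataFrame(
            {
                "perturbagen_id": np.repeat(compendium.perturbagen_ids, n_ref),
                "ref_index": np.tile(np.arange(n_ref), compendium.n_perturbagens),
                "raw_score": compendium.reference_scores.ravel(),
            }
        )
        frame.to_csv(references_path, index=False)


def read_compendium(
    profiles_path: str | Path, references_path: str | Path | None = None
) -> PerturbagenCompendium:
    ids: list[str] = []
    rows: list[list[str]] = []
    with open(profiles_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{profiles_path}:{lineno}: need ID plus ranking")
            ids.append(parts[0])
            rows.append(parts[1:])
    if not rows:
        raise ParseError(f"{profiles_path}: empty compendium file")
    universe = np.array(sorted(rows[0]))
    index = pd.Index(universe)
    rankings = np.empty((len(rows), len(universe)), dtype=np.int64)
    for i, row in enumerate(rows):
        if len(row) != len(universe):
            raise ParseError(
                f"{profiles_path}: profile {ids[i]} has {len(row)} genes, "
                f"expected {len(universe)}"
            )
        idx = index.get_indexer(row)
        if (idx < 0).any():
            bad = [g for g, j in zip(row, idx) if j < 0][:5]
            raise ParseError(f"{profiles_path}: profile {ids[i]}: unknown genes {bad}")
        rankings[i] = idx
    refs = None
    if references_path is not None:
        frame = pd.read_csv(references_path, comment="#")
        pivot = frame.pivot(index="perturbagen_id", columns="ref_index", values="raw_score")
        missing = [p for p in ids if p not in pivot.index]
        if missing:
            raise ParseError(f"{references_path}: no reference scores for {missing[:5]}")
        refs = pivot.loc[ids].to_numpy()
    return PerturbagenCompendium(
        universe=universe, perturbagen_ids=ids, rankings=rankings,
        reference_scores=refs,
    )


# ---------------------------------------------------------------------------
# report tables with traceable headers

def write_report(
    frame: pd.DataFrame, path: str | Path, seed: int, config_hash: str
) -> None:
    """Write a CSV report prefixed by a comment header with seed and config
    hash."""
    with open(path, "w") as fh:
        fh.write(f"# sigreverse v{__version__} seed={seed} config={config_hash}\n")
        frame.to_csv(fh, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# validation annotation (the literature-confirmation decision rule)

@dataclass
class ValidationSummary:
    """Counts of candidate drugs by annotation status.

    A candidate with support and no denial is *validated*; with both
    support and denial *contradicted* (excluded from the validated count);
    otherwise (including drugs absent from the annotation) *untested*.
    """

    n_candidates: int
    n_validated: int
    n_contradicted: int
    n_untested: int
    status: pd.DataFrame = field(repr=False)  # perturbagen_id, status

    @property
    def n_unvalidated(self) -> int:
        return self.n_untested

    @property
    def label(self) -> str:
        """The headline ratio, e.g. ``"50/150"``."""
        return f"{self.n_validated}/{self.n_candidates}"


def read_annotation(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    need = {"drug_id", "supported", "denied"}
    if not need <= set(frame.columns):
        raise ParseError(f"{path}: need columns drug_id, supported, denied")
    for col in ("supported", "denied"):
        vals = set(pd.unique(frame[col]))
        if not vals <= {0, 1}:
            raise ParseError(f"{path}: column {col} must be 0/1, got {sorted(vals)[:5]}")
    return frame


def annotate_validation(
    records: pd.DataFrame, annotation: pd.DataFrame
) -> ValidationSummary:
    """Join ranked candidates with a drug-annotation table and count statuses."""
    ann = annotation.set_index("drug_id")
    statuses = []
    for pid in records["perturbagen_id"]:
        if pid not in ann.index:
            statuses.append("untested")
            continue
        row = ann.loc[pid]
        if int(row["supported"]) == 1 and int(row["denied"]) == 1:
            statuses.append("contradicted")
        elif int(row["supported"]) == 1:
            statuses.append("validated")
        else:
            statuses.append("untested")
    status = pd.DataFrame(
        {"perturbagen_id": records["perturbagen_id"].to_numpy(), "status": statuses}
    )
    counts = status["status"].value_counts()
    return ValidationSummary(
        n_candidates=len(status),
        n_validated=int(counts.get("validated", 0)),
        n_contradicted=int(counts.get("contradicted", 0)),
        n_untested=int(counts.get("untested", 0)),
        status=status,
    )


# ---------------------------------------------------------------------------
# pipeline orchestration

@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    matrix_path: str
    metadata_path: str
    compendium_path: str
    references_path: str
    gene_sets_path: str
    output_dir: str
    annotation_path: str | None = None
    signature_params: SignatureParams = field(default_factory=SignatureParams)
    mode: str = "moderated"
    n_perm: int = 1000
    top_k: int = 150
    seed: int = 0

    def config_hash(self) -> str:
        # output_dir is excluded: the hash identifies the analysis, not
        # where its results land
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return digest[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sig = data.pop("signature_params", None)
        if sig is not None:
            data["signature_params"] = SignatureParams(**sig)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline and write all stage outputs plus a manifest.

    Stages: log-scale check → differential expression → signature
    extraction → compendium connectivity scoring → candidate truncation →
    pre-ranked GSEA → optional validation-annotation summary. Rerunning
    with identical config and inputs is byte-identical.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    for name in ("matrix_path", "metadata_path", "compendium_path",
                 "references_path", "gene_sets_path"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise ConfigurationError(f"{name} does not exist: {path}")
    if config.annotation_path is not None and not Path(config.annotation_path).exists():
        raise ConfigurationError(
            f"annotation_path does not exist: {config.annotation_path}"
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except SigReverseError as exc:
            raise type(exc)(f"stage {name}: {exc}") from exc

    matrix = stage("read_expression", read_expression,
                   config.matrix_path, config.metadata_path)
    matrix = stage("auto_log_check", auto_log_check, matrix)
    dge_table = stage("differential_expression", differential_expression,
                      matrix, config.mode)
    write_report(dge_table, out / "dge.csv", seed, chash)

    sig = stage("extract_signature", extract_signature,
                dge_table, config.signature_params)
    sig_frame = pd.DataFrame(
        {
            "gene_id": list(sig.up_tags) + list(sig.down_tags),
            "direction": ["up"] * len(sig.up_tags) + ["down"] * len(sig.down_tags),
        }
    )
    write_report(sig_frame, out / "signature.csv", seed, chash)

    compendium = stage("read_compendium", read_compendium,
                       config.compendium_path, config.references_path)
    records = stage("score_compendium", score_compendium,
                    sig, compendium, config.n_perm, seed)
    write_report(records, out / "connectivity.csv", seed, chash)
    candidates = stage("truncate_candidates", truncate_candidates,
                       records, config.top_k)
    write_report(candidates, out / "candidates.csv", seed, chash)

    collection = stage("read_gmt", read_gmt, config.gene_sets_path)
    ranked = stage("rank_genes", rank_genes, dge_table)
    gsea = stage("preranked_gsea", preranked_gsea,
                 ranked, collection, config.n_perm, seed)
    write_report(gsea, out / "gsea.csv", seed, chash)

    summary = None
    if config.annotation_path is not None:
        annotation = stage("read_annotation", read_annotation, config.annotation_path)
        summary = stage("annotate_validation", annotate_validation,
                        candidates, annotation)
        write_report(summary.status, out / "validation.csv", seed, chash)

    manifest = {
        "package_version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "config_hash": chash,
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "n_genes": len(dge_table),
            "n_up_tags": len(sig.up_tags),
            "n_down_tags": len(sig.down_tags),
            "n_perturbagens": compendium.n_perturbagens,
            "n_candidates": len(candidates),
            "n_gene_sets_tested": len(gsea),
        },
    }
    if summary is not None:
        manifest["validation"] = {
            "n_validated": summary.n_validated,
            "n_contradicted": summary.n_contradicted,
            "n_untested": summary.n_untested,
            "label": summary.label,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
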