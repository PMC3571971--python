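"""Pipeline orchestration: configuration, staged execution, run manifest.

The pipeline wires the analysis stages in dependency order over
standard-format inputs (per-gene FASTA alignments, a Newick tree, TSV
intensity and metadata tables): expression categorization, alignment
filtering, the rapid-evolution screen, bootstrap category contrasts, and
enrichment statistics, emitting TSV summaries and a JSON manifest with
per-file checksums so deterministic stages can be verified and skipped on
re-runs. Every stochastic stage consumes an explicit seed recorded in the
manifest; excluded genes are logged with their exclusion reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import CodonAlignment
from .alignprep import GeneExcludedError, filter_complete_codon_columns
from .categorystats import bootstrap_category_rates, compare_rate_distributions, enrichment_table
from .expression import (
    absolute_expression,
    categorize_genes,
    normalize_arrays,
    posterior_relative_expression,
)
from .screen import screen_genes, tabulate_rapid_by_category
from .trees import read_tree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    alignments_dir: str
    tree_file: str
    intensity_table: str
    metadata: str | None = None
    out_dir: str = "results"
    alpha: float = 0.05
    q_screen: float = 0.05
    q_sexual: float = 0.10
    beb_threshold: float = 0.95
    bootstrap_reps: int = 100
    genes_per_rep: int = 10
    seed: int = 1
    freq_model: str = "F3x4"
    site_classes: int = 10
    scopes: list[str] = field(default_factory=lambda: ["global"])

    def validate(self) -> None:
        for name in ("alpha", "q_screen", "q_sexual", "beb_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.bootstrap_reps < 1 or self.genes_per_rep < 1:
            raise ValueError("bootstrap settings must be positive")
        for path in (self.alignments_dir, self.tree_file, self.intensity_table):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        if self.metadata and not Path(self.metadata).exists():
            raise FileNotFoundError(self.metadata)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def record(self, path: Path) -> None:
        self.outputs[path.name] = _checksum(path)

    def write(self, path: Path) -> None:
        payload = asdict(self)
        payload["finished"] = time.time()
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_alignments(alignments_dir: str | Path) -> list[CodonAlignment]:
    paths = sorted(Path(alignments_dir).glob("*.fasta")) + sorted(
        Path(alignments_dir).glob("*.fa")
    )
    if not paths:
        raise FileNotFoundError(f"no FASTA files under {alignments_dir}")
    return [CodonAlignment.read_fasta(p) for p in paths]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in dependency order; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.content_hash(), __version__, config.seed)

    def emit(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest.record(path)
        return path

    # ---- expression stage
    intensities = pd.read_csv(config.intensity_table, sep="\t")
    ratios = normalize_arrays(intensities)
    posteriors = posterior_relative_expression(ratios)
    assignments = categorize_genes(posteriors, alpha=config.alpha, q_sexual=config.q_sexual)
    expr_abs = absolute_expression(intensities, assignments)
    emit(posteriors, "expression_posteriors.tsv")
    emit(assignments.table, "gene_categories.tsv")
    emit(expr_abs, "absolute_expression.tsv")
    manifest.stages.append("expression")

    # ---- alignment preparation
    tree = read_tree(config.tree_file)
    raw = load_alignments(config.alignments_dir)
    alignments, excluded = [], []
    for aln in raw:
        try:
            alignments.append(filter_complete_codon_columns(aln))
        except GeneExcludedError as e:
            logger.warning("excluded %s: %s", aln.gene_id, e)
            excluded.append({"gene_id": aln.gene_id, "reason": str(e)})
    if excluded:
        emit(pd.DataFrame(excluded), "excluded_genes.tsv")
    if not alignments:
        raise RuntimeError("alignprep: every gene was excluded")
    manifest.stages.append("alignprep")

    # ---- rapid-evolution screen
    results = screen_genes(
        alignments, tree, scopes=list(config.scopes),
        alpha_q=config.q_screen, freqs=config.freq_model, seed=config.seed,
    )
    screen_df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "scope": r.scope, "omega_free": r.omega_free,
                "omega_mean": r.omega_fixed_mean, "lnL_free": r.lnL_free,
                "lnL_fixed": r.lnL_fixed, "p": r.p_value, "q": r.q_value,
                "rapid": r.rapid, "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
    emit(screen_df, "screen_results.tsv")
    emit(tabulate_rapid_by_category(results, assignments), "rapid_by_category.tsv")
    manifest.stages.append("screen")

    # ---- bootstrap category contrasts
    cat_map = dict(zip(assignments.table["gene_id"], assignments.table["category"]))
    by_cat: dict[str, list[str]] = {}
    aln_map = {a.gene_id: a for a in alignments}
    for gid in aln_map:
        by_cat.setdefault(cat_map.get(gid, "n/a"), []).append(gid)
    reps_by_cat = {}
    for cat, gids in by_cat.items():
        if cat == "n/a" or len(gids) < config.genes_per_rep:
            continue
        reps_by_cat[cat] = bootstrap_category_rates(
            cat, gids, aln_map, tree,
            n_reps=config.bootstrap_reps, genes_per_rep=config.genes_per_rep,
            seed=config.seed, freqs=config.freq_model,
        )
    if reps_by_cat:
        rep_rows = [
            {"category": r.category, "replicate": r.index,
             "scope": s, "dN": v[0], "dS": v[1], "omega": v[2]}
            for reps in reps_by_cat.values() for r in reps for s, v in r.rates.items()
        ]
        emit(pd.DataFrame(rep_rows), "bootstrap_replicates.tsv")
        if len(reps_by_cat) >= 2:
            emit(compare_rate_distributions(reps_by_cat), "category_contrasts.tsv")
    manifest.stages.append("bootstrap")

    # ---- enrichment
    if config.metadata:
        meta = pd.read_csv(config.metadata, sep="\t")
        if "phylo_class" in meta.columns:
            # the measured category comes from the expression stage; a
            # simulation-truth 'category' column in the metadata is ignored
            merged = meta.drop(columns=["category"], errors="ignore").merge(
                assignments.table, on="gene_id", how="inner"
            )
            merged = merged[merged["category"] != "n/a"]
            counts = pd.crosstab(merged["phylo_class"], merged["category"])
            if counts.size and (counts.sum(axis=0) > 0).all():
                emit(enrichment_table(counts), "enrichment.tsv")
        manifest.stages.append("enrichment")

    report = out / "report.txt"
    n_rapid = int(screen_df[screen_df["rapid"] == True].groupby("gene_id").ngroups)  # noqa: E712
    report.write_text(
        "\n".join(
            [
                f"omegascreen {__version__} run (seed={config.seed})",
                f"genes analyzed: {len(alignments)} (excluded: {len(excluded)})",
                f"categories: " + ", ".join(
                    f"{c}={len(g)}" for c, g in sorted(by_cat.items())
                ),
                f"rapidly evolving genes (any scope): {n_rapid}",
                f"stages: {', '.join(manifest.stages)}",
            ]
        )
        + "\n"
    )
    manifest.record(report)
    manifest.write(out / "manifest.json")
    return manifest
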