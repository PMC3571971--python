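"""Synthetic data with the statistical structure the pipeline assumes.

Two generators cover the study design end to end without any external data:

* codon alignments evolved on a given phylogeny under configurable selection
  regimes (single omega, branch-specific omegas, or a site mixture), using
  the same substitution model the inference engine fits — the simulator and
  the estimator share only the rate-matrix definition, not the fitting code;
* four-array dye-swap two-channel microarray intensities with
  category-dependent fold changes and lognormal noise, emulating a
  competitive hybridization between sexual and vegetative tissue.

Truth labels always travel in separate tables, never inside the FASTA/TSV
files the pipeline consumes. All randomness flows from explicit integer
seeds; per-gene streams derive deterministically from (seed, gene index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .codonmodel.frequencies import CodonFrequencies
from .codonmodel.ratematrix import CodonRateMatrix
from .genetics import N_CODONS
from .trees import Tree

# ---------------------------------------------------------------- scenarios


@dataclass
class CodonSimScenario:
    """One selection regime on one tree.

    ``omega_mode`` is a float (single ratio), a dict branch-name -> omega
    (branch model; a ``"background"`` key covers unlisted branches), or a
    list of (proportion, omega) pairs (site mixture, omega drawn once per
    site and shared across branches).
    """

    tree: Tree
    kappa: float = 2.0
    codon_freqs: CodonFrequencies = field(default_factory=CodonFrequencies.equal)
    omega_mode: float | dict[str, float] | list[tuple[float, float]] = 0.2
    n_codons: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if np.any(self.tree.branch_lengths() < 0):
            raise ValueError("branch lengths must be >= 0")
        for w in self._all_omegas():
            if w < 0:
                raise ValueError("omega must be >= 0")
        if isinstance(self.omega_mode, list):
            props = np.array([p for p, _ in self.omega_mode])
            if np.any(props < 0):
                raise ValueError("mixture proportions must be >= 0")
            if abs(props.sum() - 1.0) > 1e-12:
                raise ValueError("mixture proportions must sum to 1")

    def _all_omegas(self) -> list[float]:
        if isinstance(self.omega_mode, dict):
            return list(self.omega_mode.values())
        if isinstance(self.omega_mode, list):
            return [w for _, w in self.omega_mode]
        return [float(self.omega_mode)]


@dataclass
class ArraySimScenario:
    n_genes: int = 2000
    #: (sexual, vegetative, constitutive) fractions; defaults follow the
    #: observed proportions of a genome-wide competitive hybridization
    #: (roughly 8% sexual, 10% vegetative, the rest constitutive)
    category_fractions: tuple[float, float, float] = (0.083, 0.096, 0.821)
    log2_effect: float = 1.5
    noise_sd: float = 0.5
    n_arrays: int = 4
    background_mean: float = 200.0
    #: fraction of spots failing the well-measured criterion (fg <= bg)
    dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.category_fractions) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if self.n_arrays % 2 != 0:
            raise ValueError("n_arrays must be even (dye-swap pairs)")


# ---------------------------------------------------------- codon simulator


@dataclass
class SimulatedAlignment:
    alignment: CodonAlignment
    #: true omega of every codon site (truth for site-model recovery tests)
    site_omegas: np.ndarray
    site_classes: np.ndarray


def _sample_transitions(
    P: np.ndarray, parent_states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.size)
    child = (u[:, None] > cum[parent_states]).sum(axis=1)
    return np.minimum(child, N_CODONS - 1).astype(np.int16)


def simulate_codon_alignment(
    scenario: CodonSimScenario,
    gene_id: str = "gene",
    rng: np.random.Generator | None = None,
) -> SimulatedAlignment:
    """Evolve one codon alignment along the scenario's tree.

    The root sequence is drawn from the stationary codon frequencies and
    each branch evolved with the transition probabilities of the codon
    model, so no stop codon can ever be produced. For site mixtures the
    per-site omega is drawn once at the root and held fixed over the tree.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    tree = scenario.tree
    pi = scenario.codon_freqs.pi
    n = scenario.n_codons

    class_time_factors = np.array([1.0])
    if isinstance(scenario.omega_mode, list):
        props = np.array([p for p, _ in scenario.omega_mode])
        omegas = np.array([w for _, w in scenario.omega_mode])
        site_classes = rng.choice(len(props), size=n, p=props)
        # branch lengths are mixture-averaged substitutions per codon:
        # classes share one rate normalization, so high-omega sites evolve
        # proportionally faster (matching the site-model convention)
        scales = np.array(
            [CodonRateMatrix(scenario.kappa, float(w), pi).rate_scale for w in omegas]
        )
        class_time_factors = scales / float(np.dot(props, scales))
    else:
        omegas = np.array([0.0])  # placeholder, unused
        site_classes = np.zeros(n, dtype=int)

    site_omegas = (
        omegas[site_classes]
        if isinstance(scenario.omega_mode, list)
        else np.full(n, np.nan)
    )

    q_cache: dict[float, CodonRateMatrix] = {}

    def rate_matrix(w: float) -> CodonRateMatrix:
        if w not in q_cache:
            q_cache[w] = CodonRateMatrix(scenario.kappa, w, pi)
        return q_cache[w]

    def branch_omega(name: str) -> float:
        mode = scenario.omega_mode
        if isinstance(mode, dict):
            if name in mode:
                return float(mode[name])
            if "background" in mode:
                return float(mode["background"])
            raise ValueError(f"no omega for branch {name!r} and no 'background' entry")
        return float(mode) if not isinstance(mode, list) else np.nan

    nodes = tree.nodes
    root = len(nodes) - 1
    states: dict[int, np.ndarray] = {
        root: rng.choice(N_CODONS, size=n, p=pi).astype(np.int16)
    }
    # reversed postorder = parents before children
    for i in range(len(nodes) - 2, -1, -1):
        b = nodes[i]
        parent = states[b.parent]
        t = b.length
        if t == 0.0:
            states[i] = parent.copy()
            continue
        child = np.empty(n, dtype=np.int16)
        if isinstance(scenario.omega_mode, list):
            for c, w in enumerate(omegas):
                sel = site_classes == c
                if sel.any():
                    P = rate_matrix(float(w)).transition_probabilities(
                        t * class_time_factors[c]
                    )
                    child[sel] = _sample_transitions(P, parent[sel], rng)
        else:
            P = rate_matrix(branch_omega(b.name)).transition_probabilities(t)
            child[:] = _sample_transitions(P, parent, rng)
        states[i] = child

    taxa, rows = [], []
    for i, b in enumerate(nodes):
        if b.leaf_taxon is not None:
            taxa.append(b.leaf_taxon)
            rows.append(states[i])
    aln = CodonAlignment(gene_id, taxa, np.vstack(rows))
    if not isinstance(scenario.omega_mode, list):
        base = (
            np.nan if isinstance(scenario.omega_mode, dict) else float(scenario.omega_mode)
        )
        site_omegas = np.full(n, base)
    return SimulatedAlignment(aln, site_omegas, site_classes)


# -------------------------------------------------------------- gene sets

PHYLO_CLASSES = ("lineage_specific", "clade_specific", "broad_core")
_BASE_CLASS_PROBS = np.array([0.15, 0.35, 0.50])
N_CHROMOSOMES = 7


def simulate_gene_set(
    n_genes_per_category: dict[str, int],
    scenario_by_category: dict[str, CodonSimScenario],
    *,
    enrichment_odds: float = 1.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, SimulatedAlignment]]:
    """Simulate a gene set with per-category selection regimes.

    Returns a metadata table (gene_id, category, true omega structure,
    phylogenetic-specificity class, chromosome) and the alignments.
    ``enrichment_odds`` > 1 plants an association between the sexual
    category and the most lineage-specific phylogenetic class, for
    calibrating the enrichment tests. With ``out_dir`` set, per-gene FASTA
    files and the metadata TSV are written.
    """
    if not scenario_by_category:
        raise ValueError("empty scenario map")
    for cat, k in n_genes_per_category.items():
        if k < 1:
            raise ValueError(f"category {cat!r} needs at least one gene")
        if cat not in scenario_by_category:
            raise ValueError(f"no scenario for category {cat!r}")

    rows = []
    alignments: dict[str, SimulatedAlignment] = {}
    idx = 0
    label_rng = np.random.default_rng([seed, 10**6])
    for cat in sorted(n_genes_per_category):
        scen = scenario_by_category[cat]
        for _ in range(n_genes_per_category[cat]):
            gene_id = f"SIM{idx:05d}"
            rng = np.random.default_rng([scen.seed, seed, idx])
            sim = simulate_codon_alignment(scen, gene_id, rng)
            alignments[gene_id] = sim

            probs = _BASE_CLASS_PROBS.copy()
            if cat == "sexual" and enrichment_odds != 1.0:
                odds = probs / (1 - probs)
                odds[0] *= enrichment_odds
                probs = odds / (1 + odds)
                probs /= probs.sum()
            phylo = PHYLO_CLASSES[label_rng.choice(len(PHYLO_CLASSES), p=probs)]
            chrom = int(label_rng.integers(1, N_CHROMOSOMES + 1))
            mode = scen.omega_mode
            true_omega = (
                float(np.dot([p for p, _ in mode], [w for _, w in mode]))
                if isinstance(mode, list)
                else (np.nan if isinstance(mode, dict) else float(mode))
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "category": cat,
                    "true_omega": true_omega,
                    "phylo_class": phylo,
                    "chromosome": chrom,
                    "n_codons": scen.n_codons,
                }
            )
            idx += 1

    meta = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for gene_id, sim in alignments.items():
            sim.alignment.write_fasta(out_dir / f"{gene_id}.fasta")
        meta.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    return meta, alignments


# ------------------------------------------------------------- microarray

CATEGORIES = ("sexual", "vegetative", "constitutive")


def simulate_microarray(
    scenario: ArraySimScenario,
    categories: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the two-channel dye-swap experiment.

    Returns (intensity table, truth table). Sexual-category genes have a
    positive expected log2(sexual/vegetative) ratio, vegetative genes a
    negative one, constitutive genes zero. The first half of the arrays are
    'forward' (channel 1 carries the sexual sample); dye swaps flip the
    channel assignment. Intensities are lognormal around a per-gene
    baseline with additive background.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_genes
    if categories is None:
        categories = rng.choice(
            CATEGORIES, size=n, p=np.array(scenario.category_fractions)
        )
    categories = np.asarray(categories)
    gene_ids = np.array([f"SIM{i:05d}" for i in range(n)])

    magnitude = rng.gamma(4.0, scenario.log2_effect / 4.0, size=n)
    sign = np.where(
        categories == "sexual", 1.0, np.where(categories == "vegetative", -1.0, 0.0)
    )
    true_fold = sign * magnitude
    baseline_log2 = rng.normal(10.0, 1.5, size=n)  # log2 abundance

    rows = []
    per_channel_sd = scenario.noise_sd / np.sqrt(2.0)
    for a in range(scenario.n_arrays):
        orientation = "forward" if a < scenario.n_arrays // 2 else "swap"
        sex = 2.0 ** (
            baseline_log2 + true_fold / 2.0 + rng.normal(0, per_channel_sd, n)
        )
        veg = 2.0 ** (
            baseline_log2 - true_fold / 2.0 + rng.normal(0, per_channel_sd, n)
        )
        ch1, ch2 = (sex, veg) if orientation == "forward" else (veg, sex)
        bg1 = np.abs(rng.normal(scenario.background_mean, scenario.background_mean / 10, n))
        bg2 = np.abs(rng.normal(scenario.background_mean, scenario.background_mean / 10, n))
        fg1 = bg1 + ch1
        fg2 = bg2 + ch2
        dead = rng.random(n) < scenario.dropout_rate
        fg1[dead] = bg1[dead] * rng.uniform(0.3, 1.0, dead.sum())
        fg2[dead] = bg2[dead] * rng.uniform(0.3, 1.0, dead.sum())
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "array_id": f"array{a + 1}",
                    "dye_orientation": orientation,
                    "ch1_fg": fg1,
                    "ch1_bg": bg1,
                    "ch2_fg": fg2,
                    "ch2_bg": bg2,
                }
            )
        )
    intensities = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": categories,
            "true_log2_fold": true_fold,
            "baseline_log2": baseline_log2,
        }
    )
    return intensities, truth
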