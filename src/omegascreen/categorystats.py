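"""Category-level inference: bootstrap concatenation, distribution tests,
enrichment contingency analysis, codon-usage correspondence analysis, and
expression–rate regressions.

The bootstrap overcomes the instability of per-gene rate estimates from
short sequences: each replicate concatenates a resample of genes from one
category and re-estimates dN, dS and dN/dS (globally and per branch), and
category contrasts compare the replicate distributions with Wilcoxon
rank-sum tests (normal approximation with continuity and tie correction;
exact enumeration for small samples), BH-adjusted within each
(metric, scope) family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import expected_freq
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .alignment import CodonAlignment, concatenate_alignments
from .codonmodel.fit import fit
from .codonmodel.models import M0, TwoRatio
from .genetics import MISSING, SENSE_CODONS, SYNONYMOUS_FAMILIES
from .trees import Tree

# ------------------------------------------------------------- bootstrap


@dataclass
class BootstrapReplicate:
    category: str
    index: int
    seed: int
    #: scope -> (dN, dS, dN/dS); scope is "global" or "branch:<name>"
    rates: dict[str, tuple[float, float, float]]
    converged: bool = True


def bootstrap_category_rates(
    category: str,
    gene_ids: list[str],
    alignments: dict[str, CodonAlignment],
    tree: Tree,
    *,
    n_reps: int = 1000,
    genes_per_rep: int = 10,
    seed: int = 0,
    scopes: tuple[str, ...] | None = None,
    replace: bool = True,
    freqs: str = "F3x4",
) -> list[BootstrapReplicate]:
    """Bootstrap distribution of category-level rates.

    Each replicate concatenates ``genes_per_rep`` genes drawn (with
    replacement by default) from the category and fits the one-ratio model
    plus, for each requested branch scope, the two-ratio model with that
    branch foreground. Fully seeded and reproducible.
    """
    if len(gene_ids) < genes_per_rep:
        raise ValueError(
            f"category {category!r} has {len(gene_ids)} genes; "
            f"needs >= {genes_per_rep}"
        )
    if scopes is None:
        scopes = ("global",)
    branch_scopes = [s.removeprefix("branch:") for s in scopes if s != "global"]

    out = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        chosen = rng.choice(len(gene_ids), size=genes_per_rep, replace=replace)
        concat = concatenate_alignments(
            [alignments[gene_ids[i]] for i in chosen], taxa=list(tree.taxa),
            gene_id=f"{category}_rep{rep}",
        )
        m0 = fit(concat, tree, M0(), freqs=freqs, n_starts=1, seed=seed + rep)
        rates: dict[str, tuple[float, float, float]] = {}
        ok = m0.converged
        if "global" in scopes:
            dn, ds = m0.dn_ds["global"]
            rates["global"] = (dn, ds, m0.model.omega)
        warm = tree.with_branch_lengths(
            np.array([m0.branch_lengths[b] for b in tree.branch_names()])
        )
        for b in branch_scopes:
            f = fit(
                concat, warm.with_foreground(b),
                TwoRatio(kappa=m0.kappa, omega=m0.model.omega, omega_fg=m0.model.omega),
                freqs=freqs, n_starts=1, seed=seed + rep,
            )
            dn, ds = f.dn_ds[f"branch:{b}"]
            rates[f"branch:{b}"] = (dn, ds, f.model.omega_fg)
            ok = ok and f.converged
        out.append(BootstrapReplicate(category, rep, seed, rates, ok))
    return out


def replicate_metric(
    replicates: list[BootstrapReplicate], metric: str, scope: str = "global"
) -> np.ndarray:
    col = {"dN": 0, "dS": 1, "dN/dS": 2}[metric]
    return np.array([r.rates[scope][col] for r in replicates])


# ----------------------------------------------------- distribution tests


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test; (statistic, p).

    Normal approximation with continuity and tie correction, switching to
    exact enumeration when both samples have at most 10 observations and
    no ties straddle the samples.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    small = len(x) <= 10 and len(y) <= 10
    no_ties = np.unique(np.concatenate([x, y])).size == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_rate_distributions(
    replicates_by_category: dict[str, list[BootstrapReplicate]],
    metric: str = "dN/dS",
    scope: str = "global",
) -> pd.DataFrame:
    """All pairwise category contrasts of one metric in one scope, BH-adjusted."""
    cats = sorted(replicates_by_category)
    if len(cats) < 2:
        raise ValueError("need at least two categories")
    samples = {
        c: replicate_metric(replicates_by_category[c], metric, scope) for c in cats
    }
    for c, s in samples.items():
        if s.size < 2:
            raise ValueError(f"category {c!r} has fewer than two replicates")
    rows = []
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            u, p = wilcoxon_rank_sum(samples[a], samples[b])
            rows.append(
                {
                    "category_a": a, "category_b": b, "metric": metric, "scope": scope,
                    "mean_a": samples[a].mean(), "mean_b": samples[b].mean(),
                    "statistic": u, "p": p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ------------------------------------------------------------ enrichment


@dataclass
class ContingencyTable:
    observed: np.ndarray
    expected: np.ndarray
    odds_ratio: float
    p: float
    p_adj: float | None = None


def fisher_enrichment(observed, alternative: str = "two-sided") -> ContingencyTable:
    """Fisher exact test on a 2x2 table.

    The default two-tailed p sums hypergeometric point probabilities no
    larger than the observed table's (the R convention);
    ``alternative="greater"`` gives the directional enrichment tail.
    Expected counts come from the margins.
    """
    obs = np.asarray(observed)
    if obs.shape != (2, 2) or np.any(obs < 0) or not np.issubdtype(obs.dtype, np.integer):
        obs = obs.astype(int)
        if obs.shape != (2, 2) or np.any(obs < 0):
            raise ValueError("need a nonnegative integer 2x2 table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    oddsratio, p = stats.fisher_exact(obs, alternative=alternative)
    return ContingencyTable(obs, expected_freq(obs), float(oddsratio), float(p))


def expected_counts(observed) -> np.ndarray:
    """Independence-expected counts, expected_ij = row_i * col_j / grand."""
    obs = np.asarray(observed, dtype=float)
    if obs.sum() == 0:
        raise ValueError("grand total is zero")
    return expected_freq(obs)


def enrichment_table(observed: pd.DataFrame) -> pd.DataFrame:
    """Per-cell enrichment of an r x c class-by-category count table.

    Each cell is tested as its own 2x2 (cell vs the rest), matching
    per-cell significance stars; BH adjustment spans all cells.
    """
    obs = observed.to_numpy(dtype=int)
    exp = expected_counts(obs)
    grand = obs.sum()
    rows = []
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            a = obs[i, j]
            b = obs[i].sum() - a
            c = obs[:, j].sum() - a
            d = grand - a - b - c
            ct = fisher_enrichment(np.array([[a, b], [c, d]]))
            rows.append(
                {
                    "row": observed.index[i], "column": observed.columns[j],
                    "observed": a, "expected": round(exp[i, j], 1),
                    "odds_ratio": ct.odds_ratio, "p": ct.p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ----------------------------------------------- codon usage / CA


#: codons informative for RSCU: synonymous families of size >= 2
RSCU_CODONS = [
    i
    for fam in SYNONYMOUS_FAMILIES.values()
    if len(fam) >= 2
    for i in fam
]
RSCU_CODONS.sort()


@dataclass
class CAResult:
    rscu: pd.DataFrame          # genes x informative codons
    row_coords: pd.DataFrame    # genes x axes
    col_coords: pd.DataFrame    # codons x axes
    inertia: np.ndarray         # per-axis chi-square inertia

    @property
    def total_inertia(self) -> float:
        return float(self.inertia.sum())


def rscu_matrix(sequences: dict[str, np.ndarray]) -> pd.DataFrame:
    """Relative synonymous codon usage per gene.

    RSCU of a codon is its count divided by the mean count of its
    synonymous family; families unobserved in a gene are imputed with the
    global mean RSCU of their codons. Single-codon families and stops are
    excluded (59 informative codons under the standard code).
    """
    genes = list(sequences)
    counts = np.zeros((len(genes), len(SENSE_CODONS)))
    for gi, g in enumerate(genes):
        codes = sequences[g]
        obs = codes[codes != MISSING]
        counts[gi] = np.bincount(obs, minlength=len(SENSE_CODONS))

    rscu = np.full((len(genes), len(SENSE_CODONS)), np.nan)
    for fam in SYNONYMOUS_FAMILIES.values():
        if len(fam) < 2:
            continue
        fam = list(fam)
        fam_tot = counts[:, fam].sum(axis=1)
        ok = fam_tot > 0
        rscu[np.ix_(ok, fam)] = (
            counts[np.ix_(ok, fam)] * len(fam) / fam_tot[ok, None]
        )
    rscu = rscu[:, RSCU_CODONS]
    col_mean = np.nanmean(rscu, axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    nan_mask = np.isnan(rscu)
    rscu[nan_mask] = np.broadcast_to(col_mean, rscu.shape)[nan_mask]
    return pd.DataFrame(
        rscu, index=genes, columns=[SENSE_CODONS[i] for i in RSCU_CODONS]
    )


def codon_usage_ca(sequences: dict[str, np.ndarray], n_axes: int = 2) -> CAResult:
    """Correspondence analysis of the per-gene RSCU matrix.

    Standard CA: SVD of the standardized residuals of the row/column
    profile matrix; per-axis inertia sums to the total chi-square inertia.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two genes")
    for g, codes in sequences.items():
        if codes[codes != MISSING].size < 30:
            raise ValueError(f"gene {g!r} has fewer than 30 codons")
    rscu = rscu_matrix(sequences)
    # codons never used by any gene have zero column margin and no inertia
    rscu = rscu.loc[:, rscu.sum(axis=0) > 0]
    X = rscu.to_numpy()
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(n_axes, sv.size)
    row_coords = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    col_coords = (Vt.T[:, :k] * sv[:k]) / np.sqrt(c)[:, None]
    return CAResult(
        rscu=rscu,
        row_coords=pd.DataFrame(
            row_coords, index=rscu.index, columns=[f"axis{i+1}" for i in range(k)]
        ),
        col_coords=pd.DataFrame(
            col_coords, index=rscu.columns, columns=[f"axis{i+1}" for i in range(k)]
        ),
        inertia=sv**2,
    )


# ------------------------------------------------- expression vs rate


def regress_expression_rate(table: pd.DataFrame) -> pd.DataFrame:
    """OLS of global dN/dS on absolute expression and on CDS length.

    ``table`` columns: gene_id, expression, cds_length, omega, category.
    Regressions run overall and per category; Wilcoxon contrasts of the
    expression distributions between categories are appended.
    """
    required = {"expression", "cds_length", "omega", "category"}
    if missing := required - set(table.columns):
        raise ValueError(f"missing columns {sorted(missing)}")
    t = table.dropna(subset=["expression", "cds_length", "omega"])
    if len(t) < 3:
        raise ValueError("need at least three genes with complete data")

    rows = []
    groups = [("all", t)] + [(c, g) for c, g in t.groupby("category")]
    for predictor in ("expression", "cds_length"):
        for name, g in groups:
            if len(g) < 3 or g[predictor].nunique() < 2:
                continue
            X = sm.add_constant(g[predictor].to_numpy())
            res = sm.OLS(g["omega"].to_numpy(), X).fit()
            rows.append(
                {
                    "kind": "regression", "predictor": predictor, "group": name,
                    "n": len(g), "slope": res.params[1], "r2": res.rsquared,
                    "p": res.pvalues[1],
                }
            )
    cats = sorted(t["category"].unique())
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            xa = t.loc[t["category"] == a, "expression"].to_numpy()
            xb = t.loc[t["category"] == b, "expression"].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            _, p = wilcoxon_rank_sum(xa, xb)
            rows.append(
                {
                    "kind": "wilcoxon_expression", "predictor": "expression",
                    "group": f"{a} vs {b}", "n": len(xa) + len(xb),
                    "slope": np.nan, "r2": np.nan, "p": p,
                }
            )
    return pd.DataFrame(rows)
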