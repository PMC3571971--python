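"""Genome-scale screen for rapidly evolving genes.

Per gene and scope (the whole tree, or one branch), two nested models are
fitted: the rate ratio of interest free versus fixed at the corresponding
category-wide mean, which is itself estimated once from the concatenation
of all genes (one-ratio model globally; a two-ratio model per branch, with
that branch foreground). Twice the log-likelihood difference is referred to
chi-square with 1 df; q-values control FDR within each scope family; and a
gene is called rapidly evolving only when significant (q < 0.05) AND its
free estimate exceeds the mean — the screen targets acceleration, not mere
deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, concatenate_alignments
from .codonmodel.fit import FitResult, fit, lrt
from .codonmodel.models import M0, TwoRatio
from .expression import GeneCategoryAssignment, estimate_qvalues
from .trees import Tree

logger = logging.getLogger(__name__)

GLOBAL_SCOPE = "global"


@dataclass
class MeanOmega:
    global_mean: float
    branch_means: dict[str, float]
    fits: dict[str, FitResult] = field(default_factory=dict, repr=False)

    def for_scope(self, scope: str) -> float:
        if scope == GLOBAL_SCOPE:
            return self.global_mean
        return self.branch_means[scope.removeprefix("branch:")]


@dataclass
class ScreenResult:
    gene_id: str
    scope: str  # "global" or "branch:<name>"
    omega_free: float
    omega_fixed_mean: float
    lnL_free: float
    lnL_fixed: float
    p_value: float
    q_value: float | None = None
    rapid: bool | None = None
    degenerate: bool = False


def estimate_mean_omega(
    alignments: list[CodonAlignment],
    tree: Tree,
    *,
    branches: list[str] | None = None,
    freqs: str = "F3x4",
    n_starts: int = 2,
    seed: int = 0,
) -> MeanOmega:
    """Category-wide mean rate ratios from the all-genes concatenation.

    The global mean is the one-ratio estimate on the concatenated
    alignment; each branch mean is the foreground estimate of a two-ratio
    fit on the same concatenation with that branch foreground.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    concat = concatenate_alignments(alignments, taxa=list(tree.taxa))
    global_fit = fit(concat, tree, M0(), freqs=freqs, n_starts=n_starts, seed=seed)
    fits = {GLOBAL_SCOPE: global_fit}
    branch_means: dict[str, float] = {}
    bl_tree = tree.with_branch_lengths(
        np.array([global_fit.branch_lengths[b] for b in tree.branch_names()])
    )
    for b in branches or []:
        f = fit(
            concat,
            bl_tree.with_foreground(b),
            TwoRatio(kappa=global_fit.kappa, omega=global_fit.model.omega,
                     omega_fg=global_fit.model.omega),
            freqs=freqs,
            n_starts=1,
            seed=seed,
        )
        branch_means[b] = f.model.omega_fg
        fits[f"branch:{b}"] = f
    return MeanOmega(global_fit.model.omega, branch_means, fits)


def screen_gene(
    alignment: CodonAlignment,
    tree: Tree,
    mean_omega: float,
    scope: str = GLOBAL_SCOPE,
    *,
    freqs: str = "F3x4",
    n_starts: int = 1,
    seed: int = 0,
) -> ScreenResult:
    """Free-versus-mean-fixed LRT (1 df) for one gene in one scope."""
    if scope == GLOBAL_SCOPE:
        free = fit(alignment, tree, M0(), freqs=freqs, n_starts=n_starts, seed=seed)
        fixed_kwargs = {"omega": mean_omega}
        refit_model = M0(kappa=free.kappa, omega=mean_omega)
    else:
        branch = scope.removeprefix("branch:")
        tagged = tree.with_foreground(branch)
        free = fit(alignment, tagged, TwoRatio(), freqs=freqs, n_starts=n_starts, seed=seed)
        fixed_kwargs = {"omega_fg": mean_omega}
        refit_model = TwoRatio(kappa=free.kappa, omega=free.model.omega, omega_fg=mean_omega)
        tree = tagged

    if free.degenerate:
        return ScreenResult(
            alignment.gene_id, scope, free.mean_omega, mean_omega,
            free.lnL, free.lnL, 1.0, degenerate=True,
        )

    # start the constrained fit from the free optimum's branch lengths
    warm = tree.with_branch_lengths(
        np.array([free.branch_lengths[b] for b in tree.branch_names()])
    )
    fixed = fit(
        alignment, warm, refit_model, fixed=fixed_kwargs,
        freqs=freqs, n_starts=1, seed=seed,
    )
    lnL_fixed = min(fixed.lnL, free.lnL)  # clamp optimizer jitter: nested models
    omega_free = free.model.omega_fg if scope != GLOBAL_SCOPE else free.model.omega
    return ScreenResult(
        alignment.gene_id, scope, float(omega_free), float(mean_omega),
        free.lnL, lnL_fixed, lrt(lnL_fixed, free.lnL, df=1),
    )


def adjust_screen_fdr(
    results: list[ScreenResult], alpha_q: float = 0.05
) -> list[ScreenResult]:
    """Storey q-values within each scope family; sets the rapid flag.

    rapid requires q < alpha_q AND the free estimate above the mean
    (directional filter: the screen reports acceleration only).
    """
    by_scope: dict[str, list[ScreenResult]] = {}
    for r in results:
        by_scope.setdefault(r.scope, []).append(r)
    for scope_results in by_scope.values():
        q = estimate_qvalues(np.array([r.p_value for r in scope_results]))
        for r, qv in zip(scope_results, q):
            r.q_value = float(qv)
            r.rapid = bool(
                (not r.degenerate)
                and qv < alpha_q
                and r.omega_free > r.omega_fixed_mean
            )
    return results


def screen_genes(
    alignments: list[CodonAlignment],
    tree: Tree,
    *,
    scopes: list[str] | None = None,
    mean_omega: MeanOmega | None = None,
    alpha_q: float = 0.05,
    freqs: str = "F3x4",
    seed: int = 0,
) -> list[ScreenResult]:
    """Run the full screen: means from concatenation, LRT per gene x scope, FDR."""
    if scopes is None:
        scopes = [GLOBAL_SCOPE]
    branch_scopes = [s.removeprefix("branch:") for s in scopes if s != GLOBAL_SCOPE]
    if mean_omega is None:
        mean_omega = estimate_mean_omega(
            alignments, tree, branches=branch_scopes, seed=seed
        )
    results = []
    for i, aln in enumerate(alignments):
        for scope in scopes:
            results.append(
                screen_gene(
                    aln, tree, mean_omega.for_scope(scope), scope,
                    freqs=freqs, seed=seed + i,
                )
            )
    return adjust_screen_fdr(results, alpha_q=alpha_q)


def tabulate_rapid_by_category(
    results: list[ScreenResult], assignments: GeneCategoryAssignment | pd.DataFrame
) -> pd.DataFrame:
    """Counts of rapid genes per scope x expression category.

    Rows: each category plus a 'Total' row; columns: gene counts, the union
    of scopes ('Total'), and one column per scope.
    """
    table = assignments.table if isinstance(assignments, GeneCategoryAssignment) else assignments
    cat = dict(zip(table["gene_id"], table["category"]))
    scopes = sorted({r.scope for r in results}, key=lambda s: (s != GLOBAL_SCOPE, s))
    genes = sorted({r.gene_id for r in results})

    rapid_by_scope: dict[str, set[str]] = {s: set() for s in scopes}
    for r in results:
        if r.rapid:
            rapid_by_scope[r.scope].add(r.gene_id)
    union = set().union(*rapid_by_scope.values()) if rapid_by_scope else set()

    categories = sorted({cat.get(g, "n/a") for g in genes})
    rows = []
    for c in ["Total"] + categories:
        sel = set(genes) if c == "Total" else {g for g in genes if cat.get(g, "n/a") == c}
        row = {"category": c, "n_genes": len(sel), "Total": len(union & sel)}
        for s in scopes:
            row[s] = len(rapid_by_scope[s] & sel)
        rows.append(row)
    return pd.DataFrame(rows)
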