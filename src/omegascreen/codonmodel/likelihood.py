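"""Felsenstein pruning for codon models with site-pattern compression.

Sites are iid given the model, so the alignment is compressed to unique
codon-site patterns with multiplicities; the log-likelihood is the
weight-sum of per-pattern log-likelihoods. Missing codons contribute an
all-ones conditional vector (the standard pruning convention). Internal
partials are rescaled per pattern to avoid underflow on larger trees.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from ..alignment import CodonAlignment
from ..genetics import MISSING, N_CODONS
from ..trees import Tree
from .frequencies import CodonFrequencies, resolve_frequencies
from .ratematrix import CodonRateMatrix


class LikelihoodEngine:
    """Likelihood evaluator bound to one alignment + tree + frequency model.

    The engine owns the pattern compression and the postorder traversal;
    model objects supply (kappa, branch lengths, per-branch or per-class
    omega) and get back log-likelihoods.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: Tree,
        freqs: CodonFrequencies | str = "F3x4",
    ):
        if set(alignment.taxa) != set(tree.taxa):
            raise ValueError(
                f"alignment taxa {sorted(alignment.taxa)} != tree taxa {sorted(tree.taxa)}"
            )
        self.tree = tree
        aln = alignment.reorder(tree.taxa)
        self.alignment = aln
        if isinstance(freqs, str):
            freqs = resolve_frequencies(freqs, aln.codes)
        self.freqs = freqs
        self.pi = freqs.pi

        patterns, inverse, counts = np.unique(
            aln.codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns          # (n_taxa, n_patterns)
        self.pattern_of_site = np.asarray(inverse).ravel()
        self.weights = counts.astype(float)
        self.n_sites = aln.n_codons
        self.n_patterns = patterns.shape[1]

        # leaf row in pattern matrix for each tree node (leaves only)
        taxon_row = {t: i for i, t in enumerate(tree.taxa)}
        self._leaf_row = [
            taxon_row[b.leaf_taxon] if b.leaf_taxon is not None else -1
            for b in tree.nodes
        ]
        self._q_cache: dict[tuple[float, float], CodonRateMatrix] = {}

    # ------------------------------------------------------------ internals

    def _rate_matrix(self, kappa: float, omega: float) -> CodonRateMatrix:
        key = (round(float(kappa), 12), round(float(omega), 12))
        Q = self._q_cache.get(key)
        if Q is None:
            Q = CodonRateMatrix(kappa, omega, self.pi)
            if len(self._q_cache) > 256:
                self._q_cache.clear()
            self._q_cache[key] = Q
        return Q

    def _pattern_log_likelihoods(
        self,
        kappa: float,
        branch_lengths: np.ndarray,
        branch_omegas: np.ndarray,
        time_scale: float = 1.0,
    ) -> np.ndarray:
        """Per-pattern log-likelihood for one concrete omega assignment."""
        nodes = self.tree.nodes
        n_pat = self.n_patterns
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_pat)

        for i, b in enumerate(nodes):
            if b.parent == -1:
                break  # root handled after loop
            P = self._rate_matrix(kappa, branch_omegas[i]).transition_probabilities(
                branch_lengths[i] * time_scale
            )
            row = self._leaf_row[i]
            if row >= 0:
                states = self.patterns[row]
                contrib = np.ones((N_CODONS, n_pat))
                present = states != MISSING
                contrib[:, present] = P[:, states[present]]
            else:
                part = partials.pop(i)
                contrib = P @ part
            acc = partials.get(b.parent)
            partials[b.parent] = contrib if acc is None else acc * contrib
            if row < 0:
                # rescale after folding an internal subtree in
                mx = partials[b.parent].max(axis=0)
                mx = np.where(mx > 0, mx, 1.0)
                partials[b.parent] /= mx
                logscale += np.log(mx)

        root = len(nodes) - 1
        L = self.pi @ partials[root]
        with np.errstate(divide="ignore"):
            return np.log(L) + logscale

    # ------------------------------------------------------------- public

    def log_likelihood_single(
        self, kappa: float, branch_lengths: np.ndarray, branch_omegas: np.ndarray
    ) -> float:
        """lnL for a model with one omega per branch (M0, two-ratio)."""
        site_ll = self._pattern_log_likelihoods(kappa, branch_lengths, branch_omegas)
        return float(self.weights @ site_ll)

    def class_pattern_log_likelihoods(
        self,
        kappa: float,
        branch_lengths: np.ndarray,
        omega: float,
        time_scale: float = 1.0,
    ) -> np.ndarray:
        """Per-pattern log-likelihood with a single omega on all branches.

        ``time_scale`` rescales branch time for this class; site mixtures
        use it to share one rate normalization across classes.
        """
        omegas = np.full(len(self.tree.nodes), float(omega))
        return self._pattern_log_likelihoods(kappa, branch_lengths, omegas, time_scale)

    def mixture_time_scales(
        self, kappa: float, proportions: np.ndarray, omegas: np.ndarray
    ) -> np.ndarray:
        """Per-class time multipliers under shared mixture normalization.

        Branch lengths measure expected substitutions per codon averaged
        over site classes, so class k runs at rate scale_k / mean_scale:
        high-omega classes accumulate proportionally more substitutions.
        """
        scales = np.array(
            [self._rate_matrix(kappa, w).rate_scale for w in omegas]
        )
        mean_scale = float(np.dot(proportions, scales))
        return scales / mean_scale

    def log_likelihood_mixture(
        self,
        kappa: float,
        branch_lengths: np.ndarray,
        proportions: np.ndarray,
        omegas: np.ndarray,
    ) -> float:
        """lnL under a site mixture: per site, sum_k p_k L_k."""
        logp = np.log(np.maximum(proportions, 1e-300))
        factors = self.mixture_time_scales(kappa, proportions, omegas)
        per_class = np.stack(
            [
                self.class_pattern_log_likelihoods(kappa, branch_lengths, w, f)
                for w, f in zip(omegas, factors)
            ]
        )
        site_ll = logsumexp(per_class + logp[:, None], axis=0)
        return float(self.weights @ site_ll)

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern quantity back onto alignment sites."""
        return np.asarray(per_pattern)[..., self.pattern_of_site]


def log_likelihood(alignment: CodonAlignment, tree: Tree, model, freqs="F3x4") -> float:
    """Convenience wrapper: lnL of a fully parameterized model spec."""
    engine = LikelihoodEngine(alignment, tree, freqs)
    return model.log_likelihood(engine, tree.branch_lengths())
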