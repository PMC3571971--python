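"""Maximum-likelihood fitting of codon models, LRTs, and dN/dS.

Optimization uses box-bounded quasi-Newton (L-BFGS-B) with numerical
gradients over the model's free parameters and, by default, all branch
lengths jointly. Each fit starts from a counting-based (NG86-style)
initializer plus optional random restarts; convergence is declared when the
optimizer's relative improvement drops below tolerance.

dN and dS decompose the fitted flux: with the rate matrix scaled to one
expected substitution per codon, a branch of length t has t*rhoN
nonsynonymous and t*rhoS synonymous substitutions per codon, where rhoN and
rhoS are the nonsynonymous/synonymous flux shares under the fitted Q. The
per-site normalization divides by 3*NN resp. 3*SS, the corresponding shares
of the same Q evaluated at omega = 1 (mutational opportunity), so that
dN/dS equals the fitted omega identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from ..alignment import CodonAlignment
from ..genetics import (
    AMINO_ACIDS,
    CODON_INDEX,
    MISSING,
    PAIR_I,
    PAIR_IS_SYNONYMOUS,
    PAIR_J,
    SENSE_CODONS,
)
from ..trees import Tree
from .likelihood import LikelihoodEngine
from .models import BRANCH_BOUNDS, M0, M1a, M2a, M7, M8, ModelSpec, TwoRatio
from .ratematrix import CodonRateMatrix, site_proportions


@dataclass
class FitResult:
    model: ModelSpec
    lnL: float
    branch_lengths: dict[str, float]
    engine: LikelihoodEngine = field(repr=False)
    n_function_evals: int = 0
    converged: bool = True
    degenerate: bool = False

    @property
    def kappa(self) -> float:
        return self.model.kappa

    @property
    def mean_omega(self) -> float:
        return self.model.mean_omega

    @property
    def tree_length(self) -> float:
        return float(sum(self.branch_lengths.values()))

    @property
    def dn_ds(self) -> dict[str, tuple[float, float]]:
        """(dN, dS) for the whole tree ('global') and per branch."""
        return compute_dn_ds(self)

    @property
    def dN(self) -> float:
        return self.dn_ds["global"][0]

    @property
    def dS(self) -> float:
        return self.dn_ds["global"][1]

    def summary_params(self) -> dict[str, float]:
        out = {"kappa": self.model.kappa}
        for name, *_ in self.model.param_defs():
            if name != "kappa":
                out[name] = self.model.get_param(name)
        return out


# ----------------------------------------------------------------- dN/dS

def flux_shares(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """(synonymous, nonsynonymous) shares of unit rate flux under Q."""
    Q = CodonRateMatrix(kappa, omega, pi)
    return Q.rho_syn, Q.rho_nonsyn


def dn_ds_for_branch(
    kappa: float, omega: float, pi: np.ndarray, t: float
) -> tuple[float, float]:
    """dN and dS accumulated over a branch of length t (subs/codon)."""
    if t == 0:
        return 0.0, 0.0
    rho_s, rho_n = flux_shares(kappa, omega, pi)
    ss, nn = site_proportions(kappa, pi)
    dN = t * rho_n / (3.0 * nn)
    dS = t * rho_s / (3.0 * ss)
    return dN, dS


def compute_dn_ds(result: FitResult) -> dict[str, tuple[float, float]]:
    """dN/dS decomposition per scope for a fitted model.

    Branch models use each branch's own omega; site-mixture models use the
    mixture-mean omega (the single rate ratio the mixture averages to).
    """
    model = result.model
    pi = result.engine.pi
    tree = result.engine.tree
    out: dict[str, tuple[float, float]] = {}

    if isinstance(model, TwoRatio):
        per_branch_omega = {
            b.name: (model.omega_fg if b.tag == 1 else model.omega)
            for b in tree.nodes[:-1]
        }
    else:
        w = model.mean_omega
        per_branch_omega = {b.name: w for b in tree.nodes[:-1]}

    total_dn = total_ds = 0.0
    for name, t in result.branch_lengths.items():
        dn, ds = dn_ds_for_branch(model.kappa, per_branch_omega[name], pi, t)
        out[f"branch:{name}"] = (dn, ds)
        total_dn += dn
        total_ds += ds
    out["global"] = (total_dn, total_ds)
    return out


# ------------------------------------------------------------------- LRT

def lrt(lnL_null: float, lnL_alt: float, df: int) -> float:
    """Likelihood-ratio test p-value: 2*(lnL_alt - lnL_null) ~ chi2_df."""
    if df <= 0:
        raise ValueError("df must be positive")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < -1e-6:
        raise ValueError(
            f"alternative lnL {lnL_alt} below null {lnL_null}: fits inconsistent"
        )
    stat = max(stat, 0.0)
    return float(chi2.sf(stat, df))


# ------------------------------------------------- counting-based starts

_syn_neighbors = np.zeros(len(SENSE_CODONS))
_all_neighbors = np.zeros(len(SENSE_CODONS))
np.add.at(_syn_neighbors, PAIR_I, PAIR_IS_SYNONYMOUS.astype(float))
np.add.at(_all_neighbors, PAIR_I, 1.0)
#: NG86-style synonymous site count per codon (out of 3 sites)
SYN_SITES = 3.0 * _syn_neighbors / _all_neighbors
NONSYN_SITES = 3.0 - SYN_SITES

_pair_syn = {}
for _i, _j, _s in zip(PAIR_I, PAIR_J, PAIR_IS_SYNONYMOUS):
    _pair_syn[(int(_i), int(_j))] = bool(_s)


def _jc_correct(p: float) -> float:
    p = min(p, 0.70)
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def counting_start(alignment: CodonAlignment) -> tuple[float, float]:
    """Rough (omega, mean pairwise codon distance) by NG86-style counting.

    Only used to initialize the optimizer; multi-position codon differences
    are split position-wise without pathway averaging.
    """
    codes = alignment.codes
    n_taxa = codes.shape[0]
    S = N = Sd = Nd = 0.0
    pdist = []
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            both = (codes[a] != MISSING) & (codes[b] != MISSING)
            ca, cb = codes[a][both], codes[b][both]
            if ca.size == 0:
                continue
            S += 0.5 * (SYN_SITES[ca].sum() + SYN_SITES[cb].sum())
            N += 0.5 * (NONSYN_SITES[ca].sum() + NONSYN_SITES[cb].sum())
            diff = ca != cb
            pdist.append(diff.mean())
            for x, y in zip(ca[diff], cb[diff]):
                key = (int(x), int(y))
                if key in _pair_syn:
                    if _pair_syn[key]:
                        Sd += 1.0
                    else:
                        Nd += 1.0
                else:  # multi-position difference: split by position
                    cx, cy = SENSE_CODONS[x], SENSE_CODONS[y]
                    for p in range(3):
                        if cx[p] != cy[p]:
                            mut = cx[:p] + cy[p] + cx[p + 1 :]
                            if mut in CODON_INDEX:
                                syn = AMINO_ACIDS[x] == AMINO_ACIDS[CODON_INDEX[mut]]
                                Sd += 1.0 if syn else 0.0
                                Nd += 0.0 if syn else 1.0
                            else:
                                Nd += 1.0
    if S <= 0 or N <= 0 or not pdist:
        return 0.2, 0.1
    ps, pn = Sd / S, Nd / N
    ds, dn = _jc_correct(ps), _jc_correct(pn)
    omega = dn / ds if ds > 1e-9 else 1.0
    omega = float(np.clip(omega, 5e-3, 10.0))
    mean_p = float(np.mean(pdist))
    return omega, mean_p


# ------------------------------------------------------------------- fit

def _initial_model(model: ModelSpec, omega_hat: float) -> ModelSpec:
    """Seed the model's omega structure from the counting estimate."""
    if isinstance(model, M0):
        return model.with_params(omega=omega_hat)
    if isinstance(model, TwoRatio):
        return model.with_params(omega=omega_hat, omega_fg=omega_hat)
    if isinstance(model, (M1a, M2a)):
        w0 = float(np.clip(omega_hat / 2.0, 1e-3, 0.9))
        return model.with_params(omega0=w0)
    return model


def fit(
    alignment: CodonAlignment,
    tree: Tree,
    model: ModelSpec | str,
    *,
    fixed: dict[str, float] | None = None,
    freqs="F3x4",
    optimize_branch_lengths: bool | str = True,
    n_starts: int = 4,
    seed: int = 0,
    maxiter: int = 500,
) -> FitResult:
    """Maximize lnL over the model's free parameters and branch lengths.

    ``fixed`` pins named model parameters (e.g. ``{"omega": 0.111}`` for the
    mean-fixed null of the rapid-evolution screen). ``n_starts`` counts the
    informed start plus random restarts. If no restart converges, the best
    point found is returned with ``converged=False``.

    ``optimize_branch_lengths`` may be True (joint optimization), False
    (use the tree's lengths as given), or ``"scale"`` (optimize a single
    factor multiplying the tree's lengths — the usual second stage for
    site models, whose branch lengths come from a one-ratio fit).
    """
    if isinstance(model, str):
        model = ModelSpec.create(model)
    fixed = dict(fixed or {})
    model.branch_omegas(tree)  # validates branch-model tagging up front
    engine = LikelihoodEngine(alignment, tree, freqs)

    # Degenerate alignments (no variable, fully observed pattern) cannot
    # inform omega: return the boundary fit, flagged, without optimizing.
    observed = engine.patterns[:, (engine.patterns != MISSING).all(axis=0)]
    variable = observed.size and (observed != observed[0]).any()
    if not variable:
        lo_t = BRANCH_BOUNDS[0]
        bls = np.full(tree.n_branches, lo_t)
        m = _apply_fixed(model, fixed)
        for name, lo, _hi in m.param_defs():
            if name.startswith("omega") and name not in fixed:
                m = m.with_params(**{name: lo if "omega2" not in name and name != "omega_s" else 1.0})
        lnL = m.log_likelihood(engine, bls)
        return FitResult(
            m, lnL, dict(zip(tree.branch_names(), bls)), engine,
            n_function_evals=1, converged=True, degenerate=True,
        )

    omega_hat, mean_p = counting_start(alignment)
    model0 = _apply_fixed(_initial_model(model, omega_hat), fixed)

    free_defs = [d for d in model0.param_defs() if d[0] not in fixed]
    names = [d[0] for d in free_defs]
    lows = np.array([d[1] for d in free_defs])
    highs = np.array([d[2] for d in free_defs])

    if optimize_branch_lengths is True:
        bl0 = np.maximum(tree.branch_lengths(), 1e-4)
        if not bl0.any() or np.allclose(bl0, 1e-4):
            bl0 = np.full(tree.n_branches, max(mean_p / 2.0, 0.01))
        lows = np.append(lows, np.full(tree.n_branches, BRANCH_BOUNDS[0]))
        highs = np.append(highs, np.full(tree.n_branches, BRANCH_BOUNDS[1]))
    elif optimize_branch_lengths == "scale":
        bl0 = np.maximum(tree.branch_lengths(), BRANCH_BOUNDS[0])
        lows = np.append(lows, 0.05)
        highs = np.append(highs, 20.0)
    else:
        bl0 = tree.branch_lengths()

    nfree_model = len(names)

    def unpack(x: np.ndarray) -> tuple[ModelSpec, np.ndarray]:
        m = model0.with_params(**dict(zip(names, x[:nfree_model])))
        if optimize_branch_lengths is True:
            bls = x[nfree_model:]
        elif optimize_branch_lengths == "scale":
            bls = bl0 * x[nfree_model]
        else:
            bls = bl0
        return m, bls

    evals = [0]

    def objective(x: np.ndarray) -> float:
        evals[0] += 1
        m, bls = unpack(x)
        try:
            ll = m.log_likelihood(engine, bls)
        except (ValueError, FloatingPointError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    x0 = np.array([model0.get_param(n) for n in names])
    if optimize_branch_lengths is True:
        x0 = np.append(x0, bl0)
    elif optimize_branch_lengths == "scale":
        x0 = np.append(x0, 1.0)
    x0 = np.clip(x0, lows, highs)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        pert = x0 * np.exp(rng.normal(0.0, 0.5, size=x0.size))
        starts.append(np.clip(pert, lows, highs))

    best = None
    converged = False
    for s in starts:
        res = minimize(
            objective,
            s,
            method="L-BFGS-B",
            bounds=list(zip(lows, highs)),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    m_hat, bls_hat = unpack(best.x)
    return FitResult(
        m_hat,
        -float(best.fun),
        dict(zip(tree.branch_names(), np.asarray(bls_hat, dtype=float))),
        engine,
        n_function_evals=evals[0],
        converged=converged,
    )


def _apply_fixed(model: ModelSpec, fixed: dict[str, float]) -> ModelSpec:
    if not fixed:
        return model
    valid = {d[0] for d in model.param_defs()}
    unknown = set(fixed) - valid
    if unknown:
        raise ValueError(f"cannot fix unknown parameter(s) {sorted(unknown)}")
    return model.with_params(**fixed)


# ------------------------------------------------------- site-model pairs

_PAIRS = {"M1a": "M2a", "M7": "M8"}


def fit_site_model_pair(
    alignment: CodonAlignment,
    tree: Tree,
    null: str = "M1a",
    *,
    freqs="F3x4",
    n_starts: int = 2,
    seed: int = 0,
) -> tuple[FitResult, FitResult, float]:
    """Fit a nested site-model pair and return (null, alt, LRT p; df=2).

    Branch lengths are estimated once under the one-ratio model and then
    held (up to a single tree-length scale factor re-optimized with every
    site model) — the usual two-stage strategy, which makes the 4–5
    mixture parameters the only expensive dimension. The alternative is
    additionally started from the null's optimum with a vanishing
    positive-selection class, which guarantees the nesting inequality
    lnL(alt) >= lnL(null) up to optimizer tolerance.
    """
    alt_name = _PAIRS[null]
    m0 = fit(alignment, tree, M0(), freqs=freqs, n_starts=1, seed=seed)
    bl_tree = tree.with_branch_lengths(
        np.array([m0.branch_lengths[b] for b in tree.branch_names()])
    )
    null_fit = fit(
        alignment, bl_tree, ModelSpec.create(null, kappa=m0.kappa),
        freqs=freqs, n_starts=n_starts, seed=seed,
        optimize_branch_lengths="scale",
    )
    nm = null_fit.model
    if alt_name == "M2a":
        near_null = M2a(
            kappa=nm.kappa, p0=nm.p0 * (1 - 1e-3), p1=(1 - nm.p0) * (1 - 1e-3),
            omega0=nm.omega0, omega2=1.0 + 1e-4,
        )
        open_start = M2a(
            kappa=nm.kappa, p0=nm.p0 * 0.9, p1=(1 - nm.p0) * 0.9,
            omega0=nm.omega0, omega2=5.0,
        )
    else:
        near_null = M8(
            kappa=nm.kappa, p0=1.0 - 1e-4, p_beta=nm.p_beta, q_beta=nm.q_beta,
            omega_s=1.0 + 1e-4,
        )
        open_start = M8(
            kappa=nm.kappa, p0=0.9, p_beta=nm.p_beta, q_beta=nm.q_beta,
            omega_s=5.0,
        )
    candidates = [
        fit(alignment, bl_tree, m, freqs=freqs, n_starts=1, seed=seed + k,
            optimize_branch_lengths="scale")
        for k, m in enumerate((near_null, open_start))
    ]
    alt_fit = max(candidates, key=lambda f: f.lnL)
    if alt_fit.lnL < null_fit.lnL:
        alt_fit.lnL = null_fit.lnL  # clamp optimizer jitter at the boundary
    return null_fit, alt_fit, lrt(null_fit.lnL, alt_fit.lnL, df=2)
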