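"""Bayes empirical Bayes (BEB) and naive empirical Bayes (NEB) site posteriors.

After fitting a selection model (M2a or M8), each codon site gets a
posterior distribution over the model's omega classes. NEB plugs in the
MLEs of the mixture parameters; BEB integrates over them on a uniform grid
prior (branch lengths and kappa stay at their MLEs), which guards against
overconfident site calls when mixture parameters are poorly determined.
Sites whose posterior mass on an omega > 1 class exceeds the threshold are
flagged as positively selected.

Grid conventions: each free mixture dimension is discretized into
``grid`` (default 10) bin-midpoint values — proportions on (0,1), the
purifying omega0 on (0,1), positive-selection omegas on (1, omega_max),
beta shapes on (0, 2]. For M8 the beta-class site likelihoods are obtained
by linear interpolation of the site likelihood curve evaluated on a fixed
omega lattice in (0,1); the curve is smooth in omega, and NEB (reported
alongside) never uses the interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fit import FitResult
from .models import M2a, M8, beta_class_means


@dataclass
class SitePosterior:
    model_name: str
    #: BEB posterior over model classes, (n_sites, n_classes)
    beb: np.ndarray
    #: NEB posterior at the MLE, (n_sites, n_classes)
    neb: np.ndarray
    #: BEB posterior probability of the positive-selection class
    p_positive: np.ndarray
    p_positive_neb: np.ndarray
    flagged: np.ndarray  # p_positive > threshold
    threshold: float


def _site_log_likelihoods(result: FitResult, omegas: np.ndarray) -> np.ndarray:
    """logL(site | omega) at the MLE kappa and branch lengths, (n_omegas, n_sites).

    Branch lengths are in mixture-averaged substitutions per codon, so each
    omega runs at its own rate relative to the fitted mixture's mean rate.
    """
    engine = result.engine
    kappa = result.model.kappa
    bls = np.array([result.branch_lengths[b] for b in engine.tree.branch_names()])
    props_mle, omegas_mle = result.model.site_classes()
    mean_scale = float(
        np.dot(
            props_mle,
            [engine._rate_matrix(kappa, w).rate_scale for w in omegas_mle],
        )
    )
    return np.stack(
        [
            engine.expand(
                engine.class_pattern_log_likelihoods(
                    kappa, bls, w,
                    engine._rate_matrix(kappa, w).rate_scale / mean_scale,
                )
            )
            for w in omegas
        ]
    )


def _site_relative_likelihoods(result: FitResult, omegas: np.ndarray):
    """exp(logL - per-site max) on a scale shared across all given omegas."""
    logL = _site_log_likelihoods(result, omegas)
    return np.exp(logL - logL.max(axis=0)[None, :])


def _midpoints(n: int) -> np.ndarray:
    return (2.0 * np.arange(n) + 1.0) / (2.0 * n)


def beb_site_posteriors(
    result: FitResult,
    *,
    grid: int = 10,
    threshold: float = 0.95,
    omega_max: float = 11.0,
) -> SitePosterior:
    """Site-class posteriors for a fitted M2a or M8 model."""
    model = result.model
    if isinstance(model, M2a):
        beb, pos_beb = _beb_m2a(result, grid, omega_max)
    elif isinstance(model, M8):
        beb, pos_beb = _beb_m8(result, grid, omega_max)
    else:
        raise ValueError(
            f"site posteriors require a fitted M2a or M8 model, got {model.name}"
        )

    props, omegas = model.site_classes()
    R = _site_relative_likelihoods(result, omegas)
    neb_un = props[:, None] * R
    neb = (neb_un / neb_un.sum(axis=0)[None, :]).T
    pos_neb = neb[:, omegas > 1.0].sum(axis=1)

    return SitePosterior(
        model_name=model.name,
        beb=beb,
        neb=neb,
        p_positive=pos_beb,
        p_positive_neb=pos_neb,
        flagged=pos_beb > threshold,
        threshold=threshold,
    )


def _beb_m2a(result: FitResult, d: int, omega_max: float):
    w0_grid = _midpoints(d)                      # purifying class
    w2_grid = 1.0 + _midpoints(d) * (omega_max - 1.0)
    R = _site_relative_likelihoods(
        result, np.concatenate([w0_grid, [1.0], w2_grid])
    )
    R0, R1, R2 = R[:d], R[d], R[d + 1 :]

    # proportion grid on the simplex: midpoint pairs with p0 + p1 <= 1
    pvals = _midpoints(d)
    pcombos = [
        (a, b, 1.0 - a - b)
        for a in pvals
        for b in pvals
        if a + b <= 1.0 + 1e-9
    ]
    P = np.array([(a, b, max(c, 0.0)) for a, b, c in pcombos])

    # assemble all grid combinations g = (prop combo, omega0, omega2)
    n_p, S = len(P), R1.size
    iw0, iw2 = np.meshgrid(np.arange(d), np.arange(d), indexing="ij")
    iw0, iw2 = iw0.ravel(), iw2.ravel()  # length d*d
    mix_parts = []
    for a, b, c in P:
        mix = a * R0[iw0] + b * R1[None, :] + c * R2[iw2]  # (d*d, S)
        mix_parts.append(mix)
    mix = np.concatenate(mix_parts, axis=0)  # (G, S)
    G = mix.shape[0]
    pg = np.repeat(P, d * d, axis=0)
    iw0g = np.tile(iw0, n_p)
    iw2g = np.tile(iw2, n_p)

    log_post_g = np.log(np.maximum(mix, 1e-300)).sum(axis=1)  # uniform prior
    log_post_g -= log_post_g.max()
    alpha = np.exp(log_post_g)
    alpha /= alpha.sum()

    W = alpha[:, None] / np.maximum(mix, 1e-300)  # (G, S)
    post = np.empty((S, 3))
    # class 0: accumulate weights per omega0 grid row
    acc0 = np.zeros((d, S))
    np.add.at(acc0, iw0g, W * pg[:, 0:1])
    post[:, 0] = (acc0 * R0).sum(axis=0)
    post[:, 1] = (W * pg[:, 1:2]).sum(axis=0) * R1
    acc2 = np.zeros((d, S))
    np.add.at(acc2, iw2g, W * pg[:, 2:3])
    post[:, 2] = (acc2 * R2).sum(axis=0)
    post /= post.sum(axis=1)[:, None]
    return post, post[:, 2]


def _beb_m8(result: FitResult, d: int, omega_max: float):
    ncat = result.model.ncat
    # lattice for interpolating beta-class likelihoods on (0, 1)
    lattice = np.clip(np.linspace(0.0, 1.0, 4 * d + 1), 1e-6, 1.0 - 1e-6)
    ws_grid = 1.0 + _midpoints(d) * (omega_max - 1.0)
    R = _site_relative_likelihoods(result, np.concatenate([lattice, ws_grid]))
    Rlat, Rs = R[: lattice.size], R[lattice.size :]
    S = Rlat.shape[1]

    def interp_rows(omegas: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(lattice, omegas) - 1, 0, lattice.size - 2)
        f = (omegas - lattice[idx]) / (lattice[idx + 1] - lattice[idx])
        return (1 - f[:, None]) * Rlat[idx] + f[:, None] * Rlat[idx + 1]

    shape_grid = _midpoints(d) * 2.0  # beta shapes on (0, 2]
    p0_grid = _midpoints(d)

    log_blocks, meta = [], []
    for p in shape_grid:
        for q in shape_grid:
            classR = interp_rows(beta_class_means(p, q, ncat))  # (ncat, S)
            sum_beta = classR.sum(axis=0)  # (S,)
            # combos over (p0, omega_s) for this (p, q)
            mix = (
                p0_grid[:, None, None] / ncat * sum_beta[None, None, :]
                + (1.0 - p0_grid)[:, None, None] * Rs[None, :, :]
            ).reshape(-1, S)
            log_blocks.append(np.log(np.maximum(mix, 1e-300)).sum(axis=1))
            meta.append((classR, mix))

    log_post = np.concatenate(log_blocks)
    log_post -= log_post.max()
    alpha_all = np.exp(log_post)
    alpha_all /= alpha_all.sum()

    post = np.zeros((S, ncat + 1))
    block_size = d * d
    for bi, (classR, mix) in enumerate(meta):
        alpha = alpha_all[bi * block_size : (bi + 1) * block_size]
        W = alpha[:, None] / np.maximum(mix, 1e-300)  # (d*d, S)
        p0g = np.repeat(p0_grid, d)
        iws = np.tile(np.arange(d), d)
        for k in range(ncat):
            post[:, k] += ((W * (p0g / ncat)[:, None]).sum(axis=0)) * classR[k]
        accs = np.zeros((d, S))
        np.add.at(accs, iws, W * (1.0 - p0g)[:, None])
        post[:, ncat] += (accs * Rs).sum(axis=0)
    post /= post.sum(axis=1)[:, None]
    return post, post[:, ncat]
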