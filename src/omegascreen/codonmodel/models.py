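"""Codon model specifications and their parameterizations.

A model spec is a concrete parameter assignment (usable directly for
simulation or likelihood evaluation) plus the metadata the optimizer needs:
which parameters are free, their bounds, and how constrained quantities
(mixture proportions) map to box-bounded coordinates.

Site-model conventions follow the standard nested pairs:

* M0      — one omega for all sites and branches.
* TwoRatio — foreground branches (tag ``#1``) get their own omega.
* M1a     — purifying class omega0 in (0,1) with weight p0, neutral class
            omega=1 with weight 1-p0.
* M2a     — M1a plus a positive-selection class omega2 >= 1, weight p2.
* M7      — omega ~ Beta(p, q), discretized into K equal-probability
            classes represented by their class means.
* M8      — Beta(p, q) with weight p0 plus a class omega_s >= 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

OMEGA_BOUNDS = (1e-4, 999.0)
OMEGA0_BOUNDS = (1e-4, 1.0 - 1e-6)   # purifying class, constrained < 1
OMEGA_POS_BOUNDS = (1.0, 999.0)      # positive-selection class, >= 1
KAPPA_BOUNDS = (0.1, 99.0)
BRANCH_BOUNDS = (1e-6, 50.0)
PROP_BOUNDS = (1e-6, 1.0 - 1e-6)
BETA_SHAPE_BOUNDS = (5e-3, 99.0)


def beta_class_means(p: float, q: float, ncat: int) -> np.ndarray:
    """Means of K equal-probability classes of Beta(p, q).

    The conditional mean over quantile bin [a, b] uses the identity
    int_a^b x f_{p,q}(x) dx = p/(p+q) * (I_b(p+1, q) - I_a(p+1, q)).
    """
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), p, q)
    upper = beta_dist.cdf(edges, p + 1.0, q)
    means = np.diff(upper) * ncat * p / (p + q)
    return np.clip(means, 1e-9, 1.0 - 1e-9)


@dataclass(frozen=True)
class ModelSpec:
    kappa: float = 2.0

    name = "base"

    # -- parameter plumbing ------------------------------------------------

    def param_defs(self) -> list[tuple[str, float, float]]:
        """(name, low, high) for every potentially-free scalar parameter."""
        raise NotImplementedError

    def get_param(self, name: str) -> float:
        return getattr(self, name)

    def with_params(self, **updates) -> "ModelSpec":
        return dataclasses.replace(self, **updates)

    # -- likelihood --------------------------------------------------------

    def site_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(proportions, omegas) of the site mixture; single class for M0."""
        raise NotImplementedError

    def branch_omegas(self, tree) -> np.ndarray | None:
        """Per-node omega vector for branch models, else None."""
        return None

    @property
    def mean_omega(self) -> float:
        props, omegas = self.site_classes()
        return float(np.dot(props, omegas))

    def log_likelihood(self, engine, branch_lengths: np.ndarray) -> float:
        bo = self.branch_omegas(engine.tree)
        if bo is not None:
            return engine.log_likelihood_single(self.kappa, branch_lengths, bo)
        props, omegas = self.site_classes()
        if len(omegas) == 1:
            bo = np.full(len(engine.tree.nodes), float(omegas[0]))
            return engine.log_likelihood_single(self.kappa, branch_lengths, bo)
        return engine.log_likelihood_mixture(self.kappa, branch_lengths, props, omegas)

    @staticmethod
    def create(name: str, **kwargs) -> "ModelSpec":
        try:
            cls = _REGISTRY[name]
        except KeyError:
            raise ValueError(f"unknown model {name!r}") from None
        return cls(**kwargs)


@dataclass(frozen=True)
class M0(ModelSpec):
    omega: float = 0.2

    name = "M0"

    def param_defs(self):
        return [("kappa", *KAPPA_BOUNDS), ("omega", *OMEGA_BOUNDS)]

    def site_classes(self):
        return np.array([1.0]), np.array([self.omega])


@dataclass(frozen=True)
class TwoRatio(ModelSpec):
    """Branch model: foreground branches (tag #1) have their own omega."""

    omega: float = 0.2        # background
    omega_fg: float = 0.2     # foreground

    name = "two-ratio"

    def param_defs(self):
        return [
            ("kappa", *KAPPA_BOUNDS),
            ("omega", *OMEGA_BOUNDS),
            ("omega_fg", *OMEGA_BOUNDS),
        ]

    def site_classes(self):  # used only for mean-omega reporting
        return np.array([1.0]), np.array([self.omega])

    def branch_omegas(self, tree) -> np.ndarray:
        tags = np.append(tree.tags(), 0)  # root entry unused
        if not (tags == 1).any():
            raise ValueError("two-ratio model requires a #1-tagged foreground branch")
        return np.where(tags == 1, self.omega_fg, self.omega)

    @property
    def mean_omega(self) -> float:
        return float(self.omega)


@dataclass(frozen=True)
class M1a(ModelSpec):
    p0: float = 0.8
    omega0: float = 0.1

    name = "M1a"

    def param_defs(self):
        return [
            ("kappa", *KAPPA_BOUNDS),
            ("p0", *PROP_BOUNDS),
            ("omega0", *OMEGA0_BOUNDS),
        ]

    def site_classes(self):
        return np.array([self.p0, 1.0 - self.p0]), np.array([self.omega0, 1.0])


@dataclass(frozen=True)
class M2a(ModelSpec):
    p0: float = 0.75
    p1: float = 0.2
    omega0: float = 0.1
    omega2: float = 3.0

    name = "M2a"

    # (p0, p1) live on a simplex; the optimizer sees the stick-breaking
    # coordinate p1_rel = p1 / (1 - p0) which is box-bounded in (0, 1).
    def param_defs(self):
        return [
            ("kappa", *KAPPA_BOUNDS),
            ("p0", *PROP_BOUNDS),
            ("p1_rel", *PROP_BOUNDS),
            ("omega0", *OMEGA0_BOUNDS),
            ("omega2", *OMEGA_POS_BOUNDS),
        ]

    def get_param(self, name: str) -> float:
        if name == "p1_rel":
            rest = max(1.0 - self.p0, 1e-12)
            return min(max(self.p1 / rest, 1e-6), 1.0 - 1e-6)
        return getattr(self, name)

    def with_params(self, **updates) -> "M2a":
        if "p1_rel" in updates:
            rel = updates.pop("p1_rel")
            p0 = updates.get("p0", self.p0)
            updates["p1"] = rel * (1.0 - p0)
        return dataclasses.replace(self, **updates)

    def site_classes(self):
        p2 = max(1.0 - self.p0 - self.p1, 0.0)
        return (
            np.array([self.p0, self.p1, p2]),
            np.array([self.omega0, 1.0, self.omega2]),
        )


@dataclass(frozen=True)
class M7(ModelSpec):
    p_beta: float = 0.5
    q_beta: float = 1.5
    ncat: int = 10

    name = "M7"

    def param_defs(self):
        return [
            ("kappa", *KAPPA_BOUNDS),
            ("p_beta", *BETA_SHAPE_BOUNDS),
            ("q_beta", *BETA_SHAPE_BOUNDS),
        ]

    def site_classes(self):
        means = beta_class_means(self.p_beta, self.q_beta, self.ncat)
        return np.full(self.ncat, 1.0 / self.ncat), means


@dataclass(frozen=True)
class M8(ModelSpec):
    p0: float = 0.9
    p_beta: float = 0.5
    q_beta: float = 1.5
    omega_s: float = 2.0
    ncat: int = 10

    name = "M8"

    def param_defs(self):
        return [
            ("kappa", *KAPPA_BOUNDS),
            ("p0", *PROP_BOUNDS),
            ("p_beta", *BETA_SHAPE_BOUNDS),
            ("q_beta", *BETA_SHAPE_BOUNDS),
            ("omega_s", *OMEGA_POS_BOUNDS),
        ]

    def site_classes(self):
        means = beta_class_means(self.p_beta, self.q_beta, self.ncat)
        props = np.append(np.full(self.ncat, self.p0 / self.ncat), 1.0 - self.p0)
        return props, np.append(means, self.omega_s)


_REGISTRY = {
    "M0": M0,
    "two-ratio": TwoRatio,
    "M1a": M1a,
    "M2a": M2a,
    "M7": M7,
    "M8": M8,
}
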