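"""The rho statistic, its standard errors, and TMRCA estimation.

rho is the mean number of mutations over all root-to-leaf paths of a
clade's genealogy,

    rho = (1/n) sum_i L_i = (1/n) sum_j n_j R_j,

where ``L_i`` is the mutation count on the path from the MRCA to leaf
``i``, ``R_j`` the mutation count on edge ``j`` and ``n_j`` the number
of leaves below edge ``j``.  Under the infinite-sites model with
per-lineage rate ``mu`` the edge counts are conditionally Poisson,
``R_j | T_j ~ Po(mu T_j)``, so E[rho] = mu*T and rho/mu is an unbiased
estimator of the TMRCA ``T``.

Three estimators of the standard error of rho are provided:

* ``ese_saillard`` — sqrt((1/n^2) sum_j n_j^2 R_j), the plug-in
  estimator of Var(rho | tree) = (1/n^2) sum_j n_j^2 mu T_j.  It
  accounts for the correlation of the L_i induced by shared edges.
* ``ese_cox`` — sqrt((1/n^2) sum_h f_h^2 l_h), the same formula applied
  to a fictitious star tree whose leaves are the distinct haplotypes
  (multiplicity f_h, root distance l_h).  This treats the per-haplotype
  mutation counts as independent, which they are not when haplotypes
  share internal edges.  The algebraic form is reconstructed here from
  its verbal characterisation ("star-like in the distinct haplotypes");
  see docs/methods.md.
* ``ese_lower`` — sqrt(rho/n), the star-genealogy lower bound.

On every tree ese_lower <= ese_cox <= ese_saillard, with equality of all
three on a star genealogy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .genealogy import (
    Genealogy,
    GenealogyError,
    edge_leaf_counts,
    haplotype_partition,
    leaf_path_counts,
)

__all__ = [
    "RhoResult",
    "AgeEstimate",
    "compute_rho",
    "rho",
    "ese_saillard",
    "ese_cox",
    "ese_lower",
    "estimate_age",
    "age_from_rho",
    "age_se_delta",
    "SE_METHODS",
]

SE_METHODS = ("saillard", "cox", "lower")


@dataclass
class RhoResult:
    """rho with its three estimated standard errors and edge bookkeeping."""

    rho: float
    n: int
    ese_saillard: float
    ese_cox: float
    ese_lower: float
    #: per-edge rows (edge label or child id, n_j, R_j)
    per_edge: list[tuple[str, int, int]]

    def ese(self, method: str) -> float:
        if method not in SE_METHODS:
            raise ValueError(f"unknown se_method {method!r}")
        return getattr(self, f"ese_{method}")


@dataclass
class AgeEstimate:
    """A TMRCA point estimate rho/mu with a Wald confidence interval."""

    t_hat: float
    ci_low: float
    ci_high: float
    level: float
    se_method: str
    mu: float
    rho: float
    ese_rho: float
    se_mu: float | None = None
    #: delta-method SE of t_hat, set when se_mu is given
    se_t_hat_delta: float | None = None


def compute_rho(g: Genealogy) -> RhoResult:
    """rho and all three standard errors in one pass over the tree.

    rho is computed both as the mean of the leaf path counts and as the
    edge-weighted sum (1/n) sum_j n_j R_j; the two integer totals must
    agree exactly.
    """
    n = g.n_leaves
    if n == 1 and not g.has_mutations and g.root.is_leaf:
        return RhoResult(0.0, 1, 0.0, 0.0, 0.0, [])
    if not g.has_mutations:
        raise GenealogyError("tree carries no mutation counts")

    L = leaf_path_counts(g)
    nj = edge_leaf_counts(g)
    leaf_total = sum(L.values())
    edge_total = sum(c * node.mutations for node, c in nj.items())
    if leaf_total != edge_total:  # pragma: no cover - structural safeguard
        raise AssertionError(
            f"leaf-form ({leaf_total}) and edge-form ({edge_total}) of rho disagree"
        )
    rho_val = leaf_total / n

    var_saillard = sum(c * c * node.mutations for node, c in nj.items()) / (n * n)
    part = haplotype_partition(g)
    var_cox = sum(
        b.multiplicity**2 * b.root_distance for b in part.blocks
    ) / (n * n)
    per_edge = [
        (node.label if node.label is not None else f"edge{k}", c, node.mutations)
        for k, (node, c) in enumerate(nj.items())
    ]
    return RhoResult(
        rho=rho_val,
        n=n,
        ese_saillard=math.sqrt(var_saillard),
        ese_cox=math.sqrt(var_cox),
        ese_lower=math.sqrt(rho_val / n),
        per_edge=per_edge,
    )


def rho(g: Genealogy) -> float:
    """Mean mutation count over all root-to-leaf paths."""
    return compute_rho(g).rho


def ese_saillard(g: Genealogy) -> float:
    """Edge-weighted e.s.e. of rho: sqrt((1/n^2) sum_j n_j^2 R_j)."""
    return compute_rho(g).ese_saillard


def ese_cox(g: Genealogy) -> float:
    """Distinct-haplotype star e.s.e.: sqrt((1/n^2) sum_h f_h^2 l_h)."""
    return compute_rho(g).ese_cox


def ese_lower(g: Genealogy) -> float:
    """Star-genealogy lower bound sqrt(rho/n)."""
    return compute_rho(g).ese_lower


def age_from_rho(
    result: RhoResult,
    mu: float,
    se_method: str = "saillard",
    level: float = 0.95,
    se_mu: float | None = None,
    clamp_zero: bool = False,
) -> AgeEstimate:
    """Wald age estimate (rho +/- z*e.s.e.)/mu from a precomputed RhoResult.

    ``z`` is the exact two-sided standard-normal quantile for ``level``
    (1.959964 at 0.95).  The lower CI end is not truncated at zero
    unless ``clamp_zero`` is set; coverage studies must evaluate the
    Wald interval as defined.
    """
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    ese = result.ese(se_method)
    z = norm.ppf(0.5 + level / 2)
    t_hat = result.rho / mu
    ci_low = (result.rho - z * ese) / mu
    ci_high = (result.rho + z * ese) / mu
    if clamp_zero:
        ci_low = max(ci_low, 0.0)
    se_delta = None
    if se_mu is not None:
        se_delta = age_se_delta(result.rho, ese, mu, se_mu)
    return AgeEstimate(
        t_hat=t_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        se_method=se_method,
        mu=mu,
        rho=result.rho,
        ese_rho=ese,
        se_mu=se_mu,
        se_t_hat_delta=se_delta,
    )


def estimate_age(
    g: Genealogy,
    mu: float,
    se_method: str = "saillard",
    level: float = 0.95,
    se_mu: float | None = None,
    clamp_zero: bool = False,
) -> AgeEstimate:
    """Estimate the clade TMRCA as rho/mu with a Wald interval."""
    return age_from_rho(
        compute_rho(g), mu, se_method=se_method, level=level, se_mu=se_mu,
        clamp_zero=clamp_zero,
    )


def age_se_delta(rho: float, ese_rho: float, mu: float, se_mu: float) -> float:
    """First-order delta-method SE of the age rho/mu with uncertain mu.

    Treats rho and the rate estimate as independent:

        SE(t_hat) = sqrt( ese_rho^2/mu^2 + rho^2 * se_mu^2 / mu^4 ).
    """
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if se_mu < 0:
        raise ValueError(f"se_mu must be non-negative, got {se_mu}")
    return math.sqrt(ese_rho**2 / mu**2 + rho**2 * se_mu**2 / mu**4)
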