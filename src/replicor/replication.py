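"""Bayes factors and posterior inference for replication tests of correlations.

A replication test compares the data's support for a correlation (H1) against
the point null rho = 0, under two priors:

* a one-sided uniform prior on (0, 1) or (-1, 0) -- the "naive" analysis --
  or a two-sided uniform on (-1, 1) when the expected direction is unknown;
* an informed prior: the posterior over rho obtained by updating a two-sided
  uniform base prior with the original study's likelihood, so that the
  resulting combined posterior is identical to analysing both datasets
  jointly.

Likelihood convention
---------------------
``BF_CONVENTION = "df"`` evaluates the exact r-density at an effective
sample size of n - 1 (the degrees of freedom of the correlation after
centering).  This is the convention under which the package reproduces
published replication Bayes factors computed with the widely circulated
R implementations; pass ``likelihood="n"`` to use the raw sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import RhoGrid, StudySummary, default_grid, null_density, r_density

__all__ = [
    "ReplicationResult",
    "uniform_prior",
    "likelihood_grid",
    "posterior_from_data",
    "bf10_uniform",
    "bf10_informed",
    "map_estimate",
    "credible_interval",
    "savage_dickey_bf",
    "evidence_label",
    "replication_result",
]

BF_CONVENTION = "df"


def _effective_n(n: int, likelihood: str) -> float:
    if likelihood == "df":
        return n - 1.0
    if likelihood == "n":
        return float(n)
    raise ValueError(f"likelihood must be 'df' or 'n', got {likelihood!r}")


@dataclass
class ReplicationResult:
    """Everything one replication test reports: both Bayes factors, the
    combined two-study posterior, its mode (MAP) and 95% equal-tailed
    credible interval."""

    label: str
    bf10_uniform: float
    bf10_informed: float | None
    posterior: RhoGrid
    map: float
    ci_low: float
    ci_high: float

    @property
    def evidence_uniform(self) -> str:
        return evidence_label(self.bf10_uniform)

    @property
    def evidence_informed(self) -> str | None:
        return None if self.bf10_informed is None else evidence_label(self.bf10_informed)


def uniform_prior(side: int = 0, nodes: np.ndarray | None = None) -> RhoGrid:
    """Uniform prior over rho: on (0,1) for side=+1, (-1,0) for side=-1,
    (-1,1) for side=0 (two-sided)."""
    if side not in (-1, 0, 1):
        raise ValueError(f"side must be -1, 0 or +1, got {side!r}")
    nodes = default_grid() if nodes is None else np.asarray(nodes, float)
    dens = np.ones_like(nodes)
    if side == 1:
        dens[nodes <= 0] = 0.0
    elif side == -1:
        dens[nodes >= 0] = 0.0
    return RhoGrid(nodes, dens).normalize()


def likelihood_grid(study: StudySummary, nodes: np.ndarray | None = None,
                    likelihood: str = BF_CONVENTION) -> np.ndarray:
    """The r-likelihood of ``study`` evaluated over a rho grid."""
    nodes = default_grid() if nodes is None else np.asarray(nodes, float)
    return r_density(study.r_obs, nodes, _effective_n(study.n, likelihood))


def posterior_from_data(study: StudySummary, prior: RhoGrid,
                        likelihood: str = BF_CONVENTION) -> RhoGrid:
    """Update ``prior`` with the likelihood of ``study``: the normalised
    grid proportional to prior(rho) * f(r_obs | rho, n)."""
    if prior.integral() <= 0:
        raise ValueError("degenerate prior: zero total mass")
    like = likelihood_grid(study, prior.nodes, likelihood)
    return prior.multiply(like).normalize()


def _marginal_likelihood(study: StudySummary, prior: RhoGrid, likelihood: str) -> float:
    like = likelihood_grid(study, prior.nodes, likelihood)
    return float(np.trapezoid(like * prior.density, prior.nodes))


def bf10_uniform(study: StudySummary, side: int | None = None,
                 likelihood: str = BF_CONVENTION) -> float:
    """BF10 under a uniform prior on rho.

    ``side`` defaults to the study's expected direction; +1 / -1 select the
    one-sided priors on (0,1) / (-1,0), 0 the two-sided uniform on (-1,1)
    used when the direction is unknown.
    """
    side = study.direction if side is None else side
    prior = uniform_prior(side)
    marg = _marginal_likelihood(study, prior, likelihood)
    return marg / null_density(study.r_obs, _effective_n(study.n, likelihood))


def bf10_informed(original: StudySummary, replication: StudySummary,
                  likelihood: str = BF_CONVENTION) -> float:
    """Replication BF10 with the original study's posterior as the prior.

    The informed prior is the posterior of rho given the original result
    under a two-sided uniform base prior (so credible intervals of the
    combined posterior may span zero even for directional hypotheses).
    """
    informed = posterior_from_data(original, uniform_prior(0), likelihood)
    marg = _marginal_likelihood(replication, informed, likelihood)
    return marg / null_density(replication.r_obs, _effective_n(replication.n, likelihood))


def map_estimate(dist: RhoGrid) -> float:
    """Mode of a grid density, refined by quadratic interpolation through
    the argmax and its neighbours.  A flat density reports the support
    midpoint and appends a flag to ``dist.flags``."""
    d = dist.density
    if np.allclose(d, d[0]):
        dist.flags.append("flat density: MAP reported as support midpoint")
        return float(0.5 * (dist.nodes[0] + dist.nodes[-1]))
    i = int(np.argmax(d))
    if i == 0 or i == len(d) - 1:
        return float(dist.nodes[i])
    a, b, c = d[i - 1], d[i], d[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:  # numerically flat around the peak
        return float(dist.nodes[i])
    h = dist.nodes[i + 1] - dist.nodes[i]
    return float(dist.nodes[i] + 0.5 * h * (a - c) / denom)


def credible_interval(dist: RhoGrid, mass: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval: quantiles at (1-mass)/2 and
    1-(1-mass)/2 by inverse-CDF interpolation on the grid."""
    if not 0 < mass < 1:
        raise ValueError(f"mass must be in (0, 1), got {mass!r}")
    tail = 0.5 * (1.0 - mass)
    lo, hi = dist.quantile([tail, 1.0 - tail])
    return float(lo), float(hi)


def savage_dickey_bf(prior: RhoGrid, posterior: RhoGrid) -> float:
    """BF10 for the point null rho = 0 as the prior/posterior density ratio
    at zero (Savage-Dickey).  A one-sided prior with zero density at the
    origin is evaluated as a one-sided limit and flagged."""
    if not np.array_equal(prior.nodes, posterior.nodes):
        raise ValueError("prior and posterior must share grid nodes")
    p0 = prior.at(0.0)
    q0 = posterior.at(0.0)
    if p0 <= 0:
        # one-sided prior: take the limiting density approaching 0 from the
        # supported side
        side = 1 if prior.density[prior.nodes > 0].sum() > 0 else -1
        eps = 1e-4
        p0 = prior.at(side * eps)
        q0 = posterior.at(side * eps)
        prior.flags.append("zero prior density at 0: one-sided limit used")
    if q0 <= 0:
        return np.inf
    return p0 / q0


#: Bayes-factor evidence categories (Wetzels-style labels); thresholds are
#: on BF10, mirrored below 1 for evidence favouring the null.
_EVIDENCE_BINS = [(100.0, "extreme"), (30.0, "very strong"), (10.0, "strong"),
                  (3.0, "substantial"), (1.0, "anecdotal")]


def evidence_label(bf10: float) -> str:
    """Verbal evidence category for a BF10 (direction H1 vs H0)."""
    if bf10 <= 0 or not np.isfinite(bf10):
        raise ValueError(f"BF10 must be a positive finite number, got {bf10!r}")
    if bf10 == 1:
        return "no evidence"
    favours_null = bf10 < 1
    b = 1.0 / bf10 if favours_null else bf10
    for cut, name in _EVIDENCE_BINS:
        if b > cut:
            label = name
            break
    else:  # 1 < b <= 3
        label = "anecdotal"
    return f"{label} for H0" if favours_null else f"{label} for H1"


def replication_result(original: StudySummary | None, replication: StudySummary,
                       likelihood: str = BF_CONVENTION,
                       mass: float = 0.95) -> ReplicationResult:
    """Full replication analysis for one original/replication pair.

    With ``original=None`` (direction-unknown rows with no published
    original correlation) only the uniform-prior BF is computed and the
    posterior is the replication-only posterior under the two-sided uniform.
    """
    bf_u = bf10_uniform(replication)
    if original is None:
        post = posterior_from_data(replication, uniform_prior(0), likelihood)
        bf_i = None
    else:
        informed = posterior_from_data(original, uniform_prior(0), likelihood)
        post = posterior_from_data(replication, informed, likelihood)
        bf_i = bf10_informed(original, replication, likelihood)
    lo, hi = credible_interval(post, mass)
    return ReplicationResult(
        label=replication.label, bf10_uniform=bf_u, bf10_informed=bf_i,
        posterior=post, map=map_estimate(post), ci_low=lo, ci_high=hi,
    )
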