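"""Exact sampling distribution of the Pearson correlation coefficient.

The density of the sample correlation ``r`` from ``n`` bivariate-normal
observations with population correlation ``rho`` (Hotelling's hypergeometric
form) is the likelihood kernel behind every Bayes factor and posterior in
this package.  It is implemented in log space, which is numerically stable
for every sample size used in practice (checked up to n = 10^4), so no
arbitrary-precision fallback is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

__all__ = [
    "StudySummary",
    "RhoGrid",
    "default_grid",
    "log_r_density",
    "r_density",
    "null_density",
]

#: grid convention used for all rho integrals downstream: 4001 equally spaced
#: nodes on [-0.9999, 0.9999], trapezoid rule.  Reproduces published Bayes
#: factors to 2-3 significant figures in well under a second.
GRID_SIZE = 4001
GRID_BOUND = 0.9999


@dataclass(frozen=True)
class StudySummary:
    """A published (or simulated) correlation result.

    Parameters
    ----------
    r_obs : float
        Observed Pearson correlation, strictly inside (-1, 1).
    n : int
        Number of participants; at least 4 (the density exponent
        (n - 4)/2 degenerates below that).
    direction : int
        Expected sign of the correlation: +1, -1, or 0 for two-sided /
        direction unknown.
    label : str
        Free-text identifier.
    """

    r_obs: float
    n: int
    direction: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.r_obs) or abs(self.r_obs) >= 1:
            raise ValueError(f"|r_obs| must be < 1, got {self.r_obs!r}")
        if int(self.n) != self.n or self.n < 4:
            raise ValueError(f"n must be an integer >= 4, got {self.n!r}")
        if self.direction not in (-1, 0, 1):
            raise ValueError(f"direction must be -1, 0 or +1, got {self.direction!r}")


@dataclass
class RhoGrid:
    """A discretised density over the population correlation rho on (-1, 1).

    ``nodes`` are strictly increasing and strictly inside (-1, 1);
    ``density`` is nonnegative.  When ``normalized`` is True the trapezoid
    integral of ``density`` over ``nodes`` is 1 (to 1e-6).
    """

    nodes: np.ndarray
    density: np.ndarray
    normalized: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.nodes.ndim != 1 or self.nodes.shape != self.density.shape:
            raise ValueError("nodes and density must be 1-D arrays of equal length")
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if self.nodes[0] <= -1 or self.nodes[-1] >= 1:
            raise ValueError("nodes must lie strictly inside (-1, 1)")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    # -- mass and normalisation -------------------------------------------

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.nodes))

    def normalize(self) -> "RhoGrid":
        z = self.integral()
        if z <= 0 or not np.isfinite(z):
            raise ValueError("cannot normalize a grid with zero/non-finite mass")
        return replace(self, density=self.density / z, normalized=True)

    # -- evaluation --------------------------------------------------------

    def at(self, rho: float) -> float:
        """Linearly interpolated density at ``rho`` (0 outside the nodes)."""
        return float(np.interp(rho, self.nodes, self.density, left=0.0, right=0.0))

    def cdf(self) -> np.ndarray:
        """Cumulative trapezoid integral at each node (monotone, ends at 1)."""
        incr = 0.5 * (self.density[1:] + self.density[:-1]) * np.diff(self.nodes)
        cdf = np.concatenate([[0.0], np.cumsum(incr)])
        return cdf / cdf[-1]

    def quantile(self, p) -> np.ndarray:
        return np.interp(p, self.cdf(), self.nodes)

    def mean(self) -> float:
        return float(np.trapezoid(self.nodes * self.density, self.nodes)) / self.integral()

    def multiply(self, other_density: np.ndarray) -> "RhoGrid":
        return RhoGrid(self.nodes, self.density * np.asarray(other_density, float))


def default_grid() -> np.ndarray:
    """The shared rho grid: 4001 nodes on [-0.9999, 0.9999]."""
    return np.linspace(-GRID_BOUND, GRID_BOUND, GRID_SIZE)


def _validate(r_obs: float, rho, n: float) -> None:
    rho = np.asarray(rho, dtype=float)
    if not np.isfinite(r_obs) or abs(r_obs) >= 1:
        raise ValueError(f"|r_obs| must be < 1, got {r_obs!r}")
    if np.any(~np.isfinite(rho)) or np.any(np.abs(rho) >= 1):
        raise ValueError("|rho| must be < 1")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n!r}")


def log_r_density(r_obs: float, rho, n: float) -> np.ndarray:
    """Log of the exact density of the sample correlation.

    ``rho`` may be a scalar or an array; the result is broadcast over it.
    ``n`` is the bivariate-normal sample size (n >= 4; non-integer values
    are accepted so callers may apply a degrees-of-freedom convention).
    """
    _validate(r_obs, rho, n)
    rho = np.asarray(rho, dtype=float)
    log_norm = (
        np.log(n - 2.0)
        + special.gammaln(n - 1.0)
        - 0.5 * np.log(2.0 * np.pi)
        - special.gammaln(n - 0.5)
    )
    log_kernel = (
        0.5 * (n - 1.0) * np.log1p(-rho * rho)
        + 0.5 * (n - 4.0) * np.log1p(-r_obs * r_obs)
        - (n - 1.5) * np.log1p(-rho * r_obs)
    )
    # Gauss hypergeometric argument (1 + rho*r)/2 lies in (0, 1): convergent
    # and well-conditioned for all admissible inputs.
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (1.0 + rho * r_obs))
    return log_norm + log_kernel + np.log(hyp)


def r_density(r_obs: float, rho, n: float) -> np.ndarray:
    """Exact density of observing ``r_obs`` in a sample of size ``n``
    when the population correlation is ``rho`` (bivariate normality)."""
    return np.exp(log_r_density(r_obs, rho, n))


def null_density(r_obs, n: float):
    """Density of the sample correlation under rho = 0 (closed form).

    ``f(r | 0, n) = (1 - r^2)^((n-4)/2) / B(1/2, (n-2)/2)`` -- the H0
    marginal likelihood in every Bayes factor.  ``r_obs`` may be an array.
    """
    r = np.asarray(r_obs, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r_obs| must be < 1")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n!r}")
    log_f = 0.5 * (n - 4.0) * np.log1p(-r * r) - special.betaln(0.5, 0.5 * (n - 2.0))
    out = np.exp(log_f)
    return float(out) if np.isscalar(r_obs) else out
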