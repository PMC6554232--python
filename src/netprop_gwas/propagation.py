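"""Random walk with restart over a degree-normalized network.

Seed scores F0 spread to network neighbors by iterating

    F_{t+1} = alpha * W' * F_t + (1 - alpha) * F0

where W' is the degree-normalized adjacency and ``alpha`` in [0, 1)
trades diffusion against restarting at the seeds.  The iteration
contracts (spectral radius of alpha*W' is below 1 for both supported
normalizations), so it converges to the unique fixed point

    F* = (1 - alpha) * (I - alpha * W')^{-1} * F0,

which :func:`propagate_closed_form` computes by direct linear solve as
an exact cross-check on small graphs.  Under column-stochastic
normalization the iteration conserves the total score: each column of
W' sums to 1, so sum(F_{t+1}) = alpha*sum(F_t) + (1-alpha)*sum(F0)
stays at sum(F0) for every t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, InputError
from .network_io import PropagationNetwork

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("column-stochastic", "symmetric")


@dataclass(frozen=True)
class PropagationConfig:
    """Free parameters of the restart walk.

    Attributes
    ----------
    alpha : float
        Diffusion weight in [0, 1); 0 returns the seeds unchanged.
    tol : float
        L1 convergence threshold on successive iterates.
    max_iter : int
        Iteration cap; exceeding it returns ``converged=False``.
    normalization : str
        ``column-stochastic`` (W D^-1, conserves total score) or
        ``symmetric`` (D^-1/2 W D^-1/2).
    """

    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    normalization: str = "column-stochastic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ConfigurationError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigurationError(
                f"normalization must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )


@dataclass
class PropagationResult:
    """Outcome of the iterative solve."""

    final_scores: np.ndarray
    iterations: int
    residual: float
    converged: bool
    #: L1 change at each iteration, for convergence diagnostics.
    residuals: list[float] = field(default_factory=list)
    #: total score after each iteration (conservation diagnostics).
    iterate_sums: list[float] = field(default_factory=list)


def normalize_adjacency(
    network: PropagationNetwork, mode: str = "column-stochastic"
) -> sp.csr_matrix:
    """Build the transition operator W' from the adjacency matrix.

    ``column-stochastic``: entry (i, j) = w_ij / degree(j), every column
    sums to 1.  ``symmetric``: entry (i, j) = w_ij / sqrt(d_i * d_j).
    Node order is preserved.  Degrees must all be positive (isolates are
    removed at load time).
    """
    if mode not in NORMALIZATIONS:
        raise ConfigurationError(f"unknown normalization {mode!r}")
    deg = network.degree
    if network.n_nodes == 0:
        raise InputError("normalize_adjacency: empty network")
    if np.any(deg <= 0):
        raise InputError("normalize_adjacency: zero-degree node encountered; "
                         "isolates must be removed before propagation")
    adj = network.adjacency.tocsc()
    if mode == "column-stochastic":
        inv = sp.diags(1.0 / deg)
        return (adj @ inv).tocsr()
    inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return (inv_sqrt @ adj @ inv_sqrt).tocsr()


def propagate(
    operator: sp.spmatrix,
    seeds: np.ndarray,
    config: PropagationConfig | None = None,
) -> PropagationResult:
    """Iterate the restart walk to its fixed point.

    Stops when the L1 change between successive iterates drops to
    ``config.tol`` or after ``config.max_iter`` iterations (the latter
    returns ``converged=False`` with a warning rather than raising).
    """
    if config is None:
        config = PropagationConfig()
    seeds = np.asarray(seeds, dtype=float)
    if seeds.ndim != 1 or seeds.shape[0] != operator.shape[0]:
        raise InputError(
            f"seed vector of length {seeds.shape} does not match operator {operator.shape}"
        )
    if np.any(seeds < 0):
        raise InputError("propagate: seed vector has negative entries")
    if not np.any(seeds > 0):
        raise InputError("propagate: all-zero seed vector")

    alpha = config.alpha
    f = seeds.copy()
    residuals: list[float] = []
    sums: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        f_next = alpha * (operator @ f) + (1.0 - alpha) * seeds
        res = float(np.abs(f_next - f).sum())
        f = f_next
        residuals.append(res)
        sums.append(float(f.sum()))
        if res <= config.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "propagate: not converged after %d iterations (residual %.3g > tol %.3g)",
            config.max_iter, residuals[-1], config.tol,
        )
    return PropagationResult(
        final_scores=f,
        iterations=it,
        residual=residuals[-1],
        converged=converged,
        residuals=residuals,
        iterate_sums=sums,
    )


def propagate_closed_form(
    operator: sp.spmatrix, seeds: np.ndarray, alpha: float
) -> np.ndarray:
    """Exact fixed point (1-alpha)(I - alpha W')^{-1} F0 by dense solve.

    Intended as a verification oracle and for small graphs (up to a few
    thousand nodes); the iterative solver is the scalable path.
    """
    if not (0.0 <= alpha < 1.0):
        raise ConfigurationError(f"alpha must lie in [0, 1), got {alpha}")
    seeds = np.asarray(seeds, dtype=float)
    n = operator.shape[0]
    dense = operator.toarray() if sp.issparse(operator) else np.asarray(operator)
    system = np.eye(n) - alpha * dense
    solution = np.linalg.solve(system, seeds)
    return (1.0 - alpha) * solution
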