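"""NARROMI-style gene regulatory network inference.

Two complementary filters are combined.  Mutual information between gene
pairs (plug-in estimate on equal-frequency bins) screens out noisy,
weakly dependent regulator candidates.  For each target gene, the
surviving candidates then enter a recursive-optimization regression: the
steady-state linearization of a kinetic transcription model makes the
target a linear combination of its regulators, fitted by least absolute
deviations with an L1 penalty (a linear program); the regulator of
smallest coefficient magnitude is removed and the fit re-solved for as
long as the residual does not degrade beyond a tolerance, leaving a
minimal direct-regulator set.  The two strengths are merged per edge as

    beta = sign(beta_RO) * (omega * |beta_RO| + (1 - omega) * beta_MI)

with the MI term min-max scaled to [0, 1] across all screened pairs so
the two summands are commensurable, and edges with |beta| below a final
threshold are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from sklearn.metrics import mutual_info_score

logger = logging.getLogger("dnbpipe")

__all__ = [
    "RegulatoryEdge",
    "InferredNetwork",
    "mutual_information",
    "mi_matrix",
    "mi_null_quantile",
    "mi_screen",
    "ro_regression",
    "combine_strength",
    "infer_network",
]


@dataclass(frozen=True)
class RegulatoryEdge:
    """One directed regulation regulator -> target.

    ``beta_mi`` is the (scaled, non-negative) mutual-information
    strength, ``beta_ro`` the signed regression strength, ``beta`` their
    combination under weight ``omega``.
    """

    regulator: str
    target: str
    beta_mi: float
    beta_ro: float
    beta: float
    omega: float

    def __post_init__(self) -> None:
        if self.beta_mi < 0:
            raise ValueError("beta_mi must be non-negative")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must lie in [0, 1]")
        expected = combine_strength(self.beta_ro, self.beta_mi, self.omega)
        if abs(self.beta - expected) > 1e-9:
            raise ValueError("beta inconsistent with its components")


@dataclass(frozen=True)
class InferredNetwork:
    """Edges surviving the final |beta| threshold, over a node set."""

    nodes: tuple[str, ...]
    edges: tuple[RegulatoryEdge, ...]
    threshold: float

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.regulator == e.target:
                raise ValueError("self-edges are not allowed")
            if e.regulator not in node_set or e.target not in node_set:
                raise ValueError("edge endpoint outside the node set")
            if abs(e.beta) < self.threshold - 1e-12:
                raise ValueError("edge below the retention threshold")


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value a bin label so bin counts differ by at most 1.

    Rank-based (stable on ties), which makes the label distribution —
    and hence the null MI distribution — depend only on (n, bins).
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = (np.arange(n) * bins) // n
    return labels


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Plug-in mutual information of two samples, in nats.

    Each variable is discretized into ``bins`` equal-frequency bins and
    MI is computed from the joint histogram.  Symmetric in (x, y) and
    non-negative; a constant vector gives 0 by convention (its single
    bin carries no information).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    lx = _equal_frequency_bins(x, bins)
    ly = _equal_frequency_bins(y, bins)
    return float(mutual_info_score(lx, ly))


def mi_matrix(expr: np.ndarray, bins: int | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise MI between the rows of ``expr``."""
    expr = np.asarray(expr, dtype=float)
    G, n = expr.shape
    if bins is None:
        bins = max(2, int(np.ceil(np.sqrt(n))))
    labels = [_equal_frequency_bins(expr[i], bins) for i in range(G)]
    out = np.zeros((G, G))
    for i in range(G):
        if np.ptp(expr[i]) == 0:
            continue
        for j in range(i + 1, G):
            if np.ptp(expr[j]) == 0:
                continue
            out[i, j] = out[j, i] = mutual_info_score(labels[i], labels[j])
    return out


def mi_null_quantile(
    n_samples: int, bins: int, quantile: float = 0.95,
    n_perm: int = 200, seed: int = 0,
) -> float:
    """Null quantile of the plug-in MI between independent variables.

    With equal-frequency binning the null joint histogram is a uniform
    random pairing of fixed margins, so the null depends only on the
    sample count and bin count; ``n_perm`` random pairings are simulated.
    """
    rng = np.random.default_rng(seed)
    base = (np.arange(n_samples) * bins) // n_samples
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = mutual_info_score(base, rng.permutation(base))
    return float(np.quantile(null, quantile))


def mi_screen(
    expr: np.ndarray,
    mi_threshold: float | None = None,
    bins: int | None = None,
    null_quantile: float = 0.95,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Candidate regulators per target by an MI cutoff.

    For each target gene, keeps as candidates the genes (self excluded)
    whose MI with the target reaches the threshold.  With
    ``mi_threshold=None`` the cutoff is the ``null_quantile`` of the
    permutation null for independent pairs.  Returns the per-target
    candidate index arrays and the full MI matrix.
    """
    expr = np.asarray(expr, dtype=float)
    G, n = expr.shape
    if n < 4:
        raise ValueError("MI screening needs at least 4 samples")
    if bins is None:
        bins = max(2, int(np.ceil(np.sqrt(n))))
    mi = mi_matrix(expr, bins=bins)
    if mi_threshold is None:
        mi_threshold = mi_null_quantile(n, bins, quantile=null_quantile, seed=seed)
        logger.info("MI screen: permutation-null threshold %.4g", mi_threshold)
    candidates = []
    for t in range(G):
        cand = np.flatnonzero(mi[t] >= mi_threshold)
        candidates.append(cand[cand != t])
    return candidates, mi


def ro_regression(
    target: np.ndarray,
    regulators: np.ndarray,
    lam: float = 0.01,
    delta_fit: float = 0.05,
) -> np.ndarray:
    """Signed regulatory strengths by recursive sparse LAD regression.

    Fits (centered) target = regulators' beta by minimizing the sum of
    absolute residuals plus ``lam`` times the L1 norm of beta, solved as
    a linear program.  Then repeatedly drops the regulator of smallest
    |beta| and re-solves; a removal is kept while the absolute-residual
    sum stays within a factor (1 + ``delta_fit``) of the full-model fit.
    Removed regulators get strength 0.  Deterministic: the LP is solved
    with scipy's HiGHS dual simplex.

    Parameters
    ----------
    target : (n,) sample vector of the regulated gene.
    regulators : (p, n) candidate-regulator matrix (rows = genes).
    """
    y = np.asarray(target, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(regulators, dtype=float))
    p, n = X.shape
    if y.size != n:
        raise ValueError("target and regulators must share the sample axis")
    if p < 1 or n < 2:
        raise ValueError("need at least one regulator and two samples")
    y = y - y.mean()
    X = X - X.mean(axis=1, keepdims=True)

    def solve(active: list[int]) -> tuple[np.ndarray, float]:
        """LAD + L1 fit on the active regulator subset -> (beta, residual)."""
        if not active:
            return np.zeros(0), float(np.abs(y).sum())
        Xa = X[active].T  # n x k
        k = Xa.shape[1]
        # variables: beta+ (k), beta- (k), t (n); minimize 1't + lam 1'(b+ + b-)
        c = np.concatenate([np.full(2 * k, lam), np.ones(n)])
        A_ub = np.block([
            [-Xa, Xa, -np.eye(n)],   # t >= y - Xa b
            [Xa, -Xa, -np.eye(n)],   # t >= Xa b - y
        ])
        b_ub = np.concatenate([-y, y])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, method="highs-ds")
        if not res.success:
            raise RuntimeError(f"RO regression LP failed: {res.message}")
        beta = res.x[:k] - res.x[k:2 * k]
        residual = float(np.abs(y - Xa @ beta).sum())
        return beta, residual

    active = list(range(p))
    beta, baseline = solve(active)
    tol = baseline * (1.0 + delta_fit) + 1e-9
    while active:
        drop = int(np.argmin(np.abs(beta)))
        trial = active[:drop] + active[drop + 1:]
        beta_trial, resid_trial = solve(trial)
        if resid_trial <= tol:
            active, beta = trial, beta_trial
        else:
            break
    out = np.zeros(p)
    out[active] = beta
    return out


def combine_strength(beta_ro: float, beta_mi: float, omega: float) -> float:
    """beta = sign(beta_RO) * (omega * |beta_RO| + (1 - omega) * beta_MI).

    ``sign(0)`` is 0, so a regulator eliminated by the RO step carries no
    combined strength regardless of its MI.
    """
    if not 0 <= omega <= 1:
        raise ValueError("omega must lie in [0, 1]")
    if beta_mi < 0:
        raise ValueError("beta_mi must be non-negative")
    return float(np.sign(beta_ro) * (omega * abs(beta_ro) + (1 - omega) * beta_mi))


def infer_network(
    expr: np.ndarray,
    gene_ids,
    bins: int | None = None,
    mi_threshold: float | None = None,
    null_quantile: float = 0.95,
    lam: float = 0.01,
    omega: float = 0.5,
    beta_threshold: float = 0.05,
    delta_fit: float = 0.05,
    seed: int = 0,
) -> InferredNetwork:
    """Full inference: MI screen, per-target RO regression, combination.

    ``expr`` is genes x samples (the transition-window case samples,
    typically pooled across neighboring windows to reach a workable n).
    MI values are min-max scaled to [0, 1] over all screened pairs before
    combination.  A pair supported in both directions yields two edges.
    """
    expr = np.asarray(expr, dtype=float)
    gene_ids = list(gene_ids)
    G, n = expr.shape
    if G != len(gene_ids):
        raise ValueError("gene_ids length must match the matrix rows")
    if G < 2 or n < 4:
        raise ValueError("need at least 2 genes and 4 samples")
    if not 0 <= omega <= 1:
        raise ValueError("omega must lie in [0, 1]")

    candidates, mi = mi_screen(
        expr, mi_threshold=mi_threshold, bins=bins,
        null_quantile=null_quantile, seed=seed,
    )
    screened_mi = [mi[t, cand] for t, cand in enumerate(candidates)]
    pooled = np.concatenate([v for v in screened_mi if v.size]) if any(
        v.size for v in screened_mi
    ) else np.array([])
    if pooled.size:
        lo, hi = float(pooled.min()), float(pooled.max())
        span = hi - lo
    else:
        lo, span = 0.0, 0.0

    edges: list[RegulatoryEdge] = []
    for t, cand in enumerate(candidates):
        if cand.size == 0:
            continue
        beta_ro = ro_regression(expr[t], expr[cand], lam=lam, delta_fit=delta_fit)
        for j, reg in enumerate(cand):
            mi_scaled = (mi[t, reg] - lo) / span if span > 0 else (1.0 if pooled.size else 0.0)
            beta = combine_strength(beta_ro[j], mi_scaled, omega)
            if abs(beta) >= beta_threshold:
                edges.append(
                    RegulatoryEdge(
                        regulator=gene_ids[reg],
                        target=gene_ids[t],
                        beta_mi=mi_scaled,
                        beta_ro=float(beta_ro[j]),
                        beta=beta,
                        omega=omega,
                    )
                )
    edges.sort(key=lambda e: (-abs(e.beta), e.regulator, e.target))
    logger.info("inferred %d edges over %d genes (|beta| >= %g)",
                len(edges), G, beta_threshold)
    return InferredNetwork(nodes=tuple(gene_ids), edges=tuple(edges),
                           threshold=beta_threshold)
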