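"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* :func:`simulate_transition` plants the three DNB signatures — inflated
  per-gene deviation, strong within-module correlation, weak coupling to
  the rest of the genes — at exactly one case-control window of a
  replicated time course.  Everywhere else, and for all background genes,
  expression is stationary independent Gaussian noise.  The planted
  window and member set are returned as ground truth.

* :func:`simulate_grn` draws a sparse signed coefficient matrix B
  (spectral radius rescaled below one, so a stable steady state exists)
  and samples the linear steady state x = (I - B)^{-1} eps — the
  linearization of a kinetic transcription model — as i.i.d. draws, for
  benchmarking network inference against the known adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataio import TimeCourseDataset

logger = logging.getLogger("dnbpipe")

__all__ = [
    "TransitionSimSpec",
    "GrnSimSpec",
    "simulate_transition",
    "simulate_grn",
]


@dataclass(frozen=True)
class TransitionSimSpec:
    """Parameters of a planted critical transition.

    ``tipping_index`` is the 1-based case-control window at whose *case*
    time point the module destabilizes.  ``deviation_gain`` g > 1 is the
    factor by which the module genes' SD inflates there; ``coupling`` rho
    is their expected pairwise correlation at that point.
    """

    n_genes: int = 500
    module_size: int = 30
    n_timepoints: int = 10
    n_replicates: int = 6
    tipping_index: int = 6
    deviation_gain: float = 5.0
    coupling: float = 0.9
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.module_size < self.n_genes:
            raise ValueError("need 2 <= module_size < n_genes")
        if not 1 <= self.tipping_index <= self.n_timepoints - 1:
            raise ValueError("tipping_index must be a valid window (1..T-1)")
        if not 0 <= self.coupling < 1:
            raise ValueError("coupling must lie in [0, 1)")
        if self.deviation_gain <= 0 or self.baseline_sd <= 0:
            raise ValueError("deviation_gain and baseline_sd must be positive")


@dataclass(frozen=True)
class GrnSimSpec:
    """Parameters of a sparse signed steady-state regulatory network."""

    n_genes: int = 10
    edge_density: float = 0.15
    strength_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 1.0
    n_samples: int = 200
    seed: int = 0
    spectral_radius: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must lie in [0, 1]")
        if self.noise_sd <= 0 or self.n_samples < 2 or self.n_genes < 2:
            raise ValueError("invalid GRN simulation parameters")


def simulate_transition(
    spec: TransitionSimSpec,
) -> tuple[TimeCourseDataset, dict]:
    """Generate a replicated time course with one planted transition.

    Background genes, and module genes away from the tipping window, are
    i.i.d. Normal(0, baseline_sd^2) at every sample.  At the case time
    point of the tipping window each module gene i becomes

        x_i = g * baseline_sd * (sqrt(rho) * z + sqrt(1 - rho) * e_i)

    with a latent factor z shared by all module genes within a replicate
    sample and e_i independent unit noise — so the expected per-gene SD
    is g * baseline_sd, the expected within-module correlation is rho,
    and the expected module-to-background correlation is 0.

    Returns the dataset and a ground-truth dict with keys
    ``tipping_index`` and ``module_genes``.
    """
    rng = np.random.default_rng(spec.seed)
    T, R, G = spec.n_timepoints, spec.n_replicates, spec.n_genes
    n_samples = T * R
    values = rng.normal(0.0, spec.baseline_sd, size=(G, n_samples))

    # time point k (0-based) occupies columns k*R .. k*R+R-1
    times = np.repeat(np.arange(T, dtype=float), R)
    reps = np.tile(np.arange(1, R + 1), T)

    module = np.arange(spec.module_size)  # first genes; detection is label-blind
    case_tp = spec.tipping_index  # window k pairs tp k-1 (control) with tp k (case)
    cols = np.arange(case_tp * R, case_tp * R + R)
    z = rng.normal(size=R)
    e = rng.normal(size=(spec.module_size, R))
    latent = np.sqrt(spec.coupling) * z[None, :] + np.sqrt(1 - spec.coupling) * e
    values[np.ix_(module, cols)] = spec.deviation_gain * spec.baseline_sd * latent

    gene_ids = tuple(f"G{i + 1:05d}" for i in range(G))
    ds = TimeCourseDataset(
        gene_ids=gene_ids,
        values=values,
        sample_ids=tuple(f"T{int(t)}_R{r}" for t, r in zip(times, reps)),
        sample_time=times,
        sample_replicate=reps,
    )
    truth = {
        "tipping_index": spec.tipping_index,
        "module_genes": [gene_ids[i] for i in module],
    }
    return ds, truth


def simulate_grn(spec: GrnSimSpec, max_retries: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Sample steady states of a random sparse signed linear network.

    Returns ``(samples, B)`` where ``samples`` is genes x n_samples and
    ``B`` the signed coefficient matrix (zero diagonal).  Off-diagonal
    entries are present with probability ``edge_density``; magnitudes are
    uniform in ``strength_range`` with random sign, then B is rescaled to
    the requested spectral radius.  Samples solve x = B x + eps, i.e.
    x = (I - B)^{-1} eps with eps ~ Normal(0, noise_sd^2 I).
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    for attempt in range(max_retries):
        mask = rng.random((G, G)) < spec.edge_density
        np.fill_diagonal(mask, False)
        lo, hi = spec.strength_range
        strengths = rng.uniform(lo, hi, size=(G, G))
        signs = rng.choice([-1.0, 1.0], size=(G, G))
        B = np.where(mask, signs * strengths, 0.0)
        radius = np.max(np.abs(np.linalg.eigvals(B))) if mask.any() else 0.0
        if radius > 0:
            B *= spec.spectral_radius / radius
        A = np.eye(G) - B
        if np.linalg.cond(A) < 1e12:
            break
        logger.warning("simulate_grn: ill-conditioned (I-B), retry %d", attempt + 1)
    else:
        raise RuntimeError("simulate_grn: could not draw a stable network")
    eps = rng.normal(0.0, spec.noise_sd, size=(G, spec.n_samples))
    samples = np.linalg.solve(A, eps)
    return samples, B
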