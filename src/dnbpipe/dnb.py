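"""Dynamic network biomarker (DNB) scoring and tipping-point detection.

Near a bifurcation, a dominant group of genes — the DNB module — shows
three simultaneous signatures: its members fluctuate strongly (high
average standard deviation SD_d), they become tightly co-expressed (high
average within-module Pearson correlation PCC_d), and they decouple from
the rest of the network (low module-to-outside correlation PCC_o).  The
composite index

    CI = (SD_d * PCC_d) / PCC_o

combines the three into a single early-warning score; across a sequence
of case-control windows, the window where the best module's CI peaks is
the critical transition state.

Conventions used here (documented choices, exposed as parameters):
correlations enter PCC_d and PCC_o as absolute values, since the DNB
conditions concern correlation *strength* and signed averaging can
cancel; per-gene SDs are taken on control-standardized case values so
deviations are measured relative to the reference state and comparable
across windows; candidate modules come from average-linkage hierarchical
clustering on the distance 1 - |PCC|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dataio import TimeCourseDataset
from .preprocess import CaseControlWindow, standardize_by_control

logger = logging.getLogger("dnbpipe")

#: floor on PCC_o in the CI quotient; keeps CI finite for perfectly
#: isolated modules
EPS_PCC = 1e-6

__all__ = [
    "EPS_PCC",
    "ModuleScore",
    "DnbResult",
    "pairwise_pcc",
    "candidate_modules",
    "composite_index",
    "detect_dnb",
    "bootstrap_significance",
]


@dataclass(frozen=True)
class ModuleScore:
    """DNB statistics of one candidate module in one window.

    ``sd_d``: mean standard deviation of the member genes across the
    window's (standardized) case samples.  ``pcc_d``: mean |PCC| over all
    member pairs.  ``pcc_o``: mean |PCC| between members and every
    non-member.  ``ci``: the composite index (sd_d * pcc_d) / pcc_o.
    """

    window_index: int
    genes: tuple[str, ...]
    sd_d: float
    pcc_d: float
    pcc_o: float
    ci: float

    def __post_init__(self) -> None:
        if self.sd_d < 0 or not 0 <= self.pcc_d <= 1 + 1e-12 or not 0 <= self.pcc_o <= 1 + 1e-12:
            raise ValueError("module statistics out of range")
        if not np.isfinite(self.ci) or self.ci < 0:
            raise ValueError("CI must be finite and non-negative")


@dataclass(frozen=True)
class DnbResult:
    """Outcome of tipping-point detection over all windows."""

    ci_curve: tuple[float, ...]
    tipping_window: int  # 1-based argmax of ci_curve
    dnb_genes: tuple[str, ...]
    module_scores: tuple[ModuleScore, ...]
    bootstrap_p: float | None = None
    window_n_case: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.ci_curve:
            raise ValueError("empty CI curve")
        peak = max(self.ci_curve)
        if self.ci_curve[self.tipping_window - 1] != peak:
            raise ValueError("tipping_window must index the CI maximum")


def pairwise_pcc(matrix: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the rows of ``matrix``.

    Rows with zero variance correlate 0 with everything (diagonal stays
    1).  Requires at least two columns (samples).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    pcc = unit @ unit.T
    pcc[norms == 0, :] = 0.0
    pcc[:, norms == 0] = 0.0
    np.clip(pcc, -1.0, 1.0, out=pcc)
    np.fill_diagonal(pcc, 1.0)
    return pcc


def candidate_modules(
    case_pcc: np.ndarray, min_size: int = 5, cut_height: float = 0.35
) -> list[tuple[int, ...]]:
    """Candidate DNB modules by hierarchical clustering of |PCC|.

    Average-linkage clustering on the distance 1 - |PCC|, tree cut at
    ``cut_height``; every resulting cluster with at least ``min_size``
    genes is a candidate.  Clusters are disjoint by construction and the
    result is deterministic (scipy's linkage order; clusters reported
    sorted by their lowest gene index, members ascending).
    """
    case_pcc = np.asarray(case_pcc, dtype=float)
    n = case_pcc.shape[0]
    if case_pcc.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if n < 2:
        return []
    dist = 1.0 - np.abs(case_pcc)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(idx)
    out = [tuple(sorted(m)) for m in clusters.values() if len(m) >= min_size]
    out.sort(key=lambda m: m[0])
    return out


def _module_stats(
    members: np.ndarray, sd_per_gene: np.ndarray, abs_pcc: np.ndarray,
    abs_rowsum: np.ndarray, eps_pcc: float,
) -> tuple[float, float, float, float]:
    """CI components from precomputed per-gene SDs and |PCC| matrix.

    ``abs_rowsum`` is the row sum of ``abs_pcc`` including the diagonal;
    member-to-outside sums are obtained by subtracting the within-module
    block, which keeps scoring O(m^2) per module.
    """
    m = members.size
    n = sd_per_gene.size
    sd_d = float(sd_per_gene[members].mean())
    block = abs_pcc[np.ix_(members, members)]
    within_sum = float(block.sum())  # includes diagonal (m ones)
    if m >= 2:
        pcc_d = (within_sum - m) / (m * (m - 1))
    else:
        pcc_d = 0.0
    n_out = n - m
    if n_out < 1:
        raise ValueError("module must leave at least one non-member gene")
    out_sum = float(abs_rowsum[members].sum()) - within_sum
    pcc_o = out_sum / (m * n_out)
    ci = (sd_d * pcc_d) / max(pcc_o, eps_pcc)
    return sd_d, min(pcc_d, 1.0), min(pcc_o, 1.0), ci


def composite_index(
    genes,
    standardized_case: np.ndarray,
    all_genes,
    window_index: int = 0,
    eps_pcc: float = EPS_PCC,
) -> ModuleScore:
    """Composite index CI = (SD_d * PCC_d) / max(PCC_o, eps) of one module.

    Parameters
    ----------
    genes
        Member gene ids (at least 2, and at least one non-member must
        remain in ``all_genes``).
    standardized_case
        Genes x case-samples matrix for *all* genes, rows ordered like
        ``all_genes`` (typically the output of
        :func:`dnbpipe.preprocess.standardize_by_control`).
    all_genes
        Gene ids labelling the rows of ``standardized_case``.
    """
    all_genes = list(all_genes)
    lookup = {g: i for i, g in enumerate(all_genes)}
    members = np.array(sorted(lookup[g] for g in genes), dtype=int)
    if members.size < 2:
        raise ValueError("module needs at least 2 member genes")
    if members.size >= len(all_genes):
        raise ValueError("module equals the whole gene set; PCC_o is undefined")
    mat = np.asarray(standardized_case, dtype=float)
    sd_per_gene = mat.std(axis=1, ddof=1)
    abs_pcc = np.abs(pairwise_pcc(mat))
    sd_d, pcc_d, pcc_o, ci = _module_stats(
        members, sd_per_gene, abs_pcc, abs_pcc.sum(axis=1), eps_pcc
    )
    return ModuleScore(
        window_index=window_index,
        genes=tuple(all_genes[i] for i in members),
        sd_d=sd_d,
        pcc_d=pcc_d,
        pcc_o=pcc_o,
        ci=ci,
    )


def detect_dnb(
    ds_filtered: TimeCourseDataset,
    windows: list[CaseControlWindow],
    min_size: int = 5,
    cut_height: float = 0.35,
    pool_neighbors: bool = False,
    eps_pcc: float = EPS_PCC,
) -> DnbResult:
    """Locate the critical transition window and its DNB module.

    For every window: standardize the case samples against the control
    state, cluster genes on 1 - |PCC| into candidate modules, score each
    candidate's CI, and keep the maximum.  The tipping window is the
    argmax of the per-window best CI (earliest window on exact ties; the
    lexicographically smallest module on within-window ties).  Windows
    with no candidate module score 0 (logged).

    With ``pool_neighbors=True`` the correlation statistics (PCC_d,
    PCC_o, and the clustering) are computed on the case samples pooled
    with the window's neighbor samples — pooling exists to stabilize the
    correlation estimates — while SD_d stays on the window's own case
    samples, so the deviation signal remains local to the window.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to trace a CI curve")
    ci_curve: list[float] = []
    best_scores: list[ModuleScore | None] = []
    all_scores: list[ModuleScore] = []
    n_case: list[int] = []
    for w in windows:
        std_core = standardize_by_control(w, ds_filtered, pool_neighbors=False)
        std_case = (
            standardize_by_control(w, ds_filtered, pool_neighbors=True)
            if pool_neighbors else std_core
        )
        n_case.append(std_case.shape[1])
        sd_per_gene = std_core.std(axis=1, ddof=1)
        abs_pcc = np.abs(pairwise_pcc(std_case))
        rowsum = abs_pcc.sum(axis=1)
        modules = candidate_modules(abs_pcc, min_size=min_size, cut_height=cut_height)
        modules = [m for m in modules if len(m) < ds_filtered.n_genes]
        best: ModuleScore | None = None
        for members in modules:
            idx = np.asarray(members, dtype=int)
            sd_d, pcc_d, pcc_o, ci = _module_stats(
                idx, sd_per_gene, abs_pcc, rowsum, eps_pcc
            )
            score = ModuleScore(
                window_index=w.index,
                genes=tuple(ds_filtered.gene_ids[i] for i in members),
                sd_d=sd_d, pcc_d=pcc_d, pcc_o=pcc_o, ci=ci,
            )
            all_scores.append(score)
            if best is None or score.ci > best.ci or (
                score.ci == best.ci and score.genes < best.genes
            ):
                best = score
        if best is None:
            logger.warning("window %d: no candidate module; CI recorded as 0", w.index)
            ci_curve.append(0.0)
        else:
            ci_curve.append(best.ci)
        best_scores.append(best)

    tipping = int(np.argmax(ci_curve)) + 1  # argmax takes the earliest on ties
    best_at_tipping = best_scores[tipping - 1]
    if best_at_tipping is None:
        raise ValueError("no window produced a candidate module; lower min_size")
    logger.info(
        "tipping window %d (control t=%g, case t=%g), CI=%.4g, module of %d genes",
        tipping, windows[tipping - 1].control_time, windows[tipping - 1].case_time,
        ci_curve[tipping - 1], len(best_at_tipping.genes),
    )
    return DnbResult(
        ci_curve=tuple(ci_curve),
        tipping_window=tipping,
        dnb_genes=best_at_tipping.genes,
        module_scores=tuple(all_scores),
        window_n_case=tuple(n_case),
    )


def bootstrap_significance(
    ds: TimeCourseDataset,
    window: CaseControlWindow,
    dnb_genes,
    n_boot: int = 1000,
    seed: int = 0,
    pool_neighbors: bool = False,
    eps_pcc: float = EPS_PCC,
) -> float:
    """Empirical p-value of a module's CI against random gene sets.

    Draws ``n_boot`` uniform gene sets of the same size (without
    replacement within a draw), scores each in the same window, and
    returns p = (1 + #{CI_rand >= CI_module}) / (1 + n_boot), so p is
    never exactly zero.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    members = ds.gene_index(dnb_genes)
    m = members.size
    if m >= ds.n_genes:
        raise ValueError("module must be smaller than the gene universe")
    std_core = standardize_by_control(window, ds, pool_neighbors=False)
    std_case = (
        standardize_by_control(window, ds, pool_neighbors=True)
        if pool_neighbors else std_core
    )
    sd_per_gene = std_core.std(axis=1, ddof=1)
    abs_pcc = np.abs(pairwise_pcc(std_case))
    rowsum = abs_pcc.sum(axis=1)
    *_, ci_obs = _module_stats(members, sd_per_gene, abs_pcc, rowsum, eps_pcc)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_boot):
        rand = rng.choice(ds.n_genes, size=m, replace=False)
        *_, ci_rand = _module_stats(np.sort(rand), sd_per_gene, abs_pcc, rowsum, eps_pcc)
        if ci_rand >= ci_obs:
            n_ge += 1
    return (1 + n_ge) / (1 + n_boot)
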