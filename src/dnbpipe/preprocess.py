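"""Low-expression filtering and case-control window construction.

A time course with T time points is turned into T-1 two-state comparisons:
in window k the samples at time point k are the reference (control) state
and the samples at time point k+1 the tested (case) state.  Optionally,
samples from other time points within a neighbor interval of the case time
are recorded so they can be pooled into the case side — with only three
replicates per time point, correlation estimates are noisy, and pooling
raises the effective sample size.

Case values are standardized gene-wise by the control mean and standard
deviation, which makes per-gene deviations comparable across windows and
expresses them relative to the reference state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import TimeCourseDataset

logger = logging.getLogger("dnbpipe")

#: floor on the control standard deviation, avoids division by zero for
#: genes constant in the control samples
EPS_SD = 1e-8

__all__ = [
    "CaseControlWindow",
    "EPS_SD",
    "filter_low_expression",
    "build_windows",
    "standardize_by_control",
]


@dataclass(frozen=True)
class CaseControlWindow:
    """One (control time point, case time point) comparison unit.

    ``index`` is 1-based; windows built from one dataset are numbered
    1..T-1 with strictly increasing case times.  ``neighbor_samples``
    holds column indices of samples from *other* time points within the
    neighbor interval of the case time (empty unless requested).
    """

    index: int
    control_time: float
    case_time: float
    control_samples: tuple[int, ...]
    case_samples: tuple[int, ...]
    neighbor_samples: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.control_time < self.case_time:
            raise ValueError("control_time must precede case_time")
        if not self.control_samples or not self.case_samples:
            raise ValueError("control and case sample sets must be non-empty")
        if set(self.control_samples) & set(self.case_samples):
            raise ValueError("control and case samples must be disjoint")


def filter_low_expression(
    ds: TimeCourseDataset, threshold: float, min_fraction: float = 1.0
) -> TimeCourseDataset:
    """Drop genes not exceeding ``threshold`` in ``min_fraction`` of samples.

    Retains exactly the genes whose expression is greater than
    ``threshold`` in at least ``min_fraction`` of the samples (the
    low-value filter applied to microarray matrices before network
    analysis).  Returns a new dataset.
    """
    if not np.isfinite(threshold) and threshold > 0:
        raise ValueError("threshold must be finite or -inf")
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be within [0, 1]")
    frac_above = (ds.values > threshold).mean(axis=1)
    keep = np.flatnonzero(frac_above >= min_fraction)
    if keep.size == 0:
        raise ValueError(
            f"low-expression filter at threshold={threshold} removed every "
            "gene; lower the threshold or min_fraction"
        )
    logger.info(
        "low-expression filter: kept %d of %d genes (threshold=%g, min_fraction=%g)",
        keep.size, ds.n_genes, threshold, min_fraction,
    )
    return ds.subset_genes(keep)


def build_windows(
    ds: TimeCourseDataset, neighbor_interval: float | None = None
) -> list[CaseControlWindow]:
    """Pair each consecutive time point with its predecessor.

    A dataset with T time points yields exactly T-1 windows: window k
    compares time point k (control) against time point k+1 (case).  If
    ``neighbor_interval`` is given, each window additionally records
    samples from other time points whose time is within that interval of
    the case time (excluding the control and case points themselves).
    """
    if ds.n_timepoints < 2:
        raise ValueError("need at least 2 time points to build windows")
    windows: list[CaseControlWindow] = []
    for k in range(ds.n_timepoints - 1):
        t_ctrl = ds.time_order[k]
        t_case = ds.time_order[k + 1]
        neighbors: tuple[int, ...] = ()
        if neighbor_interval is not None:
            mask = (
                (np.abs(ds.sample_time - t_case) <= neighbor_interval)
                & ~np.isclose(ds.sample_time, t_case)
                & ~np.isclose(ds.sample_time, t_ctrl)
            )
            neighbors = tuple(np.flatnonzero(mask).tolist())
        windows.append(
            CaseControlWindow(
                index=k + 1,
                control_time=t_ctrl,
                case_time=t_case,
                control_samples=tuple(ds.samples_at(t_ctrl).tolist()),
                case_samples=tuple(ds.samples_at(t_case).tolist()),
                neighbor_samples=neighbors,
            )
        )
    return windows


def standardize_by_control(
    window: CaseControlWindow,
    ds: TimeCourseDataset,
    pool_neighbors: bool = False,
    eps_sd: float = EPS_SD,
    shrink_df: float = 3.0,
) -> np.ndarray:
    """Standardize each gene's case values by its control mean and SD.

    Returns a genes x case-samples matrix ``(x - mu_ctrl) / sigma_ctrl``
    (sample SD, n-1 denominator).  Genes constant in the control samples
    are scaled by the ``eps_sd`` floor instead of zero.  With
    ``pool_neighbors=True`` the window's neighbor samples are appended as
    extra case columns.

    With few control replicates the per-gene SD estimate is unstable (2
    degrees of freedom at 3 replicates), and dividing by an accidentally
    tiny SD inflates a gene's standardized deviation arbitrarily.  The
    control variance is therefore moderated toward the cross-gene median
    control variance with ``shrink_df`` prior degrees of freedom,

        sigma_i^2 <- (nu * s_i^2 + shrink_df * s0^2) / (nu + shrink_df),

    where nu = n_ctrl - 1 and s0^2 is the median of the per-gene control
    variances.  The moderation vanishes as replication grows, and for a
    single-gene dataset (s0^2 = s_i^2) it is the identity.  Set
    ``shrink_df=0`` for the raw per-gene SD.
    """
    ctrl = ds.values[:, list(window.control_samples)]
    case_cols = list(window.case_samples)
    if pool_neighbors:
        case_cols += list(window.neighbor_samples)
    case = ds.values[:, case_cols]
    mu = ctrl.mean(axis=1, keepdims=True)
    if ctrl.shape[1] > 1:
        var = ctrl.var(axis=1, ddof=1, keepdims=True)
        if shrink_df > 0:
            nu = ctrl.shape[1] - 1
            var0 = np.median(var)
            var = (nu * var + shrink_df * var0) / (nu + shrink_df)
        sd = np.sqrt(var)
    else:
        sd = np.zeros((ds.n_genes, 1))
    sd = np.maximum(sd, eps_sd)
    return (case - mu) / sd
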