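"""Reading time-course expression matrices and writing network files.

The pipeline's sole input is a genes x samples expression matrix together
with a per-sample (time, replicate) annotation.  Values are taken as
provided (log or linear scale is not interpreted).  Sample order inside a
:class:`TimeCourseDataset` is canonical: sorted by (time, replicate), so
loading a matrix with permuted columns yields an identical object.

Outputs for downstream network viewers are plain tab-separated files: a
three-column edge list (or SIF), and a two-column node-attribute table
mapping each gene to its standard deviation at the transition window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dnbpipe")

__all__ = [
    "TimeCourseDataset",
    "read_expression_matrix",
    "read_time_map",
    "write_network",
    "read_network",
    "write_node_attributes",
    "read_node_attributes",
]


@dataclass(frozen=True)
class TimeCourseDataset:
    """Expression matrix plus per-sample time-point and replicate labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    values
        Numeric matrix, genes x samples, in the units provided upstream.
    sample_ids
        Sample names, one per matrix column.
    sample_time
        Numeric time value of each sample (e.g. days).
    sample_replicate
        Replicate index of each sample within its time point.
    time_unit
        Free-text unit of ``sample_time`` (informational only).
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    sample_ids: tuple[str, ...]
    sample_time: np.ndarray
    sample_replicate: np.ndarray
    time_unit: str = "d"
    time_order: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dupes}")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_ids[r]!r} "
                f"in sample {self.sample_ids[c]!r}"
            )
        time = np.asarray(self.sample_time, dtype=float)
        rep = np.asarray(self.sample_replicate, dtype=int)
        if time.shape != (n_samples,) or rep.shape != (n_samples,):
            raise ValueError("sample_time/sample_replicate length mismatch")
        # canonical order: (time, replicate)
        order = np.lexsort((rep, time))
        object.__setattr__(self, "values", values[:, order])
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids[i] for i in order))
        object.__setattr__(self, "sample_time", time[order])
        object.__setattr__(self, "sample_replicate", rep[order])
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        time_order = tuple(float(t) for t in np.unique(self.sample_time))
        object.__setattr__(self, "time_order", time_order)
        for t in time_order:
            reps = self.sample_replicate[self.sample_time == t]
            if len(set(reps.tolist())) != len(reps):
                raise ValueError(f"duplicate replicate index at time {t}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return len(self.time_order)

    def samples_at(self, time: float) -> np.ndarray:
        """Column indices of the samples measured at ``time``."""
        idx = np.flatnonzero(np.isclose(self.sample_time, time))
        if idx.size == 0:
            raise KeyError(f"no samples at time {time}")
        return idx

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Row indices of ``gene_ids``; unknown ids raise ``KeyError``."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def subset_genes(self, keep: Sequence[int]) -> "TimeCourseDataset":
        keep = np.asarray(keep, dtype=int)
        return TimeCourseDataset(
            gene_ids=tuple(self.gene_ids[i] for i in keep),
            values=self.values[keep],
            sample_ids=self.sample_ids,
            sample_time=self.sample_time.copy(),
            sample_replicate=self.sample_replicate.copy(),
            time_unit=self.time_unit,
        )


def read_time_map(path: str | Path) -> dict[str, tuple[float, int]]:
    """Read a sample -> (time, replicate) mapping from a TSV file.

    Expected columns: sample, time, replicate (header required).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"time map must have columns {sorted(required)}")
    return {
        str(row["sample"]): (float(row["time"]), int(row["replicate"]))
        for _, row in df.iterrows()
    }


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    """Read a delimited matrix, skipping GEO series-matrix '!' header lines."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="!")
    return df


def read_expression_matrix(
    path: str | Path,
    time_map: Mapping[str, tuple[float, int]] | str | Path,
    layout: str = "genes-in-rows",
    sep: str | None = None,
    impute_missing: bool = False,
    time_unit: str = "d",
) -> TimeCourseDataset:
    """Load a delimited expression matrix into a :class:`TimeCourseDataset`.

    Parameters
    ----------
    path
        Delimited numeric matrix with one header row and one leading id
        column.  Lines starting with ``!`` (GEO series-matrix metadata)
        are skipped.
    time_map
        Mapping of sample name to (time value, replicate index), or the
        path of a TSV with columns sample/time/replicate.
    layout
        ``"genes-in-rows"`` (default) or ``"genes-in-columns"``.
    impute_missing
        If True, missing cells are imputed by the per-gene mean (count
        logged); otherwise any missing cell is an error.
    """
    if layout not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown layout {layout!r}")
    if not isinstance(time_map, Mapping):
        time_map = read_time_map(time_map)

    df = _read_table(path, sep)
    if layout == "genes-in-columns":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    non_numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = non_numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    df = non_numeric

    if df.isna().to_numpy().any():
        if not impute_missing:
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at gene {df.index[r]!r}, sample {df.columns[c]!r} "
                "(pass impute_missing=True for per-gene mean imputation)"
            )
        n_missing = int(df.isna().to_numpy().sum())
        df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        logger.info("imputed %d missing values by per-gene mean", n_missing)

    missing = [s for s in df.columns if s not in time_map]
    if missing:
        raise ValueError(f"sample {missing[0]!r} not present in time map")

    times = np.array([time_map[s][0] for s in df.columns], dtype=float)
    reps = np.array([time_map[s][1] for s in df.columns], dtype=int)
    ds = TimeCourseDataset(
        gene_ids=tuple(df.index),
        values=df.to_numpy(dtype=float),
        sample_ids=tuple(df.columns),
        sample_time=times,
        sample_replicate=reps,
        time_unit=time_unit,
    )
    logger.info(
        "loaded %d genes x %d samples (%d time points) from %s",
        ds.n_genes, ds.n_samples, ds.n_timepoints, path,
    )
    return ds


# ---------------------------------------------------------------------------
# network / attribute writers (Cytoscape-compatible plain text)
# ---------------------------------------------------------------------------

def write_network(edges, path: str | Path, known_genes: Iterable[str] | None = None,
                  sif: bool = False) -> None:
    """Write a directed edge list as TSV (source/target/weight) or SIF.

    ``edges`` is an iterable of objects with ``regulator``, ``target`` and
    ``beta`` attributes (see :class:`dnbpipe.narromi.RegulatoryEdge`).
    With ``sif=True`` the format is ``source<TAB>interaction<TAB>target``
    and the weight is dropped.
    """
    edges = list(edges)
    if known_genes is not None:
        known = set(known_genes)
        for e in edges:
            if e.regulator not in known or e.target not in known:
                raise ValueError(
                    f"edge {e.regulator}->{e.target} references an unknown gene"
                )
    path = Path(path)
    with path.open("w") as fh:
        if sif:
            for e in edges:
                fh.write(f"{e.regulator}\tregulates\t{e.target}\n")
        else:
            fh.write("source\ttarget\tweight\n")
            for e in edges:
                fh.write(f"{e.regulator}\t{e.target}\t{e.beta:.17g}\n")


def read_network(path: str | Path) -> list[tuple[str, str, float]]:
    """Read back a TSV edge list written by :func:`write_network`."""
    out: list[tuple[str, str, float]] = []
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("source\t"):
            raise ValueError("not a dnbpipe edge-list file")
        for line in fh:
            s, t, w = line.rstrip("\n").split("\t")
            out.append((s, t, float(w)))
    return out


def write_node_attributes(genes: Sequence[str], sd_per_gene: Sequence[float],
                          path: str | Path) -> None:
    """Write the per-gene standard deviation table (gene<TAB>sd)."""
    if len(genes) != len(sd_per_gene):
        raise ValueError("genes and sd_per_gene must have equal length")
    with Path(path).open("w") as fh:
        fh.write("gene\tsd\n")
        for g, sd in zip(genes, sd_per_gene):
            fh.write(f"{g}\t{float(sd):.17g}\n")


def read_node_attributes(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("gene\t"):
            raise ValueError("not a dnbpipe node-attribute file")
        for line in fh:
            g, sd = line.rstrip("\n").split("\t")
            out[g] = float(sd)
    return out
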