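"""End-to-end orchestration: filter -> windows -> DNB -> bootstrap -> network.

A single :class:`PipelineConfig` carries every tunable of the upstream
stages.  One master seed feeds a fixed derivation scheme (seed + stage
offset), so the bootstrap and any simulation stage are independently
reproducible.  Outputs are plain-text tables plus a JSON manifest with a
SHA-256 hash per file; rerunning with an identical config and inputs
reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dataio, dnb, narromi, preprocess

logger = logging.getLogger("dnbpipe")

__all__ = ["PipelineConfig", "load_config", "run"]

# fixed offsets added to the master seed, one per randomized stage
_SEED_OFFSETS = {"bootstrap": 101, "mi_null": 202}


@dataclass
class PipelineConfig:
    """All pipeline parameters, with the package defaults resolved."""

    matrix: str = ""
    time_map: str = ""
    out_dir: str = "dnb_out"
    layout: str = "genes-in-rows"
    # preprocess
    threshold: float = -np.inf
    min_fraction: float = 1.0
    neighbor_interval: float | None = None
    pool_neighbors: bool = False
    # dnb
    min_size: int = 5
    cut_height: float = 0.35
    eps_sd: float = preprocess.EPS_SD
    eps_pcc: float = dnb.EPS_PCC
    n_boot: int = 1000
    seed: int = 0
    # narromi
    bins: int | None = None
    omega: float = 0.5
    lam: float = 0.01
    beta_threshold: float = 0.05
    mi_threshold: float | None = None
    pool_windows: int = 1  # pool case samples of tipping window +/- this many

    def validate(self) -> None:
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must lie in [0, 1]")
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in [0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.cut_height <= 0 or self.beta_threshold < 0 or self.lam < 0:
            raise ValueError("cut_height, beta_threshold and lam must be non-negative")
        if self.pool_windows < 0:
            raise ValueError("pool_windows must be >= 0")


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a plain-text ``key = value`` config file.

    Lines starting with ``#`` are comments; unknown keys are rejected;
    ``none`` clears an optional field.
    """
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    cfg = PipelineConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
        current = getattr(cfg, key)
        if value.lower() == "none":
            parsed = None
        elif isinstance(current, bool):
            parsed = _BOOL[value.lower()]
        elif key in ("min_size", "n_boot", "seed", "bins", "pool_windows"):
            parsed = int(value)
        elif key in ("matrix", "time_map", "out_dir", "layout"):
            parsed = value
        else:
            parsed = float(value)
        setattr(cfg, key, parsed)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_config(cfg: PipelineConfig, path: Path) -> None:
    lines = []
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        lines.append(f"{f.name} = {'none' if v is None else v}")
    path.write_text("\n".join(lines) + "\n")


def run(config: PipelineConfig,
        dataset: dataio.TimeCourseDataset | None = None) -> dict:
    """Execute the full analysis and return the output manifest.

    ``dataset`` may be passed directly (e.g. a simulated one); otherwise
    it is loaded from ``config.matrix`` / ``config.time_map``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "stages": []}

    def _stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        _stage("load")
        if dataset is None:
            dataset = dataio.read_expression_matrix(
                config.matrix, config.time_map, layout=config.layout
            )

        _stage("filter")
        ds = preprocess.filter_low_expression(
            dataset, config.threshold, config.min_fraction
        )

        _stage("windows")
        windows = preprocess.build_windows(ds, config.neighbor_interval)

        _stage("detect")
        result = dnb.detect_dnb(
            ds, windows,
            min_size=config.min_size, cut_height=config.cut_height,
            pool_neighbors=config.pool_neighbors, eps_pcc=config.eps_pcc,
        )

        _stage("bootstrap")
        tip_window = windows[result.tipping_window - 1]
        p = dnb.bootstrap_significance(
            ds, tip_window, result.dnb_genes,
            n_boot=config.n_boot,
            seed=config.seed + _SEED_OFFSETS["bootstrap"],
            pool_neighbors=config.pool_neighbors,
            eps_pcc=config.eps_pcc,
        )

        _stage("network")
        members = ds.gene_index(result.dnb_genes)
        lo = max(0, result.tipping_window - 1 - config.pool_windows)
        hi = min(len(windows), result.tipping_window + config.pool_windows)
        cols: list[int] = []
        for w in windows[lo:hi]:
            cols.extend(w.case_samples)
        expr = ds.values[np.ix_(members, sorted(set(cols)))]
        network = narromi.infer_network(
            expr, result.dnb_genes,
            bins=config.bins, mi_threshold=config.mi_threshold,
            lam=config.lam, omega=config.omega,
            beta_threshold=config.beta_threshold,
            seed=config.seed + _SEED_OFFSETS["mi_null"],
        )

        _stage("write")
        with (out / "ci_curve.tsv").open("w") as fh:
            fh.write("window\tcontrol_time\tcase_time\tn_case\tCI\n")
            for w, n_case, ci in zip(windows, result.window_n_case, result.ci_curve):
                fh.write(f"{w.index}\t{w.control_time:g}\t{w.case_time:g}\t"
                         f"{n_case}\t{ci:.17g}\n")
        (out / "dnb_genes.txt").write_text("\n".join(result.dnb_genes) + "\n")
        with (out / "module_scores.tsv").open("w") as fh:
            fh.write("window\tn_genes\tSD_d\tPCC_d\tPCC_o\tCI\n")
            for s in result.module_scores:
                fh.write(f"{s.window_index}\t{len(s.genes)}\t{s.sd_d:.17g}\t"
                         f"{s.pcc_d:.17g}\t{s.pcc_o:.17g}\t{s.ci:.17g}\n")
        (out / "bootstrap.txt").write_text(
            f"tipping_window\t{result.tipping_window}\n"
            f"n_boot\t{config.n_boot}\np_value\t{p:.17g}\n"
        )
        dataio.write_network(network.edges, out / "network.tsv",
                             known_genes=network.nodes)
        std_case = preprocess.standardize_by_control(
            tip_window, ds, pool_neighbors=config.pool_neighbors
        )
        sd = std_case.std(axis=1, ddof=1)
        dataio.write_node_attributes(
            result.dnb_genes, sd[members], out / "node_attributes.tsv"
        )
        _dump_config(config, out / "effective_config.txt")
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    manifest["tipping_window"] = result.tipping_window
    manifest["n_dnb_genes"] = len(result.dnb_genes)
    manifest["bootstrap_p"] = p
    manifest["n_edges"] = len(network.edges)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
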