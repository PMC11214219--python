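"""End-to-end orchestration: data -> scores -> correlation -> network ->
metrics -> stability -> comparison -> report bundle.

A single master seed deterministically derives a named seed for every
stochastic stage, so a fixed configuration reproduces every product
byte-for-byte.  Stage wall times go to the console logger only; the bundled
run log records stages, seeds and warnings so the bundle itself stays
byte-stable.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .comparison import nct
from .ggm import default_lambda_grid, select_lambda_ebic
from .layout import fruchterman_reingold
from .metrics import edge_betweenness, node_centralities, shortest_paths, to_distance
from .polychoric import CorrelationPolicy, build_correlation_matrix
from .report import export_report
from .scales import InstrumentSchema, ScaleScoreTable, load_responses, score_scales, study_schema
from .simulate import EmulatorSpec, simulate_items
from .stability import (
    DEFAULT_DROP_GRID,
    bootstrap_edges,
    case_drop_bootstrap,
    cs_coefficient,
)

__all__ = ["RunConfig", "run", "derive_seeds"]

logger = logging.getLogger("symptomnet")

_STAGE_SEEDS = ("emulate", "edge_bootstrap", "case_drop", "nct", "layout")


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    state = ss.generate_state(len(_STAGE_SEEDS), dtype=np.uint64)
    return {name: int(s % (2**31)) for name, s in zip(_STAGE_SEEDS, state)}


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; round-trips through YAML."""

    # input: either a CSV path or the built-in emulator
    input_path: str | None = None
    emulate: bool = False
    emulate_n: int = 207
    node_mode: str = "scale"          # "scale": CSV of construct scores; "item": Likert items
    schema_path: str | None = None    # item-level schema; default = study battery
    missing_policy: str = "listwise"

    # correlation policy
    max_categories: int = 10
    bin_deciles: bool = False

    # GGM
    ebic_gamma: float = 0.5
    n_lambda: int = 100
    lambda_ratio: float = 0.01

    # stability
    run_stability: bool = True
    boot_edges_B: int = 1000
    case_drop_B: int = 250
    drop_grid: tuple = DEFAULT_DROP_GRID
    cs_cor_threshold: float = 0.7
    cs_confidence: float = 0.95

    # comparison
    run_nct: bool = False
    input_path_b: str | None = None
    nct_iterations: int = 1000
    nct_paired: bool = False

    # layout / output
    layout_iterations: int = 500
    master_seed: int = 0
    output_dir: str = "symptomnet_run"

    def validate(self) -> None:
        if self.node_mode not in {"scale", "item"}:
            raise ValueError("node_mode must be 'scale' or 'item'")
        if not self.emulate and self.input_path is None:
            raise ValueError("either emulate=True or input_path is required")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input file not found: {self.input_path}")
        if self.schema_path is not None and not Path(self.schema_path).exists():
            raise ValueError(f"schema file not found: {self.schema_path}")
        if self.run_nct and not self.emulate and self.input_path_b is None:
            raise ValueError("run_nct requires input_path_b (second group)")
        if self.input_path_b is not None and not Path(self.input_path_b).exists():
            raise ValueError(f"input file not found: {self.input_path_b}")
        if not (0 < self.lambda_ratio < 1):
            raise ValueError("lambda_ratio must be in (0, 1)")
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be nonnegative")
        if self.boot_edges_B < 100 or self.case_drop_B < 100:
            raise ValueError("bootstrap B values must be >= 100")
        if any(not (0 < d < 0.95) for d in self.drop_grid):
            raise ValueError("drop_grid proportions must lie in (0, 0.95)")
        if self.nct_iterations < 100:
            raise ValueError("nct_iterations must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.drop_grid, list):
            cfg.drop_grid = tuple(cfg.drop_grid)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["drop_grid"] = list(d["drop_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drop_grid"] = list(d["drop_grid"])
        # the bundle's location is not part of the analysis configuration
        d.pop("output_dir")
        return d


def _load_scores(config: RunConfig, seeds: dict[str, int], log: list[str]):
    schema = (
        InstrumentSchema.from_file(config.schema_path) if config.schema_path else study_schema()
    )
    if config.emulate:
        spec = EmulatorSpec(n=config.emulate_n, seed=seeds["emulate"], schema=schema)
        items = simulate_items(spec)
        log.append(f"stage=data emulator n={spec.n} items={items.n_items} seed={seeds['emulate']}")
        return score_scales(items, config.missing_policy)
    if config.node_mode == "item":
        items = load_responses(config.input_path, schema)
        log.append(f"stage=data input={config.input_path} items={items.n_items}")
        return score_scales(items, config.missing_policy, schema=schema)
    log.append(f"stage=data input={config.input_path} (scale-level)")
    return ScaleScoreTable.from_csv(config.input_path)


def run(config: RunConfig) -> Path:
    """Execute the configured pipeline; returns the report-bundle path."""
    config.validate()
    seeds = derive_seeds(config.master_seed)
    log: list[str] = [f"master_seed={config.master_seed}"]
    t_start = time.perf_counter()

    def tick(stage: str, t0: float) -> None:
        logger.info("%s finished in %.2fs", stage, time.perf_counter() - t0)

    t0 = time.perf_counter()
    scores = _load_scores(config, seeds, log)
    tick("data", t0)

    t0 = time.perf_counter()
    policy = CorrelationPolicy(
        max_categories=config.max_categories, bin_deciles=config.bin_deciles
    )
    corr = build_correlation_matrix(scores, policy)
    log.append(
        f"stage=correlation n={corr.n} p={corr.p} psd_repaired={corr.psd_repaired}"
    )
    tick("correlation", t0)

    t0 = time.perf_counter()
    grid = default_lambda_grid(corr, n_points=config.n_lambda, ratio=config.lambda_ratio)
    network = select_lambda_ebic(corr, n=corr.n, lambda_grid=grid, gamma=config.ebic_gamma)
    log.append(
        f"stage=network lambda={network.lambda_selected:.6g} edges={network.n_edges}"
    )
    tick("network", t0)

    t0 = time.perf_counter()
    cent = node_centralities(network)
    ebet = edge_betweenness(network)
    plens = shortest_paths(to_distance(network))
    log.append("stage=metrics ok")
    tick("metrics", t0)

    boot = drop_curve = cs = None
    if config.run_stability:
        t0 = time.perf_counter()
        boot = bootstrap_edges(
            scores,
            B=config.boot_edges_B,
            seed=seeds["edge_bootstrap"],
            gamma=config.ebic_gamma,
            n_lambda=config.n_lambda,
            lambda_ratio=config.lambda_ratio,
        )
        drop_curve = case_drop_bootstrap(
            scores,
            drop_grid=config.drop_grid,
            B=config.case_drop_B,
            seed=seeds["case_drop"],
            gamma=config.ebic_gamma,
            n_lambda=config.n_lambda,
            lambda_ratio=config.lambda_ratio,
        )
        cs = cs_coefficient(drop_curve, config.cs_cor_threshold, config.cs_confidence)
        log.append(
            "stage=stability B_edges=%d B_drop=%d seed_edges=%d seed_drop=%d cs_strength=%.3g"
            % (
                config.boot_edges_B,
                config.case_drop_B,
                seeds["edge_bootstrap"],
                seeds["case_drop"],
                cs["strength"],
            )
        )
        tick("stability", t0)

    nct_res = None
    if config.run_nct:
        t0 = time.perf_counter()
        if config.emulate:
            # split the emulated sample in half for a self-contained comparison
            half = scores.n // 2
            group_a = ScaleScoreTable(scores.scores.iloc[:half])
            group_b = ScaleScoreTable(scores.scores.iloc[half:])
        else:
            group_a = scores
            group_b = ScaleScoreTable.from_csv(config.input_path_b)
        nct_res = nct(
            group_a,
            group_b,
            iterations=config.nct_iterations,
            paired=config.nct_paired,
            seed=seeds["nct"],
            gamma=config.ebic_gamma,
            n_lambda=config.n_lambda,
            lambda_ratio=config.lambda_ratio,
        )
        log.append(
            f"stage=comparison iterations={config.nct_iterations} "
            f"p_strength={nct_res.p_strength:.4g} p_structure={nct_res.p_structure:.4g}"
        )
        tick("comparison", t0)

    t0 = time.perf_counter()
    coords = fruchterman_reingold(
        network, seed=seeds["layout"], iterations=config.layout_iterations
    )
    out = export_report(
        config.output_dir,
        network=network,
        correlation=corr,
        centrality=cent,
        edge_betw=ebet,
        path_lengths=plens,
        edge_boot=boot,
        case_drop=drop_curve,
        cs=cs,
        nct_result=nct_res,
        layout_coords=coords,
        config=config.as_dict(),
        seeds=seeds,
        log_lines=log,
    )
    tick("report", t0)
    logger.info("pipeline finished in %.2fs -> %s", time.perf_counter() - t_start, out)
    return out
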