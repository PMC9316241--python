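"""End-to-end orchestration: simulate -> classify -> tabulate -> diversity -> spatial.

A run is described by one declarative config (YAML or dict). All randomness
flows from the single root seed, split per stage deterministically, so a rerun
with the same config yields byte-identical outputs; the manifest records
checksums to prove it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__, geo
from .classify import assign_all, panel_separability
from .distance import distance_matrix
from .diversity import hill_profile, profiles_to_csv
from .nj import neighbor_joining, species_monophyly, write_newick
from .sequences import ReferencePanel, read_fasta
from .simulate import (
    SimSeqConfig,
    SimSurveyConfig,
    simulate_reference_panel,
    simulate_survey,
    write_panel_files,
    write_survey_files,
)
from .spatial import PointPattern, clark_evans, kde
from .survey import SurveyDataset, site_cooccurrence_summary, tabulate_survey

STAGES = ("simulate", "classify", "tabulate", "diversity", "spatial")


@dataclass
class RunConfig:
    outdir: str = "retidiv_out"
    seed: Optional[int] = None
    model: str = "k2p"
    bootstrap: int = 0
    guard: Any = "auto"          # "auto" or nonnegative km
    kde_bandwidth: Any = "auto"  # "auto" or positive km
    kde_grid: tuple[int, int] = (64, 64)
    simulate: bool = True
    sim_sequences: dict = field(default_factory=dict)
    sim_survey: dict = field(default_factory=dict)
    # input paths; filled by the simulate stage when simulate=True
    panel: Optional[str] = None
    queries: Optional[str] = None
    sites: Optional[str] = None
    samples: Optional[str] = None
    window: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kde_grid" in raw:
            raw["kde_grid"] = tuple(raw["kde_grid"])
        return cls(**raw)


@dataclass(frozen=True)
class Problem:
    field: str
    message: str


def validate_config(cfg: RunConfig) -> list[Problem]:
    """Collect config problems as data; empty list means runnable."""
    problems = []
    if cfg.model not in ("p", "jc", "k2p"):
        problems.append(Problem("model", f"unknown model {cfg.model!r}"))
    if (cfg.simulate or cfg.bootstrap > 0) and cfg.seed is None:
        problems.append(Problem("seed", "seed is mandatory for stochastic stages"))
    if cfg.bootstrap < 0:
        problems.append(Problem("bootstrap", "bootstrap count must be >= 0"))
    if cfg.guard != "auto" and (
        not isinstance(cfg.guard, (int, float)) or cfg.guard < 0
    ):
        problems.append(Problem("guard", 'guard must be "auto" or >= 0'))
    if cfg.kde_bandwidth != "auto" and (
        not isinstance(cfg.kde_bandwidth, (int, float)) or cfg.kde_bandwidth <= 0
    ):
        problems.append(Problem("kde_bandwidth", 'must be "auto" or > 0'))
    if not cfg.simulate:
        for name in ("panel", "queries", "sites", "samples", "window"):
            path = getattr(cfg, name)
            if path is None:
                problems.append(Problem(name, "path required when simulate is off"))
            elif not Path(path).exists():
                problems.append(Problem(name, f"path {path!r} does not exist"))
    return problems


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    failed_stage: Optional[str] = None
    error: Optional[str] = None

    def record(self, stage: str, outputs: dict[str, Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {
                k: {"path": str(p), "sha256": _sha256(Path(p))}
                for k, p in outputs.items()
            },
            "seconds": round(seconds, 3),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Run all stages in order; on a stage error, stop with a partial manifest."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError(
            "invalid config: " + "; ".join(f"{p.field}: {p.message}" for p in problems)
        )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(cfg), version=__version__)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:  # short-circuit with a partial manifest
            manifest.failed_stage = name
            manifest.error = str(exc)
            manifest.write(outdir / "manifest.json")
            raise StageError(name, exc) from exc
        manifest.record(name, outputs, time.perf_counter() - t0)

    # -- simulate -----------------------------------------------------------
    if cfg.simulate:
        def do_simulate():
            seq_cfg = SimSeqConfig(
                **{**cfg.sim_sequences, "seed": _stage_seed(cfg.seed, "sequences")}
            )
            survey_kwargs = dict(cfg.sim_survey)
            if "county_grid" in survey_kwargs:
                survey_kwargs["county_grid"] = tuple(survey_kwargs["county_grid"])
            if "window" in survey_kwargs:
                survey_kwargs["window"] = tuple(survey_kwargs["window"])
            sur_cfg = SimSurveyConfig(
                **{**survey_kwargs, "seed": _stage_seed(cfg.seed, "survey")}
            )
            panel, queries = simulate_reference_panel(seq_cfg)
            ds = simulate_survey(sur_cfg)
            data_dir = outdir / "data"
            paths = write_panel_files(panel, queries, data_dir)
            paths |= write_survey_files(ds, sur_cfg, data_dir)
            cfg.panel = str(paths["panel"])
            cfg.queries = str(paths["queries"])
            cfg.sites = str(paths["sites"])
            cfg.samples = str(paths["samples"])
            cfg.window = str(paths["window"])
            return paths

        run_stage("simulate", do_simulate)

    # -- classify -----------------------------------------------------------
    def do_classify():
        panel = ReferencePanel.from_fasta(cfg.panel)
        queries = read_fasta(cfg.queries)
        sep = panel_separability(panel, cfg.model)
        if not sep.passed:
            manifest.warnings.append(
                {"stage": "classify", "warning": "barcode gap failed",
                 "pair": sep.worst_pair}
            )
        results = assign_all(
            queries, panel, cfg.model, cfg.bootstrap,
            None if cfg.seed is None else _stage_seed(cfg.seed, "bootstrap"),
        )
        assign_path = outdir / "assignments.csv"
        pd.DataFrame(
            [
                {
                    "query_id": r.query_id,
                    "assigned": r.assigned_species or "",
                    "distance": r.nearest_distance,
                    "margin": r.margin,
                    "support": "" if r.bootstrap_support is None else r.bootstrap_support,
                    "flags": ";".join(sorted(r.flags)),
                }
                for r in results
            ]
        ).to_csv(assign_path, index=False)
        tree = neighbor_joining(distance_matrix(panel.all_records(), cfg.model))
        tree_path = outdir / "panel_nj.nwk"
        write_newick(tree, tree_path)
        mono = species_monophyly(
            tree, {r.id: r.label for r in panel.all_records()}
        )
        mono_path = outdir / "monophyly.csv"
        pd.DataFrame(
            {"species": list(mono), "monophyletic": list(mono.values())}
        ).to_csv(mono_path, index=False)
        sep_path = outdir / "separability.json"
        sep_path.write_text(json.dumps(dataclasses.asdict(sep), indent=1))
        return {
            "assignments": assign_path, "tree": tree_path,
            "monophyly": mono_path, "separability": sep_path,
        }

    run_stage("classify", do_classify)

    # -- tabulate -----------------------------------------------------------
    ds_holder: dict[str, SurveyDataset] = {}

    def do_tabulate():
        ds = SurveyDataset.from_csv(cfg.sites, cfg.samples)
        ds_holder["ds"] = ds
        table = tabulate_survey(ds)
        t1_path = outdir / "table1.csv"
        table.to_csv(t1_path)
        cooc_path = outdir / "cooccurrence.csv"
        site_cooccurrence_summary(ds).to_csv(cooc_path, index=False)
        return {"table1": t1_path, "cooccurrence": cooc_path}

    run_stage("tabulate", do_tabulate)

    # -- diversity ----------------------------------------------------------
    def do_diversity():
        profiles = hill_profile(ds_holder["ds"])
        t2_path = outdir / "table2.csv"
        profiles_to_csv(profiles.values(), t2_path)
        return {"table2": t2_path}

    run_stage("diversity", do_diversity)

    # -- spatial ------------------------------------------------------------
    def do_spatial():
        ds = ds_holder["ds"]
        window, _ = geo.read_window_geojson(cfg.window)
        guard = None if cfg.guard == "auto" else float(cfg.guard)
        bw = None if cfg.kde_bandwidth == "auto" else float(cfg.kde_bandwidth)
        merged = ds.samples.merge(ds.sites, on="site_id")
        rows = []
        outputs = {}
        for sp in ds.species:
            pts = (
                merged[merged.species == sp][["site_id", "x", "y"]]
                .drop_duplicates("site_id")[["x", "y"]]
                .to_numpy()
            )
            if len(pts) < 2:
                manifest.warnings.append(
                    {"stage": "spatial", "warning": f"species {sp}: < 2 sites"}
                )
                continue
            pp = PointPattern(pts, window)
            res = clark_evans(pp, guard)
            rows.append(
                {"species": sp, "R": res.R, "z": res.z, "p": res.p,
                 "n_focal": res.n_focal}
            )
            grid = kde(pp, bw, cfg.kde_grid)
            kde_path = outdir / f"kde_{sp}.txt"
            grid.to_text(kde_path)
            outputs[f"kde_{sp}"] = kde_path
        t3_path = outdir / "table3.csv"
        pd.DataFrame(rows).to_csv(t3_path, index=False)
        outputs["table3"] = t3_path
        return outputs

    run_stage("spatial", do_spatial)

    manifest.write(outdir / "manifest.json")
    return manifest
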