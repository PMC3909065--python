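"""End-to-end orchestration: simulate → rank → qpcr-process → associate → panel.

A ``PipelineConfig`` (usually loaded from YAML) parameterises every stage;
the single global seed feeds each stage's RNG, so a re-run with the same
config reproduces identical outputs. A JSON manifest records the package
version, seed, a hash of the configuration, and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ann import SplitScheme, TrainConfig, prepare_screen_matrix, rank_probes, \
    ranked_list_frame, select_top_k
from .association import associate_expression
from .io import read_ct_table, read_sample_sheet, write_ct_table, write_sample_sheet
from .panel import panel_table, search_combinations
from .qpcr import aggregate_triplicates, calibrate_interplate, compute_expression, \
    summaries_to_frame
from .synthetic import CohortSpec, generate_cohort, generate_triplicate_plates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, resolvable before any stage runs."""

    out_dir: str = "results"
    seed: int = 0
    # simulation (set simulate=False to run on existing CSVs instead)
    simulate: bool = True
    screen_ct_path: str | None = None
    screen_samples_path: str | None = None
    validation_ct_path: str | None = None
    validation_samples_path: str | None = None
    n_screen_cases: int = 10
    n_screen_controls: int = 10
    n_probes: int = 100
    n_planted: int = 5
    delta_ct_shift: float = 2.0
    validation_delta_ct_shift: float = 0.52
    n_validation_cases: int = 44
    n_validation_controls: int = 46
    # processing / modelling
    reference_mirna: str = "miR-16"
    iac_sample_id: str = "IAC"
    hidden_nodes: int = 2
    n_repeats: int = 50
    top_k: int = 10
    max_panel_size: int = 3
    candidate_mirnas: list[str] = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def validate_paths(self) -> None:
        if not self.simulate:
            for name in ("screen_ct_path", "screen_samples_path",
                         "validation_ct_path", "validation_samples_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} not resolvable: {p!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dict (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- stage: simulate (or load) -----------------------------------------
    if config.simulate:
        planted = [f"miR-planted{i:02d}" for i in range(1, config.n_planted + 1)]
        probe_ids = tuple(planted + [f"miR-bg{i:03d}" for i in
                                     range(1, config.n_probes - config.n_planted + 1)])
        screen_spec = CohortSpec(
            n_cases=config.n_screen_cases, n_controls=config.n_screen_controls,
            n_probes=config.n_probes, probe_ids=probe_ids,
            planted_probe_ids=frozenset(planted),
            delta_ct_shift=config.delta_ct_shift, seed=config.seed,
        )
        screen_samples, screen_ct = generate_cohort(screen_spec)
        val_panel = planted + [config.reference_mirna]
        val_spec = CohortSpec(
            n_cases=config.n_validation_cases, n_controls=config.n_validation_controls,
            n_probes=len(val_panel), probe_ids=tuple(val_panel),
            planted_probe_ids=frozenset(planted),
            delta_ct_shift=config.validation_delta_ct_shift, seed=config.seed + 1,
        )
        val_samples, val_ct = generate_triplicate_plates(
            val_spec, val_panel, iac_sample_id=config.iac_sample_id,
            reference_mirna=config.reference_mirna)
        write_sample_sheet(screen_samples, out / "screen_samples.csv")
        write_ct_table(screen_ct, out / "screen_ct.csv")
        write_sample_sheet(val_samples, out / "validation_samples.csv")
        write_ct_table(val_ct, out / "validation_ct.csv")
    else:
        screen_ct = read_ct_table(config.screen_ct_path)
        screen_samples = read_sample_sheet(config.screen_samples_path)
        val_ct = read_ct_table(config.validation_ct_path)
        val_samples = read_sample_sheet(config.validation_samples_path)
    counts["screen_ct_rows"] = len(screen_ct)
    counts["validation_ct_rows"] = len(val_ct)

    # --- stage: rank --------------------------------------------------------
    matrix = prepare_screen_matrix(screen_ct, screen_samples)
    ranked = rank_probes(matrix,
                         TrainConfig(hidden_nodes=config.hidden_nodes, seed=config.seed),
                         SplitScheme(n_repeats=config.n_repeats, seed=config.seed))
    ranked_frame = ranked_list_frame(ranked)
    ranked_frame.to_csv(out / "ranked_probes.csv", index=False)
    shortlist = select_top_k(ranked, min(config.top_k, len(ranked)))
    counts["probes_ranked"] = len(ranked)

    # --- stage: qpcr-process ------------------------------------------------
    summaries = aggregate_triplicates(val_ct)
    summaries = calibrate_interplate(summaries, config.iac_sample_id)
    summaries_to_frame(summaries).to_csv(out / "triplicate_summaries.csv", index=False)
    expression = compute_expression(summaries, config.reference_mirna,
                                    exclude_samples=(config.iac_sample_id,))
    expression.to_csv(out / "expression_nrq.csv")
    counts["triplicate_summaries"] = len(summaries)
    counts["expression_samples"] = len(expression.sample_ids)

    # --- stage: associate ---------------------------------------------------
    assoc = associate_expression(expression, val_samples, seed=config.seed)
    assoc.to_csv(out / "associations.csv", index=False)
    counts["association_tests"] = len(assoc)

    # --- stage: panel -------------------------------------------------------
    candidates = config.candidate_mirnas or [
        m for m in shortlist if m in expression.mirna_ids][:4]
    candidates = [m for m in candidates if m != config.reference_mirna]
    labels = val_samples.set_index("sample_id")["group"].map(
        {"case": 1, "control": 0})
    panels = search_combinations(expression, candidates, labels,
                                 min(config.max_panel_size, len(candidates)))
    panel_table(panels).to_csv(out / "panels.csv", index=False)
    counts["panels_evaluated"] = len(panels)

    manifest = {
        "package": "circmir",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "row_counts": counts,
        "top_probes": shortlist,
        "best_panel": {
            "mirna_ids": list(panels[0].mirna_ids),
            "auc": round(panels[0].auc, 6),
            "sensitivity": round(panels[0].sensitivity, 6),
            "specificity": round(panels[0].specificity, 6),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
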