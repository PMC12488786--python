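"""End-to-end orchestration: simulate (or ingest) -> select instruments ->
two-sample MR -> mediation -> report.

A :class:`RunConfig` carries every stage parameter (defaults are the
conventional analysis settings: p < 5e-8, clump r^2 0.001 within 10,000 kb,
MAF > 1%, F >= 10, Steiger alpha 0.05, proxy r^2 > 0.8, Bonferroni alpha
0.05, 95% intervals) plus the scenario and seed, and is serialized verbatim
into the report directory for provenance.  All randomness flows from the
single top-level seed through ``numpy.random.SeedSequence`` spawning, one
child per stage in fixed order, so adding a stage cannot perturb earlier
stages' draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gwas_io import write_summary
from .instruments import InstrumentConfig, select_instruments
from .mediation import run_two_step
from .simulate import SimulationConfig, simulate_panel

log = logging.getLogger("mrpath")

__all__ = ["RunConfig", "run_pipeline", "load_scenario", "default_scenario_path"]


def default_scenario_path() -> Path:
    return Path(__file__).parent / "scenarios" / "default.yaml"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serialized next to its outputs."""

    seed: int = 7
    out_dir: str = "mrpath_run"
    alpha: float = 0.05
    n_boot: int = 200
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    instruments: InstrumentConfig = field(default_factory=InstrumentConfig)
    panel: dict = field(
        default_factory=lambda: dict(
            n_mediators=168, n_true=95, n_reverse_instances=704, n_pleiotropic=1
        )
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_scenario(cls, scenario: dict, **overrides) -> "RunConfig":
        sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        inst_keys = {f.name for f in dataclasses.fields(InstrumentConfig)}
        sim = {k: v for k, v in scenario.items() if k in sim_keys}
        inst = {k: v for k, v in scenario.items() if k in inst_keys}
        panel = scenario.get("panel", {})
        top = {
            k: v
            for k, v in scenario.items()
            if k in {"seed", "out_dir", "alpha", "n_boot"}
        }
        top.update(overrides)
        for key in ("a_vec", "b_vec", "pleiotropy", "maf_range", "f_true_range",
                    "mediator_f_range", "palindrome_eaf_window"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
            if key in inst and isinstance(inst[key], list):
                inst[key] = tuple(inst[key])
        return cls(
            simulation=SimulationConfig(**sim),
            instruments=InstrumentConfig(**inst),
            panel=panel or cls.__dataclass_fields__["panel"].default_factory(),
            **top,
        )


def load_scenario(path=None) -> dict:
    """Read a plain-text scenario file (YAML key-value mapping)."""
    with open(path or default_scenario_path()) as fh:
        return yaml.safe_load(fh)


def _write_tables(report, out: Path) -> None:
    report.method_table.to_csv(out / "tsmr_methods.tsv", sep="\t", index=False)
    report.screen.table.to_csv(out / "mediator_screen.tsv", sep="\t", index=False)
    report.candidate_table.to_csv(out / "mediator_outcome.tsv", sep="\t", index=False)
    report.mvmr_table.to_csv(out / "mvmr_mediators.tsv", sep="\t", index=False)
    report.mediation_table.to_csv(out / "mediation.tsv", sep="\t", index=False)
    report.sign_exclusions.to_csv(out / "sign_exclusions.tsv", sep="\t", index=False)


def run_pipeline(config: RunConfig, write_datasets: bool = False):
    """Execute the full synthetic workflow and write the report bundle.

    Returns ``(report, summary_dict)``.  The directory receives the
    Fig-2-shaped method table, the screening and step-2 tables, the
    mediation decompositions, a stage-attrition table, the verbatim
    configuration, and a machine-readable ``summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_analysis = ss.spawn(2)

    t0 = time.perf_counter()
    log.info("stage=simulate seed=%s", config.seed)
    exposure, mediators, outcome, truth = simulate_panel(
        config.simulation, seed=seed_sim, **config.panel
    )
    log.info("stage=simulate done in %.1fs (%d mediators, %d variants)",
             time.perf_counter() - t0, len(mediators), len(exposure))
    if write_datasets:
        data_dir = out / "data"
        data_dir.mkdir(exist_ok=True)
        write_summary(exposure, data_dir / "exposure.tsv")
        write_summary(outcome, data_dir / "outcome.tsv")
        for name, med in mediators.items():
            write_summary(med, data_dir / f"{name}.tsv")

    t1 = time.perf_counter()
    instruments, h_total = select_instruments(
        exposure, outcome, config=config.instruments
    )
    instruments.attrition.to_csv(out / "attrition.tsv", sep="\t", index=False)
    log.info("stage=instruments done in %.1fs (%d instruments, mean F %.1f)",
             time.perf_counter() - t1, len(instruments.variant_ids), instruments.mean_f)

    t2 = time.perf_counter()
    report = run_two_step(
        exposure, mediators, outcome,
        config=config.instruments, alpha=config.alpha,
        seed=int(seed_analysis.generate_state(1)[0] % (2**31)),
        n_boot=config.n_boot,
    )
    log.info("stage=two_step done in %.1fs", time.perf_counter() - t2)

    _write_tables(report, out)
    summary = report.summary_dict()
    summary["config_seed"] = config.seed
    summary["n_instruments"] = len(instruments.variant_ids)
    summary["mean_f"] = instruments.mean_f
    summary["truth"] = dict(
        theta_total=truth.config.theta_total,
        c_prime=truth.config.c_prime,
        proportions=[float(p) for p in np.atleast_1d(truth.proportions)],
        mediators_of_interest=list(truth.mediator_instrument_ids)[: len(truth.config.a_vec)],
        pleiotropic_mediators=truth.pleiotropic_mediators,
        n_reverse_instances=len(truth.reverse_instances),
    )
    text = json.dumps(summary, sort_keys=True, indent=2, default=_jsonable)
    (out / "summary.json").write_text(text)
    return report, summary


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
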