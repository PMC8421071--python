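"""End-to-end characterization pipeline: config, orchestration, reports.

A run is described by a YAML config (see :class:`RunConfig`). ``simulate``
writes synthetic event tables plus ground-truth sidecars; ``characterize``
computes per-sample metrics (median, CoV, VIV, bootstrap CIs, fold metrics),
fits the dose-response curve and extracts the dynamic range and induction
threshold, writing a tidy metrics CSV, a JSON dose-response report and a JSON
run log. All outputs are deterministic for a given config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dose_response import (
    FpLogisticModel,
    fit_fplogistic,
    induction_threshold,
    input_dynamic_range,
)
from .errors import ConfigError
from .expression_metrics import coefficient_of_variation, median_fluorescence
from .flow_events import ChannelMap, EventTable, load_events, write_events
from .synthetic_flow import (
    DnaSpec,
    PopulationSpec,
    derive_seed,
    simulate_dna_population,
    simulate_dose_series,
    simulate_population,
)
from .variation import bootstrap_ci, viv, volume_proxy

__all__ = ["RunConfig", "characterize", "simulate"]

# Tidy metrics CSV columns; order is part of the public contract (v1).
METRICS_COLUMNS = [
    "sample_id", "dose_atc", "n_events",
    "median", "median_ci_lower", "median_ci_upper",
    "cov",
    "viv_rsd", "viv_ci_lower", "viv_ci_upper", "viv_n_used", "viv_n_dropped",
    "fold_over_autofluorescence", "percent_of_reference",
]

MODES = ("simulate", "characterize", "viv", "ploidy", "calibrate")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    mode: str = "characterize"
    seed: int | None = None
    channels: ChannelMap = field(default_factory=ChannelMap)
    population: PopulationSpec | None = None
    dna: DnaSpec | None = None
    doses: list[float] = field(default_factory=list)
    inputs: list[str] = field(default_factory=list)
    n_boot: int = 1000
    level: float = 0.95
    viv_n_boot: int | None = None  # defaults to n_boot
    viv_transform: str = "loglog"
    p1: float = 1.0
    p2: float = 2.0
    epsilon_frac: float = 0.01
    include_autofluorescence: bool = True

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError("mode", f"must be one of {MODES}, got {self.mode!r}")
        if self.seed is None and (self.population or self.dna or self.n_boot):
            raise ConfigError("seed", "required whenever any stochastic step runs")
        for p in self.inputs:
            if not Path(p).exists():
                raise ConfigError("inputs", f"input path does not exist: {p}")
        if any(d < 0 for d in self.doses):
            raise ConfigError("doses", "doses must be >= 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "channels" in raw:
            raw["channels"] = ChannelMap(**raw["channels"])
        if raw.get("population") is not None:
            raw["population"] = PopulationSpec.from_dict(raw["population"])
        if raw.get("dna") is not None:
            raw["dna"] = DnaSpec(**raw["dna"])
        bad = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if bad:
            raise ConfigError(sorted(bad)[0], "unknown config field")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("<root>", "config file must contain a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = dataclasses.asdict(self.channels)
        d["population"] = self.population.to_dict() if self.population else None
        d["dna"] = self.dna.to_dict() if self.dna else None
        return d


def _json_dump(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _autofluorescence_spec(pop: PopulationSpec, p1: float, p2: float) -> PopulationSpec:
    """Same population with the expression term zeroed (floor-only strain)."""
    return replace(pop, dose_model=FpLogisticModel(0.0, 0.0, 0.0, 0.0, p1, p2))


def _collect_samples(config: RunConfig):
    """Yield (EventTable, GroundTruth-or-None) per dose, plus the
    autofluorescence table when configured."""
    samples, auto_table = [], None
    if config.population is not None:
        if not config.doses:
            raise ConfigError("doses", "required with a population spec")
        pop = replace(config.population, seed=config.seed)
        samples = simulate_dose_series(pop, config.doses)
        if config.include_autofluorescence:
            auto_spec = replace(
                _autofluorescence_spec(pop, config.p1, config.p2),
                seed=derive_seed(config.seed, 10_001),
            )
            auto_table, _ = simulate_population(auto_spec, 0.0, sample_id="autofluorescence")
    elif config.inputs:
        for p in config.inputs:
            t = load_events(p)
            config.channels.validate(t, roles=("volume_x", "volume_y", "reporter"))
            samples.append((t, None))
        samples.sort(key=lambda st: st[0].meta.dose_atc)
    else:
        raise ConfigError("population", "either a population spec or inputs required")
    return samples, auto_table


def characterize(config: RunConfig, out_dir) -> dict:
    """Run the full characterization and write the report bundle.

    Writes ``metrics.csv``, ``dose_response.json`` and ``run_log.json`` into
    ``out_dir`` and returns the in-memory bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = config.channels
    samples, auto_table = _collect_samples(config)
    if len(samples) < 5:
        raise ConfigError("doses", "characterize needs >= 5 dose points")

    auto_median = (
        median_fluorescence(auto_table, cmap.reporter) if auto_table is not None else None
    )
    ref_table = samples[-1][0]  # top dose serves as the reference sample
    ref_median = median_fluorescence(ref_table, cmap.reporter)
    viv_n_boot = config.viv_n_boot if config.viv_n_boot is not None else config.n_boot

    rows, median_cis, dropped = [], [], {}
    for i, (table, _truth) in enumerate(samples):
        reporter = table.channel(cmap.reporter)
        med_ci = bootstrap_ci(
            reporter, "median", n_boot=config.n_boot, level=config.level,
            seed=derive_seed(config.seed, 20_000 + i),
        )
        median_cis.append(med_ci)
        v = viv(table, cmap, transform=config.viv_transform)
        pairs = np.column_stack([volume_proxy(table, cmap), reporter])
        viv_ci = bootstrap_ci(
            pairs, "viv_rsd", n_boot=viv_n_boot, level=config.level,
            seed=derive_seed(config.seed, 30_000 + i),
            transform=config.viv_transform,
        )
        dropped[table.meta.sample_id] = v.n_dropped
        rows.append({
            "sample_id": table.meta.sample_id,
            "dose_atc": table.meta.dose_atc,
            "n_events": table.n_events,
            "median": med_ci.point,
            "median_ci_lower": med_ci.lower,
            "median_ci_upper": med_ci.upper,
            "cov": coefficient_of_variation(table, cmap.reporter),
            "viv_rsd": v.rsd,
            "viv_ci_lower": viv_ci.lower,
            "viv_ci_upper": viv_ci.upper,
            "viv_n_used": v.n_used,
            "viv_n_dropped": v.n_dropped,
            "fold_over_autofluorescence": (
                med_ci.point / auto_median if auto_median else np.nan
            ),
            "percent_of_reference": 100.0 * med_ci.point / ref_median,
        })
    metrics = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    metrics.to_csv(out_dir / "metrics.csv", index=False, float_format="%.10g")

    doses = np.array([t.meta.dose_atc for t, _ in samples])
    medians = np.array([r["median"] for r in rows])
    fit = fit_fplogistic(doses, medians, p1=config.p1, p2=config.p2)
    dr = input_dynamic_range(fit.model, epsilon_frac=config.epsilon_frac)
    threshold = None
    if np.any(doses == 0):
        zero_ci = median_cis[int(np.flatnonzero(doses == 0)[0])]
        threshold = induction_threshold(doses, medians, zero_ci)
    fold_diff = float(medians.max() / medians.min()) if medians.min() > 0 else None

    report = {
        **fit.model.to_dict(),
        "rmse": fit.rmse,
        "converged": bool(fit.converged),
        "flat": bool(fit.flat),
        "dynamic_range": dr.to_dict(),
        "induction_threshold": threshold,
        "fold_difference": fold_diff,
    }
    _json_dump(report, out_dir / "dose_response.json")

    run_log = {
        "titerflow_version": __version__,
        "config": config.to_dict(),
        "sample_seeds": {
            t.meta.sample_id: derive_seed(config.seed, i)
            for i, (t, _) in enumerate(samples)
        },
        "dropped_events": dropped,
    }
    _json_dump(run_log, out_dir / "run_log.json")
    return {"metrics": metrics, "dose_response": report, "run_log": run_log}


def simulate(config: RunConfig, out_dir) -> list[Path]:
    """Write synthetic event tables and ground-truth sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if config.population is not None:
        if not config.doses:
            raise ConfigError("doses", "required with a population spec")
        pop = replace(config.population, seed=config.seed)
        for i, (table, truth) in enumerate(simulate_dose_series(pop, config.doses)):
            stem = f"events_{i:02d}_dose_{table.meta.dose_atc:g}"
            written.append(write_events(table, out_dir / f"{stem}.csv"))
            written.append(truth.write_csv(out_dir / f"{stem}.truth.csv"))
    elif config.dna is not None:
        dna = replace(config.dna, seed=config.seed)
        table, truth = simulate_dna_population(dna)
        written.append(write_events(table, out_dir / "dna_events.csv"))
        lab = pd.DataFrame({"label": truth.labels})
        lab_path = out_dir / "dna_events.truth.csv"
        lab.to_csv(lab_path, index=False)
        written.append(lab_path)
    else:
        raise ConfigError("population", "a population or dna spec is required")
    return written
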