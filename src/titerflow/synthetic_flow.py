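"""Seeded synthetic flow-cytometry populations with known ground truth.

The generative model per event i:

* volume        ``V_i ~ LogNormal(vol_meanlog, vol_sdlog)`` (fL)
* scatter       ``FSC-W_i = scatter_gain_x * V_i * exp(eps)`` and likewise
  SSC-H / FSC-A, with ``eps ~ Normal(0, scatter_noise_sd)`` drawn per channel
* reporter      ``A_i + M(dose) * (V_i / median V)^expr_alpha * exp(xi + eta)``
  where ``A_i`` is lognormal autofluorescence (additive floor), ``M(dose)``
  is the dose-response model median, ``xi ~ N(0, expr_extrinsic_sd)`` is
  between-cell extrinsic noise and ``eta ~ N(0, viv_sd)`` is the injected
  volume-independent variation.

All randomness flows through ``numpy.random.Generator`` seeded with PCG64,
so identical specs and seeds give bit-identical tables. DNA-content
populations are 1n/2n/>2n mixtures of truncated normals on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .dose_response import FpLogisticModel, fplogistic_eval
from .errors import ParameterError
from .flow_events import EventTable, SampleMeta

__all__ = [
    "PopulationSpec",
    "DnaSpec",
    "GroundTruth",
    "DnaGroundTruth",
    "simulate_population",
    "simulate_dose_series",
    "simulate_dna_population",
    "DEFAULT_DOSE_MODEL",
]

# An increasing curve: f(0) = (c+d)/2 = 550 a.u., saturating at d = 1000.
DEFAULT_DOSE_MODEL = FpLogisticModel(b=-2.0, c=100.0, d=1000.0, e=-0.1, p1=1.0, p2=2.0)

CHANNELS = ("FSC-A", "FSC-W", "SSC-H", "FL1")


@dataclass(frozen=True)
class PopulationSpec:
    """Hidden parameters of one synthetic population."""

    n_events: int = 10_000
    seed: int = 0
    vol_meanlog: float = float(np.log(40.0))  # median volume 40 fL
    vol_sdlog: float = 0.25
    scatter_gain_x: float = 25.0
    scatter_gain_y: float = 12.0
    scatter_noise_sd: float = 0.05
    auto_meanlog: float = float(np.log(80.0))
    auto_sdlog: float = 0.25
    expr_alpha: float = 1.0
    expr_extrinsic_sd: float = 0.2
    viv_sd: float = 0.2
    dose_model: FpLogisticModel = DEFAULT_DOSE_MODEL

    def __post_init__(self):
        if self.n_events < 1:
            raise ParameterError("n_events must be >= 1")
        for name in ("vol_sdlog", "scatter_noise_sd", "auto_sdlog",
                     "expr_extrinsic_sd", "viv_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.scatter_gain_x <= 0 or self.scatter_gain_y <= 0:
            raise ParameterError("scatter gains must be > 0")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_events", "seed", "vol_meanlog", "vol_sdlog", "scatter_gain_x",
            "scatter_gain_y", "scatter_noise_sd", "auto_meanlog", "auto_sdlog",
            "expr_alpha", "expr_extrinsic_sd", "viv_sd")}
        d["dose_model"] = self.dose_model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        if "dose_model" in d and isinstance(d["dose_model"], dict):
            d["dose_model"] = FpLogisticModel(**d["dose_model"])
        return cls(**d)


@dataclass(frozen=True)
class DnaSpec:
    """Parameters of a synthetic DNA-content (ploidy) population."""

    n_events: int = 10_000
    seed: int = 0
    frac_1n: float = 0.5
    frac_2n: float = 0.5
    frac_gt2n: float = 0.0
    peak_1n_mean: float = 1000.0
    peak_cv: float = 0.08
    gt2n_factor: float = 4.0

    def __post_init__(self):
        w = (self.frac_1n, self.frac_2n, self.frac_gt2n)
        if any(x < 0 for x in w):
            raise ParameterError("mixture weights must be >= 0")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ParameterError(f"mixture weights must sum to 1, got {sum(w)}")
        if self.peak_cv <= 0:
            raise ParameterError("peak_cv must be > 0")
        if self.n_events < 1:
            raise ParameterError("n_events must be >= 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_events", "seed", "frac_1n", "frac_2n", "frac_gt2n",
            "peak_1n_mean", "peak_cv", "gt2n_factor")}


@dataclass
class GroundTruth:
    """Per-event hidden state of a simulated population, row-aligned with the
    emitted EventTable, plus the scalar truths recovery tests check against."""

    volume: np.ndarray          # true volume, fL
    expression: np.ndarray      # reporter signal minus autofluorescence, a.u.
    true_median: float          # exact median of the expression term = M(dose)
    auto_median: float          # exact median of the autofluorescence term
    viv_sd: float               # injected volume-independent log-noise SD
    dose: float

    @property
    def predicted_reporter_median(self) -> float:
        """Large-n approximation of the reporter median (additive floor)."""
        return self.auto_median + self.true_median

    def write_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#true_median={self.true_median!r}\n")
            fh.write(f"#auto_median={self.auto_median!r}\n")
            fh.write(f"#viv_sd={self.viv_sd!r}\n")
            fh.write(f"#dose={self.dose!r}\n")
            fh.write("volume,expression\n")
            np.savetxt(fh, np.column_stack([self.volume, self.expression]),
                       fmt="%.17g", delimiter=",")
        return path


@dataclass
class DnaGroundTruth:
    """Component labels (0=1n, 1=2n, 2=>2n) and mixture truths."""

    labels: np.ndarray
    means: tuple[float, float, float]
    weights: tuple[float, float, float]

    @property
    def label_fractions(self) -> tuple[float, float, float]:
        n = len(self.labels)
        return tuple(float(np.sum(self.labels == k)) / n for k in range(3))


def _normal(rng, sd: float, n: int) -> np.ndarray:
    # draw even when sd == 0 so the stream layout is sd-independent
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


def simulate_population(
    spec: PopulationSpec, dose: float, sample_id: str | None = None
) -> tuple[EventTable, GroundTruth]:
    """Simulate one population at the given aTc dose.

    Identical (spec, dose) pairs produce bit-identical outputs.
    """
    if dose < 0:
        raise ParameterError(f"dose must be >= 0, got {dose}")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_events

    volume = np.exp(rng.normal(spec.vol_meanlog, spec.vol_sdlog, n)) \
        if spec.vol_sdlog > 0 else np.full(n, np.exp(spec.vol_meanlog))
    fsc_a = spec.scatter_gain_x * volume * np.exp(_normal(rng, spec.scatter_noise_sd, n))
    fsc_w = spec.scatter_gain_x * volume * np.exp(_normal(rng, spec.scatter_noise_sd, n))
    ssc_h = spec.scatter_gain_y * volume * np.exp(_normal(rng, spec.scatter_noise_sd, n))

    auto = np.exp(rng.normal(spec.auto_meanlog, spec.auto_sdlog, n)) \
        if spec.auto_sdlog > 0 else np.full(n, np.exp(spec.auto_meanlog))

    m_dose = fplogistic_eval(spec.dose_model, dose)
    med_v = float(np.median(volume))
    xi = _normal(rng, spec.expr_extrinsic_sd, n)
    eta = _normal(rng, spec.viv_sd, n)
    expression = m_dose * (volume / med_v) ** spec.expr_alpha * np.exp(xi + eta)
    reporter = auto + expression

    meta = SampleMeta(
        sample_id=sample_id or f"sim_dose_{dose:g}",
        strain_id="synthetic",
        dose_atc=float(dose),
    )
    table = EventTable(
        np.column_stack([fsc_a, fsc_w, ssc_h, reporter]), CHANNELS, meta
    )
    truth = GroundTruth(
        volume=volume,
        expression=expression,
        true_median=float(m_dose),
        auto_median=float(np.exp(spec.auto_meanlog)),
        viv_sd=spec.viv_sd,
        dose=float(dose),
    )
    return table, truth


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic child seed for the index-th member of a series."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(ss.generate_state(1, np.uint64)[0])


def simulate_dose_series(
    spec: PopulationSpec, doses
) -> list[tuple[EventTable, GroundTruth]]:
    """One population per dose, with per-dose seeds derived from spec.seed."""
    doses = list(doses)
    if len(doses) == 0:
        raise ParameterError("dose list must be nonempty")
    if any(d < 0 for d in doses):
        raise ParameterError("all doses must be >= 0")
    out = []
    for i, dose in enumerate(doses):
        sub = replace(spec, seed=derive_seed(spec.seed, i))
        out.append(simulate_population(sub, dose))
    return out


def simulate_dna_population(spec: DnaSpec) -> tuple[EventTable, DnaGroundTruth]:
    """Mixture of 1n/2n/>2n DNA-stain peaks (truncated normals, linear scale)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_events
    weights = (spec.frac_1n, spec.frac_2n, spec.frac_gt2n)
    means = (
        spec.peak_1n_mean,
        2.0 * spec.peak_1n_mean,
        spec.gt2n_factor * spec.peak_1n_mean,
    )
    labels = rng.choice(3, size=n, p=weights)
    signal = np.empty(n)
    for k in range(3):
        idx = labels == k
        cnt = int(idx.sum())
        if cnt == 0:
            continue
        mu, sd = means[k], spec.peak_cv * means[k]
        a = (0.0 - mu) / sd  # truncate at zero signal
        signal[idx] = truncnorm.rvs(a, np.inf, loc=mu, scale=sd,
                                    size=cnt, random_state=rng)
    meta = SampleMeta(sample_id=f"dna_{spec.seed}", strain_id="synthetic")
    table = EventTable(signal[:, None], ("DNA",), meta)
    return table, DnaGroundTruth(labels=labels, means=means, weights=weights)
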