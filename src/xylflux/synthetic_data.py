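"""Synthetic-data generators standing in for the study's raw measurements.

Two generators, both seeded and deterministic:

* labeled-fragment MID datasets with additive Gaussian measurement noise
  (clipped and renormalized), emulating GC-MS/IC-MS mass-isotopomer data
  measured after growth on 1,2-13C xylose;
* OD600 growth curves with a lag phase, logistic (capacity-limited)
  exponential growth, multiplicative noise, and yield-coupled substrate
  depletion, sampled on a plate-reader-like schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_network import AtomMappedNetwork, FluxDistribution
from .isotope_forward import (MeasurementSpec, MidDataset, MidVector,
                              TracerSpec, simulate_mids)

__all__ = [
    "MidNoiseModel",
    "GrowthGeneratorSpec",
    "generate_mid_dataset",
    "generate_growth_curves",
    "DEFAULT_TRACER",
]

#: The study's tracer: 100% [1,2-13C]xylose at 99% isotopic purity.
DEFAULT_TRACER = TracerSpec("XYL.ext", (((1, 2), 1.0),), purity=0.99)


@dataclass
class MidNoiseModel:
    """Additive Gaussian noise per mass fraction (default SD 0.004, a
    typical GC-MS MID repeatability), with optional multiplicative mode."""

    sd: float = 0.004
    renormalize: bool = True
    multiplicative: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise SD must be >= 0")


def generate_mid_dataset(net: AtomMappedNetwork, truth: FluxDistribution,
                         tracer: TracerSpec, spec: MeasurementSpec,
                         noise: MidNoiseModel,
                         sd_floor: float = 0.003) -> tuple[MidDataset, FluxDistribution]:
    """Simulate MIDs from a ground-truth flux distribution and add noise.

    Returns ``(dataset, truth)`` so the truth rides alongside for scoring.
    The recorded SD column is ``max(noise.sd, sd_floor)``.
    """
    clean = simulate_mids(net, truth, tracer, spec)
    rng = np.random.default_rng(noise.seed)
    sd_rec = max(noise.sd, sd_floor)
    out = {}
    for f in spec.fragments:
        y = clean[f.id].fractions.copy()
        if noise.sd > 0:
            if noise.multiplicative:
                y = y * (1.0 + noise.sd * rng.standard_normal(len(y)))
            else:
                y = y + noise.sd * rng.standard_normal(len(y))
            y = np.clip(y, 0.0, None)
            if noise.renormalize:
                y = y / y.sum()
        out[f.id] = MidVector(f.id, y, sd=np.full(len(y), sd_rec))
    return MidDataset(out), truth


@dataclass
class GrowthGeneratorSpec:
    """Parameters of the growth-curve generator.

    Defaults emulate the study's batch cultures: 5 g/L xylose minimal
    medium, OD sampled every 15 min, OD-to-CDW factor 0.39 g/L per OD unit.
    """

    od0: float = 0.05
    mumax: float = 0.21          # 1/h
    lag: float = 3.4             # h
    capacity: float = 3.5        # OD units
    noise_sd: float = 0.01       # multiplicative
    dt: float = 0.25             # h (15 min)
    t_end: float = 30.0          # h
    od_to_cdw: float = 0.39      # gCDW/L per OD
    s0: float = 5.0              # g/L substrate
    yield_gx: float = 0.31       # gCDW per g substrate

    def __post_init__(self):
        for name in ("od0", "mumax", "lag", "capacity", "dt", "t_end",
                     "od_to_cdw", "s0", "yield_gx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def mean_od(self, t: np.ndarray) -> np.ndarray:
        """Lagged logistic growth curve."""
        te = np.clip(t - self.lag, 0.0, None)
        if self.mumax == 0:
            return np.full_like(t, self.od0, dtype=float)
        e = np.exp(self.mumax * te)
        return self.capacity * self.od0 * e / (
            self.capacity + self.od0 * (e - 1.0))


def generate_growth_curves(spec: GrowthGeneratorSpec, n_replicates: int = 1,
                           seed: int | None = None,
                           with_substrate: bool = True) -> pd.DataFrame:
    """Plate/flask table with columns well_or_flask, t_h, od600[, substrate_gL]."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, spec.t_end + spec.dt / 2, spec.dt)
    mean = spec.mean_od(t)
    frames = []
    for i in range(n_replicates):
        noise = 1.0 + spec.noise_sd * rng.standard_normal(len(t)) \
            if spec.noise_sd > 0 else np.ones(len(t))
        od = np.clip(mean * noise, 0.0, None)
        rec = {"well_or_flask": f"rep{i + 1}", "t_h": t, "od600": od}
        if with_substrate:
            cdw = mean * spec.od_to_cdw
            cdw0 = mean[0] * spec.od_to_cdw
            s = spec.s0 - (cdw - cdw0) / spec.yield_gx if spec.yield_gx > 0 \
                else np.full_like(t, spec.s0)
            rec["substrate_gL"] = np.clip(s, 0.0, None)
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)
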