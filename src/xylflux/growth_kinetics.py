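"""Growth-kinetics estimation from OD600 (and substrate) time series.

The maximal specific growth rate is the steepest slope of ln(OD) over a
sliding window that passes an R-squared screen (a rolling log-linear
regression); the lag is where that tangent intersects the initial
ln(OD) baseline.  Biomass yield and the specific substrate uptake rate
follow from the OD-to-CDW conversion (0.39 gCDW/L per OD unit,
gravimetrically determined for these strains) and the xylose molar mass.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthRecord",
    "GrowthFit",
    "NoExponentialPhaseError",
    "fit_growth",
    "yield_and_uptake",
    "generations",
    "load_growth_csv",
    "M_XYLOSE",
    "OD_TO_CDW_DEFAULT",
]

M_XYLOSE = 150.13        # g/mol
OD_TO_CDW_DEFAULT = 0.39  # gCDW/L per OD600 unit


class NoExponentialPhaseError(RuntimeError):
    pass


@dataclass
class GrowthRecord:
    t: np.ndarray                  # h, strictly increasing
    od: np.ndarray                 # OD600
    substrate: np.ndarray | None = None  # g/L, same grid
    od_to_cdw: float = OD_TO_CDW_DEFAULT

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.t.ndim != 1 or len(self.t) != len(self.od):
            raise ValueError("t and od must be 1-D and equally long")
        if not (np.diff(self.t) > 0).all():
            raise ValueError("time points must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("negative OD values")
        if self.substrate is not None:
            self.substrate = np.asarray(self.substrate, dtype=float)
            if len(self.substrate) != len(self.t):
                raise ValueError("substrate series length mismatch")


@dataclass
class GrowthFit:
    mumax: float               # 1/h
    lag: float | None          # h; None when undefined (no growth)
    window: tuple[int, int]    # index range of the best window
    r2: float
    y_xs: float | None = None  # gCDW per g substrate
    q_s: float | None = None   # mmol gCDW^-1 h^-1


def fit_growth(record: GrowthRecord, window: int = 13, min_r2: float = 0.97,
               od_floor: float = 0.01) -> GrowthFit:
    """Rolling log-linear regression for mumax and tangent-intercept lag.

    Points with OD below ``od_floor`` are excluded from log fits.  Raises
    :class:`NoExponentialPhaseError` when no window reaches ``min_r2``.
    A flat culture returns mumax 0 with lag None.
    """
    mask = record.od > od_floor
    t, od = record.t[mask], record.od[mask]
    if len(t) < window:
        raise NoExponentialPhaseError(
            f"only {len(t)} points above the OD floor; window is {window}")
    ln = np.log(od)
    best = None
    for i in range(len(t) - window + 1):
        ts, ys = t[i:i + window], ln[i:i + window]
        slope, intercept = np.polyfit(ts, ys, 1)
        pred = slope * ts + intercept
        sst = np.sum((ys - ys.mean()) ** 2)
        r2 = 1.0 - np.sum((ys - pred) ** 2) / sst if sst > 0 else 1.0
        if r2 >= min_r2 and (best is None or slope > best[0]):
            best = (slope, intercept, i, r2)
    if best is None:
        raise NoExponentialPhaseError(
            f"no {window}-point window reached R^2 >= {min_r2}")
    slope, intercept, i, r2 = best
    mumax = max(slope, 0.0)
    if mumax <= 1e-9:
        return GrowthFit(0.0, None, (i, i + window), r2)
    baseline = ln[: max(window // 2, 2)].mean()
    lag = (baseline - intercept) / slope
    return GrowthFit(float(mumax), float(max(lag, 0.0)), (i, i + window),
                     float(r2))


def yield_and_uptake(record: GrowthRecord, window: int = 13,
                     min_r2: float = 0.97,
                     m_substrate: float = M_XYLOSE) -> GrowthFit:
    """Biomass yield Y_X/S and specific uptake q_S over the consumption window.

    Y_X/S = dCDW/dS with CDW = OD * od_to_cdw; q_S = mumax / (Y_X/S * M)
    in mmol gCDW^-1 h^-1 (M in g/mmol).
    """
    if record.substrate is None:
        raise ValueError("record has no substrate series")
    fit = fit_growth(record, window=window, min_r2=min_r2)
    if fit.mumax <= 0:
        raise ValueError("no growth; yield undefined")
    s = record.substrate
    ds_steps = np.diff(s)
    if (ds_steps > 3 * np.std(ds_steps) + 1e-12).any():
        import warnings

        warnings.warn("substrate series increases beyond noise", stacklevel=2)
    consumed = s[0] - s[-1]
    if consumed <= 0:
        raise ValueError("no net substrate consumption")
    d_cdw = (record.od[-1] - record.od[0]) * record.od_to_cdw
    y_xs = d_cdw / consumed
    q_s = fit.mumax / (y_xs * (m_substrate / 1000.0))
    return GrowthFit(fit.mumax, fit.lag, fit.window, fit.r2,
                     y_xs=float(y_xs), q_s=float(q_s))


def generations(od_initial: float, od_final: float) -> float:
    """Number of generations = ln(OD_final / OD_initial) / ln 2."""
    if od_initial <= 0 or od_final <= 0:
        raise ValueError("OD values must be positive")
    return float(np.log(od_final / od_initial) / np.log(2.0))


def load_growth_csv(text: str, od_to_cdw: float = OD_TO_CDW_DEFAULT
                    ) -> dict[str, GrowthRecord]:
    """Plate/flask CSV (well_or_flask, t_h, od600[, substrate_gL]) to records."""
    df = pd.read_csv(io.StringIO(text))
    out = {}
    for well, grp in df.groupby("well_or_flask", sort=False):
        grp = grp.sort_values("t_h")
        sub = grp["substrate_gL"].to_numpy() if "substrate_gL" in grp else None
        out[well] = GrowthRecord(grp["t_h"].to_numpy(), grp["od600"].to_numpy(),
                                 substrate=sub, od_to_cdw=od_to_cdw)
    return out
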