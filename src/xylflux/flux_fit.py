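"""Estimation of the flux distribution from corrected MIDs.

The steady-state constraint S.v = 0 together with the measured uptake
(set to 100%) and growth-scaled biomass drains leaves a small number of
free net fluxes; reversible reactions additionally carry bidirectional
exchange fluxes, optimized through the bounded transform
rho = exch / (exch + uptake).  The variance-weighted sum of squared
residuals between simulated and measured mass fractions is minimized by
bound-constrained nonlinear least squares from multiple seeded starts, and
confidence intervals are profiled by parameter continuation: the target
flux is stepped away from its optimum, all other parameters re-optimized,
until the SSR crosses the chi-square threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .core_network import AtomMappedNetwork, FluxDistribution
from .isotope_forward import (EmuDecomposition, MeasurementSpec, MidDataset,
                              TracerSpec, decompose_emu, simulate_mids)

__all__ = [
    "PRECURSOR_DEMANDS",
    "biomass_drain_fluxes",
    "project_to_steady_state",
    "FreeFluxParam",
    "FitResult",
    "fit_fluxes",
    "goodness_of_fit",
    "GoodnessOfFit",
    "confidence_interval_continuation",
    "sample_steady_state_fluxes",
]

#: Biomass precursor demands in mmol per gCDW (standard Gram-negative
#: composition), keyed by the drain reaction ids of the packaged core
#: network.  The G3P/PEP-stage demand is lumped onto the PEP drain because
#: the core model lumps the lower EMP steps.
PRECURSOR_DEMANDS: dict[str, float] = {
    "dG6P": 0.205,
    "dF6P": 0.0709,
    "dR5P": 0.0898,
    "dE4P": 0.0361,
    "dGAP": 0.0129,
    "dPEP": 2.0151,   # 3-phosphoglycerate + PEP demand combined
    "dPYR": 2.8328,
    "dAcCoA": 3.7478,
    "dOAA": 1.7867,
    "dAKG": 1.0789,
}

#: Default free net fluxes and fitted exchange fluxes for the packaged
#: EDEMP core network.
DEFAULT_FREE_REACTIONS = ("pgi", "ppc", "maeB", "pyc", "fbp")
DEFAULT_EXCHANGE_REACTIONS = ("tkt1", "tkt2", "tal", "pgi")


def biomass_drain_fluxes(mu: float, q_s: float,
                         demands: dict[str, float] | None = None) -> dict[str, float]:
    """Drain fluxes in % of uptake for growth rate ``mu`` (1/h) and uptake
    ``q_s`` (mmol gCDW^-1 h^-1): demand_i * mu / q_s * 100."""
    demands = demands or PRECURSOR_DEMANDS
    return {r: d * mu / q_s * 100.0 for r, d in demands.items()}


class FreeFluxParam:
    """Linear parameterization of the steady-state flux space.

    Given fixed fluxes (uptake and drains) and a set of free reactions whose
    net fluxes serve as coordinates, every flux vector is
    ``v = v0 + W @ theta``.  Raises if the free set does not complete the
    constraint system to full rank.
    """

    def __init__(self, net: AtomMappedNetwork, fixed: dict[str, float],
                 free_reactions: list[str] | None = None, flux_cap: float = 300.0):
        self.net = net
        self.fixed = dict(fixed)
        S, mets, rxns = net.stoichiometric_matrix()
        self.reaction_ids = rxns
        self._ridx = {r: i for i, r in enumerate(rxns)}
        n = len(rxns)

        rows = [S]
        rhs0 = [np.zeros(S.shape[0])]
        for r, val in self.fixed.items():
            if r not in self._ridx:
                raise KeyError(f"fixed reaction {r!r} not in network")
            e = np.zeros(n); e[self._ridx[r]] = 1.0
            rows.append(e[None, :]); rhs0.append([val])
        C = np.vstack(rows)
        b_fixed = np.concatenate(rhs0)
        probe = np.linalg.lstsq(C, b_fixed, rcond=None)[0]
        if np.abs(C @ probe - b_fixed).max() > 1e-6:
            raise ValueError("fixed fluxes are inconsistent with steady state")
        base_rank = np.linalg.matrix_rank(C)
        self.n_free = n - base_rank
        if free_reactions is None:
            free_reactions = self._auto_select(C, n, base_rank)
        if len(free_reactions) != self.n_free:
            raise ValueError(
                f"need {self.n_free} free reactions, got {len(free_reactions)}")
        self.free_reactions = list(free_reactions)

        M = np.vstack([C] + [self._unit(r, n)[None, :] for r in self.free_reactions])
        if np.linalg.matrix_rank(M) < n:
            raise ValueError(
                f"free reaction set {self.free_reactions} leaves the flux space "
                f"underdetermined")
        b0 = np.concatenate(rhs0 + [np.zeros(len(self.free_reactions))])
        sol, res, *_ = np.linalg.lstsq(M, b0, rcond=None)
        if np.abs(M @ sol - b0).max() > 1e-8:
            raise ValueError("fixed fluxes are inconsistent with steady state")
        self.v0 = sol
        W = np.empty((n, self.n_free))
        for j in range(self.n_free):
            b = b0.copy(); b[C.shape[0] + j] = 1.0
            W[:, j] = np.linalg.lstsq(M, b, rcond=None)[0] - self.v0
        self.W = W
        self.flux_cap = flux_cap
        self._irrev_idx = np.array(
            [self._ridx[r] for r in rxns if not net.reactions[r].reversible],
            dtype=int)
        self._irrev_ids = [r for r in rxns if not net.reactions[r].reversible]

    def _unit(self, r, n):
        e = np.zeros(n); e[self._ridx[r]] = 1.0
        return e

    def _auto_select(self, C, n, base_rank):
        chosen = []
        cur = C
        for r in self.reaction_ids:
            if r in self.fixed:
                continue
            cand = np.vstack([cur, self._unit(r, n)[None, :]])
            if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(cur):
                chosen.append(r)
                cur = cand
            if len(chosen) == n - base_rank:
                break
        return chosen

    # -- mapping -----------------------------------------------------------
    def flux_vector(self, theta: np.ndarray) -> np.ndarray:
        return self.v0 + self.W @ np.asarray(theta, dtype=float)

    def theta_of(self, flux: FluxDistribution) -> np.ndarray:
        return np.array([flux.net[r] for r in self.free_reactions])

    def to_distribution(self, theta: np.ndarray,
                        exchange: dict[str, float] | None = None) -> FluxDistribution:
        v = self.flux_vector(theta)
        return FluxDistribution(
            net={r: float(v[self._ridx[r]]) for r in self.reaction_ids},
            exchange=dict(exchange or {}))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb, ub = [], []
        for r in self.free_reactions:
            if self.net.reactions[r].reversible:
                lb.append(-self.flux_cap)
            else:
                lb.append(0.0)
            ub.append(self.flux_cap)
        return np.array(lb), np.array(ub)

    def infeasibility(self, v: np.ndarray) -> np.ndarray:
        """Negative parts of irreversible net fluxes (all zero when feasible)."""
        return np.clip(-v[self._irrev_idx], 0.0, None)

    def with_free(self, target: str) -> "FreeFluxParam":
        """Rebuild with ``target`` guaranteed to be a free coordinate
        (used by parameter continuation)."""
        if target in self.free_reactions:
            return self
        for drop in self.free_reactions:
            cand = [target] + [r for r in self.free_reactions if r != drop]
            try:
                return FreeFluxParam(self.net, self.fixed, cand, self.flux_cap)
            except ValueError:
                continue
        raise ValueError(f"cannot make {target!r} a free flux")


def project_to_steady_state(pfp: FreeFluxParam,
                            flux: FluxDistribution) -> FluxDistribution:
    """Exactly re-balance a (possibly rounded) flux distribution by reading
    its free-flux coordinates and rebuilding all dependent fluxes from the
    steady-state constraints.  Exchange fluxes are carried over unchanged."""
    theta = pfp.theta_of(flux)
    out = pfp.to_distribution(theta, dict(flux.exchange))
    out.uptake_rate_abs = flux.uptake_rate_abs
    out.sd = dict(flux.sd)
    return out


def sample_steady_state_fluxes(pfp: FreeFluxParam, rng: np.random.Generator,
                               box: tuple[float, float] = (1.0, 120.0),
                               min_flux: float = 0.0, max_tries: int = 10000,
                               exchange_box: tuple[float, float] | None = None,
                               center: np.ndarray | None = None,
                               spread: float = 0.3) -> FluxDistribution:
    """Rejection-sample a steady-state flux distribution with all
    irreversible net fluxes >= ``min_flux``; used by property tests and the
    synthetic generators.  With ``center`` given, free fluxes are drawn as
    multiplicative perturbations of that coordinate vector (useful on tightly
    constrained networks where box rejection rarely succeeds)."""
    lb, ub = pfp.bounds()
    for _ in range(max_tries):
        if center is not None:
            theta = np.asarray(center, dtype=float) * rng.uniform(
                1.0 - spread, 1.0 + spread, size=pfp.n_free)
            theta = np.clip(theta, lb, ub)
        else:
            theta = rng.uniform(np.maximum(lb, -box[1]), np.minimum(ub, box[1]))
        v = pfp.flux_vector(theta)
        free_irrev = np.array([i for i, r in zip(pfp._irrev_idx, pfp._irrev_ids)
                               if r not in pfp.fixed], dtype=int)
        if (v[free_irrev] >= min_flux).all() and (v[pfp._irrev_idx] >= 0).all():
            exch = {}
            if exchange_box is not None:
                for r in pfp.reaction_ids:
                    if pfp.net.reactions[r].reversible:
                        exch[r] = float(rng.uniform(*exchange_box))
            return pfp.to_distribution(theta, exch)
    raise RuntimeError("could not sample a feasible flux distribution")


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    flux: FluxDistribution
    ssr: float
    dof: int
    n_residuals: int
    theta: np.ndarray
    rho: np.ndarray
    free_reactions: list[str]
    exchange_reactions: list[str]
    n_starts: int
    seed: int | None
    start_ssrs: list[float] = field(default_factory=list)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def chi2_bounds(self) -> tuple[float, float]:
        return (float(stats.chi2.ppf(0.025, self.dof)),
                float(stats.chi2.ppf(0.975, self.dof)))


class _Objective:
    """Weighted residuals between simulated and measured mass fractions,
    plus hinge penalties keeping dependent irreversible fluxes >= 0."""

    PENALTY = 30.0

    def __init__(self, pfp: FreeFluxParam, dec: EmuDecomposition,
                 dataset: MidDataset, tracer: TracerSpec, spec: MeasurementSpec,
                 exchange_reactions: list[str], sd_floor: float):
        self.pfp = pfp
        self.dec = dec
        self.tracer = tracer
        self.spec = spec
        self.exchange_reactions = list(exchange_reactions)
        self.frag_ids = [f.id for f in spec.fragments if f.id in dataset]
        self.meas = np.concatenate([dataset[f].fractions for f in self.frag_ids])
        sds = []
        for f in self.frag_ids:
            sd = dataset[f].sd
            if sd is None:
                sd = np.full_like(dataset[f].fractions, sd_floor)
            sds.append(np.maximum(sd, sd_floor))
        self.sd = np.concatenate(sds)
        self.n_residuals = len(self.meas)

    def split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = len(self.pfp.free_reactions)
        return x[:k], x[k:]

    def flux_of(self, x: np.ndarray) -> FluxDistribution:
        theta, rho = self.split(x)
        exch = {r: 100.0 * p / (1.0 - p)
                for r, p in zip(self.exchange_reactions, rho)}
        return self.pfp.to_distribution(theta, exch)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        theta, rho = self.split(x)
        v = self.pfp.flux_vector(theta)
        infeas = self.pfp.infeasibility(v)
        if infeas.max(initial=0.0) > 0.0:
            # clip to the feasible boundary for simulation; the penalty
            # residuals push the optimizer back inside
            v = v.copy()
            v[self.pfp._irrev_idx] = np.clip(v[self.pfp._irrev_idx], 0.0, None)
        flux = FluxDistribution(
            net={r: float(v[self.pfp._ridx[r]]) for r in self.pfp.reaction_ids},
            exchange={r: 100.0 * p / (1.0 - p)
                      for r, p in zip(self.exchange_reactions, rho)})
        sim = simulate_mids(self.pfp.net, flux, self.tracer, self.spec, self.dec,
                            strict=False)
        simv = np.concatenate([sim[f].fractions for f in self.frag_ids])
        resid = (simv - self.meas) / self.sd
        return np.concatenate([resid, self.PENALTY * infeas])

    def ssr(self, x: np.ndarray) -> float:
        return float(np.sum(self(x) ** 2))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb, ub = self.pfp.bounds()
        k = len(self.exchange_reactions)
        return (np.concatenate([lb, np.zeros(k)]),
                np.concatenate([ub, np.full(k, 0.9)]))


def _draw_start(obj: _Objective, rng: np.random.Generator) -> np.ndarray:
    lb, ub = obj.bounds()
    k = len(obj.pfp.free_reactions)
    x = np.empty(len(lb))
    for i in range(k):
        if lb[i] >= 0.0:
            x[i] = np.exp(rng.uniform(np.log(0.5), np.log(max(ub[i], 1.0))))
        else:
            mag = np.exp(rng.uniform(np.log(0.5), np.log(max(ub[i], 1.0))))
            x[i] = mag if rng.random() < 0.5 else -mag
    x[k:] = rng.uniform(0.0, 0.5, size=len(lb) - k)
    return np.clip(x, lb, ub)


def fit_fluxes(net: AtomMappedNetwork, dataset: MidDataset, tracer: TracerSpec,
               spec: MeasurementSpec,
               measured_rates: dict[str, float] | None = None,
               n_starts: int = 50, seed: int | None = None,
               free_reactions: list[str] | None = None,
               exchange_reactions: list[str] | None = None,
               fixed_fluxes: dict[str, float] | None = None,
               sd_floor: float = 0.003, flux_cap: float = 300.0,
               xtol: float = 1e-12) -> FitResult:
    """Multi-start weighted least-squares flux estimation.

    ``measured_rates`` = {"uptake": q_S (mmol/gCDW/h), "growth": mu (1/h)}
    scales the biomass precursor drains; alternatively pass ``fixed_fluxes``
    (in % of uptake) directly.  The uptake reaction is fixed at 100%.
    Deterministic for a given seed and inputs.
    """
    if fixed_fluxes is None:
        if measured_rates is None:
            raise ValueError("provide measured_rates or fixed_fluxes")
        drains = biomass_drain_fluxes(measured_rates["growth"],
                                      measured_rates["uptake"])
        fixed_fluxes = {r: f for r, f in drains.items() if r in net.reactions}
    fixed = dict(fixed_fluxes)
    fixed[net.uptake_reaction_id] = 100.0

    if free_reactions is None and all(
            r in net.reactions for r in DEFAULT_FREE_REACTIONS):
        free_reactions = list(DEFAULT_FREE_REACTIONS)
    if exchange_reactions is None:
        exchange_reactions = [r for r in DEFAULT_EXCHANGE_REACTIONS
                              if r in net.reactions
                              and net.reactions[r].reversible]

    pfp = FreeFluxParam(net, fixed, free_reactions, flux_cap)
    dec = decompose_emu(net, spec)
    obj = _Objective(pfp, dec, dataset, tracer, spec, exchange_reactions, sd_floor)
    lb, ub = obj.bounds()
    rng = np.random.default_rng(seed)

    best = None
    start_ssrs = []
    failures = []
    for _ in range(n_starts):
        x0 = _draw_start(obj, rng)
        try:
            res = least_squares(obj, x0, bounds=(lb, ub), method="trf",
                                xtol=xtol, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # singular EMU systems at pathological starts
            failures.append(str(exc))
            continue
        ssr = float(np.sum(res.fun ** 2))
        start_ssrs.append(ssr)
        if best is None or ssr < best[0]:
            best = (ssr, res.x.copy())
    if best is None:
        raise RuntimeError(
            f"no start converged ({n_starts} attempted); diagnostics: "
            f"{failures[:3]}")

    ssr, x = best
    # polish the winner
    res = least_squares(obj, x, bounds=(lb, ub), method="trf",
                        xtol=1e-14, ftol=1e-15, gtol=1e-15)
    if float(np.sum(res.fun ** 2)) <= ssr:
        ssr, x = float(np.sum(res.fun ** 2)), res.x

    theta, rho = obj.split(x)
    flux = obj.flux_of(x)
    v = pfp.flux_vector(theta)
    assert pfp.infeasibility(v).max(initial=0.0) < 1e-6, \
        "optimum violates irreversibility"
    n_params = len(x)
    dof = sum(len(dataset[f].fractions) - 1 for f in obj.frag_ids) - n_params
    return FitResult(flux=flux, ssr=ssr, dof=dof, n_residuals=obj.n_residuals,
                     theta=theta, rho=rho, free_reactions=pfp.free_reactions,
                     exchange_reactions=list(exchange_reactions),
                     n_starts=n_starts, seed=seed, start_ssrs=start_ssrs)


@dataclass
class GoodnessOfFit:
    ssr: float
    dof: int
    lower: float
    upper: float
    passed: bool
    fail_low: bool


def goodness_of_fit(fit: FitResult, alpha: float = 0.05) -> GoodnessOfFit:
    """Chi-square acceptance test: SSR must lie within the central
    (1 - alpha) band of the chi-square distribution with the fit's degrees
    of freedom."""
    if fit.dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({fit.dof}): "
                         f"model is overparameterized for this dataset")
    lo = float(stats.chi2.ppf(alpha / 2, fit.dof))
    hi = float(stats.chi2.ppf(1 - alpha / 2, fit.dof))
    return GoodnessOfFit(fit.ssr, fit.dof, lo, hi,
                         passed=lo <= fit.ssr <= hi,
                         fail_low=fit.ssr < lo)


# ---------------------------------------------------------------------------
# parameter continuation

def _profile_ssr(obj: _Objective, free_idx: int, value: float,
                 x_warm: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimize SSR with one free coordinate pinned to ``value``."""
    mask = np.ones(len(x_warm), dtype=bool)
    mask[free_idx] = False

    def sub(xs):
        full = x_warm.copy()
        full[mask] = xs
        full[free_idx] = value
        return obj(full)

    res = least_squares(sub, np.clip(x_warm[mask], lb[mask], ub[mask]),
                        bounds=(lb[mask], ub[mask]), method="trf",
                        jac="3-point", xtol=1e-10, ftol=1e-12, gtol=1e-12)
    full = x_warm.copy()
    full[mask] = res.x
    full[free_idx] = value
    return float(np.sum(res.fun ** 2)), full


def confidence_interval_continuation(
        net: AtomMappedNetwork, dataset: MidDataset, tracer: TracerSpec,
        spec: MeasurementSpec, fit: FitResult, reaction_id: str,
        alpha: float = 0.05, fixed_fluxes: dict[str, float] | None = None,
        measured_rates: dict[str, float] | None = None,
        sd_floor: float = 0.003, step: float | None = None,
        max_steps: int = 60, tol: float = 0.05,
        flux_cap: float = 300.0) -> tuple[float, float, dict]:
    """Profile-likelihood CI for one net flux by parameter continuation.

    Steps the target flux away from its optimum (re-optimizing everything
    else, warm-started) until SSR exceeds ``SSR_opt + chi2_1(1-alpha)``,
    then locates the crossing by bisection.  Open bounds (never crossing
    within the feasible range) are flagged in the returned info dict.
    """
    if fixed_fluxes is None:
        if measured_rates is not None:
            drains = biomass_drain_fluxes(measured_rates["growth"],
                                          measured_rates["uptake"])
            fixed_fluxes = {r: f for r, f in drains.items() if r in net.reactions}
        else:
            raise ValueError("provide measured_rates or fixed_fluxes")
    fixed = dict(fixed_fluxes)
    fixed[net.uptake_reaction_id] = 100.0

    pfp = FreeFluxParam(net, fixed, fit.free_reactions, flux_cap).with_free(reaction_id)
    dec = decompose_emu(net, spec)
    obj = _Objective(pfp, dec, dataset, tracer, spec, fit.exchange_reactions,
                     sd_floor)
    lb, ub = obj.bounds()
    # express the fit optimum in the (possibly re-based) parameterization
    theta0 = np.array([fit.flux.net[r] for r in pfp.free_reactions])
    x_opt = np.concatenate([theta0, fit.rho])
    x_opt = np.clip(x_opt, lb, ub)
    free_idx = pfp.free_reactions.index(reaction_id)
    v_opt = float(fit.flux.net[reaction_id])
    ssr_opt, x_opt = _profile_ssr(obj, free_idx, v_opt, x_opt, lb, ub)
    threshold = ssr_opt + float(stats.chi2.ppf(1 - alpha, 1))

    if step is None:
        step = max(0.5, 0.05 * abs(v_opt))

    info = {"ssr_opt": ssr_opt, "threshold": threshold,
            "open_lower": False, "open_upper": False}

    def search(direction: int) -> float:
        lo_val, lo_x = v_opt, x_opt
        h = step
        for _ in range(max_steps):
            cand = lo_val + direction * h
            if cand < lb[free_idx] or cand > ub[free_idx]:
                cand = lb[free_idx] if direction < 0 else ub[free_idx]
                ssr, _ = _profile_ssr(obj, free_idx, cand, lo_x, lb, ub)
                if ssr < threshold:
                    info["open_lower" if direction < 0 else "open_upper"] = True
                    return cand
                break
            ssr, xc = _profile_ssr(obj, free_idx, cand, lo_x, lb, ub)
            if ssr >= threshold:
                break
            lo_val, lo_x = cand, xc
            h *= 1.6
        else:
            info["open_lower" if direction < 0 else "open_upper"] = True
            return lo_val
        hi_val = cand
        # bisection between the last sub-threshold and first supra-threshold
        for _ in range(40):
            if abs(hi_val - lo_val) <= tol:
                break
            mid = 0.5 * (lo_val + hi_val)
            ssr, xm = _profile_ssr(obj, free_idx, mid, lo_x, lb, ub)
            if ssr >= threshold:
                hi_val = mid
            else:
                lo_val, lo_x = mid, xm
        return 0.5 * (lo_val + hi_val)

    upper = search(+1)
    lower = search(-1)
    return lower, upper, info
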