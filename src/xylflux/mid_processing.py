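"""Correction of measured MIDs for natural isotope abundance and for
unlabeled biomass carried over with the inoculum.

GC-MS fragments of TBDMS-derivatized amino acids drag along large Si/C/H/N/O
envelopes whose natural heavy isotopes (and the natural 13C of the backbone
itself) shift the observed mass distribution away from the tracer-derived
labeling.  The observed distribution is the clean backbone-label MID pushed
through a linear convolution map; correction inverts that map by
non-negative least squares.  The same machinery covers IC-MS sugar
phosphates (no derivatization, just the molecular formula).

All maps here are linear and column-stochastic, so natural-abundance
correction and unlabeled-biomass removal commute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .isotope_forward import MidDataset, MidVector

__all__ = [
    "FragmentFormula",
    "CorrectionConfig",
    "CorrectionResult",
    "IUPAC_ABUNDANCES",
    "correction_matrix",
    "correct_mid",
    "remove_unlabeled_biomass",
    "correct_dataset",
    "load_formula_table",
]

#: Natural isotope abundances (IUPAC 2013), as mass-shift distributions
#: (index = extra mass units relative to the lightest isotope).
IUPAC_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "P": (1.0,),
}


@dataclass(frozen=True)
class FragmentFormula:
    """Element counts of the detected fragment ion, plus how many of the
    carbons belong to the metabolite backbone (= correctable label
    positions)."""

    fragment_id: str
    elements: dict[str, int]
    backbone_carbons: int

    def __post_init__(self):
        total_c = self.elements.get("C", 0)
        if self.backbone_carbons > total_c:
            raise ValueError(
                f"{self.fragment_id}: backbone carbons ({self.backbone_carbons}) "
                f"exceed total C ({total_c})")
        if any(v < 0 for v in self.elements.values()):
            raise ValueError(f"{self.fragment_id}: negative element count")


@dataclass
class CorrectionConfig:
    abundances: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(IUPAC_ABUNDANCES))
    unlabeled_biomass_fraction: float = 0.0

    def __post_init__(self):
        for el, dist in self.abundances.items():
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"abundances for {el} sum to {sum(dist)}, not 1")
        if not 0.0 <= self.unlabeled_biomass_fraction < 1.0:
            raise ValueError("unlabeled_biomass_fraction must be in [0, 1)")


def _power_convolve(dist: np.ndarray, n: int) -> np.ndarray:
    out = np.array([1.0])
    for _ in range(n):
        out = np.convolve(out, dist)
    return out


def correction_matrix(formula: FragmentFormula, cfg: CorrectionConfig | None = None,
                      n_rows: int | None = None) -> np.ndarray:
    """Column-stochastic matrix mapping the backbone-label MID to the
    observed mass-shift distribution.

    Column j (j labeled backbone carbons) is the convolution of the natural
    isotope envelopes of all non-backbone atoms with natural 13C over the
    remaining ``backbone - j`` positions, shifted by j.
    """
    cfg = cfg or CorrectionConfig()
    nb = formula.backbone_carbons
    base = np.array([1.0])
    for el, count in formula.elements.items():
        if count == 0:
            continue
        n = count - nb if el == "C" else count
        if el not in cfg.abundances:
            raise KeyError(f"no natural-abundance entry for element {el!r}")
        base = np.convolve(base, _power_convolve(np.asarray(cfg.abundances[el]), n))
    c_dist = np.asarray(cfg.abundances.get("C", IUPAC_ABUNDANCES["C"]))
    cols = []
    for j in range(nb + 1):
        unl = _power_convolve(c_dist, nb - j)
        col = np.convolve(base, unl)
        shifted = np.concatenate([np.zeros(j), col])
        cols.append(shifted)
    n_rows = n_rows or max(len(c) for c in cols)
    M = np.zeros((n_rows, nb + 1))
    for j, col in enumerate(cols):
        k = min(n_rows, len(col))
        M[:k, j] = col[:k]
    return M


@dataclass
class CorrectionResult:
    mid: MidVector
    residual: float
    warning: str | None = None


def correct_mid(observed: MidVector, formula: FragmentFormula,
                cfg: CorrectionConfig | None = None,
                residual_threshold: float = 0.02) -> CorrectionResult:
    """Invert the natural-abundance convolution by non-negative least squares.

    Returns the renormalized backbone-label MID, the NNLS residual, and a
    quality warning when the fit is poor.
    """
    cfg = cfg or CorrectionConfig()
    y = np.asarray(observed.fractions, dtype=float)
    nb = formula.backbone_carbons
    if len(y) < nb + 1:
        raise ValueError(
            f"{observed.fragment_id}: observed vector has {len(y)} entries, "
            f"needs at least {nb + 1}")
    M = correction_matrix(formula, cfg, n_rows=len(y))
    x, rnorm = nnls(M, y)
    warning = None
    if rnorm > residual_threshold:
        warning = (f"{observed.fragment_id}: correction residual {rnorm:.4f} "
                   f"exceeds {residual_threshold}")
        warnings.warn(warning, stacklevel=2)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{observed.fragment_id}: corrected MID vanished")
    mid = MidVector(observed.fragment_id, x / total, sd=observed.sd)
    return CorrectionResult(mid, float(rnorm), warning)


def remove_unlabeled_biomass(corrected: MidVector, f: float,
                             unlabeled_mid: np.ndarray | None = None) -> MidVector:
    """Remove the unlabeled cell population introduced with the inoculum.

    The measured pool is a (1-f):f mixture of tracer-grown and unlabeled
    biomass; the labeled-population MID is ``(mid - f * unlabeled) / (1 - f)``,
    clipped at zero and renormalized.  After natural-abundance correction the
    unlabeled population is pure M+0, which is the default.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError(f"unlabeled biomass fraction must be in [0, 1), got {f}")
    y = np.asarray(corrected.fractions, dtype=float)
    if unlabeled_mid is None:
        unlabeled = np.zeros_like(y)
        unlabeled[0] = 1.0
    else:
        unlabeled = np.asarray(unlabeled_mid, dtype=float)
    out = (y - f * unlabeled) / (1.0 - f)
    out = np.clip(out, 0.0, None)
    total = out.sum()
    if total <= 0:
        raise ValueError(f"{corrected.fragment_id}: biomass correction vanished")
    return MidVector(corrected.fragment_id, out / total, sd=corrected.sd)


def correct_dataset(dataset: MidDataset, formulas: dict[str, FragmentFormula],
                    cfg: CorrectionConfig | None = None) -> tuple[MidDataset, dict[str, float]]:
    """Natural-abundance + unlabeled-biomass correction of a whole dataset.

    Fragments without a formula entry are passed through unchanged.
    Returns the corrected dataset and per-fragment NNLS residuals.
    """
    cfg = cfg or CorrectionConfig()
    out, residuals = {}, {}
    for mv in dataset:
        if mv.fragment_id in formulas:
            res = correct_mid(mv, formulas[mv.fragment_id], cfg)
            mid = res.mid
            residuals[mv.fragment_id] = res.residual
        else:
            mid = mv
        if cfg.unlabeled_biomass_fraction > 0:
            mid = remove_unlabeled_biomass(mid, cfg.unlabeled_biomass_fraction)
        out[mv.fragment_id] = mid
    return MidDataset(out), residuals


def load_formula_table(text: str) -> dict[str, FragmentFormula]:
    """Fragment formula CSV: fragment_id,C,H,N,O,Si,S,backbone_carbons."""
    import io

    import pandas as pd

    df = pd.read_csv(io.StringIO(text))
    out = {}
    for _, row in df.iterrows():
        elements = {el: int(row[el]) for el in ("C", "H", "N", "O", "Si", "S")
                    if el in row and int(row[el]) > 0}
        out[row["fragment_id"]] = FragmentFormula(
            row["fragment_id"], elements, int(row["backbone_carbons"]))
    return out


def load_packaged_formulas() -> dict[str, FragmentFormula]:
    from importlib.resources import files

    return load_formula_table(
        files("xylflux.data").joinpath("fragment_formulas.csv").read_text())
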