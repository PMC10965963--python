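"""Atom-mapped metabolic networks and flux distributions.

The central objects of the package: a small, human-auditable text dialect
for carbon-mapped reaction networks (one reaction per line), the stoichiometric
matrix over balanced metabolites, and flux distributions expressed as molar
percent of substrate uptake (uptake = 100).

Network file dialect
--------------------
::

    # comment
    @substrate XYL.ext
    @uptake upt
    @unbalanced XYL.ext CO2
    @met X5P 5 xylulose 5-phosphate
    upt:  XYL.ext (abcde) -> XYL (abcde) ! XylE
    tkt1: X5P (abcde) + R5P (fghij) <-> S7P (abfghij) + GAP (cde) ! Tkt
    sdh:  SUC (abcd) -> FUM (abcd|dcba) ! Sdh
    dG6P: G6P -> ! drain

* one letter per carbon atom; the multiset of letters must balance between
  the two sides (drain lines, which carry no letters, are exempt);
* ``A|B`` gives equal-weight atom-map variants, used for the 50/50
  orientation scrambling of the symmetric intermediates succinate and
  fumarate;
* ``<->`` marks a reaction as reversible, ``->`` as irreversible;
* ``! label`` attaches an enzyme label (hyphenated for lumped steps,
  e.g. ``Zwf-Pgl``);
* ``@unbalanced`` lists source/sink species excluded from the steady-state
  balance (the substrate feed and the CO2 pool).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Metabolite",
    "AtomMap",
    "Reaction",
    "AtomMappedNetwork",
    "FluxDistribution",
    "NetworkParseError",
    "NetworkValidationError",
    "parse_network",
    "write_network",
    "validate_steady_state",
    "load_flux_table",
    "write_flux_table",
    "load_packaged_network",
    "load_packaged_fluxes",
]


class NetworkParseError(ValueError):
    """Malformed network file line."""


class NetworkValidationError(ValueError):
    """Structurally valid file that violates a network invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    name: str = ""
    is_balanced: bool = True

    def __post_init__(self):
        if self.n_carbons < 0:
            raise NetworkValidationError(f"{self.id}: negative carbon count")


@dataclass(frozen=True)
class AtomMap:
    """One atom-transition variant: carbon letters per substrate/product slot.

    ``substrates``/``products`` hold ``(metabolite_id, letters)`` in the order
    the species appear in the reaction line.
    """

    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]

    def reversed(self) -> "AtomMap":
        return AtomMap(substrates=self.products, products=self.substrates)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # signed; negative = consumed
    reversible: bool = False
    atom_maps: tuple[AtomMap, ...] = ()  # equal-weight variants; empty for drains
    enzyme_label: str = ""

    @property
    def substrate_ids(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def product_ids(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class AtomMappedNetwork:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    substrate_id: str
    uptake_reaction_id: str

    # -- structure ---------------------------------------------------------
    @property
    def balanced_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.is_balanced]

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """S over balanced metabolites; returns (S, metabolite ids, reaction ids)."""
        mets = self.balanced_ids
        rxns = self.reaction_ids
        midx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        for j, rid in enumerate(rxns):
            for m, c in self.reactions[rid].stoichiometry.items():
                if m in midx:
                    S[midx[m], j] = c
        return S, mets, rxns

    def enzyme_components(self) -> set[str]:
        """Individual enzyme names, splitting hyphenated lumped labels."""
        out: set[str] = set()
        for r in self.reactions.values():
            if r.enzyme_label:
                out.update(p for p in r.enzyme_label.split("-") if p)
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for rid, rxn in self.reactions.items():
            for amap in rxn.atom_maps:
                sub_letters: list[str] = []
                for m, letters in amap.substrates + amap.products:
                    nc = self.metabolites[m].n_carbons
                    if len(letters) != nc:
                        raise NetworkValidationError(
                            f"reaction {rid}: {m} has {nc} carbons but atom map "
                            f"'{letters}' has {len(letters)} letters"
                        )
                for m, letters in amap.substrates:
                    sub_letters.extend(letters)
                prod_letters = [c for _, s in amap.products for c in s]
                if sorted(sub_letters) != sorted(prod_letters):
                    raise NetworkValidationError(
                        f"reaction {rid}: atom letters unbalanced "
                        f"({''.join(sorted(sub_letters))} vs {''.join(sorted(prod_letters))})"
                    )
        upt = self.reactions.get(self.uptake_reaction_id)
        if upt is None:
            raise NetworkValidationError(f"uptake reaction {self.uptake_reaction_id!r} missing")
        if self.substrate_id not in upt.substrate_ids:
            raise NetworkValidationError(
                f"uptake reaction {self.uptake_reaction_id!r} does not consume "
                f"substrate {self.substrate_id!r}"
            )

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "substrate_id": self.substrate_id,
            "uptake_reaction_id": self.uptake_reaction_id,
            "metabolites": [
                {"id": m.id, "n_carbons": m.n_carbons, "name": m.name,
                 "is_balanced": m.is_balanced}
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": r.stoichiometry,
                    "reversible": r.reversible,
                    "enzyme_label": r.enzyme_label,
                    "atom_maps": [
                        {"substrates": list(map(list, a.substrates)),
                         "products": list(map(list, a.products))}
                        for a in r.atom_maps
                    ],
                }
                for r in self.reactions.values()
            ],
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AtomMappedNetwork":
        obj = json.loads(text)
        mets = {
            m["id"]: Metabolite(m["id"], m["n_carbons"], m.get("name", ""),
                                m.get("is_balanced", True))
            for m in obj["metabolites"]
        }
        rxns = {}
        for r in obj["reactions"]:
            maps = tuple(
                AtomMap(
                    substrates=tuple((s[0], s[1]) for s in a["substrates"]),
                    products=tuple((p[0], p[1]) for p in a["products"]),
                )
                for a in r["atom_maps"]
            )
            rxns[r["id"]] = Reaction(r["id"], dict(r["stoichiometry"]),
                                     r["reversible"], maps, r.get("enzyme_label", ""))
        net = cls(mets, rxns, obj["substrate_id"], obj["uptake_reaction_id"])
        net.validate()
        return net


# ---------------------------------------------------------------------------
# parsing

_SPECIES_RE = re.compile(
    r"^\s*(?:(?P<coeff>\d+(?:\.\d+)?)\s+)?(?P<met>[A-Za-z0-9_.]+)"
    r"(?:\s*\((?P<letters>[a-zA-Z|]+)\))?\s*$"
)


def _parse_side(side: str, lineno: int):
    """Returns list of (met, coeff, letter_variants or None)."""
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split("+"):
        m = _SPECIES_RE.match(term)
        if not m:
            raise NetworkParseError(f"line {lineno}: cannot parse species term {term.strip()!r}")
        coeff = float(m.group("coeff") or 1.0)
        letters = m.group("letters")
        variants = tuple(letters.split("|")) if letters else None
        out.append((m.group("met"), coeff, variants))
    return out


def parse_network(text: str) -> AtomMappedNetwork:
    """Parse the network-file dialect into a validated :class:`AtomMappedNetwork`."""
    substrate_id = None
    uptake_id = None
    unbalanced: set[str] = set()
    declared: dict[str, tuple[int, str]] = {}
    reactions: dict[str, Reaction] = {}
    carbon_counts: dict[str, int] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@"):
            parts = line.split()
            key = parts[0]
            if key == "@substrate":
                substrate_id = parts[1]
            elif key == "@uptake":
                uptake_id = parts[1]
            elif key == "@unbalanced":
                unbalanced.update(parts[1:])
            elif key == "@met":
                declared[parts[1]] = (int(parts[2]), " ".join(parts[3:]))
            else:
                raise NetworkParseError(f"line {lineno}: unknown directive {key!r}")
            continue

        if ":" not in line:
            raise NetworkParseError(f"line {lineno}: expected 'id: reaction', got {line!r}")
        rid, body = line.split(":", 1)
        rid = rid.strip()
        label = ""
        if "!" in body:
            body, label = body.rsplit("!", 1)
            label = label.strip()
        if "<->" in body:
            reversible = True
            lhs, rhs = body.split("<->", 1)
        elif "->" in body:
            reversible = False
            lhs, rhs = body.split("->", 1)
        else:
            raise NetworkParseError(f"line {lineno}: reaction {rid!r} has no arrow")
        subs = _parse_side(lhs, lineno)
        prods = _parse_side(rhs, lineno)
        if not subs:
            raise NetworkParseError(f"line {lineno}: reaction {rid!r} has no substrates")
        if rid in reactions:
            raise NetworkParseError(f"line {lineno}: duplicate reaction id {rid!r}")

        stoich: dict[str, float] = {}
        for met, coeff, _ in subs:
            stoich[met] = stoich.get(met, 0.0) - coeff
        for met, coeff, _ in prods:
            stoich[met] = stoich.get(met, 0.0) + coeff

        # atom maps: broadcast single-variant species across the variant count
        n_var = max([len(v) for _, _, v in subs + prods if v is not None], default=0)
        has_letters = [v is not None for _, _, v in subs + prods]
        maps: tuple[AtomMap, ...] = ()
        if any(has_letters):
            if not all(has_letters):
                raise NetworkParseError(
                    f"line {lineno}: reaction {rid!r} mixes mapped and unmapped species"
                )
            variant_maps = []
            for k in range(n_var):
                def pick(v):
                    if len(v) == 1:
                        return v[0]
                    if len(v) != n_var:
                        raise NetworkParseError(
                            f"line {lineno}: reaction {rid!r} has inconsistent "
                            f"variant counts"
                        )
                    return v[k]
                variant_maps.append(AtomMap(
                    substrates=tuple((met, pick(v)) for met, _, v in subs),
                    products=tuple((met, pick(v)) for met, _, v in prods),
                ))
            maps = tuple(variant_maps)
            for met, _, v in subs + prods:
                for s in v:
                    n = len(s)
                    if met in carbon_counts and carbon_counts[met] != n:
                        raise NetworkValidationError(
                            f"line {lineno}: {met} has {carbon_counts[met]} carbons "
                            f"elsewhere but {n} in reaction {rid!r}"
                        )
                    carbon_counts[met] = n

        reactions[rid] = Reaction(rid, stoich, reversible, maps, label)

    all_mets: set[str] = set()
    for r in reactions.values():
        all_mets.update(r.stoichiometry)
    metabolites = {}
    for m in sorted(all_mets):
        if m in declared:
            nc, name = declared[m]
            if m in carbon_counts and carbon_counts[m] != nc:
                raise NetworkValidationError(
                    f"{m}: declared {nc} carbons but atom maps imply {carbon_counts[m]}"
                )
        else:
            nc, name = carbon_counts.get(m, 0), ""
        metabolites[m] = Metabolite(m, nc, name, is_balanced=m not in unbalanced)

    if substrate_id is None or uptake_id is None:
        # single-reaction convenience: infer from the first reaction
        first = next(iter(reactions.values()))
        if uptake_id is None:
            uptake_id = first.id
        if substrate_id is None:
            substrate_id = first.substrate_ids[0]
        # the inferred feed species is a source
        metabolites[substrate_id] = Metabolite(
            substrate_id, metabolites[substrate_id].n_carbons,
            metabolites[substrate_id].name, is_balanced=False)

    net = AtomMappedNetwork(metabolites, reactions, substrate_id, uptake_id)
    net.validate()
    return net


def write_network(net: AtomMappedNetwork) -> str:
    """Serialize back to the text dialect (inverse of :func:`parse_network`)."""
    lines = [f"@substrate {net.substrate_id}", f"@uptake {net.uptake_reaction_id}"]
    unbal = [m.id for m in net.metabolites.values() if not m.is_balanced]
    if unbal:
        lines.append("@unbalanced " + " ".join(unbal))
    for m in net.metabolites.values():
        if m.name:
            lines.append(f"@met {m.id} {m.n_carbons} {m.name}")

    def fmt_side(slots, variants_by_slot):
        terms = []
        for i, (met, coeff) in enumerate(slots):
            c = "" if coeff == 1 else f"{coeff:g} "
            if variants_by_slot is not None:
                letters = "|".join(variants_by_slot[i])
                terms.append(f"{c}{met} ({letters})")
            else:
                terms.append(f"{c}{met}")
        return " + ".join(terms)

    for r in net.reactions.values():
        arrow = "<->" if r.reversible else "->"
        if r.atom_maps:
            sub_slots = [(m, -r.stoichiometry[m] if r.stoichiometry[m] < 0 else 1.0)
                         for m, _ in r.atom_maps[0].substrates]
            prod_slots = [(m, 1.0) for m, _ in r.atom_maps[0].products]
            sub_vars = [[a.substrates[i][1] for a in r.atom_maps]
                        for i in range(len(r.atom_maps[0].substrates))]
            prod_vars = [[a.products[i][1] for a in r.atom_maps]
                         for i in range(len(r.atom_maps[0].products))]
            # collapse identical variants
            sub_vars = [v if len(set(v)) > 1 else [v[0]] for v in sub_vars]
            prod_vars = [v if len(set(v)) > 1 else [v[0]] for v in prod_vars]
            lhs = fmt_side(sub_slots, sub_vars)
            rhs = fmt_side(prod_slots, prod_vars)
        else:
            lhs = fmt_side([(m, -c) for m, c in r.stoichiometry.items() if c < 0], None)
            rhs = fmt_side([(m, c) for m, c in r.stoichiometry.items() if c > 0], None)
        label = f" ! {r.enzyme_label}" if r.enzyme_label else ""
        lines.append(f"{r.id}: {lhs} {arrow} {rhs}{label}".rstrip())
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# flux distributions

@dataclass
class FluxDistribution:
    """Net fluxes in molar % of substrate uptake (uptake = 100).

    ``exchange`` holds bidirectional exchange fluxes (same units) for
    reversible reactions; ``sd`` per-reaction standard errors;
    ``uptake_rate_abs`` the absolute uptake in mmol gCDW^-1 h^-1 used to
    convert percentages to absolute rates.
    """

    net: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)
    exchange: dict[str, float] = field(default_factory=dict)
    lb: dict[str, float] = field(default_factory=dict)
    ub: dict[str, float] = field(default_factory=dict)
    uptake_rate_abs: float = float("nan")

    def absolute(self, reaction_id: str) -> float:
        """Net flux in mmol gCDW^-1 h^-1."""
        return self.net[reaction_id] * self.uptake_rate_abs / 100.0

    def vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.net[r] for r in reaction_ids])


@dataclass
class SteadyStateReport:
    max_residual: float
    residuals: dict[str, float]
    tol_abs: float
    passed: bool


def validate_steady_state(net: AtomMappedNetwork, flux: FluxDistribution,
                          tol: float = 0.02) -> SteadyStateReport:
    """Check S.v = 0 over balanced metabolites.

    ``tol`` is a fraction of the uptake flux (uptake = 100), so the default
    0.02 accepts node imbalances up to 2% of uptake.
    """
    S, mets, rxns = net.stoichiometric_matrix()
    missing = [r for r in rxns if r not in flux.net]
    if missing:
        raise ValueError(f"flux distribution missing reactions: {missing}")
    v = flux.vector(rxns)
    resid = S @ v
    residuals = {m: float(r) for m, r in zip(mets, resid)}
    max_res = float(np.max(np.abs(resid))) if len(resid) else 0.0
    return SteadyStateReport(max_res, residuals, tol * 100.0, max_res <= tol * 100.0)


def load_flux_table(text: str, uptake_reaction_id: str = "upt") -> FluxDistribution:
    """Load the flux TSV (columns reaction, net_pct, sd_pct[, exch_pct, lb_pct, ub_pct]).

    A header line ``# uptake_rate_abs = X`` carries the absolute uptake rate.
    Fluxes are rescaled so that the uptake reaction is exactly 100 (with a
    warning if the stored table used a different normalization).
    """
    import io

    import pandas as pd

    uptake_abs = float("nan")
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            m = re.search(r"uptake_rate_abs\s*=\s*([0-9.eE+-]+)", line)
            if m:
                uptake_abs = float(m.group(1))
            continue
        body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    required = {"reaction", "net_pct", "sd_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"flux table needs columns {sorted(required)}")
    if (df["sd_pct"] < 0).any():
        bad = df.loc[df["sd_pct"] < 0, "reaction"].tolist()
        raise ValueError(f"negative sd for {bad}")
    df = df.set_index("reaction")
    if uptake_reaction_id not in df.index:
        raise ValueError(f"uptake reaction {uptake_reaction_id!r} absent from table")
    scale = 100.0 / df.loc[uptake_reaction_id, "net_pct"]
    if abs(scale - 1.0) > 1e-9:
        warnings.warn(
            f"flux table uptake was {df.loc[uptake_reaction_id, 'net_pct']:g}; "
            f"rescaling so uptake = 100", stacklevel=2)
    flux = FluxDistribution(
        net={r: float(x) * scale for r, x in df["net_pct"].items()},
        sd={r: float(x) * abs(scale) for r, x in df["sd_pct"].items()},
        uptake_rate_abs=uptake_abs,
    )
    for col, attr in [("exch_pct", "exchange"), ("lb_pct", "lb"), ("ub_pct", "ub")]:
        if col in df.columns:
            setattr(flux, attr,
                    {r: float(x) * scale for r, x in df[col].items() if pd.notna(x)})
    return flux


def write_flux_table(flux: FluxDistribution, uptake_reaction_id: str = "upt") -> str:
    cols = ["reaction", "net_pct", "sd_pct"]
    if flux.exchange:
        cols.append("exch_pct")
    if flux.lb:
        cols += ["lb_pct", "ub_pct"]
    lines = []
    if flux.uptake_rate_abs == flux.uptake_rate_abs:  # not NaN
        lines.append(f"# uptake_rate_abs = {flux.uptake_rate_abs:g}")
    lines.append("\t".join(cols))
    for r, v in flux.net.items():
        row = [r, f"{v:.8g}", f"{flux.sd.get(r, 0.0):.6g}"]
        if flux.exchange:
            row.append(f"{flux.exchange.get(r, 0.0):.6g}")
        if flux.lb:
            row += [f"{flux.lb.get(r, float('nan')):.6g}",
                    f"{flux.ub.get(r, float('nan')):.6g}"]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str):
    from importlib.resources import files

    return files("xylflux.data").joinpath(name)


def load_packaged_network(name: str = "edemp_core.net") -> AtomMappedNetwork:
    """Load a network shipped with the package (EDEMP core or the toys)."""
    return parse_network(_data_path(name).read_text())


def load_packaged_fluxes(name: str = "edemp_fluxes.tsv",
                         uptake_reaction_id: str = "upt") -> FluxDistribution:
    """Load the packaged ground-truth flux distribution (xylose-grown PD310)."""
    return load_flux_table(_data_path(name).read_text(), uptake_reaction_id)
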