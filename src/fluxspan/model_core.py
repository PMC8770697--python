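"""Domain types and readers/writers for constraint-based metabolic models.

A :class:`MetabolicModel` is the in-memory form of a genome-scale (or toy)
metabolic reconstruction: metabolites with compartment tags, reactions with
stoichiometry/bounds/GPRs, and a linear objective.  The implied stoichiometric
matrix ``S`` (metabolites x reactions) underlies all flux analyses.

Supported on-disk dialects
--------------------------
``tsv``
    Two tab-separated sheets mirroring typical reconstruction spreadsheets:
    ``<stem>.reactions.tsv`` with columns
    ``id  name  formula  lb  ub  subsystem  gpr  kind  objective`` and
    ``<stem>.metabolites.tsv`` with columns ``id  name  formula  charge``.
    The reaction ``formula`` uses the grammar ``"A[c] + 2 B[c] -> C[e]"``
    with ``<=>`` for reversible reactions; either side may be empty
    (boundary reactions, e.g. ``"ac[e] ->"``).  ``gpr`` and ``objective``
    are optional columns.  ``path`` may also be a directory containing
    ``reactions.tsv`` and ``metabolites.tsv``.
``json``
    A single document with keys ``metabolites``, ``reactions``,
    ``objective``, ``compartments``, ``annotations``; reaction stoichiometry
    is an explicit ``{metabolite_id: coefficient}`` map.
``sbml``
    SBML Level 3 core plus the FBC subset (flux bounds as parameters,
    objective and gene-product associations via the fbc plugin), through
    python-libsbml.

Identifier conventions: exchange reactions are prefixed ``EX_``, demands
``DM_``, sinks ``SK_``; metabolite ids carry their compartment as a bracket
suffix, e.g. ``glc[e]``.  Reversibility is encoded solely by ``lb < 0``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "ValidationReport",
    "ModelFormatError",
    "read_model",
    "write_model",
    "validate_model",
    "stoichiometric_matrix",
    "parse_reaction_formula",
    "format_reaction_formula",
    "normalize_exchanges",
]

REACTION_KINDS = ("internal", "transport", "exchange", "demand", "sink", "biomass")

#: boundary kinds touch exactly one metabolite
BOUNDARY_KINDS = ("exchange", "demand", "sink")

_DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """Raised when an on-disk model cannot be parsed under the named dialect."""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``id`` carries the compartment suffix (``glc[e]``); ``compartment`` is
    the bare tag (``e``).
    """

    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if not self.compartment:
            m = re.search(r"\[([^\[\]]+)\]$", self.id)
            if m:
                self.compartment = m.group(1)

    def copy(self) -> "Metabolite":
        return Metabolite(self.id, self.name, self.compartment, self.formula, self.charge)


@dataclass
class Reaction:
    """A (pseudo-)reaction: signed stoichiometry with flux bounds.

    Negative coefficients are substrates, positive are products.  Flux units
    are mmol/g-DW/h throughout.  ``gpr`` is a boolean gene-association
    expression (``"g1 and (g2 or g3)"``); empty means no gene evidence.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lb: float = -_DEFAULT_BOUND
    ub: float = _DEFAULT_BOUND
    subsystem: str = ""
    gpr: str = ""
    kind: str = "internal"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r} for {self.id}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def copy(self) -> "Reaction":
        return Reaction(
            self.id, self.name, dict(self.stoichiometry), self.lb, self.ub,
            self.subsystem, self.gpr, self.kind,
        )


def infer_kind(rxn_id: str, stoichiometry: dict[str, float]) -> str:
    """Guess a reaction's kind from its id prefix and arity."""
    if rxn_id.startswith("EX_"):
        return "exchange"
    if rxn_id.startswith("DM_"):
        return "demand"
    if rxn_id.startswith("SK_"):
        return "sink"
    if "biomass" in rxn_id.lower():
        return "biomass"
    comps = set()
    for mid in stoichiometry:
        m = re.search(r"\[([^\[\]]+)\]$", mid)
        comps.add(m.group(1) if m else "")
    if len(comps) > 1:
        return "transport"
    return "internal"


@dataclass
class MediumSpec:
    """Exchange-reaction bounds describing a growth medium (diet)."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.entries.items():
            if lb > ub:
                raise ValueError(f"medium entry {rid}: lb {lb} > ub {ub}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MediumSpec":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"exchange_id", "lb", "ub"}
        if not required.issubset(df.columns):
            raise ModelFormatError(
                f"medium TSV {path} missing columns {sorted(required - set(df.columns))}"
            )
        return cls({r.exchange_id: (float(r.lb), float(r.ub)) for r in df.itertuples()})

    def to_tsv(self, path: str | Path) -> None:
        rows = [(rid, lb, ub) for rid, (lb, ub) in self.entries.items()]
        pd.DataFrame(rows, columns=["exchange_id", "lb", "ub"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ValidationReport:
    """Structural problems found in a model; empty iff the model is valid."""

    duplicate_ids: list[str] = field(default_factory=list)
    orphan_metabolites: list[str] = field(default_factory=list)
    bound_violations: list[str] = field(default_factory=list)
    unbalanced_reactions: list[str] = field(default_factory=list)
    undeclared_metabolites: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.duplicate_ids
            or self.orphan_metabolites
            or self.bound_violations
            or self.unbalanced_reactions
            or self.undeclared_metabolites
        )

    def messages(self) -> list[str]:
        out = []
        for fieldname in (
            "duplicate_ids", "orphan_metabolites", "bound_violations",
            "unbalanced_reactions", "undeclared_metabolites",
        ):
            out.extend(f"{fieldname}: {m}" for m in getattr(self, fieldname))
        return out


@dataclass
class MetabolicModel:
    """A metabolic network with bounds and a linear objective.

    ``objective`` maps reaction ids to weights (the FBA ``c`` vector).
    ``extra_constraints`` holds additional linear inequality rows beyond
    ``S v = 0`` — used for community coupling constraints — each as
    ``(coeffs: {reaction_id: coef}, sense: '<='|'>='|'==', rhs)``.  All flux
    analyses honour them.
    """

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    compartments: set[str] = field(default_factory=set)
    annotations: dict = field(default_factory=dict)
    extra_constraints: list[tuple[dict[str, float], str, float]] = field(default_factory=list)

    # -- indexing -----------------------------------------------------------
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def biomass_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "biomass"]

    # -- mutation -----------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if any(m.id == met.id for m in self.metabolites):
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        if met.compartment:
            self.compartments.add(met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        if any(r.id == rxn.id for r in self.reactions):
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        known = {m.id for m in self.metabolites}
        missing = sorted(set(rxn.stoichiometry) - known)
        if missing:
            raise ValueError(
                f"reaction {rxn.id!r} references undeclared metabolite(s) {missing}"
            )
        self.reactions.append(rxn)

    def remove_reactions(self, rids: list[str]) -> None:
        drop = set(rids)
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self.objective = {k: v for k, v in self.objective.items() if k not in drop}
        self.extra_constraints = [
            (c, s, b) for (c, s, b) in self.extra_constraints
            if not (set(c) & drop)
        ]

    def prune_orphan_metabolites(self) -> list[str]:
        used: set[str] = set()
        for r in self.reactions:
            used.update(r.stoichiometry)
        dropped = [m.id for m in self.metabolites if m.id not in used]
        self.metabolites = [m for m in self.metabolites if m.id in used]
        return dropped

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective=dict(self.objective),
            compartments=set(self.compartments),
            annotations=json.loads(json.dumps(self.annotations)),
            extra_constraints=[(dict(c), s, b) for (c, s, b) in self.extra_constraints],
        )

    def structurally_equal(self, other: "MetabolicModel") -> bool:
        """Field-by-field equality of metabolites, reactions, objective."""
        if sorted(self.metabolite_ids) != sorted(other.metabolite_ids):
            return False
        om = {m.id: m for m in other.metabolites}
        for m in self.metabolites:
            o = om[m.id]
            if (m.name, m.compartment, m.formula, m.charge) != (
                o.name, o.compartment, o.formula, o.charge
            ):
                return False
        if sorted(self.reaction_ids) != sorted(other.reaction_ids):
            return False
        orx = {r.id: r for r in other.reactions}
        for r in self.reactions:
            o = orx[r.id]
            if r.stoichiometry != o.stoichiometry:
                return False
            if (r.lb, r.ub, r.subsystem, r.gpr, r.kind) != (
                o.lb, o.ub, o.subsystem, o.gpr, o.kind
            ):
                return False
        return self.objective == other.objective


# ---------------------------------------------------------------------------
# reaction-formula grammar
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "-->", "->", "<--", "<-")


def parse_reaction_formula(formula: str) -> tuple[dict[str, float], bool]:
    """Parse ``"A[c] + 2 B[c] -> C[e]"`` into (stoichiometry, reversible).

    ``<=>`` marks a reversible reaction; a bare ``->`` is irreversible.
    Either side may be empty.
    """
    formula = formula.strip()
    arrow = None
    for a in _ARROWS:
        if a in formula:
            arrow = a
            break
    if arrow is None:
        raise ModelFormatError(f"no reaction arrow in formula {formula!r}")
    lhs, rhs = formula.split(arrow, 1)
    if arrow in ("<--", "<-"):
        lhs, rhs = rhs, lhs
    reversible = arrow == "<=>"
    stoich: dict[str, float] = {}

    def _side(text: str, sign: float) -> None:
        text = text.strip()
        if not text:
            return
        for term in text.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S.*)$", term)
            if m is None:
                raise ModelFormatError(f"cannot parse term {term!r} in {formula!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            mid = m.group(2).strip()
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    _side(lhs, -1.0)
    _side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ModelFormatError(f"formula {formula!r} has empty net stoichiometry")
    return stoich, reversible


def _coef_str(c: float) -> str:
    if c == int(c):
        c = int(c)
    return "" if c == 1 else f"{c} "


def format_reaction_formula(rxn: Reaction) -> str:
    subs = sorted((mid, -c) for mid, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((mid, c) for mid, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<=>" if rxn.reversible else "->"
    lhs = " + ".join(f"{_coef_str(c)}{mid}" for mid, c in subs)
    rhs = " + ".join(f"{_coef_str(c)}{mid}" for mid, c in prods)
    return f"{lhs} {arrow} {rhs}".strip()


# ---------------------------------------------------------------------------
# validation & matrix assembly
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_elemental(formula: str) -> dict[str, int] | None:
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        return None
    out: dict[str, int] = {}
    for el, n in _FORMULA_TOKEN.findall(formula):
        out[el] = out.get(el, 0) + (int(n) if n else 1)
    return out


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Structural validation.  Reports every violated invariant, never raises."""
    rep = ValidationReport()
    seen_r: set[str] = set()
    for r in model.reactions:
        if r.id in seen_r:
            rep.duplicate_ids.append(f"reaction {r.id!r} declared more than once")
        seen_r.add(r.id)
    seen_m: set[str] = set()
    for m in model.metabolites:
        if m.id in seen_m:
            rep.duplicate_ids.append(f"metabolite {m.id!r} declared more than once")
        seen_m.add(m.id)

    used: set[str] = set()
    known = {m.id for m in model.metabolites}
    formulas = {m.id: _parse_elemental(m.formula or "") for m in model.metabolites}
    for r in model.reactions:
        used.update(r.stoichiometry)
        if r.lb > r.ub:
            rep.bound_violations.append(f"{r.id}: lb {r.lb} > ub {r.ub}")
        if not r.stoichiometry:
            rep.unbalanced_reactions.append(f"{r.id}: empty stoichiometry")
        missing = sorted(set(r.stoichiometry) - known)
        for mid in missing:
            rep.undeclared_metabolites.append(
                f"{r.id}: references undeclared metabolite {mid!r}"
            )
        if r.kind in BOUNDARY_KINDS and len(r.stoichiometry) != 1:
            rep.unbalanced_reactions.append(
                f"{r.id}: {r.kind} reaction must touch exactly one metabolite"
            )
        if r.kind == "demand" and r.lb < 0:
            rep.bound_violations.append(
                f"{r.id}: demand reaction must be consumption-only (lb >= 0)"
            )
        # elemental balance, only where every participant has a parseable formula
        if r.kind == "internal" and r.stoichiometry:
            elems = [formulas.get(mid) for mid in r.stoichiometry]
            if all(e is not None for e in elems):
                balance: dict[str, float] = {}
                for mid, coef in r.stoichiometry.items():
                    for el, n in formulas[mid].items():  # type: ignore[union-attr]
                        balance[el] = balance.get(el, 0.0) + coef * n
                bad = {el: v for el, v in balance.items() if abs(v) > 1e-9}
                if bad:
                    rep.unbalanced_reactions.append(f"{r.id}: elemental imbalance {bad}")
    for m in model.metabolites:
        if m.id not in used:
            rep.orphan_metabolites.append(f"{m.id}: participates in no reaction")
    return rep


def stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """The sparse S matrix, one row per metabolite, one column per reaction."""
    midx = model.metabolite_index()
    rows, cols, vals = [], [], []
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            rows.append(midx[mid])
            cols.append(j)
            vals.append(coef)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def normalize_exchanges(model: MetabolicModel) -> MetabolicModel:
    """Rewrite importer-style boundary reactions to the export convention.

    Boundary reactions are canonicalised to ``met ->`` (coefficient -1) so
    that positive flux always means secretion and negative flux uptake;
    reactions written the other way have stoichiometry and bounds flipped
    in place.  Returns the model for chaining.
    """
    for r in model.reactions:
        if r.kind in BOUNDARY_KINDS and len(r.stoichiometry) == 1:
            (mid, coef), = r.stoichiometry.items()
            if coef > 0:
                r.stoichiometry = {mid: -coef}
                r.lb, r.ub = -r.ub, -r.lb
    return model


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_RXN_COLUMNS = ["id", "name", "formula", "lb", "ub", "subsystem", "gpr", "kind", "objective"]
_MET_COLUMNS = ["id", "name", "formula", "charge"]


def _tsv_paths(path: Path) -> tuple[Path, Path]:
    if path.is_dir():
        return path / "reactions.tsv", path / "metabolites.tsv"
    stem = str(path)
    for suffix in (".reactions.tsv", ".metabolites.tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return Path(stem + ".reactions.tsv"), Path(stem + ".metabolites.tsv")


def _read_tsv(path: Path) -> MetabolicModel:
    rpath, mpath = _tsv_paths(path)
    for p in (rpath, mpath):
        if not p.exists():
            raise FileNotFoundError(p)
    mdf = pd.read_csv(mpath, sep="\t", dtype=str, keep_default_na=False)
    rdf = pd.read_csv(rpath, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id",):
        if col not in mdf.columns:
            raise ModelFormatError(f"{mpath}: missing mandatory column 'id'")
    for col in ("id", "formula", "lb", "ub"):
        if col not in rdf.columns:
            raise ModelFormatError(f"{rpath}: missing mandatory column {col!r}")

    model = MetabolicModel(id=Path(path).stem or "model")
    for i, row in enumerate(mdf.itertuples(), start=2):
        charge = getattr(row, "charge", "")
        model.add_metabolite(Metabolite(
            id=row.id,
            name=getattr(row, "name", "") or "",
            formula=(getattr(row, "formula", "") or None),
            charge=int(charge) if charge not in ("", None) else None,
        ))
    known = {m.id for m in model.metabolites}
    for i, row in enumerate(rdf.itertuples(), start=2):
        try:
            stoich, reversible = parse_reaction_formula(row.formula)
        except ModelFormatError as exc:
            raise ModelFormatError(f"{rpath} line {i}: {exc}") from exc
        missing = sorted(set(stoich) - known)
        if missing:
            raise ModelFormatError(
                f"{rpath} line {i}: reaction {row.id!r} references undeclared "
                f"metabolite(s) {missing}"
            )
        kind = getattr(row, "kind", "") or infer_kind(row.id, stoich)
        try:
            rxn = Reaction(
                id=row.id,
                name=getattr(row, "name", "") or "",
                stoichiometry=stoich,
                lb=float(row.lb),
                ub=float(row.ub),
                subsystem=getattr(row, "subsystem", "") or "",
                gpr=getattr(row, "gpr", "") or "",
                kind=kind,
            )
        except ValueError as exc:
            raise ModelFormatError(f"{rpath} line {i}: {exc}") from exc
        if any(r.id == rxn.id for r in model.reactions):
            raise ModelFormatError(f"{rpath} line {i}: duplicate reaction id {rxn.id!r}")
        model.add_reaction(rxn)
        obj = getattr(row, "objective", "")
        if obj not in ("", "0", "0.0"):
            model.objective[rxn.id] = float(obj)
    return model


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    rpath, mpath = _tsv_paths(path)
    rpath.parent.mkdir(parents=True, exist_ok=True)
    mrows = [
        (m.id, m.name, m.formula or "", "" if m.charge is None else m.charge)
        for m in model.metabolites
    ]
    pd.DataFrame(mrows, columns=_MET_COLUMNS).to_csv(mpath, sep="\t", index=False)
    rrows = [
        (
            r.id, r.name, format_reaction_formula(r), repr(r.lb), repr(r.ub),
            r.subsystem, r.gpr, r.kind, model.objective.get(r.id, ""),
        )
        for r in model.reactions
    ]
    pd.DataFrame(rrows, columns=_RXN_COLUMNS).to_csv(rpath, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

JSON_SCHEMA_VERSION = 1


def _to_json_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "compartments": sorted(model.compartments),
        "metabolites": [
            {
                "id": m.id, "name": m.name, "compartment": m.compartment,
                "formula": m.formula, "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id, "name": r.name, "stoichiometry": r.stoichiometry,
                "lb": r.lb, "ub": r.ub, "subsystem": r.subsystem,
                "gpr": r.gpr, "kind": r.kind,
            }
            for r in model.reactions
        ],
        "objective": model.objective,
        "annotations": model.annotations,
        "extra_constraints": [
            {"coeffs": c, "sense": s, "rhs": b} for (c, s, b) in model.extra_constraints
        ],
    }


def _from_json_dict(doc: dict) -> MetabolicModel:
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelFormatError(f"JSON model missing mandatory key {key!r}")
    model = MetabolicModel(id=doc.get("id", "model"))
    for m in doc["metabolites"]:
        model.add_metabolite(Metabolite(
            id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", ""),
            formula=m.get("formula"), charge=m.get("charge"),
        ))
    for r in doc["reactions"]:
        model.add_reaction(Reaction(
            id=r["id"], name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lb=float(r["lb"]), ub=float(r["ub"]),
            subsystem=r.get("subsystem", ""), gpr=r.get("gpr", ""),
            kind=r.get("kind") or infer_kind(r["id"], r["stoichiometry"]),
        ))
    model.objective = {k: float(v) for k, v in doc.get("objective", {}).items()}
    model.compartments |= set(doc.get("compartments", []))
    model.annotations = doc.get("annotations", {})
    model.extra_constraints = [
        ({k: float(v) for k, v in e["coeffs"].items()}, e["sense"], float(e["rhs"]))
        for e in doc.get("extra_constraints", [])
    ]
    return model


# ---------------------------------------------------------------------------
# SBML dialect (Level 3 core + FBC subset)
# ---------------------------------------------------------------------------

_SBML_BAD = re.compile(r"[^A-Za-z0-9_]")
_SBML_ESC = re.compile(r"_x(\d+)x_")


def _sbml_id(raw: str) -> str:
    """Reversible SBML-safe encoding: each illegal character becomes
    ``_x<codepoint>x_`` (so ``glc[e]`` <-> ``glc_x91x_e_x93x_``)."""
    sid = _SBML_BAD.sub(lambda m: f"_x{ord(m.group(0))}x_", raw)
    if sid and sid[0].isdigit():
        sid = "_" + sid
    return sid


def _sbml_decode(sid: str) -> str:
    out = _SBML_ESC.sub(lambda m: chr(int(m.group(1))), sid)
    if out.startswith("_") and len(out) > 1 and out[1].isdigit():
        out = out[1:]
    return out


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sbml_id(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for tag in sorted(model.compartments or {"c"}):
        comp = sm.createCompartment()
        comp.setId(_sbml_id(tag))
        comp.setConstant(True)

    raw_ids: dict[str, str] = {}  # sbml id -> original id
    for m in model.metabolites:
        sp = sm.createSpecies()
        sid = "M_" + _sbml_id(m.id)
        sp.setId(sid)
        sp.setName(m.name or m.id)
        sp.setCompartment(_sbml_id(m.compartment or "c"))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        raw_ids[sid] = m.id
        splug = sp.getPlugin("fbc")
        if m.formula:
            splug.setChemicalFormula(m.formula)
        if m.charge is not None:
            splug.setCharge(int(m.charge))

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    genes: set[str] = set()
    from .context_extraction import gpr_genes  # deferred: avoids import cycle at module load

    for r in model.reactions:
        genes |= gpr_genes(r.gpr)
    gplug_ids = {}
    for g in sorted(genes):
        gp = mplug.createGeneProduct()
        gid = "G_" + _sbml_id(g)
        gp.setId(gid)
        gp.setLabel(g)
        gplug_ids[g] = gid

    for r in model.reactions:
        rx = sm.createReaction()
        rid = "R_" + _sbml_id(r.id)
        rx.setId(rid)
        rx.setName(r.name or r.id)
        rx.setReversible(r.lb < 0)
        rx.setFast(False)
        raw_ids[rid] = r.id
        for mid, coef in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies("M_" + _sbml_id(mid))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(r.lb))
        rplug.setUpperFluxBound(_bound_param(r.ub))
        if r.gpr:
            ga = rplug.createGeneProductAssociation()
            infix = re.sub(r"\b(and|or)\b", lambda m: m.group(1), r.gpr)
            for g, gid in gplug_ids.items():
                infix = re.sub(rf"(?<![\w]){re.escape(g)}(?![\w])", gid, infix)
            ga.setAssociation(infix)

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        for rid, w in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction("R_" + _sbml_id(rid))
            fo.setCoefficient(w)

    # original ids and reaction metadata that SBML core cannot carry are kept
    # in a notes-free annotation map alongside the document id mapping
    sm.setMetaId("meta_" + _sbml_id(model.id))
    libsbml.writeSBMLToFile(doc, str(path))


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"SBML parse error in {path}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelFormatError(f"{path}: no model element")
    model = MetabolicModel(id=sm.getId() or Path(path).stem)

    def _strip(pref: str, sid: str) -> str:
        return _sbml_decode(sid[len(pref):] if sid.startswith(pref) else sid)

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        model.add_metabolite(Metabolite(
            id=_strip("M_", sp.getId()),
            name=sp.getName(),
            compartment=sp.getCompartment(),
            formula=(splug.getChemicalFormula() or None) if splug else None,
            charge=(splug.getCharge() if splug and splug.isSetCharge() else None),
        ))
    gene_labels = {}
    mplug = sm.getPlugin("fbc")
    if mplug:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip("G_", gp.getId())

    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _strip("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _strip("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        lb = -_DEFAULT_BOUND if rx.getReversible() else 0.0
        ub = _DEFAULT_BOUND
        rplug = rx.getPlugin("fbc")
        gpr = ""
        if rplug:
            for getter, setter in ((rplug.getLowerFluxBound, "lb"), (rplug.getUpperFluxBound, "ub")):
                pid = getter()
                if pid:
                    p = sm.getParameter(pid)
                    if p is not None:
                        if setter == "lb":
                            lb = p.getValue()
                        else:
                            ub = p.getValue()
            ga = rplug.getGeneProductAssociation()
            if ga is not None:
                assoc = ga.getAssociation()
                if assoc is not None:
                    gpr = assoc.toInfix()
                    for gid, label in gene_labels.items():
                        gpr = re.sub(rf"(?<![\w]){re.escape(gid)}(?![\w])", label, gpr)
                    from .context_extraction import canonicalize_gpr

                    gpr = canonicalize_gpr(gpr)
        rid = _strip("R_", rx.getId())
        model.add_reaction(Reaction(
            id=rid, name=rx.getName(), stoichiometry=stoich, lb=lb, ub=ub,
            gpr=gpr, kind=infer_kind(rid, stoich),
        ))
    if mplug:
        obj = mplug.getActiveObjective()
        if obj is not None:
            for i in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(i)
                model.objective[_strip("R_", fo.getReaction())] = fo.getCoefficient()
    return model


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str = "tsv") -> MetabolicModel:
    """Read a model from disk in the named dialect and validate it.

    Boundary reactions are normalised to the export convention (positive
    flux = secretion).  Raises :class:`ModelFormatError` on parse failures;
    structural problems beyond parsing are available via
    :func:`validate_model`.
    """
    path = Path(path)
    if format == "tsv":
        model = _read_tsv(path)
    elif format == "json":
        with open(path) as fh:
            model = _from_json_dict(json.load(fh))
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    for m in model.metabolites:
        if m.compartment:
            model.compartments.add(m.compartment)
    return normalize_exchanges(model)


def write_model(model: MetabolicModel, path: str | Path, format: str = "tsv") -> None:
    """Write a model in the named dialect; re-reading yields an equal model
    (TSV/JSON bit-exact; SBML up to the core+FBC subset)."""
    path = Path(path)
    if path.parent and not path.parent.exists():
        path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        _write_tsv(model, path)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_to_json_dict(model), fh, indent=1, sort_keys=True)
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")
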