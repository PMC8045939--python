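"""Stoichiometric network data model, JSON I/O, validation and in-place edits.

The native model format is a small JSON document (see :func:`load_model`);
an optional SBML adapter maps SBML files into the same type via cobra.
Sign convention throughout the package: for an exchange reaction a negative
flux is uptake and a positive flux is secretion. All fluxes are in
mmol·gCDW⁻¹·h⁻¹.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Reactants considered "highly connected" (currency/inorganic species) and
#: excluded from kinetic-order fitting by default: water, protons, CO2,
#: bicarbonate, sulfate, phosphate and ammonia.
HIGHLY_CONNECTED_DEFAULT = ("h2o", "h", "co2", "hco3", "so4", "pi", "nh4")

EXTERNAL_COMPARTMENT = "e"


class ModelSchemaError(ValueError):
    """Raised when a model document violates the schema or its invariants."""


class EditError(ValueError):
    """Raised when a model edit references unknown ids or is inapplicable."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    monoisotopic_mass: float | None = None  # Da, neutral
    highly_connected: bool = False

    @property
    def is_external(self) -> bool:
        return self.compartment == EXTERNAL_COMPARTMENT


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    is_exchange: bool = False
    catalysts: list[str] = field(default_factory=list)

    def substrate_ids(self) -> list[str]:
        """Metabolite ids consumed in the forward direction (coef < 0)."""
        return [m for m, c in self.stoichiometry.items() if c < 0]


@dataclass
class Condition:
    """One steady-state culture condition."""

    id: str
    limitation: str  # catabolic | anabolic | reference
    induction_level: int
    growth_rate: float  # μ in h⁻¹

    LIMITATIONS = ("catabolic", "anabolic", "reference")


@dataclass
class Violation:
    code: str
    element: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.element}: {self.message}"


@dataclass
class StoichiometricModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    atp_maintenance_id: str
    biomass_id: str

    # -- structure -------------------------------------------------------

    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.is_external]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Return (S, metabolite row ids, reaction column ids).

        One row per *internal* metabolite, one column per reaction.
        """
        met_ids = self.internal_metabolite_ids()
        rxn_ids = list(self.reactions)
        met_pos = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                if mid in met_pos:
                    S[met_pos[mid], j] = coef
        return S, met_ids, rxn_ids

    def exchange_for(self, metabolite_id: str) -> str | None:
        """Return the id of the exchange reaction touching this metabolite."""
        for rid, rxn in self.reactions.items():
            if rxn.is_exchange and metabolite_id in rxn.stoichiometry:
                return rid
        return None

    def reaction_substrates(
        self, reaction_id: str, exclude_highly_connected: bool = True
    ) -> list[str]:
        """Internal substrates of a reaction, optionally dropping currency species."""
        rxn = self.reactions[reaction_id]
        out = []
        for mid in rxn.substrate_ids():
            met = self.metabolites.get(mid)
            if met is None or met.is_external:
                continue
            if exclude_highly_connected and met.highly_connected:
                continue
            out.append(mid)
        return out

    def copy(self) -> "StoichiometricModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------


def _model_from_dict(doc: Mapping) -> StoichiometricModel:
    if "metabolites" not in doc or "reactions" not in doc:
        raise ModelSchemaError("document must contain 'metabolites' and 'reactions'")
    metabolites: dict[str, Metabolite] = {}
    for m in doc["metabolites"]:
        mid = m["id"]
        if mid in metabolites:
            raise ModelSchemaError(f"duplicate metabolite id {mid!r}")
        mass = m.get("mass")
        metabolites[mid] = Metabolite(
            id=mid,
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            monoisotopic_mass=float(mass) if mass is not None else None,
            highly_connected=bool(m.get("highly_connected", False)),
        )
    reactions: dict[str, Reaction] = {}
    for r in doc["reactions"]:
        rid = r["id"]
        if rid in reactions:
            raise ModelSchemaError(f"duplicate reaction id {rid!r}")
        stoich = {str(k): float(v) for k, v in r["stoichiometry"].items()}
        for mid in stoich:
            if mid not in metabolites:
                raise ModelSchemaError(
                    f"reaction {rid!r} references undeclared metabolite {mid!r}"
                )
        reactions[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=float(r.get("lb", 0.0)),
            upper_bound=float(r.get("ub", 1000.0)),
            is_exchange=bool(r.get("exchange", False)),
            catalysts=list(r.get("catalysts", [])),
        )
    for key in ("atp_maintenance", "biomass"):
        rid = doc.get(key)
        if rid is None or rid not in reactions:
            raise ModelSchemaError(f"{key!r} must name a declared reaction (got {rid!r})")
    return StoichiometricModel(
        metabolites=metabolites,
        reactions=reactions,
        atp_maintenance_id=doc["atp_maintenance"],
        biomass_id=doc["biomass"],
    )


def load_model(source: str | Path) -> StoichiometricModel:
    """Load a stoichiometric model from a JSON document (path or JSON text).

    Raises :class:`ModelSchemaError` on schema violations, naming the
    offending element.
    """
    text = None
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        stripped = source.lstrip()
        if stripped.startswith("{"):
            text = source
        else:
            text = Path(source).read_text()
    doc = json.loads(text)
    model = _model_from_dict(doc)
    report = validate_model(model)
    if report:
        raise ModelSchemaError("; ".join(str(v) for v in report))
    return model


def model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "mass": m.monoisotopic_mass,
                "highly_connected": m.highly_connected,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "exchange": r.is_exchange,
                "catalysts": list(r.catalysts),
            }
            for r in model.reactions.values()
        ],
        "atp_maintenance": model.atp_maintenance_id,
        "biomass": model.biomass_id,
    }


def write_model(model: StoichiometricModel, path: str | Path | None = None) -> str:
    """Serialize a model to its JSON document; write to *path* when given.

    Ordering is preserved, so load → write → load is the identity.
    """
    text = json.dumps(model_to_dict(model), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def load_sbml(path: str | Path) -> StoichiometricModel:
    """Optional SBML ingestion mapped onto the native model type.

    Requires cobra (``pip install coordflux[sbml]``). The SBML objective is
    used as the ATP-maintenance analog only if a reaction named "ATPM"
    exists; biomass is taken from the objective.
    """
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("SBML reading requires the optional 'cobra' dependency") from exc
    cm = cobra.io.read_sbml_model(str(path))
    mets = {
        m.id: Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            highly_connected=False,
        )
        for m in cm.metabolites
    }
    rxns = {}
    for r in cm.reactions:
        rxns[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            is_exchange=r.id.startswith("EX_") or r.boundary,
            catalysts=sorted(g.id for g in r.genes),
        )
    atpm = "ATPM" if "ATPM" in rxns else next(iter(rxns))
    biomass = next((r.id for r in cm.reactions if r.objective_coefficient), atpm)
    return StoichiometricModel(mets, rxns, atpm, biomass)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_model(model: StoichiometricModel) -> list[Violation]:
    """Check all type invariants; return the (possibly empty) violation list."""
    out: list[Violation] = []
    for m in model.metabolites.values():
        if m.monoisotopic_mass is not None and m.monoisotopic_mass <= 0:
            out.append(Violation("mass", m.id, "monoisotopic mass must be > 0"))
    for r in model.reactions.values():
        if not r.stoichiometry:
            out.append(Violation("stoichiometry", r.id, "empty stoichiometry"))
        if r.lower_bound > r.upper_bound:
            out.append(
                Violation("bounds", r.id, f"lb {r.lower_bound} > ub {r.upper_bound}")
            )
        for mid in r.stoichiometry:
            if mid not in model.metabolites:
                out.append(Violation("reference", r.id, f"undeclared metabolite {mid!r}"))
        if r.is_exchange:
            internal = [
                mid
                for mid in r.stoichiometry
                if mid in model.metabolites and not model.metabolites[mid].is_external
            ]
            if len(internal) != 1:
                out.append(
                    Violation(
                        "exchange",
                        r.id,
                        f"exchange must touch exactly one internal metabolite, "
                        f"touches {len(internal)}",
                    )
                )
    for key, rid in (
        ("atp_maintenance", model.atp_maintenance_id),
        ("biomass", model.biomass_id),
    ):
        if rid not in model.reactions:
            out.append(Violation("reference", key, f"unknown reaction {rid!r}"))
    return out


# ---------------------------------------------------------------------------
# Edits
# ---------------------------------------------------------------------------


def edit_model(
    model: StoichiometricModel, edits: Iterable[Sequence]
) -> StoichiometricModel:
    """Apply a list of edits, in order, to a copy of the model.

    Edits are tuples::

        ("disable", reaction_id)
        ("set_bounds", reaction_id, lb, ub)
        ("make_reversible", reaction_id)           # lb := -ub
        ("make_reversible", reaction_id, lb)       # explicit lb
        ("add_exchange", metabolite_id)

    ``disable`` is shorthand for ``set_bounds(r, 0, 0)``.
    """
    new = model.copy()
    for edit in edits:
        op = edit[0]
        if op == "disable":
            rid = edit[1]
            _require_reaction(new, rid)
            new.reactions[rid].lower_bound = 0.0
            new.reactions[rid].upper_bound = 0.0
        elif op == "set_bounds":
            rid, lb, ub = edit[1], float(edit[2]), float(edit[3])
            _require_reaction(new, rid)
            new.reactions[rid].lower_bound = lb
            new.reactions[rid].upper_bound = ub
        elif op == "make_reversible":
            rid = edit[1]
            _require_reaction(new, rid)
            rxn = new.reactions[rid]
            rxn.lower_bound = float(edit[2]) if len(edit) > 2 else -rxn.upper_bound
        elif op == "add_exchange":
            mid = edit[1]
            if mid not in new.metabolites:
                raise EditError(f"unknown metabolite {mid!r}")
            if new.exchange_for(mid) is not None:
                raise EditError(f"metabolite {mid!r} already has an exchange reaction")
            rid = f"EX_{mid}"
            new.reactions[rid] = Reaction(
                id=rid,
                stoichiometry={mid: -1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
                is_exchange=True,
            )
        else:
            raise EditError(f"unknown edit {op!r}")
    return new


def _require_reaction(model: StoichiometricModel, rid: str) -> None:
    if rid not in model.reactions:
        raise EditError(f"unknown reaction {rid!r}")
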