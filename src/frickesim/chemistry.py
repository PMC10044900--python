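"""Chemical data model: species, reactions, and packaged reaction sets.

The packaged sets cover acidic-water spur chemistry, the ferrous-sulfate
(Fricke) dosimeter, sulfate radical chemistry in 0.4 M H2SO4, and cystamine
(RSSR) scavenging.  Every rate constant is the value at zero ionic strength;
per-medium corrections are applied downstream (:mod:`frickesim.medium`).

Reactions carry a ``kind`` tag:

``pair_diffusive``
    both partners are transient track species; the IRT engine inverts the
    rate constant into an encounter radius.
``scavenging``
    at least one partner is a homogeneously distributed background solute,
    giving pseudo-first-order kinetics.
``unimolecular``
    first-order transformation (rate in 1/s).

The tag is advisory: the engine decides pair vs. pseudo-first-order use per
medium, so a reaction such as e-aq + H+ serves both roles.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ChemicalSpecies",
    "Reaction",
    "ReactionSet",
    "ReactionSetError",
    "ValidationIssue",
    "load_reaction_set",
    "load_species_table",
    "validate_reaction_set",
    "PACKAGED_SETS",
]

REACTION_KINDS = ("pair_diffusive", "scavenging", "unimolecular")

#: Species that exist as constant reservoirs in the medium.  When they appear
#: as reaction *products* they are counted but not instantiated as particles.
RESERVOIR_SPECIES = frozenset({"H+", "HSO4-", "SO42-", "Fe2+", "O2", "RSSR"})


class ReactionSetError(ValueError):
    """Raised when a reaction table fails validation on load."""


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with its transport properties.

    Parameters
    ----------
    name : str
        Unique identifier (e.g. ``"e-aq"``, ``"Fe2+"``).
    charge : int
        Net molecular charge in elementary units.  Cystamine-family species
        carry the charges of the doubly protonated (+NH3 ... NH3+) forms.
    diffusion : float
        Diffusion coefficient at 25 C in m^2/s.
    tags : tuple of str
        Any of ``radiolytic_primary``, ``background_solute``, ``product``.
    """

    name: str
    charge: int
    diffusion: float
    tags: tuple[str, ...] = ()
    provenance: str = "literature-default"
    note: str = ""


@dataclass(frozen=True)
class Reaction:
    """A single reaction channel with its zero-ionic-strength rate constant.

    ``co_reactants`` lists reservoir species consumed stoichiometrically but
    not kinetically (e.g. the acid proton in H + Fe2+ -> Fe3+ + H2); they
    participate in charge bookkeeping only.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k0: float
    kind: str
    co_reactants: tuple[str, ...] = ()
    exempt_ionic: bool = False
    provenance: str = "literature-default"
    label: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ReactionSetError(f"{self.label}: unknown reaction kind {self.kind!r}")
        if self.k0 <= 0:
            raise ReactionSetError(f"{self.label}: non-positive rate constant {self.k0}")
        n = len(self.reactants)
        if self.kind == "unimolecular":
            if n != 1:
                raise ReactionSetError(f"{self.label}: unimolecular reactions take 1 reactant")
        elif n != 2:
            raise ReactionSetError(f"{self.label}: bimolecular reactions take exactly 2 reactants")
        if not 0 <= len(self.products) <= 3:
            raise ReactionSetError(f"{self.label}: 0-3 products allowed")

    @property
    def pair_key(self) -> tuple[str, str]:
        return tuple(sorted(self.reactants))  # type: ignore[return-value]


@dataclass(frozen=True)
class ValidationIssue:
    label: str
    kind: str
    message: str


@dataclass
class ReactionSet:
    """A validated registry of species plus a list of reaction channels."""

    species: dict[str, ChemicalSpecies] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    name: str = ""

    # -- construction -----------------------------------------------------
    def add_species(self, sp: ChemicalSpecies) -> None:
        if sp.name in self.species:
            raise ReactionSetError(f"duplicate species {sp.name!r}")
        self.species[sp.name] = sp

    def add_reaction(self, rxn: Reaction) -> None:
        for s in (*rxn.reactants, *rxn.products, *rxn.co_reactants):
            if s not in self.species:
                raise ReactionSetError(f"{rxn.label}: unknown species reference {s!r}")
        dz = self._charge_change(rxn)
        if dz != 0:
            raise ReactionSetError(
                f"{rxn.label}: charge-unbalanced reaction (net change {dz:+d})"
            )
        self.reactions.append(rxn)

    def _charge_change(self, rxn: Reaction) -> int:
        z = lambda s: self.species[s].charge
        return sum(z(s) for s in rxn.products) - sum(
            z(s) for s in (*rxn.reactants, *rxn.co_reactants)
        )

    # -- lookup -----------------------------------------------------------
    def pair_channels(self) -> dict[tuple[str, str], list[Reaction]]:
        """Index bimolecular channels by the sorted reactant pair."""
        idx: dict[tuple[str, str], list[Reaction]] = {}
        for r in self.reactions:
            if len(r.reactants) == 2:
                idx.setdefault(r.pair_key, []).append(r)
        return idx

    def union(self, other: "ReactionSet", name: str = "") -> "ReactionSet":
        out = ReactionSet(name=name or f"{self.name}+{other.name}")
        for sp in self.species.values():
            out.add_species(sp)
        for nm, sp in other.species.items():
            if nm not in out.species:
                out.add_species(sp)
        seen: set[tuple[tuple[str, str], tuple[str, ...]]] = set()
        for r in (*self.reactions, *other.reactions):
            key = (r.pair_key if len(r.reactants) == 2 else (r.reactants[0], ""),
                   tuple(sorted(r.products)))
            if key in seen:
                raise ReactionSetError(
                    f"{r.label}: duplicate channel (same reactants and products)"
                )
            seen.add(key)
            out.add_reaction(r)
        return out

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "species": [vars(s) | {"tags": list(s.tags)} for s in self.species.values()],
            "reactions": [
                {
                    "label": r.label,
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "co_reactants": list(r.co_reactants),
                    "k0": r.k0,
                    "kind": r.kind,
                    "zA": self.species[r.reactants[0]].charge,
                    "zB": self.species[r.reactants[1]].charge if len(r.reactants) == 2 else 0,
                    "exempt_ionic": r.exempt_ionic,
                    "provenance": r.provenance,
                    "note": r.note,
                }
                for r in self.reactions
            ],
        }
        return json.dumps(payload, indent=1)

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["label", "reactants", "products", "co_reactants", "k0", "kind",
                    "zA", "zB", "exempt_ionic", "provenance", "note"])
        for r in self.reactions:
            w.writerow([
                r.label,
                ";".join(r.reactants),
                ";".join(r.products),
                ";".join(r.co_reactants),
                repr(r.k0),
                r.kind,
                self.species[r.reactants[0]].charge,
                self.species[r.reactants[1]].charge if len(r.reactants) == 2 else 0,
                str(r.exempt_ionic).lower(),
                r.provenance,
                r.note,
            ])
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(self.to_json())
        else:
            path.write_text(self.to_csv())


# ---------------------------------------------------------------------------
# loading

_DATA_PKG = "frickesim.data"

PACKAGED_SETS: dict[str, tuple[str, ...]] = {
    "water_core": ("reactions_water_core.csv",),
    "fricke_core": ("reactions_fricke_core.csv",),
    "sulfate": ("reactions_sulfate.csv",),
    "cystamine": ("reactions_cystamine.csv",),
    "fricke_full": (
        "reactions_water_core.csv",
        "reactions_fricke_core.csv",
        "reactions_sulfate.csv",
    ),
    "fricke_cystamine_full": (
        "reactions_water_core.csv",
        "reactions_fricke_core.csv",
        "reactions_sulfate.csv",
        "reactions_cystamine.csv",
    ),
}


def _read_packaged(fname: str) -> str:
    return resources.files(_DATA_PKG).joinpath(fname).read_text()


def load_species_table(text: str | None = None) -> dict[str, ChemicalSpecies]:
    """Parse the species CSV (packaged table when ``text`` is None)."""
    if text is None:
        text = _read_packaged("species.csv")
    out: dict[str, ChemicalSpecies] = {}
    for i, row in enumerate(csv.DictReader(io.StringIO(text)), start=2):
        name = row["name"].strip()
        if name in out:
            raise ReactionSetError(f"species.csv line {i}: duplicate species {name!r}")
        d = float(row["diffusion_m2_s"])
        if d <= 0:
            raise ReactionSetError(f"species.csv line {i}: non-positive diffusion for {name}")
        out[name] = ChemicalSpecies(
            name=name,
            charge=int(row["charge"]),
            diffusion=d,
            tags=tuple(t for t in row.get("tags", "").split(";") if t),
            provenance=row.get("provenance", ""),
            note=row.get("note", ""),
        )
    return out


def _parse_reaction_rows(text: str, species: Mapping[str, ChemicalSpecies],
                         origin: str) -> list[Reaction]:
    rxns = []
    for i, row in enumerate(csv.DictReader(io.StringIO(text)), start=2):
        label = row.get("label") or f"{origin}:{i}"
        reactants = tuple(s for s in row["reactants"].split(";") if s)
        try:
            rxn = Reaction(
                reactants=reactants,
                products=tuple(s for s in row["products"].split(";") if s),
                co_reactants=tuple(s for s in row.get("co_reactants", "").split(";") if s),
                k0=float(row["k0"]),
                kind=row["kind"].strip(),
                exempt_ionic=row.get("exempt_ionic", "false").strip().lower() == "true",
                provenance=row.get("provenance", "literature-default"),
                label=label,
                note=row.get("note", ""),
            )
        except (ReactionSetError, ValueError) as exc:
            raise ReactionSetError(f"{origin} line {i} ({label}): {exc}") from exc
        # cross-check the declared reactant charges against the species table
        for col, idx in (("zA", 0), ("zB", 1)):
            if row.get(col) not in (None, "",):
                if idx < len(reactants):
                    declared = int(row[col])
                    actual = species[reactants[idx]].charge if reactants[idx] in species else None
                    if actual is not None and declared != actual:
                        raise ReactionSetError(
                            f"{origin} line {i} ({label}): {col}={declared} disagrees with "
                            f"species table charge {actual} for {reactants[idx]}"
                        )
        rxns.append(rxn)
    return rxns


def load_reaction_set(source: str | Path) -> ReactionSet:
    """Load a packaged reaction set by name, or a CSV/JSON file by path.

    Raises :class:`ReactionSetError` naming the offending line for unknown
    species, charge-unbalanced reactions, or non-positive rate constants.
    """
    species = load_species_table()
    if isinstance(source, str) and source in PACKAGED_SETS:
        rset = ReactionSet(name=source)
        for sp in species.values():
            rset.add_species(sp)
        for fname in PACKAGED_SETS[source]:
            for rxn in _parse_reaction_rows(_read_packaged(fname), species, fname):
                rset.add_reaction(rxn)
        return rset

    path = Path(source)
    if not path.exists():
        raise ReactionSetError(f"unknown packaged set or missing file: {source!r}")
    rset = ReactionSet(name=path.stem)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        for s in payload["species"]:
            rset.add_species(ChemicalSpecies(
                name=s["name"], charge=int(s["charge"]), diffusion=float(s["diffusion"]),
                tags=tuple(s.get("tags", ())), provenance=s.get("provenance", ""),
                note=s.get("note", ""),
            ))
        for r in payload["reactions"]:
            rset.add_reaction(Reaction(
                reactants=tuple(r["reactants"]), products=tuple(r["products"]),
                co_reactants=tuple(r.get("co_reactants", ())), k0=float(r["k0"]),
                kind=r["kind"], exempt_ionic=bool(r.get("exempt_ionic", False)),
                provenance=r.get("provenance", ""), label=r.get("label", ""),
                note=r.get("note", ""),
            ))
    else:
        for sp in species.values():
            rset.add_species(sp)
        for rxn in _parse_reaction_rows(path.read_text(), species, path.name):
            rset.add_reaction(rxn)
    return rset


def validate_reaction_set(rset: ReactionSet) -> list[ValidationIssue]:
    """Report (without raising) charge imbalance, unreachable species, and
    missing diffusion coefficients for pair-diffusive participants."""
    issues: list[ValidationIssue] = []
    for r in rset.reactions:
        dz = rset._charge_change(r)
        if dz != 0:
            issues.append(ValidationIssue(r.label, "charge", f"net charge change {dz:+d}"))
        if r.kind == "pair_diffusive":
            for s in r.reactants:
                if rset.species[s].diffusion <= 0:
                    issues.append(ValidationIssue(
                        r.label, "diffusion", f"{s} lacks a positive diffusion coefficient"))
    referenced = {s for r in rset.reactions
                  for s in (*r.reactants, *r.products, *r.co_reactants)}
    for name in rset.species:
        if rset.reactions and name not in referenced:
            issues.append(ValidationIssue(name, "unreachable", "species never referenced"))
    return issues
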