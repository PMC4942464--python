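"""Embedded catalog of per-receptor Hill parameters and basis-set assembly.

The catalog is shipped as a JSON package data file. Each entry stores the
Hill characterization of one receptor for one species query tag ("human" or
"rodent"); the source species actually measured (rat, mouse, bovine, ...)
is kept alongside, and entries standing in from another species are flagged
``surrogate_species``. Non-responsive receptors (no ATP-evoked response)
carry no numeric parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .errors import CatalogMissError, DataError, InvalidParameterError
from .hill_core import hill_response

__all__ = [
    "ReceptorParams",
    "BasisSet",
    "catalog_version",
    "all_entries",
    "get_receptor",
    "osteoblast_basis",
    "make_basis",
    "evaluate_basis",
    "export_catalog_json",
    "OSTEOBLAST_RECEPTORS",
]

# ATP-responsive receptors expressed on osteoblasts; P2X6 and P2Y6 are also
# expressed but evoke no ATP response and are excluded from basis sets.
OSTEOBLAST_RECEPTORS = ("P2X2", "P2X5", "P2X7", "P2Y1", "P2Y2", "P2Y4")

_SPECIES_ALIASES = {
    "human": "human",
    "rodent": "rodent",
    "rat": "rodent",
    "mouse": "rodent",
    "murine": "rodent",
}


@dataclass(frozen=True)
class ReceptorParams:
    """Hill characterization of one receptor as catalogued for one species."""

    name: str
    species: str
    source_species: str
    k_half: Optional[float]
    k_half_err: Optional[float]
    hill_coeff: Optional[float]
    hill_coeff_err: Optional[float]
    r_squared: Optional[float]
    source: str
    responsive: bool
    surrogate_species: bool = False
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.responsive:
            if not (self.k_half and self.k_half > 0):
                raise InvalidParameterError(
                    f"{self.name}/{self.species}: responsive entry needs k_half > 0"
                )
            if not (self.hill_coeff and self.hill_coeff > 0):
                raise InvalidParameterError(
                    f"{self.name}/{self.species}: responsive entry needs hill_coeff > 0"
                )
        else:
            if self.k_half is not None or self.hill_coeff is not None:
                raise InvalidParameterError(
                    f"{self.name}/{self.species}: non-responsive entry must carry "
                    "no numeric parameters"
                )

    def response(self, concentration):
        if not self.responsive:
            raise InvalidParameterError(
                f"{self.name}/{self.species} is not ATP-responsive"
            )
        return hill_response(concentration, self.k_half, self.hill_coeff)


@dataclass(frozen=True)
class BasisSet:
    """Ordered set of responsive receptors used as dose-response basis functions."""

    members: tuple
    species: str

    def __post_init__(self) -> None:
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise DataError(f"basis member names must be unique, got {names}")
        for m in self.members:
            if not m.responsive:
                raise DataError(f"basis member {m.name} is not ATP-responsive")

    @property
    def names(self) -> tuple:
        return tuple(m.name for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def _load_raw() -> dict:
    text = (
        resources.files("p2ensemble").joinpath("data/receptor_catalog.json").read_text()
    )
    return json.loads(text)


_RAW = _load_raw()


def catalog_version() -> str:
    return _RAW["version"]


def _entry_to_params(rec: dict) -> ReceptorParams:
    return ReceptorParams(
        name=rec["receptor"],
        species=rec["species"],
        source_species=rec["source_species"],
        k_half=rec["k_half_M"],
        k_half_err=rec["k_half_err_M"],
        hill_coeff=rec["hill"],
        hill_coeff_err=rec["hill_err"],
        r_squared=rec["r2"],
        source=rec["source"],
        responsive=rec["responsive"],
        surrogate_species=rec["surrogate_species"],
        note=rec["note"],
    )


def all_entries() -> list:
    """Every catalog entry as :class:`ReceptorParams`, in catalog order."""
    return [_entry_to_params(rec) for rec in _RAW["entries"]]


def get_receptor(name: str, species: str) -> ReceptorParams:
    """Look up one receptor by name and species tag.

    ``species`` accepts "human", "rodent" and the aliases rat/mouse/murine
    (all resolved to the rodent tag, whose entries come from rat or mouse
    measurements as published).
    """
    tag = _SPECIES_ALIASES.get(species.lower())
    if tag is None:
        raise CatalogMissError(
            f"unknown species {species!r}; known: human, rodent (aliases rat, mouse)",
            available=sorted({r["species"] for r in _RAW["entries"]}),
        )
    for rec in _RAW["entries"]:
        if rec["receptor"].upper() == name.upper() and rec["species"] == tag:
            return _entry_to_params(rec)
    pairs = sorted({(r["receptor"], r["species"]) for r in _RAW["entries"]})
    raise CatalogMissError(
        f"no catalog entry for ({name!r}, {tag!r}); available pairs: {pairs}",
        available=pairs,
    )


def make_basis(names: Sequence[str], species: str) -> BasisSet:
    """Assemble a basis set from receptor names for one species."""
    members = tuple(get_receptor(n, species) for n in names)
    return BasisSet(members=members, species=_SPECIES_ALIASES.get(species.lower(), species))


def osteoblast_basis(species: str) -> BasisSet:
    """The ATP-responsive receptors expressed on osteoblasts, as a basis set."""
    return make_basis(OSTEOBLAST_RECEPTORS, species)


def evaluate_basis(basis: BasisSet, concentrations) -> np.ndarray:
    """Evaluate every basis member at the given concentrations.

    Returns an (n_concentrations, n_members) matrix; column order matches
    basis order. Empty concentration input yields a (0, n_members) matrix.
    """
    conc = np.atleast_1d(np.asarray(concentrations, dtype=float))
    if conc.size == 0:
        return np.empty((0, len(basis)))
    cols = [m.response(conc) for m in basis]
    return np.column_stack(cols)


def export_catalog_json() -> str:
    """Serialize the catalog; round-trips bit-exactly with the shipped file."""
    return json.dumps(_RAW, indent=2)
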