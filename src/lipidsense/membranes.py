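"""Liposome compositions and saturated-acyl-chain (SFA) accounting.

Membrane lipid saturation is the experimental axis of the whole study:
every liposome condition is labelled by the percentage of its phospholipid
acyl chains that carry zero double bonds.  Sterols (cholesterol) have no
acyl chains in this model and are excluded from the chain arithmetic, so a
mixture's SFA label is a property of its phospholipid fraction alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LipidSpecies",
    "MembraneComposition",
    "CompositionError",
    "CHAIN_LIBRARY",
    "species_from_name",
    "validate_composition",
    "sfa_chain_fraction",
    "builtin_compositions",
    "read_composition_csv",
    "write_composition_csv",
    "read_composition_json",
    "write_composition_json",
]


class CompositionError(ValueError):
    """A membrane composition violates a structural invariant."""


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species with annotated acyl chains.

    ``acyl_chains`` is a tuple of ``(carbons, double_bonds)`` pairs.  A
    chain is saturated iff ``double_bonds == 0``.  Sterols carry no acyl
    chains; every non-sterol glycerophospholipid carries exactly two.
    """

    name: str
    acyl_chains: tuple[tuple[int, int], ...] = ()
    is_sterol: bool = False

    def __post_init__(self) -> None:
        if self.is_sterol:
            if self.acyl_chains:
                raise CompositionError(
                    f"sterol {self.name!r} must not have acyl chains"
                )
        elif len(self.acyl_chains) != 2:
            raise CompositionError(
                f"non-sterol {self.name!r} must have exactly 2 acyl chains, "
                f"got {len(self.acyl_chains)}"
            )
        for carbons, dbonds in self.acyl_chains:
            if carbons <= 0 or dbonds < 0:
                raise CompositionError(
                    f"invalid chain ({carbons}:{dbonds}) on {self.name!r}"
                )

    @property
    def n_saturated_chains(self) -> int:
        return sum(1 for _, db in self.acyl_chains if db == 0)

    @property
    def n_chains(self) -> int:
        return len(self.acyl_chains)


# Common abbreviations used for the synthetic lipids in this study.
# PO = palmitoyl(16:0)/oleoyl(18:1); DO = dioleoyl; DP = dipalmitoyl;
# "16:1" species carry two palmitoleoyl chains.
CHAIN_LIBRARY: dict[str, LipidSpecies] = {
    s.name: s
    for s in (
        LipidSpecies("POPC", ((16, 0), (18, 1))),
        LipidSpecies("POPE", ((16, 0), (18, 1))),
        LipidSpecies("DOPC", ((18, 1), (18, 1))),
        LipidSpecies("DOPE", ((18, 1), (18, 1))),
        LipidSpecies("DOPS", ((18, 1), (18, 1))),
        LipidSpecies("DPPC", ((16, 0), (16, 0))),
        LipidSpecies("16:1 PC", ((16, 1), (16, 1))),
        LipidSpecies("16:1 PE", ((16, 1), (16, 1))),
        LipidSpecies("cholesterol", (), is_sterol=True),
    )
}


def species_from_name(name: str) -> LipidSpecies:
    """Look up a species by abbreviation in the built-in chain library.

    Unknown species require explicit chain annotation via
    :class:`LipidSpecies` — abbreviations do not encode chains reliably.
    """
    try:
        return CHAIN_LIBRARY[name]
    except KeyError:
        raise CompositionError(
            f"unknown lipid species {name!r}; construct a LipidSpecies with "
            "explicit acyl-chain annotation"
        ) from None


@dataclass
class MembraneComposition:
    """A named lipid mixture given as (species, mol%) entries."""

    entries: list[tuple[LipidSpecies, float]]
    label: str | None = None
    sum_tolerance: float = field(default=0.5, repr=False)

    @classmethod
    def from_dict(
        cls,
        mol_percent: Mapping[str, float],
        label: str | None = None,
        *,
        extra_species: Mapping[str, LipidSpecies] | None = None,
        validate: bool = True,
    ) -> "MembraneComposition":
        """Build a composition from ``{species name: mol%}``.

        Species are resolved through the built-in chain library, optionally
        extended with ``extra_species``.
        """
        lib = dict(CHAIN_LIBRARY)
        if extra_species:
            lib.update(extra_species)
        entries = []
        for name, pct in mol_percent.items():
            if name not in lib:
                raise CompositionError(
                    f"unknown lipid species {name!r}; pass extra_species with "
                    "explicit chain annotation"
                )
            entries.append((lib[name], float(pct)))
        comp = cls(entries=entries, label=label)
        return validate_composition(comp) if validate else comp

    def as_dict(self) -> dict[str, float]:
        return {sp.name: pct for sp, pct in self.entries}

    @property
    def total_mol_percent(self) -> float:
        return sum(pct for _, pct in self.entries)


def validate_composition(comp: MembraneComposition) -> MembraneComposition:
    """Check composition invariants and return the composition unchanged.

    Raises :class:`CompositionError` if entries are empty, any mol% is
    negative, species names repeat, or the mol% total deviates from 100 by
    more than ``comp.sum_tolerance`` (default ±0.5, accommodating rounded
    entries such as 66.7/16.7/6.7).
    """
    if not comp.entries:
        raise CompositionError("composition has no entries")
    names = [sp.name for sp, _ in comp.entries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise CompositionError(f"duplicate species: {dupes}")
    for sp, pct in comp.entries:
        if pct < 0:
            raise CompositionError(f"negative mol% for {sp.name}: {pct}")
    total = comp.total_mol_percent
    if abs(total - 100.0) > comp.sum_tolerance:
        raise CompositionError(
            f"mol% sum {total:g} outside 100 ± {comp.sum_tolerance:g}"
        )
    return comp


def sfa_chain_fraction(comp: MembraneComposition) -> float:
    """Percentage of phospholipid acyl chains that are saturated.

    Computed as ``100 · Σ(mol% · saturated chains) / Σ(mol% · total
    chains)`` over non-sterol species; sterols contribute neither chains
    nor weight.  The value is invariant under common rescaling of all mol%
    and under adding sterol at the expense of a proportional phospholipid
    rescale.
    """
    validate_composition(comp)
    sat = 0.0
    tot = 0.0
    for sp, pct in comp.entries:
        if sp.is_sterol:
            continue
        sat += pct * sp.n_saturated_chains
        tot += pct * sp.n_chains
    if tot == 0:
        raise CompositionError(
            "SFA chain fraction undefined: composition has no phospholipids"
        )
    return 100.0 * sat / tot


def _data_path() -> Path:
    return Path(str(resources.files("lipidsense").joinpath("data")))


def builtin_compositions() -> dict[str, MembraneComposition]:
    """The eleven liposome mixtures used in the study, keyed by SFA label.

    Labels name the phospholipid mixture (e.g. ``"33% SFA (ER-like)"``,
    ``"60% SFA +cholesterol"``); for the "+cholesterol" variants the label
    is metadata inherited from the parent phospholipid mix, not recomputed
    from chain arithmetic.
    """
    path = _data_path() / "liposome_compositions.csv"
    table = pd.read_csv(path, comment="#")
    out: dict[str, MembraneComposition] = {}
    for label, grp in table.groupby("label", sort=False):
        out[str(label)] = MembraneComposition.from_dict(
            dict(zip(grp["species"], grp["mol_percent"])), label=str(label)
        )
    return out


def read_composition_csv(path: str | Path, label: str | None = None) -> MembraneComposition:
    """Read a composition from CSV with columns ``species, mol_percent``."""
    table = pd.read_csv(path, comment="#")
    missing = {"species", "mol_percent"} - set(table.columns)
    if missing:
        raise CompositionError(f"{path}: missing columns {sorted(missing)}")
    return MembraneComposition.from_dict(
        dict(zip(table["species"], table["mol_percent"])), label=label
    )


def write_composition_csv(comp: MembraneComposition, path: str | Path) -> None:
    pd.DataFrame(
        {"species": [sp.name for sp, _ in comp.entries],
         "mol_percent": [pct for _, pct in comp.entries]}
    ).to_csv(path, index=False)


def read_composition_json(path: str | Path) -> MembraneComposition:
    with open(path) as fh:
        payload = json.load(fh)
    return MembraneComposition.from_dict(
        payload["mol_percent"], label=payload.get("label")
    )


def write_composition_json(comp: MembraneComposition, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"label": comp.label, "mol_percent": comp.as_dict()}, fh, indent=2)
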