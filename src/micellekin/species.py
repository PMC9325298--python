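"""Lipid species definitions: headgroup moieties and toy pseudo-atom layouts.

The five surfactants studied here share a 12-carbon tail and differ only in
headgroup chemistry:

* SDS  -- sodium dodecyl sulfate, single negative sulfate moiety ``S``;
* DDA  -- dodecyl dimethyl amine-oxide, single positive ammonium moiety ``N``;
* DPC  -- dodecyl phosphocholine, zwitterionic (choline ``N`` +, phosphate
  ``P`` -);
* DAS  -- dodecyl dimethyl ammonio propane sulfonate, zwitterionic
  (sulfonate ``S`` -, ammonium ``N`` +);
* LAU  -- lauric acid, neutral carboxyl moiety ``C1``.

Each species carries a "prominent" head atom (the reference point for the
orientation analysis) and the terminal tail carbon ``C12``.  For synthetic
trajectories every lipid is represented by a short pseudo-atom chain -- the
head moiety atoms followed by three tail beads -- laid out along the
head-to-tail axis; this is the smallest layout that supports both the
headgroup-interaction and the orientation geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml


@dataclass(frozen=True)
class Moiety:
    """A headgroup moiety: atom label plus charge sign (+1, -1 or 0)."""

    label: str
    charge: int

    def __post_init__(self):
        if self.charge not in (-1, 0, 1):
            raise ValueError(f"moiety charge must be -1, 0 or +1, got {self.charge}")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid type with its moieties and toy pseudo-atom geometry.

    ``atom_labels``/``atom_offsets`` describe the pseudo-atom chain used by the
    synthetic trajectory generator: offsets are distances (nm) along the
    head-to-tail axis from the prominent-head end.  ``moiety_of_atom`` maps
    atom labels to moiety labels for the atoms that belong to the headgroup.
    """

    name: str
    moieties: tuple[Moiety, ...]
    prominent_head_atom: str
    terminal_tail_atom: str
    net_charge: int
    atom_labels: tuple[str, ...]
    atom_offsets: tuple[float, ...]
    moiety_of_atom: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.moieties:
            raise ValueError(f"{self.name}: species needs at least one moiety")
        if len(self.atom_labels) != len(self.atom_offsets):
            raise ValueError(f"{self.name}: atom labels and offsets differ in length")
        for atom in (self.prominent_head_atom, self.terminal_tail_atom):
            if atom not in self.atom_labels:
                raise ValueError(f"{self.name}: atom {atom!r} missing from layout")
        for m in self.moieties:
            if m.label not in self.atom_labels:
                raise ValueError(f"{self.name}: moiety atom {m.label!r} missing from layout")

    @property
    def moiety_labels(self) -> tuple[str, ...]:
        return tuple(m.label for m in self.moieties)

    @property
    def is_single_moiety(self) -> bool:
        return len(self.moieties) == 1

    def moiety_charge(self, label: str) -> int:
        for m in self.moieties:
            if m.label == label:
                return m.charge
        raise KeyError(label)


def _sp(name, moieties, prominent, charge, head_atoms, head_offsets):
    tail_labels = ("C4", "C8", "C12")
    tail0 = head_offsets[-1] + 0.12
    tail_offsets = (tail0, tail0 + 0.12, tail0 + 0.24)
    return LipidSpecies(
        name=name,
        moieties=tuple(Moiety(l, c) for l, c in moieties),
        prominent_head_atom=prominent,
        terminal_tail_atom="C12",
        net_charge=charge,
        atom_labels=tuple(head_atoms) + tail_labels,
        atom_offsets=tuple(head_offsets) + tail_offsets,
        moiety_of_atom={l: l for l, _ in moieties},
    )


SDS = _sp("SDS", [("S", -1)], "S", -1, ["S"], [0.0])
DDA = _sp("DDA", [("N", +1)], "N", +1, ["N"], [0.0])
DPC = _sp("DPC", [("N", +1), ("P", -1)], "N", 0, ["N", "P"], [0.0, 0.10])
DAS = _sp("DAS", [("S", -1), ("N", +1)], "S", 0, ["S", "N"], [0.0, 0.10])
LAU = _sp("LAU", [("C1", 0)], "C1", 0, ["C1"], [0.0])

#: The five default species, keyed by name.
DEFAULT_SPECIES: dict[str, LipidSpecies] = {s.name: s for s in (SDS, DDA, DPC, DAS, LAU)}


def species_table_to_yaml(species: dict[str, LipidSpecies], path) -> None:
    """Write a species/moiety mapping table as YAML."""
    data = {}
    for name, sp in species.items():
        data[name] = {
            "resname": name,
            "moieties": [{"label": m.label, "charge": m.charge} for m in sp.moieties],
            "prominent_head_atom": sp.prominent_head_atom,
            "terminal_tail_atom": sp.terminal_tail_atom,
            "net_charge": sp.net_charge,
            "atom_labels": list(sp.atom_labels),
            "atom_offsets": [float(x) for x in sp.atom_offsets],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def species_table_from_yaml(path) -> dict[str, LipidSpecies]:
    """Read a species/moiety mapping table written by :func:`species_table_to_yaml`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = {}
    for name, d in data.items():
        out[name] = LipidSpecies(
            name=name,
            moieties=tuple(Moiety(m["label"], int(m["charge"])) for m in d["moieties"]),
            prominent_head_atom=d["prominent_head_atom"],
            terminal_tail_atom=d["terminal_tail_atom"],
            net_charge=int(d["net_charge"]),
            atom_labels=tuple(d["atom_labels"]),
            atom_offsets=tuple(float(x) for x in d["atom_offsets"]),
            moiety_of_atom={m["label"]: m["label"] for m in d["moieties"]},
        )
    return out
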