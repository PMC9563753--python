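"""Shorthand sphingolipid nomenclature, elemental formulas, and negative-mode ion masses.

Sulfatides (SHexCer, SHex2Cer), sphingomyelins (SM), and sterol sulfates
(StS) are quantified in negative-ion MALDI as deprotonated molecules
([M-H]-) or, for SM, as the demethylated [M-CH3]- ion.  This module turns
shorthand names like ``SHexCer 42:1;O3`` into elemental compositions and
theoretical ion m/z values, and assembles them into a sorted annotation
database used for peak assignment.

Conventions
-----------
* Sum-level names are ``<CLASS> <C>:<DB>;O<k>`` where C is the total chain
  carbon count, DB the number of double bonds, and k the hydroxyl-type
  oxygen count of the ceramide part (k = 2 for non-hydroxylated species).
* Species-level names ``<CLASS> <base>:<bDB>;O<k>/<acyl>:<aDB>`` (e.g. the
  internal standard ``SHexCer 18:1;O2/12:0``) are normalized to sum-level
  totals for database keys; the species-level string is kept for display.
* Sterol sulfates are opaque identifiers (``StS 3`` ...) whose elemental
  compositions are not public; they must carry a user-supplied formula or
  an explicit m/z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LipidSpecies",
    "AnnotationDB",
    "LipidParseError",
    "MONOISOTOPIC",
    "ELECTRON_MASS",
    "parse_shorthand",
    "derive_formula",
    "formula_mass",
    "ion_mz",
    "annotate",
    "build_database",
    "parse_formula",
    "formula_to_string",
    "read_panel",
    "write_database",
]

# Single-isotope (monoisotopic) atomic masses, Da.
MONOISOTOPIC: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737615,
    "S": 31.9720707,
}

#: Mass of one electron, Da.  Anion m/z includes it: at R = 100,000 the
#: instrument resolves ~7 mDa at m/z 700, so the 0.55 mDa shift matters.
ELECTRON_MASS = 0.00054858

SPHINGOLIPID_CLASSES = ("SM", "SHexCer", "SHex2Cer")
KNOWN_CLASSES = SPHINGOLIPID_CLASSES + ("StS",)

#: Neutral fragment removed by each supported negative-mode adduct.
ADDUCT_LOSSES: dict[str, dict[str, int]] = {
    "[M-H]-": {"H": 1},
    "[M-CH3]-": {"C": 1, "H": 3},
}

#: Default adduct per lipid class (SM loses a phosphocholine methyl).
CLASS_ADDUCTS: dict[str, str] = {
    "SM": "[M-CH3]-",
    "SHexCer": "[M-H]-",
    "SHex2Cer": "[M-H]-",
    "StS": "[M-H]-",
}

# Head-group increments relative to the ceramide core (net of condensation).
_PHOSPHOCHOLINE_NET = {"C": 5, "H": 12, "N": 1, "O": 3, "P": 1}  # C5H14NO4P - H2O
_HEXOSE_NET = {"C": 6, "H": 10, "O": 5}  # C6H12O6 - H2O
_SULFATE_NET = {"S": 1, "O": 3}  # SO3


class LipidParseError(ValueError):
    """Raised when a shorthand lipid name cannot be interpreted."""


@dataclass
class LipidSpecies:
    """One lipid channel of the annotation database."""

    name: str
    lipid_class: str
    carbons: int | None = None
    double_bonds: int | None = None
    hydroxyl_count: int | None = None
    formula: dict[str, int] | None = None
    neutral_mass: float | None = None
    adduct: str | None = None
    ion_mz: float | None = None
    #: original (species-level) string when ``name`` was normalized
    display_name: str | None = None

    def key(self) -> tuple[str, str | None]:
        return (self.name, self.adduct)


_DESCRIPTOR_RE = re.compile(
    r"^(?P<c>\d+):(?P<db>\d+);O(?P<k>\d+)(?:/(?P<c2>\d+):(?P<db2>\d+))?$"
)


def parse_shorthand(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a partially populated species.

    Species-level names (``SHexCer 18:1;O2/12:0``) are summed into
    sum-level totals; the full string is retained as ``display_name``.
    ``StS`` names are treated as opaque identifiers.
    """
    tokens = name.strip().split(None, 1)
    if len(tokens) != 2:
        raise LipidParseError(f"malformed lipid name {name!r}: expected '<CLASS> <descriptor>'")
    cls, descriptor = tokens
    if cls not in KNOWN_CLASSES:
        raise LipidParseError(f"unknown lipid class token {cls!r} in {name!r}")
    if cls == "StS":
        # opaque identifier; composition must be supplied by the caller
        return LipidSpecies(name=name.strip(), lipid_class=cls)

    m = _DESCRIPTOR_RE.match(descriptor)
    if m is None:
        raise LipidParseError(f"malformed descriptor {descriptor!r} in {name!r}")
    carbons = int(m.group("c"))
    double_bonds = int(m.group("db"))
    hydroxyls = int(m.group("k"))
    display = None
    if m.group("c2") is not None:
        display = name.strip()
        carbons += int(m.group("c2"))
        double_bonds += int(m.group("db2"))
    if hydroxyls not in (2, 3, 4):
        raise LipidParseError(
            f"hydroxyl count O{hydroxyls} outside the sphingolipid range 2-4 in {name!r}"
        )
    sum_name = f"{cls} {carbons}:{double_bonds};O{hydroxyls}"
    return LipidSpecies(
        name=sum_name,
        lipid_class=cls,
        carbons=carbons,
        double_bonds=double_bonds,
        hydroxyl_count=hydroxyls,
        display_name=display,
    )


def _merge(*parts: Mapping[str, int]) -> dict[str, int]:
    out: dict[str, int] = {}
    for part in parts:
        for el, n in part.items():
            out[el] = out.get(el, 0) + n
    return {el: n for el, n in out.items() if n != 0}


def ceramide_core_formula(carbons: int, double_bonds: int, hydroxyls: int) -> dict[str, int]:
    """Elemental composition of the ceramide core C:n DB:d ;Ok.

    The core (sphingoid base amide-linked to a fatty acyl) is
    C_n H_(2n+1-2d) N O_(k+1): e.g. Cer 30:1;O2 (d18:1/12:0) = C30H59NO3.
    """
    h = 2 * carbons + 1 - 2 * double_bonds
    if h <= 0:
        raise LipidParseError(
            f"inconsistent ceramide descriptor {carbons}:{double_bonds} (negative H count)"
        )
    return {"C": carbons, "H": h, "N": 1, "O": hydroxyls + 1}


def derive_formula(species: LipidSpecies) -> dict[str, int]:
    """Derive the neutral elemental composition of a sphingolipid.

    SM adds the phosphocholine head (C5H14NO4P, net of condensation water);
    SHexCer adds one hexose (net C6H10O5) plus SO3; SHex2Cer adds two
    hexoses plus SO3.  StS species carry no constructive rule and must be
    given an explicit formula or m/z.
    """
    if species.lipid_class == "StS":
        raise LipidParseError(
            f"formula required: sterol sulfate {species.name!r} has no constructive "
            "composition rule; supply a formula or explicit m/z"
        )
    if species.carbons is None or species.double_bonds is None or species.hydroxyl_count is None:
        raise LipidParseError(f"species {species.name!r} lacks a parsed C:DB;O descriptor")
    core = ceramide_core_formula(species.carbons, species.double_bonds, species.hydroxyl_count)
    if species.lipid_class == "SM":
        return _merge(core, _PHOSPHOCHOLINE_NET)
    if species.lipid_class == "SHexCer":
        return _merge(core, _HEXOSE_NET, _SULFATE_NET)
    if species.lipid_class == "SHex2Cer":
        return _merge(core, _HEXOSE_NET, _HEXOSE_NET, _SULFATE_NET)
    raise LipidParseError(f"unknown lipid class {species.lipid_class!r}")


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a neutral elemental composition."""
    mass = 0.0
    for el, n in formula.items():
        if el not in MONOISOTOPIC:
            raise LipidParseError(f"no monoisotopic mass for element {el!r}")
        if n < 0:
            raise LipidParseError(f"negative count for element {el!r}")
        mass += MONOISOTOPIC[el] * n
    return mass


def ion_mz(formula: Mapping[str, int], adduct: str) -> float:
    """m/z of the singly charged anion formed by the given neutral loss.

    The electron gained by the anion is included (+``ELECTRON_MASS``).
    """
    if adduct not in ADDUCT_LOSSES:
        raise LipidParseError(f"unsupported adduct {adduct!r}")
    loss = ADDUCT_LOSSES[adduct]
    for el, n in loss.items():
        if formula.get(el, 0) < n:
            raise LipidParseError(
                f"adduct {adduct} removes {n} x {el} but formula has {formula.get(el, 0)}"
            )
    return formula_mass(formula) - formula_mass(loss) + ELECTRON_MASS


def annotate(species: LipidSpecies, adduct: str | None = None) -> LipidSpecies:
    """Fill formula, neutral mass, adduct, and ion m/z on a parsed species."""
    formula = species.formula if species.formula is not None else derive_formula(species)
    add = adduct or species.adduct or CLASS_ADDUCTS[species.lipid_class]
    neutral = formula_mass(formula)
    return replace(
        species,
        formula=formula,
        neutral_mass=neutral,
        adduct=add,
        ion_mz=ion_mz(formula, add),
    )


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string such as ``C36H69NO11S``."""
    pos = 0
    out: dict[str, int] = {}
    for m in _FORMULA_RE.finditer(text.strip()):
        if m.start() != pos:
            raise LipidParseError(f"malformed formula {text!r}")
        pos = m.end()
        if not m.group(0):
            break
        el = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        out[el] = out.get(el, 0) + n
    if pos != len(text.strip()) or not out:
        raise LipidParseError(f"malformed formula {text!r}")
    return out


def formula_to_string(formula: Mapping[str, int]) -> str:
    """Hill-order string (C, H, then alphabetical)."""
    order = ["C", "H"] + sorted(el for el in formula if el not in ("C", "H"))
    parts = []
    for el in order:
        n = formula.get(el, 0)
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


@dataclass
class AnnotationDB:
    """Lipid annotation database sorted by theoretical ion m/z."""

    entries: list[LipidSpecies] = field(default_factory=list)
    tolerance_ppm: float = 5.0

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda s: s.ion_mz)
        mzs = [e.ion_mz for e in self.entries]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("annotation database entries must be strictly sorted by ion m/z")

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def mz_values(self) -> list[float]:
        return [e.ion_mz for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "class": [e.lipid_class for e in self.entries],
                "adduct": [e.adduct for e in self.entries],
                "formula": [
                    formula_to_string(e.formula) if e.formula else "" for e in self.entries
                ],
                "mz": [e.ion_mz for e in self.entries],
            }
        )


def _species_from_record(rec: Mapping[str, object]) -> LipidSpecies:
    name = str(rec["name"])
    formula = rec.get("formula")
    mz = rec.get("mz")
    adduct = rec.get("adduct")
    if isinstance(formula, str) and formula:
        formula = parse_formula(formula)
    elif not isinstance(formula, Mapping):
        formula = None
    try:
        species = parse_shorthand(name)
    except LipidParseError:
        # opaque channel (e.g. a deuterated IS): allowed only with explicit m/z
        if mz is None:
            raise
        return LipidSpecies(
            name=name,
            lipid_class=str(rec.get("class", "StS")),
            adduct=str(adduct) if adduct else "[M-H]-",
            ion_mz=float(mz),  # type: ignore[arg-type]
        )
    if formula is not None:
        species = replace(species, formula=dict(formula))
    if species.lipid_class == "StS" and species.formula is None:
        if mz is None:
            raise LipidParseError(
                f"formula required: StS record {name!r} needs a formula or explicit m/z"
            )
        # verbatim pass-through: the m/z is taken on trust
        return replace(
            species,
            adduct=str(adduct) if adduct else CLASS_ADDUCTS["StS"],
            ion_mz=float(mz),  # type: ignore[arg-type]
        )
    annotated = annotate(species, adduct=str(adduct) if adduct else None)
    if mz is not None:
        annotated = replace(annotated, ion_mz=float(mz))  # type: ignore[arg-type]
    return annotated


def build_database(
    panel: Sequence[str | Mapping[str, object]],
    tolerance_ppm: float = 5.0,
    adduct_rules: Mapping[str, str] | None = None,
) -> AnnotationDB:
    """Build a sorted :class:`AnnotationDB` from shorthand names or records.

    ``panel`` items are either bare shorthand strings or mappings with keys
    ``name`` and optionally ``adduct``, ``formula`` (Hill string or element
    map) and ``mz`` (explicit ion m/z, required for StS without formula).
    Duplicate (name, adduct) pairs are rejected.
    """
    if not panel:
        raise ValueError("empty lipid panel")
    rules = dict(CLASS_ADDUCTS)
    if adduct_rules:
        rules.update(adduct_rules)
    entries: list[LipidSpecies] = []
    seen: set[tuple[str, str | None]] = set()
    for item in panel:
        rec: Mapping[str, object] = {"name": item} if isinstance(item, str) else item
        species = _species_from_record(rec)
        if species.adduct is None:
            species = annotate(species, adduct=rules[species.lipid_class])
        if species.key() in seen:
            raise ValueError(f"duplicate panel entry {species.key()!r}")
        seen.add(species.key())
        entries.append(species)
    return AnnotationDB(entries=entries, tolerance_ppm=tolerance_ppm)


def read_panel(path) -> list[dict[str, object]]:
    """Read a lipid panel file (delimited text: name[, class, adduct, formula, mz])."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "name" not in df.columns:
        raise ValueError("panel file must have a 'name' column")
    records: list[dict[str, object]] = []
    for _, row in df.iterrows():
        rec: dict[str, object] = {"name": row["name"]}
        for col in ("adduct", "formula", "mz"):
            if col in df.columns and pd.notna(row[col]) and row[col] != "":
                rec[col] = row[col]
        records.append(rec)
    return records


def write_database(db: AnnotationDB, path) -> None:
    """Export the database as delimited text sorted by m/z."""
    db.to_frame().to_csv(path, sep="\t", index=False)
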