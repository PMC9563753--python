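"""Default lipid panels, internal standards, and dysregulation maps.

The package ships one panel per sample matrix (plasma, urine, tissue)
mirroring the channel composition of the study cohorts: 33 quantified
plasma lipids (SM + SHexCer), 33 urine lipids (18 SHexCer + 4 SHex2Cer +
11 StS), and 44 tissue lipids.  Each panel additionally carries

* low-abundance "rare" channels that fail the 50%-presence inclusion
  criterion and feed the presence/absence contingency analysis,
* one channel with deliberately poor QC reproducibility (dropped by the
  35% QC-CV criterion), and
* the spiked internal standards (IS) used for molar normalization.

Sterol sulfate compositions are not public; StS channels carry synthetic
placeholder m/z values spaced far apart (> 50 ppm).  Dysregulation
directions follow the reported body-fluid/tissue patterns (lactosyl-
sulfatides and polyunsaturated SHexCer up in cancer, hydroxylated
sulfatides and long-chain SM down); the magnitudes are package defaults
for the synthetic cohorts, with the late-stage bracket (T3-4) farther
from 1 than the early bracket (T1-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "PanelChannel",
    "EffectSizes",
    "default_panel",
    "default_effect_map",
    "default_is_declarations",
    "lipid_class_of",
    "CLASS_GROUPS",
]

#: Relative percentages are computed within these class groups: SM,
#: sulfatides (SHexCer + SHex2Cer together), and sterol sulfates.
CLASS_GROUPS: dict[str, str] = {
    "SM": "SM",
    "SHexCer": "sulfatide",
    "SHex2Cer": "sulfatide",
    "StS": "StS",
}

#: Default dysregulation multipliers (cases vs controls) per stage bracket.
UP_MULT = (1.6, 2.0)  # (T1-2, T3-4)
DOWN_MULT = (0.625, 0.5)


@dataclass(frozen=True)
class PanelChannel:
    """One m/z channel of a panel with its simulation parameters."""

    name: str
    role: str = "main"  # main | rare | is
    base: float = 1e5  # median raw intensity in controls
    qc_cv: float | None = None  # override of the pooled-QC CV for this channel
    presence: tuple[float, float] | None = None  # (p_control, p_case) for rare channels
    mz: float | None = None  # explicit ion m/z (StS, deuterated IS)
    formula: str | None = None
    is_amount: float | None = None  # spiked amount, nmol per mL (or per g of tissue)
    is_classes: tuple[str, ...] = ()

    def record(self) -> dict[str, object]:
        """Panel record consumed by :func:`sulfascreen.lipid_db.build_database`."""
        rec: dict[str, object] = {"name": self.name}
        if self.mz is not None:
            rec["mz"] = self.mz
            rec["class"] = lipid_class_of(self.name)
        if self.formula is not None:
            rec["formula"] = self.formula
        return rec


@dataclass(frozen=True)
class EffectSizes:
    """Stage-bracket multipliers of one dysregulated lipid."""

    early: float
    late: float

    @property
    def direction(self) -> str:
        if self.late > 1.0:
            return "up"
        if self.late < 1.0:
            return "down"
        return "null"


def _bases(names: list[str], lo: float = 4.6, span: float = 0.5) -> list[float]:
    # deterministic spread of baseline medians over about half a decade
    return [10 ** (lo + span * ((7 * i) % 11) / 10.0) for i, n in enumerate(names)]


_PLASMA_SM = [
    "SM 32:1;O2", "SM 32:2;O2", "SM 33:1;O2", "SM 34:0;O2", "SM 34:1;O2",
    "SM 34:2;O2", "SM 36:0;O2", "SM 36:1;O2", "SM 36:2;O2", "SM 38:1;O2",
    "SM 38:2;O2", "SM 39:1;O2", "SM 40:1;O2", "SM 41:1;O2", "SM 42:1;O2",
    "SM 42:2;O2",
]
_PLASMA_SHEXCER = [
    "SHexCer 34:1;O2", "SHexCer 34:1;O3", "SHexCer 36:1;O2", "SHexCer 36:1;O3",
    "SHexCer 38:1;O2", "SHexCer 40:1;O2", "SHexCer 40:1;O3", "SHexCer 41:1;O2",
    "SHexCer 41:1;O3", "SHexCer 42:1;O2", "SHexCer 42:1;O3", "SHexCer 42:2;O2",
    "SHexCer 42:2;O3", "SHexCer 42:3;O2", "SHexCer 42:3;O3", "SHexCer 43:1;O2",
    "SHexCer 43:1;O3",
]

_URINE_SHEXCER = [
    "SHexCer 34:1;O2", "SHexCer 34:1;O3", "SHexCer 36:1;O2", "SHexCer 38:1;O2",
    "SHexCer 38:1;O3", "SHexCer 40:1;O2", "SHexCer 40:1;O3", "SHexCer 40:1;O4",
    "SHexCer 41:1;O3", "SHexCer 42:1;O2", "SHexCer 42:1;O3", "SHexCer 42:1;O4",
    "SHexCer 42:2;O2", "SHexCer 42:2;O3", "SHexCer 42:3;O2", "SHexCer 43:1;O3",
    "SHexCer 44:1;O3", "SHexCer 44:1;O4",
]
_URINE_SHEX2CER = [
    "SHex2Cer 34:1;O2", "SHex2Cer 40:1;O2", "SHex2Cer 42:1;O2", "SHex2Cer 42:2;O2",
]
# Placeholder m/z values, 3 Da apart (>> 50 ppm), below the sphingolipid region.
_URINE_STS = [(f"StS {i}", 380.0 + 3.0 * i + 0.21) for i in range(1, 12)]

_TISSUE_SHEXCER = _URINE_SHEXCER + ["SHexCer 36:1;O3", "SHexCer 43:1;O4"]
_TISSUE_SHEX2CER = [
    "SHex2Cer 34:1;O2", "SHex2Cer 36:1;O2", "SHex2Cer 38:1;O2", "SHex2Cer 40:1;O2",
    "SHex2Cer 40:1;O3", "SHex2Cer 41:1;O2", "SHex2Cer 42:1;O2", "SHex2Cer 42:1;O3",
    "SHex2Cer 42:2;O2", "SHex2Cer 42:2;O3", "SHex2Cer 42:3;O2", "SHex2Cer 44:1;O2",
]
_TISSUE_SM = [
    "SM 32:1;O2", "SM 33:1;O2", "SM 34:1;O2", "SM 36:1;O2", "SM 36:2;O2",
    "SM 38:1;O2", "SM 39:1;O2", "SM 40:1;O2", "SM 41:1;O2", "SM 42:1;O2",
    "SM 42:2;O2", "SM 42:3;O2",
]

#: Deuterated taurocholic acid IS (urine sterol-sulfate channel); the
#: deuterium content is outside the single-isotope table, so the ion m/z
#: is carried explicitly.
_D4_TCA_MZ = 518.3095


def _main_channels(names: list[str]) -> list[PanelChannel]:
    return [PanelChannel(name=n, base=b) for n, b in zip(names, _bases(names))]


def default_panel(matrix: str) -> list[PanelChannel]:
    """Default panel (main + rare + QC-noisy + IS channels) for a matrix."""
    if matrix == "plasma":
        channels = _main_channels(_PLASMA_SM + _PLASMA_SHEXCER)
        channels.append(PanelChannel("SM 35:1;O2", base=6e4, qc_cv=0.55))
        channels += [
            PanelChannel("SHex2Cer 42:2;O2", role="rare", base=2.5e4,
                         presence=(2 / 207, 24 / 143)),
            PanelChannel("SM 43:1;O2", role="rare", base=2.2e4, presence=(0.35, 0.12)),
            PanelChannel("SHexCer 44:1;O3", role="rare", base=2.0e4, presence=(0.38, 0.15)),
            PanelChannel("SHexCer 18:1;O2/12:0", role="is", base=1.2e5,
                         is_amount=0.1, is_classes=("SHexCer", "SHex2Cer")),
            PanelChannel("SM 18:1;O2/12:0", role="is", base=6e5,
                         is_amount=43.3, is_classes=("SM",)),
        ]
        return channels
    if matrix == "urine":
        names = _URINE_SHEXCER + _URINE_SHEX2CER
        channels = _main_channels(names)
        channels += [
            PanelChannel(n, base=b, mz=mz)
            for (n, mz), b in zip(_URINE_STS, _bases([n for n, _ in _URINE_STS], lo=4.7))
        ]
        channels.append(PanelChannel("SHexCer 36:1;O3", base=5e4, qc_cv=0.55))
        channels += [
            PanelChannel("SHexCer 43:1;O4", role="rare", base=2.1e4, presence=(0.40, 0.15)),
            PanelChannel("SHexCer 34:1;O4", role="rare", base=2.3e4, presence=(0.35, 0.12)),
            PanelChannel("SHexCer 18:1;O2/12:0", role="is", base=9e4,
                         is_amount=0.04, is_classes=("SHexCer", "SHex2Cer")),
            PanelChannel("D4-TCA", role="is", base=2.5e5, mz=_D4_TCA_MZ,
                         is_amount=0.55, is_classes=("StS",)),
        ]
        return channels
    if matrix == "tissue":
        channels = _main_channels(_TISSUE_SHEXCER + _TISSUE_SHEX2CER + _TISSUE_SM)
        channels.append(PanelChannel("SM 35:1;O2", base=5e4, qc_cv=0.55))
        channels += [
            PanelChannel("SHexCer 34:1;O4", role="rare", base=2.0e4, presence=(0.42, 0.15)),
            PanelChannel("SM 43:1;O2", role="rare", base=2.2e4, presence=(0.36, 0.12)),
            PanelChannel("SHexCer 18:1;O2/12:0", role="is", base=1.0e5,
                         is_amount=0.1, is_classes=("SHexCer", "SHex2Cer")),
            PanelChannel("SM 18:1;O2/12:0", role="is", base=5e5,
                         is_amount=43.3, is_classes=("SM",)),
        ]
        return channels
    raise ValueError(f"unknown sample matrix {matrix!r}")


def default_effect_map(matrix: str) -> dict[str, EffectSizes]:
    """Per-lipid stage-bracket multipliers for the synthetic cohorts.

    Unlisted panel lipids are null (multiplier 1 in both brackets).
    """
    up = EffectSizes(*UP_MULT)
    down = EffectSizes(*DOWN_MULT)
    if matrix == "plasma":
        m = {
            # long-chain and short-chain SM reduced in cancer plasma
            "SM 32:1;O2": down, "SM 33:1;O2": down, "SM 38:1;O2": down,
            "SM 39:1;O2": down, "SM 40:1;O2": down, "SM 41:1;O2": down,
            # hydroxylated monounsaturated sulfatides reduced
            "SHexCer 40:1;O2": down, "SHexCer 40:1;O3": down,
            "SHexCer 41:1;O3": down, "SHexCer 42:1;O3": down,
            # polyunsaturated sulfatides elevated
            "SHexCer 42:2;O2": up, "SHexCer 42:3;O2": up, "SHexCer 42:3;O3": up,
        }
        return m
    if matrix == "urine":
        m = {
            # lactosylsulfatides elevated in cancer urine
            "SHex2Cer 34:1;O2": up, "SHex2Cer 40:1;O2": up,
            "SHex2Cer 42:1;O2": up, "SHex2Cer 42:2;O2": up,
            # hydroxylated sulfatides reduced
            "SHexCer 40:1;O3": down, "SHexCer 40:1;O4": down,
            "SHexCer 41:1;O3": down, "SHexCer 42:1;O3": down,
            "SHexCer 42:1;O4": down, "SHexCer 44:1;O4": down,
            # cortisol-like sterol sulfates up, lithocholic-like down
            "StS 3": up, "StS 4": up, "StS 8": down, "StS 11": down,
        }
        return m
    if matrix == "tissue":
        m = {
            "SHex2Cer 34:1;O2": up, "SHex2Cer 40:1;O2": up, "SHex2Cer 42:1;O2": up,
            "SHex2Cer 42:2;O2": up, "SHexCer 42:2;O2": up, "SHexCer 42:3;O2": up,
            "SM 42:2;O2": up,
            "SHexCer 40:1;O3": down, "SHexCer 40:1;O4": down, "SHexCer 41:1;O3": down,
            "SHexCer 42:1;O3": down, "SHexCer 42:1;O4": down, "SHexCer 44:1;O4": down,
            "SM 41:1;O2": down, "SM 42:1;O2": down,
        }
        return m
    raise ValueError(f"unknown sample matrix {matrix!r}")


def default_is_declarations(matrix: str) -> dict[str, dict[str, object]]:
    """Internal-standard declarations: spiked amount and covered classes."""
    out: dict[str, dict[str, object]] = {}
    for ch in default_panel(matrix):
        if ch.role == "is":
            out[ch.name] = {"amount": ch.is_amount, "classes": list(ch.is_classes)}
    return out


def lipid_class_of(name: str) -> str:
    """Lipid class token of a channel name (IS channels keep their class)."""
    if name == "D4-TCA":
        return "StS"
    return name.split(None, 1)[0]
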