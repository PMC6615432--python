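"""The vitamin panel: which B-vitamin phenotypes a reference collection carries.

Every matrix in the pipeline (binary phenotype matrix, community phenotype
matrix, community signatures) shares one vitamin dimension, defined here. The
default panel covers the eight major B-vitamins, each the biosynthetic
precursor of an essential cofactor (B1 -> TPP, B2 -> FMN/FAD, ...). The panel
is configurable so the machinery generalizes to other trait sets; the packaged
fixtures all use the 8-vitamin default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .errors import ConfigError

DEFAULT_VITAMINS: tuple[str, ...] = ("B1", "B2", "B3", "B5", "B6", "B7", "B9", "B12")

#: Display-only cofactor labels for the default panel.
DEFAULT_COFACTORS: Mapping[str, str] = MappingProxyType({
    "B1": "TPP",
    "B2": "FMN/FAD",
    "B3": "NAD/NADP",
    "B5": "Coenzyme A",
    "B6": "PLP/PMP",
    "B7": "Biotinyl-ACP",
    "B9": "THF/DHF",
    "B12": "(Ado)-Cob",
})

#: Trivial vitamin names, display only.
VITAMIN_NAMES: Mapping[str, str] = MappingProxyType({
    "B1": "Thiamine",
    "B2": "Riboflavin",
    "B3": "Niacin",
    "B5": "Pantothenate",
    "B6": "Pyridoxine",
    "B7": "Biotin",
    "B9": "Folate",
    "B12": "Cobalamin",
})


@dataclass(frozen=True)
class VitaminPanel:
    """Ordered set of vitamin codes plus display-only cofactor labels."""

    vitamins: tuple[str, ...] = DEFAULT_VITAMINS
    cofactors: Mapping[str, str] = field(default_factory=lambda: DEFAULT_COFACTORS)

    def __post_init__(self) -> None:
        if not self.vitamins:
            raise ConfigError("vitamin panel must be non-empty")
        if len(set(self.vitamins)) != len(self.vitamins):
            raise ConfigError(f"duplicate vitamin codes in panel: {self.vitamins}")

    def __len__(self) -> int:
        return len(self.vitamins)

    def __iter__(self):
        return iter(self.vitamins)

    def index(self, code: str) -> int:
        try:
            return self.vitamins.index(code)
        except ValueError:
            raise ConfigError(f"vitamin {code!r} not in panel {self.vitamins}") from None

    def cofactor(self, code: str) -> str:
        return self.cofactors.get(code, "")


DEFAULT_PANEL = VitaminPanel()
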