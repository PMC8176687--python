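"""Inheritance-mode vocabulary for reciprocal-cross expression analysis.

The four genetic groups are two purebreds and their reciprocal F1 crosses,
with the sire's breed listed first:

    1 = Bt x Bt   (purebred taurine, e.g. Angus)
    2 = Bi x Bt   (indicine sire, taurine dam)
    3 = Bt x Bi   (taurine sire, indicine dam)
    4 = Bi x Bi   (purebred indicine, e.g. Brahman)

A gene's inheritance mode describes where the two cross means sit relative
to the purebred means: midway (additive), at the dam's purebred level
(maternally driven), at the sire's level (paternally driven), both at one
breed's level (breed dominance, activation when that breed is the high
expresser), or none of the above (complex).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class InheritanceCategory(str, Enum):
    """Closed set of inheritance-mode labels.

    ``NULL`` is simulation-only (non-differential filler genes); the
    classifier never emits it.  ``UNCLASSIFIED`` marks genes failing the
    minimum purebred-separation guard, not a biological class.
    """

    NULL = "NULL"
    ADDITIVE = "ADDITIVE"
    MATERNAL_TAURINE = "MATERNAL_TAURINE"
    MATERNAL_INDICINE = "MATERNAL_INDICINE"
    PATERNAL_TAURINE = "PATERNAL_TAURINE"
    PATERNAL_INDICINE = "PATERNAL_INDICINE"
    TAURINE_DOMINANT_ACTIVATION = "TAURINE_DOMINANT_ACTIVATION"
    TAURINE_DOMINANT_INHIBITION = "TAURINE_DOMINANT_INHIBITION"
    INDICINE_DOMINANT_ACTIVATION = "INDICINE_DOMINANT_ACTIVATION"
    INDICINE_DOMINANT_INHIBITION = "INDICINE_DOMINANT_INHIBITION"
    COMPLEX = "COMPLEX"
    UNCLASSIFIED = "UNCLASSIFIED"


C = InheritanceCategory

PARENTAL_CATEGORIES = frozenset(
    {C.MATERNAL_TAURINE, C.MATERNAL_INDICINE, C.PATERNAL_TAURINE, C.PATERNAL_INDICINE}
)
DOMINANT_CATEGORIES = frozenset(
    {
        C.TAURINE_DOMINANT_ACTIVATION,
        C.TAURINE_DOMINANT_INHIBITION,
        C.INDICINE_DOMINANT_ACTIVATION,
        C.INDICINE_DOMINANT_INHIBITION,
    }
)
#: The eight parent-of-origin / breed-dominance classes (Table-1 style tally).
POE_CATEGORIES = PARENTAL_CATEGORIES | DOMINANT_CATEGORIES


@dataclass(frozen=True)
class GeneticGroup:
    """One of the four genetic groups; sire breed listed first."""

    code: int
    sire_breed: str
    dam_breed: str

    def __post_init__(self) -> None:
        if self.code not in (1, 2, 3, 4):
            raise ValueError(f"group code must be 1-4, got {self.code}")
        for b in (self.sire_breed, self.dam_breed):
            if b not in ("Bt", "Bi"):
                raise ValueError(f"breed must be 'Bt' or 'Bi', got {b!r}")


#: Fixed group coding: 1=BtxBt, 2=BixBt, 3=BtxBi, 4=BixBi (sire first).
GENETIC_GROUPS: dict[int, GeneticGroup] = {
    1: GeneticGroup(1, "Bt", "Bt"),
    2: GeneticGroup(2, "Bi", "Bt"),
    3: GeneticGroup(3, "Bt", "Bi"),
    4: GeneticGroup(4, "Bi", "Bi"),
}

GROUP_CODES = (1, 2, 3, 4)
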