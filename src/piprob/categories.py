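"""IUIS diagnostic categories used as the prescriptive output of the network.

The International Union of Immunological Societies (IUIS) classifies inborn
errors of immunity into phenotypic tables.  The network collapses them to
seven category nodes: the first two IUIS tables are merged into a single
T-cell/combined node, and the bone-marrow-failure and phenocopy tables are
out of scope.  The enumeration order below is canonical and is used for every
deterministic tie-break in ranking.
"""

from __future__ import annotations

import enum


class IUISCategory(str, enum.Enum):
    """The seven IUIS disorder categories, in canonical tie-break order."""

    T_CID = "T/CID"  # T-cell / combined immunodeficiency (IUIS tables 1-2)
    PAD = "PAD"      # predominantly antibody deficiency
    PIRD = "PIRD"    # immune dysregulation
    PD = "PD"        # phagocyte disorder
    ID = "ID"        # innate immune defect
    AID = "AID"      # autoinflammatory disorder
    CD = "CD"        # complement deficiency

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used for all tie-breaks (ranking, reports).
CANONICAL_ORDER: tuple[IUISCategory, ...] = tuple(IUISCategory)

#: Rank of each category within the canonical order.
CANONICAL_RANK: dict[IUISCategory, int] = {c: i for i, c in enumerate(IUISCategory)}
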