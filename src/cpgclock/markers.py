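"""Registry of the nine blood pyrosequencing CpG markers used by the clocks.

Marker ids follow the pyrosequencing assay order (``ELOVL2_CpG4`` .. ``CpG7``),
never genomic coordinates.  ``expected_sign`` is the direction of the
methylation-vs-age correlation in adult blood; ``drift_flag`` marks the four
CpGs whose between-individual dispersion is known to widen at extreme ages
(epigenetic drift) while the other five stay tight.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CpGMarker:
    """One CpG site quantified as a pyrosequencing methylation percentage."""

    id: str
    gene: str
    expected_sign: int  # +1 methylation rises with age, -1 it falls
    drift_flag: bool

    def __post_init__(self) -> None:
        if self.expected_sign not in (+1, -1):
            raise ValueError(f"expected_sign must be +1 or -1, got {self.expected_sign}")


_MARKERS = (
    CpGMarker("ASPA_CpG1", "ASPA", -1, True),
    CpGMarker("EDARADD_CpG1", "EDARADD", -1, False),
    CpGMarker("ELOVL2_CpG4", "ELOVL2", +1, False),
    CpGMarker("ELOVL2_CpG5", "ELOVL2", +1, False),
    CpGMarker("ELOVL2_CpG6", "ELOVL2", +1, False),
    CpGMarker("ELOVL2_CpG7", "ELOVL2", +1, False),
    CpGMarker("KLF14_CpG2", "KLF14", +1, True),
    CpGMarker("PDE4C_CpG1", "PDE4C", +1, True),
    CpGMarker("TRIM59_CpG5", "TRIM59", +1, True),
)

#: id -> CpGMarker for the nine built-in markers.
MARKER_REGISTRY: dict[str, CpGMarker] = {m.id: m for m in _MARKERS}

#: Marker ids in canonical (registry) order.
MARKER_IDS: tuple[str, ...] = tuple(MARKER_REGISTRY)

#: The four CpGs subject to epigenetic drift at extreme ages.
DRIFT_MARKERS: tuple[str, ...] = tuple(m.id for m in _MARKERS if m.drift_flag)

#: The five drift-resistant CpGs.
NON_DRIFT_MARKERS: tuple[str, ...] = tuple(m.id for m in _MARKERS if not m.drift_flag)


def get_marker(marker_id: str) -> CpGMarker:
    """Look up a built-in marker, raising ``KeyError`` with a helpful message."""
    try:
        return MARKER_REGISTRY[marker_id]
    except KeyError:
        raise KeyError(
            f"unknown CpG marker {marker_id!r}; known markers: {', '.join(MARKER_IDS)}"
        ) from None
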