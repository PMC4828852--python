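"""Left-ventricular segment schema and coronary territory assignment.

Quantitative speckle-tracking parameters are measured in the 12 segments
visible from the apical 4- and 2-chamber views (basal/mid/apical levels of
the septal, lateral, inferior and anterior walls).  Each segment is
assigned to the coronary artery that conventionally perfuses it (LAD, LCX
or RCA), following the standard ASE territory chart; the map can be
overridden where an individual lab uses a different convention.
"""

from __future__ import annotations

from typing import Mapping

#: The 12 apical-view segments: 6 from the 4-chamber view (septal +
#: lateral walls) and 6 from the 2-chamber view (inferior + anterior).
SEGMENTS: tuple[str, ...] = (
    "basal septal",
    "mid septal",
    "apical septal",
    "basal lateral",
    "mid lateral",
    "apical lateral",
    "basal inferior",
    "mid inferior",
    "apical inferior",
    "basal anterior",
    "mid anterior",
    "apical anterior",
)

VESSELS: tuple[str, ...] = ("LAD", "LCX", "RCA")

#: Conventional ASE territory assignment.  The apical cap and anterior wall
#: belong to the LAD, the lateral wall to the LCX, and the inferior wall
#: plus basal septum to the RCA.
DEFAULT_TERRITORY: Mapping[str, str] = {
    "basal anterior": "LAD",
    "mid anterior": "LAD",
    "apical anterior": "LAD",
    "mid septal": "LAD",
    "apical septal": "LAD",
    "apical lateral": "LAD",
    "basal lateral": "LCX",
    "mid lateral": "LCX",
    "basal septal": "RCA",
    "basal inferior": "RCA",
    "mid inferior": "RCA",
    "apical inferior": "RCA",
}


def territory_of(segment: str, territory_map: Mapping[str, str] | None = None) -> str:
    """Return the coronary vessel (LAD/LCX/RCA) perfusing ``segment``.

    Parameters
    ----------
    segment
        One of the 12 apical-view segment names in :data:`SEGMENTS`.
    territory_map
        Optional override of the default ASE assignment; must cover every
        segment it is queried for and map onto :data:`VESSELS`.

    Raises
    ------
    KeyError
        If the segment name is not part of the 12-segment schema.
    """
    tmap = DEFAULT_TERRITORY if territory_map is None else territory_map
    if segment not in SEGMENTS:
        raise KeyError(f"unknown segment name: {segment!r}")
    vessel = tmap[segment]
    if vessel not in VESSELS:
        raise ValueError(f"territory map assigns {segment!r} to unknown vessel {vessel!r}")
    return vessel


def segments_of(vessel: str, territory_map: Mapping[str, str] | None = None) -> tuple[str, ...]:
    """Inverse of :func:`territory_of`: all segments in a vessel's territory."""
    if vessel not in VESSELS:
        raise KeyError(f"unknown vessel: {vessel!r}")
    tmap = DEFAULT_TERRITORY if territory_map is None else territory_map
    return tuple(s for s in SEGMENTS if tmap[s] == vessel)
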