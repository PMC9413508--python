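"""Site-marker competitive displacement analysis.

Serum albumin carries two principal drug pockets (Sudlow sites I and II,
probed by warfarin and ibuprofen respectively).  Titrating a pre-formed
drug–protein solution with a site marker and following the fluorescence
ratio

    I(%) = 100 * F2 / F1

(F1 = intensity without marker, F2 = with marker) reveals competition: a
marker sharing the drug's pocket displaces it and I drops markedly, while a
marker for the other pocket leaves I near 100.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np

from .errors import InvalidInputError


class Site(str, enum.Enum):
    SITE_I = "site_I"
    SITE_II = "site_II"


class SiteAssignment(str, enum.Enum):
    SITE_I = "site_I"
    SITE_II = "site_II"
    BOTH = "both"
    INDETERMINATE = "indeterminate"


#: Built-in marker -> Sudlow site registry (keys lower-case).
MARKER_SITES: Dict[str, Site] = {
    "warfarin": Site.SITE_I,
    "wf-na": Site.SITE_I,
    "warfarin sodium": Site.SITE_I,
    "ibuprofen": Site.SITE_II,
    "ib": Site.SITE_II,
}

#: Default competition criterion: drop in I at the top marker concentration,
#: in percentage points.
DEFAULT_DROP_THRESHOLD = 20.0


def marker_site(name: str, registry: Mapping[str, Site] = MARKER_SITES) -> Site:
    try:
        return registry[name.strip().lower()]
    except KeyError:
        raise InvalidInputError(f"unknown site marker {name!r}; extend the registry") from None


@dataclass(frozen=True)
class DisplacementSeries:
    """Marker titration of a drug–protein solution; first concentration is 0."""

    marker_name: str
    marker_site: Site
    marker_concs: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.marker_concs, dtype=float)
        f = np.asarray(self.intensities, dtype=float)
        if c.ndim != 1 or c.shape != f.shape or c.size == 0:
            raise InvalidInputError("marker_concs and intensities must be 1-D, equal length")
        if c[0] != 0.0:
            raise InvalidInputError("the first marker concentration must be 0 (defines F1)")
        if c.size >= 2 and not np.all(np.diff(c) > 0):
            raise InvalidInputError("marker concentrations must be strictly increasing")
        object.__setattr__(self, "marker_concs", c)
        object.__setattr__(self, "intensities", f)


def displacement_index(series: DisplacementSeries) -> np.ndarray:
    """Displacement percentages I_j = 100 * F2_j / F1 (I_0 = 100 by construction)."""
    f1 = float(series.intensities[0])
    if f1 <= 0:
        raise InvalidInputError("F1 (intensity at zero marker) must be positive")
    return 100.0 * series.intensities / f1


@dataclass(frozen=True)
class SiteEvidence:
    marker_name: str
    site: Site
    drop_points: float  # percentage-point drop of I at the top marker concentration
    competes: bool


def assign_site(
    series_by_marker: Mapping[str, DisplacementSeries],
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> Tuple[SiteAssignment, Tuple[SiteEvidence, ...]]:
    """Assign the drug's binding site from marker competition.

    A marker competes when I at its highest concentration has fallen by more
    than ``drop_threshold`` percentage points below the marker-free value of
    100.  The assignment is the site of the competing marker(s).
    """
    if not series_by_marker:
        raise InvalidInputError("no displacement series given")
    evidence = []
    competing_sites = set()
    for name, series in series_by_marker.items():
        idx = displacement_index(series)
        drop = 100.0 - float(idx[-1])
        competes = drop > drop_threshold
        evidence.append(SiteEvidence(name, series.marker_site, drop, competes))
        if competes:
            competing_sites.add(series.marker_site)
    if not competing_sites:
        label = SiteAssignment.INDETERMINATE
    elif competing_sites == {Site.SITE_I}:
        label = SiteAssignment.SITE_I
    elif competing_sites == {Site.SITE_II}:
        label = SiteAssignment.SITE_II
    else:
        label = SiteAssignment.BOTH
    return label, tuple(evidence)
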