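"""Core data model for plates of multi-channel fluorescence site images.

A *site* is one field of view acquired from a well; a *plate* holds one
culture's treatment groups.  The statistical unit of the study is the culture
(one plate == one culture, n = 1); sites are technical replicates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

PRIMARY_MARKERS = ("drebrin", "glut4", "vglut1", "synapsin1", "calcein")

#: final bath concentrations of the IRAP inhibitor, mol/L (vehicle = 0.1% DMSO)
ALLOWED_CONCENTRATIONS = (1e-9, 1e-8, 1e-7, 1e-6, 1e-5)
VEHICLE_LABEL = "vehicle"

MAX_GREY = 65535  # 16-bit camera range


class ChannelMismatchError(ValueError):
    """Image holds fewer channels than the channel map requires."""


class BitDepthError(ValueError):
    """Image is not 16-bit and the caller did not allow conversion."""


class PlacementError(RuntimeError):
    """Synthetic cells could not be placed at the required separation."""


class DegenerateDataError(ValueError):
    """Statistical input with no usable variance / replication."""


@dataclass(frozen=True)
class ChannelMap:
    """Role -> channel-index mapping for one staining round.

    ``nuclei`` (DAPI) is always present.  ``primary_marker`` is the
    Alexa-488-type channel and carries one of drebrin, GLUT4, vGluT1,
    synapsin I or calcein.  ``map2`` and ``gfap`` are optional because the
    calcein / synaptic-marker rounds image only DAPI plus the marker.
    """

    nuclei: int
    primary_marker: int
    primary_marker_name: str
    map2: int | None = None
    gfap: int | None = None

    def __post_init__(self) -> None:
        if self.primary_marker_name not in PRIMARY_MARKERS:
            raise ValueError(
                f"unknown primary marker {self.primary_marker_name!r}; "
                f"expected one of {PRIMARY_MARKERS}"
            )
        idx = list(self.roles.values())
        if any(i < 0 for i in idx):
            raise ValueError("channel indices must be non-negative")
        if len(set(idx)) != len(idx):
            raise ValueError("every role must map to a distinct channel index")

    @property
    def roles(self) -> dict[str, int]:
        r = {"nuclei": self.nuclei, "primary_marker": self.primary_marker}
        if self.map2 is not None:
            r["map2"] = self.map2
        if self.gfap is not None:
            r["gfap"] = self.gfap
        return r

    def index(self, role: str) -> int:
        try:
            return self.roles[role]
        except KeyError:
            raise KeyError(f"role {role!r} is not mapped") from None

    def has(self, role: str) -> bool:
        return role in self.roles

    @property
    def n_channels(self) -> int:
        return max(self.roles.values()) + 1

    def to_dict(self) -> dict[str, object]:
        return {
            "nuclei": self.nuclei,
            "primary_marker": self.primary_marker,
            "primary_marker_name": self.primary_marker_name,
            "map2": self.map2,
            "gfap": self.gfap,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "ChannelMap":
        def _idx(v):
            return None if v in (None, "", "None") else int(v)  # type: ignore[arg-type]

        return cls(
            nuclei=int(d["nuclei"]),  # type: ignore[arg-type]
            primary_marker=int(d["primary_marker"]),  # type: ignore[arg-type]
            primary_marker_name=str(d["primary_marker_name"]),
            map2=_idx(d.get("map2")),
            gfap=_idx(d.get("gfap")),
        )


def default_channel_map(marker: str = "drebrin") -> ChannelMap:
    """Four-channel map (DAPI, marker, MAP2, GFAP) or two-channel for the
    DAPI-plus-marker rounds (vGluT1, synapsin I, calcein)."""
    if marker in ("vglut1", "synapsin1", "calcein"):
        return ChannelMap(nuclei=0, primary_marker=1, primary_marker_name=marker)
    return ChannelMap(nuclei=0, primary_marker=1, primary_marker_name=marker,
                      map2=2, gfap=3)


@dataclass(frozen=True)
class TreatmentGroup:
    label: str
    concentration: float | None  # mol/L; None == vehicle (0.1% DMSO)

    def __post_init__(self) -> None:
        if self.concentration is None:
            return
        if not any(np.isclose(self.concentration, c, rtol=1e-6)
                   for c in ALLOWED_CONCENTRATIONS):
            raise ValueError(
                f"concentration {self.concentration!r} not in dosing set "
                f"{ALLOWED_CONCENTRATIONS} (or None for vehicle)"
            )

    @property
    def is_vehicle(self) -> bool:
        return self.concentration is None


def standard_groups() -> tuple[TreatmentGroup, ...]:
    """Vehicle plus the five-point concentration series of the dosing design."""
    groups = [TreatmentGroup(VEHICLE_LABEL, None)]
    for c in ALLOWED_CONCENTRATIONS:
        groups.append(TreatmentGroup(f"{c:.0e}", c))
    return tuple(groups)


@dataclass(frozen=True)
class PlateLayout:
    """One culture's plate: treatment groups x wells x imaging sites.

    Defaults follow the acquisition design: 9 sites per well, three wells per
    treatment group, i.e. 27 sites per group per culture.
    """

    culture_id: str
    region: str  # "hippocampal" | "cortical"
    groups: tuple[TreatmentGroup, ...] = field(default_factory=standard_groups)
    wells_per_group: int = 3
    sites_per_well: int = 9

    def __post_init__(self) -> None:
        if self.region not in ("hippocampal", "cortical"):
            raise ValueError("region must be 'hippocampal' or 'cortical'")
        if self.wells_per_group < 1 or self.sites_per_well < 1:
            raise ValueError("wells_per_group and sites_per_well must be >= 1")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")

    @property
    def sites_per_group(self) -> int:
        return self.wells_per_group * self.sites_per_well

    @property
    def n_sites(self) -> int:
        return len(self.groups) * self.sites_per_group

    def iter_sites(self) -> Iterator[tuple[TreatmentGroup, int, int]]:
        """Yield (group, well, site) in a fixed deterministic order."""
        for g in self.groups:
            for w in range(self.wells_per_group):
                for s in range(self.sites_per_well):
                    yield g, w, s


@dataclass(frozen=True)
class SiteIds:
    culture: str
    group: str
    well: int
    site: int


@dataclass
class SiteImage:
    """One site's multi-channel 16-bit raster plus identity and QC state.

    ``pixels`` has shape (channel, height, width), dtype uint16, and is never
    rescaled by the package: all intensities are raw camera grey levels.
    """

    pixels: np.ndarray
    channel_map: ChannelMap
    ids: SiteIds
    qc_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (channel, height, width)")
        if self.pixels.dtype != np.uint16:
            raise BitDepthError(f"expected uint16 pixels, got {self.pixels.dtype}")
        if self.pixels.shape[1] < 1 or self.pixels.shape[2] < 1:
            raise ValueError("height and width must be positive")
        if self.pixels.shape[0] < self.channel_map.n_channels:
            raise ChannelMismatchError(
                f"image has {self.pixels.shape[0]} channels but the map needs "
                f"{self.channel_map.n_channels}"
            )
        self.qc_flags = frozenset(self.qc_flags)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, role: str) -> np.ndarray:
        """2-D view of the channel carrying ``role``."""
        return self.pixels[self.channel_map.index(role)]

    def with_flags(self, flags: set[str] | frozenset[str]) -> "SiteImage":
        return SiteImage(self.pixels, self.channel_map, self.ids,
                         frozenset(self.qc_flags) | frozenset(flags))
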