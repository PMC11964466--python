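"""Domain types: site records, study configuration and phase/dataset selection.

Coordinates are always metres in a single equal-area projection (default
intent: a Lambert azimuthal equal-area centred on Europe) so that every
derived quantity is a true area in km². The CRS is carried as an opaque
identifier in :class:`StudyConfig`; no reprojection happens in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from shapely.geometry.base import BaseGeometry

#: The five chronological attribution flags used by the study design.
#: GI1DA / GS1 are the two phases proper; FP_GENERIC and FP_PB_GENERIC are
#: generic Final-Palaeolithic (and Final-Palaeolithic-to-Preboreal) time-bins;
#: GS1_PB covers assemblages straddling the end of GS-1 and the Preboreal.
ATTRIBUTION_FLAGS = ("GI1DA", "GS1", "FP_GENERIC", "FP_PB_GENERIC", "GS1_PB")

EVIDENCE_CLASSES = ("excavation", "surface")


class Phase(str, Enum):
    GI1DA = "GI1DA"
    GS1 = "GS1"


class Dataset(str, Enum):
    #: all sites, including generically attributed time-bins
    A = "A"
    #: only assemblages with a clear phase subdivision
    B = "B"


@dataclass(frozen=True)
class PhaseDataset:
    """A phase/dataset selection, e.g. (GI1DA, A)."""

    phase: Phase
    dataset: Dataset

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "dataset", Dataset(self.dataset))


@dataclass(frozen=True)
class SiteRecord:
    """One assemblage: projected coordinates plus chronological attribution.

    ``attributions`` is a frozenset drawn from :data:`ATTRIBUTION_FLAGS` and
    must be non-empty; a site attributed to both phases carries both flags and
    is counted once per phase selection.
    """

    id: str
    x: float
    y: float
    region: str
    attributions: frozenset[str]
    evidence: str = "excavation"

    def __post_init__(self) -> None:
        attrs = frozenset(self.attributions)
        if not attrs:
            raise ValueError(f"record {self.id!r}: attributions must be non-empty")
        bad = attrs - set(ATTRIBUTION_FLAGS)
        if bad:
            raise ValueError(f"record {self.id!r}: unknown attribution flags {sorted(bad)}")
        if self.evidence not in EVIDENCE_CLASSES:
            raise ValueError(f"record {self.id!r}: unknown evidence class {self.evidence!r}")
        object.__setattr__(self, "attributions", attrs)


@dataclass
class StudyConfig:
    """Study-window geometry, region partitions and protocol constants.

    ``calibration_regions`` are the (few, large) zones within which the
    optimally describing isoline is modelled independently; the study used
    three. ``estimate_regions`` are the named rows of the estimate tables.
    ``rmca_blocks`` groups estimate regions that share one raw-material
    quartile set (adjacency transfer).
    """

    window: BaseGeometry
    calibration_regions: Mapping[str, BaseGeometry] = field(default_factory=dict)
    estimate_regions: Mapping[str, BaseGeometry] = field(default_factory=dict)
    rmca_blocks: Mapping[str, Sequence[str]] = field(default_factory=dict)
    group_size: float = 42.5
    tac_area_km2: float = 2_600_000.0
    crs: str = "custom-equal-area"

    def __post_init__(self) -> None:
        if self.group_size <= 0:
            raise ValueError("group_size must be positive")
        seen: dict[str, str] = {}
        for block, regions in self.rmca_blocks.items():
            for r in regions:
                if r in seen:
                    raise ValueError(
                        f"estimate region {r!r} assigned to blocks {seen[r]!r} and {block!r}"
                    )
                seen[r] = block


def select_dataset(
    records: Iterable[SiteRecord], sel: PhaseDataset | tuple[str, str]
) -> list[SiteRecord]:
    """Select the records contributing to one phase under dataset A or B.

    Dataset B keeps records whose attributions include the phase flag itself
    (records flagged for both phases appear in both phase selections).
    Dataset A additionally keeps the generic time-bins: FP_GENERIC and
    FP_PB_GENERIC for either phase, and GS1_PB for GS-1 only.
    """
    if not isinstance(sel, PhaseDataset):
        sel = PhaseDataset(*sel)
    wanted = {sel.phase.value}
    if sel.dataset is Dataset.A:
        wanted |= {"FP_GENERIC", "FP_PB_GENERIC"}
        if sel.phase is Phase.GS1:
            wanted.add("GS1_PB")
    return [r for r in records if r.attributions & wanted]
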