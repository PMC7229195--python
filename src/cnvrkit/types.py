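"""Core domain types shared by all pipeline stages.

Coordinate convention: every interval in memory is 1-based and inclusive
on both ends (the convention both caller dialects print).  Only the BED
writer/reader in :mod:`cnvrkit.io_formats` converts to and from 0-based
half-open coordinates.

Chromosome labels are plain strings with any leading ``"chr"`` prefix
stripped at ingestion; autosomes of the bovine assembly are ``"1"``
through ``"29"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Autosome labels of the working (bovine) assembly.
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 30))


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and surrounding whitespace."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def chrom_sort_key(chrom: str):
    """Sort numeric chromosome names numerically, others lexically after."""
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


class Source(str, Enum):
    """Data source of a CNV call: genotyping array or whole-genome sequence."""

    GEN = "GEN"
    WGS = "WGS"


class Event(str, Enum):
    """Copy-number event direction."""

    LOSS = "loss"
    GAIN = "gain"


class RegionType(str, Enum):
    """Region event type: all-loss (CNL), all-gain (CNG), or both (MIX)."""

    CNL = "CNL"
    CNG = "CNG"
    MIX = "MIX"


class SourceSet(str, Enum):
    """Provenance of a collated region."""

    GEN_CNVR = "GEN_CNVR"
    WGS_CNVR = "WGS_CNVR"
    ANIMAL_CNVR = "ANIMAL_CNVR"
    POPULATION_CNVR = "POPULATION_CNVR"
    UNIQUE_HC = "UNIQUE_HC"


def region_type(events: Iterable[Event]) -> RegionType:
    """CNL if every event is a loss, CNG if every event is a gain, MIX otherwise."""
    seen = {Event(e) for e in events}
    if not seen:
        raise ValueError("cannot type a region with no member events")
    if seen == {Event.LOSS}:
        return RegionType.CNL
    if seen == {Event.GAIN}:
        return RegionType.CNG
    return RegionType.MIX


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        """Number of bases covered: end - start + 1."""
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared bases with *other*; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval containing both (same chromosome required)."""
        if self.chrom != other.chrom:
            raise ValueError("union span requires the same chromosome")
        return GenomicInterval(self.chrom, min(self.start, other.start), max(self.end, other.end))


@dataclass(frozen=True)
class CNVCall:
    """One caller-emitted variant in one sample.

    GEN (array) calls carry ``n_markers``; WGS (read-depth) calls carry
    ``rd_pvalue`` (significance of the region's mean read depth against
    the sample average) and ``q0`` (fraction of reads with mapping
    quality zero).  ``copy_number`` is an integer copy state for GEN
    calls and a normalized read-depth ratio for WGS calls.
    """

    interval: GenomicInterval
    sample_id: str
    source: Source
    event: Event
    copy_number: float
    n_markers: Optional[int] = None
    rd_pvalue: Optional[float] = None
    q0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source == Source.GEN:
            if self.n_markers is None or self.n_markers < 1:
                raise ValueError("GEN calls require n_markers >= 1")
        else:
            if self.rd_pvalue is None or self.q0 is None:
                raise ValueError("WGS calls require rd_pvalue and q0")
            if not (0.0 <= self.rd_pvalue <= 1.0):
                raise ValueError(f"rd_pvalue outside [0,1]: {self.rd_pvalue}")
            if not (0.0 <= self.q0 <= 1.0):
                raise ValueError(f"q0 outside [0,1]: {self.q0}")

    @property
    def length(self) -> int:
        return self.interval.length


def event_from_copy_number(copy_number: float, source: Source) -> Event:
    """Loss iff copy state < 2 (GEN) or read-depth ratio < 1 (WGS)."""
    neutral = 2.0 if source == Source.GEN else 1.0
    return Event.LOSS if copy_number < neutral else Event.GAIN


@dataclass(frozen=True)
class SampleQC:
    """Per-sample array quality summary gating sample inclusion."""

    sample_id: str
    panel: str
    lrr_sd: float
    baf_drift: float
    wave_factor: float

    def __post_init__(self) -> None:
        if self.lrr_sd < 0 or self.baf_drift < 0:
            raise ValueError("lrr_sd and baf_drift must be non-negative")


@dataclass(frozen=True)
class KnownRegion:
    """A previously published CNVR, already on the working assembly."""

    interval: GenomicInterval
    event: str  # "loss" | "gain" | "mixed" | "unknown"
    study_label: str


@dataclass(frozen=True)
class CNVRegion:
    """A collated region with event type, carriers, and provenance.

    ``origins`` records which high-confidence sets contributed when
    regions from several sets are merged (unique-region building).
    """

    interval: GenomicInterval
    rtype: RegionType
    samples: frozenset
    source_set: SourceSet
    member_calls: tuple = ()
    origins: frozenset = frozenset()

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class FilterReport:
    """Input/output accounting of one filtering operation.

    Invariant: ``n_input == n_passed + sum(removals.values())`` — every
    removed record is counted under exactly one rule (the first violated
    rule in the operation's documented order).
    """

    n_input: int
    n_passed: int
    removals: dict

    def __post_init__(self) -> None:
        if self.n_input != self.n_passed + sum(self.removals.values()):
            raise ValueError("FilterReport does not conserve records")


class MarkerPanel:
    """Ordered marker map of one array density.

    Holds a table with columns ``name``, ``chrom``, ``pos`` sorted by
    (chromosome, position); marker names are unique.
    """

    def __init__(self, name: str, table: pd.DataFrame):
        table = table.loc[:, ["name", "chrom", "pos"]].copy()
        table["chrom"] = table["chrom"].map(normalize_chrom)
        table["pos"] = table["pos"].astype(np.int64)
        dup = table["name"][table["name"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate marker names: {sorted(set(dup))[:10]}")
        table["_key"] = table["chrom"].map(chrom_sort_key)
        table = table.sort_values(["_key", "pos"], kind="mergesort").drop(columns="_key")
        self.name = name
        self.table = table.reset_index(drop=True)
        self._by_chrom: dict[str, np.ndarray] = {
            c: g["pos"].to_numpy() for c, g in self.table.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.table)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted marker positions on *chrom* (empty array if none)."""
        return self._by_chrom.get(normalize_chrom(chrom), np.empty(0, dtype=np.int64))

    def count_in(self, interval: GenomicInterval) -> int:
        """Number of panel markers inside *interval* (inclusive)."""
        pos = self.positions(interval.chrom)
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="right")
        return int(hi - lo)

    def span_within(self, interval: GenomicInterval) -> Optional[tuple[int, int, int]]:
        """(first_pos, last_pos, n_markers) of markers inside *interval*, or None."""
        pos = self.positions(interval.chrom)
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="right")
        if hi <= lo:
            return None
        return int(pos[lo]), int(pos[hi - 1]), int(hi - lo)

    def subset_names(self, names: Iterable[str], name: Optional[str] = None) -> "MarkerPanel":
        """Panel restricted to the given marker names (positions kept)."""
        keep = self.table[self.table["name"].isin(set(names))]
        return MarkerPanel(name or self.name, keep)

    @property
    def marker_names(self) -> set:
        return set(self.table["name"])


#: Minimum markers an array call must span, by panel (HD arrays are denser,
#: so short spurious runs are cheap there and the bar is higher).
MIN_MARKERS_BY_PANEL: Mapping[str, int] = {"HD": 10}
DEFAULT_MIN_MARKERS = 3


def min_markers_for_panel(panel: str) -> int:
    return MIN_MARKERS_BY_PANEL.get(panel, DEFAULT_MIN_MARKERS)
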