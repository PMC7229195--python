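"""Comparison of a high-confidence region set against published catalogues.

Two regions are considered equal when they reciprocally overlap over at
least 50% of each of their lengths (the same rule the consensus
pipelines use).  Published catalogues are filtered to regions shorter
than 5 Mb and, where per-region frequencies are available, carried by
at least 5% of the source study's samples (non-strict, unlike the
population pipeline's strict floor), then collated so overlapping
records from several studies count once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .consensus import reciprocal_overlap
from .io_formats import PathLike, read_known_table
from .types import CNVRegion, Event, GenomicInterval, KnownRegion, RegionType, chrom_sort_key

_KNOWN_EVENTS = {"loss", "gain", "mixed", "unknown"}

#: Region type <-> catalogue event compatibility used by require_type.
_TYPE_COMPAT = {
    RegionType.CNL: {"loss", "mixed", "unknown"},
    RegionType.CNG: {"gain", "mixed", "unknown"},
    RegionType.MIX: {"mixed", "loss", "gain", "unknown"},
}


@dataclass
class ComparisonResult:
    """Counts and the list of qualifying (query, known) matches."""

    n_query: int
    n_matched: int
    n_novel: int
    matches: list  # (query CNVRegion, KnownRegion, frac_query, frac_known)

    def __post_init__(self) -> None:
        if self.n_matched + self.n_novel != self.n_query:
            raise ValueError("matched + novel must equal the query count")


def _normalize_event(value: str) -> str:
    value = str(value).strip().lower()
    aliases = {
        "cnl": "loss",
        "deletion": "loss",
        "del": "loss",
        "loss": "loss",
        "cng": "gain",
        "duplication": "gain",
        "dup": "gain",
        "gain": "gain",
        "mix": "mixed",
        "mixed": "mixed",
        "both": "mixed",
    }
    return aliases.get(value, "unknown")


def load_known(
    paths: Union[PathLike, Sequence[PathLike]],
    max_len: int = 5_000_000,
    min_freq: float = 0.05,
) -> list[KnownRegion]:
    """Load, filter and merge published CNVR tables.

    Regions of ``max_len`` or longer are excluded (strictly "shorter
    than 5 Mb"); rows with a frequency column are kept when frequency
    >= ``min_freq``; rows without one are kept.  Overlapping or adjacent
    records are merged, with study labels and event types unioned.
    """
    if isinstance(paths, (str, bytes)) or not isinstance(paths, Sequence):
        paths = [paths]
    frames = [read_known_table(p) for p in paths]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    records: list[KnownRegion] = []
    for row in table.itertuples():
        length = int(row.end) - int(row.start) + 1
        if length >= max_len:
            continue
        if pd.notna(row.frequency) and float(row.frequency) < min_freq:
            continue
        records.append(
            KnownRegion(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                event=_normalize_event(row.type),
                study_label=str(row.study),
            )
        )
    return _merge_known(records)


def _merge_known(records: Sequence[KnownRegion]) -> list[KnownRegion]:
    by_chrom: dict[str, list[KnownRegion]] = {}
    for r in records:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    merged: list[KnownRegion] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        group = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        cur = [group[0]]
        cur_end = group[0].interval.end
        for r in group[1:]:
            if r.interval.start <= cur_end + 1:
                cur.append(r)
                cur_end = max(cur_end, r.interval.end)
            else:
                merged.append(_merge_known_group(cur))
                cur = [r]
                cur_end = r.interval.end
        merged.append(_merge_known_group(cur))
    return merged


def _merge_known_group(group: Sequence[KnownRegion]) -> KnownRegion:
    interval = GenomicInterval(
        group[0].interval.chrom,
        min(r.interval.start for r in group),
        max(r.interval.end for r in group),
    )
    events = {r.event for r in group} - {"unknown"}
    if not events:
        event = "unknown"
    elif events <= {"loss"}:
        event = "loss"
    elif events <= {"gain"}:
        event = "gain"
    else:
        event = "mixed"
    studies = sorted({s for r in group for s in r.study_label.split(";")})
    return KnownRegion(interval=interval, event=event, study_label=";".join(studies))


def compare(
    query: Sequence[CNVRegion],
    known: Sequence[KnownRegion],
    threshold: float = 0.5,
    require_type: bool = False,
) -> ComparisonResult:
    """Match query regions against the known set at a reciprocal threshold.

    A query region is *matched* when at least one known region
    reciprocally overlaps it at >= ``threshold``; otherwise it is
    *novel*.  All qualifying matches are listed.  With ``require_type``
    the known region's event must also be compatible with the query's
    region type.
    """
    known_by_chrom: dict[str, list[KnownRegion]] = {}
    for k in known:
        known_by_chrom.setdefault(k.interval.chrom, []).append(k)
    for chrom in known_by_chrom:
        known_by_chrom[chrom].sort(key=lambda k: k.interval.start)

    matches = []
    n_matched = 0
    for q in query:
        hit = False
        for k in known_by_chrom.get(q.interval.chrom, ()):
            if k.interval.start > q.interval.end:
                break
            fq, fk = reciprocal_overlap(q.interval, k.interval)
            if min(fq, fk) < threshold:
                continue
            if require_type and k.event not in _TYPE_COMPAT[q.rtype]:
                continue
            matches.append((q, k, fq, fk))
            hit = True
        n_matched += hit
    return ComparisonResult(
        n_query=len(query),
        n_matched=n_matched,
        n_novel=len(query) - n_matched,
        matches=matches,
    )
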