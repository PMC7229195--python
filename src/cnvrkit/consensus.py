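"""High-confidence CNVR construction by array/sequence consensus.

Two pipelines produce high-confidence region sets from filtered call
sets:

* **animal pipeline** — within each sample, every (array call,
  read-depth call) pair with reciprocal overlap >= the threshold and a
  concordant event direction becomes one high-confidence CNV (the union
  span of the pair); these are then collated across samples into
  ANIMAL_CNVR.
* **population pipeline** — calls of each source are first collated
  across all samples into GEN_CNVR and WGS_CNVR; cross-source region
  pairs with reciprocal overlap >= the threshold whose combined carrier
  set exceeds the population frequency floor (strictly more than 5% of
  QC-passing samples by default) are merged into POPULATION_CNVR.

Collation merges same-chromosome intervals that overlap by >= 1 bp or
are within ``contiguity_gap`` bases of each other (default 0: directly
adjacent intervals merge), taking the transitive closure.  A region is
typed CNL when all member events are losses, CNG when all are gains,
and MIX otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CNVCall,
    CNVRegion,
    Event,
    GenomicInterval,
    RegionType,
    SourceSet,
    chrom_sort_key,
    region_type,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds of both consensus pipelines.

    ``reciprocal_min`` is applied symmetrically (both fractions must
    reach it).  ``population_min_freq`` is a strict floor by default
    ("more than 5% of the samples"); set ``strict=False`` for an
    inclusive one.  ``contiguity_gap`` is the largest gap (bp) between
    calls still collated into one region; 0 merges only overlapping or
    directly adjacent calls.
    """

    reciprocal_min: float = 0.5
    population_min_freq: float = 0.05
    strict: bool = True
    contiguity_gap: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.reciprocal_min <= 1.0):
            raise ValueError("reciprocal_min must be in (0, 1]")
        if self.contiguity_gap < 0:
            raise ValueError("contiguity_gap must be >= 0")


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap of *a* and *b* as a fraction of each interval's own length."""
    shared = a.overlap_bp(b)
    return shared / a.length, shared / b.length


def passes_reciprocal(a: GenomicInterval, b: GenomicInterval, threshold: float) -> bool:
    """True when both reciprocal fractions reach *threshold*."""
    fa, fb = reciprocal_overlap(a, b)
    return min(fa, fb) >= threshold


def collate_regions(
    calls: Sequence[CNVCall],
    contiguity_gap: int = 0,
    source_set: SourceSet = SourceSet.GEN_CNVR,
) -> list[CNVRegion]:
    """Collate calls into regions: transitive closure of
    "overlap >= 1 bp OR gap <= contiguity_gap" per chromosome.

    The output is sorted by (chromosome, start), pairwise non-mergeable,
    and independent of the input order.
    """
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    regions: list[CNVRegion] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        group = sorted(by_chrom[chrom], key=lambda c: (c.interval.start, c.interval.end))
        cur: list[CNVCall] = [group[0]]
        cur_end = group[0].interval.end
        for c in group[1:]:
            if c.interval.start <= cur_end + 1 + contiguity_gap:
                cur.append(c)
                cur_end = max(cur_end, c.interval.end)
            else:
                regions.append(_region_from_calls(cur, source_set))
                cur = [c]
                cur_end = c.interval.end
        regions.append(_region_from_calls(cur, source_set))
    return regions


def _region_from_calls(calls: Sequence[CNVCall], source_set: SourceSet) -> CNVRegion:
    chrom = calls[0].interval.chrom
    interval = GenomicInterval(
        chrom, min(c.interval.start for c in calls), max(c.interval.end for c in calls)
    )
    return CNVRegion(
        interval=interval,
        rtype=region_type(c.event for c in calls),
        samples=frozenset(c.sample_id for c in calls),
        source_set=source_set,
        member_calls=tuple(calls),
    )


def merge_regions(
    regions: Sequence[CNVRegion],
    source_set: SourceSet,
    contiguity_gap: int = 0,
    overlap_only: bool = False,
) -> list[CNVRegion]:
    """Merge region-like records under the collation relation.

    With ``overlap_only`` the merge requires a shared base (>= 1 bp);
    otherwise adjacency within ``contiguity_gap`` also merges.  Carrier
    sets, member calls and origins are unioned.
    """
    by_chrom: dict[str, list[CNVRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    slack = 0 if overlap_only else 1 + contiguity_gap
    out: list[CNVRegion] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        group = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        cur = [group[0]]
        cur_end = group[0].interval.end
        for r in group[1:]:
            if r.interval.start <= cur_end + slack:
                cur.append(r)
                cur_end = max(cur_end, r.interval.end)
            else:
                out.append(_merge_region_group(cur, source_set))
                cur = [r]
                cur_end = r.interval.end
        out.append(_merge_region_group(cur, source_set))
    return out


def _merge_region_group(group: Sequence[CNVRegion], source_set: SourceSet) -> CNVRegion:
    interval = GenomicInterval(
        group[0].interval.chrom,
        min(r.interval.start for r in group),
        max(r.interval.end for r in group),
    )
    members: list = []
    samples: set = set()
    origins: set = set()
    for r in group:
        members.extend(r.member_calls)
        samples |= r.samples
        origins |= set(r.origins) or {r.source_set.value}
    rtype = (
        region_type(c.event for c in members)
        if members
        else (group[0].rtype if len({r.rtype for r in group}) == 1 else RegionType.MIX)
    )
    return CNVRegion(
        interval=interval,
        rtype=rtype,
        samples=frozenset(samples),
        source_set=source_set,
        member_calls=tuple(members),
        origins=frozenset(origins),
    )


def animal_high_confidence_calls(
    gen_calls: Sequence[CNVCall],
    wgs_calls: Sequence[CNVCall],
    reciprocal_min: float,
) -> tuple[list[CNVCall], int]:
    """Per-sample cross-source matching step of the animal pipeline.

    Every (GEN, WGS) pair within one sample passing the reciprocal
    threshold yields one high-confidence CNV spanning the union of the
    pair, carrying the array call's event.  Pairs with discordant event
    directions are not considered high confidence and are dropped; the
    count of dropped pairs is returned.
    """
    gen_by_sample: dict[str, list[CNVCall]] = {}
    for c in gen_calls:
        gen_by_sample.setdefault(c.sample_id, []).append(c)
    wgs_by_sample: dict[str, list[CNVCall]] = {}
    for c in wgs_calls:
        wgs_by_sample.setdefault(c.sample_id, []).append(c)

    hc: list[CNVCall] = []
    n_discordant = 0
    for sample, gens in gen_by_sample.items():
        wgss = wgs_by_sample.get(sample)
        if not wgss:
            continue
        wgs_by_chrom: dict[str, list[CNVCall]] = {}
        for w in wgss:
            wgs_by_chrom.setdefault(w.interval.chrom, []).append(w)
        for chrom in wgs_by_chrom:
            wgs_by_chrom[chrom].sort(key=lambda c: c.interval.start)
        for g in gens:
            for w in wgs_by_chrom.get(g.interval.chrom, ()):
                if w.interval.start > g.interval.end:
                    break
                if not passes_reciprocal(g.interval, w.interval, reciprocal_min):
                    continue
                if g.event != w.event:
                    n_discordant += 1
                    continue
                hc.append(
                    CNVCall(
                        interval=g.interval.union_span(w.interval),
                        sample_id=sample,
                        source=g.source,
                        event=g.event,
                        copy_number=g.copy_number,
                        n_markers=g.n_markers,
                    )
                )
    if n_discordant:
        logger.info("animal matching: %d discordant-event pairs dropped", n_discordant)
    return hc, n_discordant


def animal_pipeline(
    gen_calls: Sequence[CNVCall],
    wgs_calls: Sequence[CNVCall],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> list[CNVRegion]:
    """ANIMAL_CNVR: same-sample cross-source matches collated over all samples."""
    hc, _ = animal_high_confidence_calls(gen_calls, wgs_calls, cfg.reciprocal_min)
    return collate_regions(hc, cfg.contiguity_gap, SourceSet.ANIMAL_CNVR)


def population_pipeline(
    gen_calls: Sequence[CNVCall],
    wgs_calls: Sequence[CNVCall],
    n_samples_total: int,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> list[CNVRegion]:
    """POPULATION_CNVR: cross-source consensus between per-source region sets.

    ``n_samples_total`` is the number of QC-passing samples (the carrier
    frequency denominator).
    """
    if n_samples_total <= 0:
        raise ValueError("n_samples_total must be positive")
    gen_cnvr = collate_regions(gen_calls, cfg.contiguity_gap, SourceSet.GEN_CNVR)
    wgs_cnvr = collate_regions(wgs_calls, cfg.contiguity_gap, SourceSet.WGS_CNVR)

    wgs_by_chrom: dict[str, list[CNVRegion]] = {}
    for r in wgs_cnvr:
        wgs_by_chrom.setdefault(r.interval.chrom, []).append(r)
    for chrom in wgs_by_chrom:
        wgs_by_chrom[chrom].sort(key=lambda r: r.interval.start)

    candidates: list[CNVRegion] = []
    for g in gen_cnvr:
        for w in wgs_by_chrom.get(g.interval.chrom, ()):
            if w.interval.start > g.interval.end:
                break
            if not passes_reciprocal(g.interval, w.interval, cfg.reciprocal_min):
                continue
            carriers = g.samples | w.samples
            freq = len(carriers) / n_samples_total
            if (freq > cfg.population_min_freq) if cfg.strict else (freq >= cfg.population_min_freq):
                members = tuple(g.member_calls) + tuple(w.member_calls)
                candidates.append(
                    CNVRegion(
                        interval=g.interval.union_span(w.interval),
                        rtype=region_type(c.event for c in members),
                        samples=frozenset(carriers),
                        source_set=SourceSet.POPULATION_CNVR,
                        member_calls=members,
                    )
                )
    if not candidates:
        return []
    return merge_regions(candidates, SourceSet.POPULATION_CNVR, cfg.contiguity_gap)


def unique_high_confidence(
    animal_set: Sequence[CNVRegion], population_set: Sequence[CNVRegion]
) -> list[CNVRegion]:
    """Merge both high-confidence sets so overlapping regions count once.

    Merging requires a shared base (>= 1 bp); each output region's
    ``origins`` records which input sets contributed.
    """
    tagged = [
        CNVRegion(
            interval=r.interval,
            rtype=r.rtype,
            samples=r.samples,
            source_set=r.source_set,
            member_calls=r.member_calls,
            origins=frozenset({r.source_set.value}),
        )
        for r in list(animal_set) + list(population_set)
    ]
    if not tagged:
        return []
    return merge_regions(tagged, SourceSet.UNIQUE_HC, overlap_only=True)


def threshold_sweep(
    gen_calls: Sequence[CNVCall],
    wgs_calls: Sequence[CNVCall],
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2)),
    cfg: ConsensusConfig = ConsensusConfig(),
) -> pd.DataFrame:
    """Animal-level high-confidence region counts across reciprocal thresholds.

    Returns a table (threshold, n_regions); counts are non-increasing in
    the threshold.
    """
    rows = []
    for t in thresholds:
        if not (0.0 < t < 1.0):
            raise ValueError(f"threshold outside (0,1): {t}")
        sweep_cfg = ConsensusConfig(
            reciprocal_min=float(t),
            population_min_freq=cfg.population_min_freq,
            strict=cfg.strict,
            contiguity_gap=cfg.contiguity_gap,
        )
        rows.append({"threshold": float(t), "n_regions": len(animal_pipeline(gen_calls, wgs_calls, sweep_cfg))})
    return pd.DataFrame(rows)


def summarize(
    regions: Sequence[CNVRegion],
    genome: Mapping[str, int],
    n_samples_total: int,
) -> dict:
    """Descriptive statistics of a region set.

    Genome coverage is the summed region length over the summed
    chromosome lengths, as a percentage.
    """
    genome_bp = float(sum(genome.values()))
    if not regions:
        return {
            "n_regions": 0,
            "n_cnl": 0,
            "n_cng": 0,
            "n_mix": 0,
            "coverage_pct": 0.0,
            "samples_min": 0,
            "samples_max": 0,
            "samples_mean": 0.0,
            "length_min": 0,
            "length_median": 0.0,
            "length_mean": 0.0,
            "length_max": 0,
            "n_private": 0,
            "n_shared_by_all": 0,
        }
    for r in regions:
        if r.interval.chrom not in genome:
            raise KeyError(f"region on unknown chromosome {r.interval.chrom!r}")
    lengths = np.array([r.length for r in regions], dtype=float)
    carriers = np.array([r.n_samples for r in regions], dtype=float)
    by_type = {t: sum(1 for r in regions if r.rtype == t) for t in RegionType}
    return {
        "n_regions": len(regions),
        "n_cnl": by_type[RegionType.CNL],
        "n_cng": by_type[RegionType.CNG],
        "n_mix": by_type[RegionType.MIX],
        "coverage_pct": float(lengths.sum() / genome_bp * 100.0),
        "samples_min": int(carriers.min()),
        "samples_max": int(carriers.max()),
        "samples_mean": float(carriers.mean()),
        "length_min": int(lengths.min()),
        "length_median": float(np.median(lengths)),
        "length_mean": float(lengths.mean()),
        "length_max": int(lengths.max()),
        "n_private": int((carriers == 1).sum()),
        "n_shared_by_all": int((carriers == n_samples_total).sum()),
    }
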