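"""Marker-density masking experiment and false-positive-rate statistics.

The experiment compares CNV calls obtained from the same samples at
three array densities (HD, 150K, 50K; the lower densities are marker
subsets of the HD array).  Calls across densities that share at least
one base are considered the same event; each resulting cluster is
labelled by the densities that contributed, giving the seven Venn zones
a..g:

===== ==========================
zone  densities containing the event
===== ==========================
a     HD only
b     HD and 150K
c     150K only
d     HD and 50K
e     HD, 150K and 50K
f     150K and 50K (not HD)
g     50K only
===== ==========================

Treating any HD-supported event as true, the per-sample false-positive
discovery rates are (c + f) / n for the 150K density and (f + g) / n
for the 50K density, where n is the total number of distinct events
(clusters) seen at any density.  Uncertainty is quantified by a
percentile bootstrap of the across-sample mean (samples are the
exchangeable unit), 10,000 resamples by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CNVCall, GenomicInterval, MarkerPanel, chrom_sort_key

DENSITIES = ("HD", "150K", "50K")

ZONES: Mapping[frozenset, str] = {
    frozenset({"HD"}): "a",
    frozenset({"HD", "150K"}): "b",
    frozenset({"150K"}): "c",
    frozenset({"HD", "50K"}): "d",
    frozenset({"HD", "150K", "50K"}): "e",
    frozenset({"150K", "50K"}): "f",
    frozenset({"50K"}): "g",
}

DEFAULT_BOOTSTRAP_SEED = 20200515


@dataclass
class DensityCallProfile:
    """One sample's call sets at the three densities."""

    sample_id: str
    calls_by_density: dict

    def __post_init__(self) -> None:
        missing = [d for d in DENSITIES if d not in self.calls_by_density]
        if missing:
            raise ValueError(f"profile {self.sample_id!r} missing densities: {missing}")


@dataclass(frozen=True)
class Cluster:
    """One cross-density event: the union span of >=1 bp-overlapping calls."""

    interval: GenomicInterval
    densities: frozenset
    calls: tuple

    @property
    def zone(self) -> str:
        return ZONES[self.densities]


@dataclass
class SampleFPRates:
    """Per-sample event count, zone counts, and both FP rates."""

    sample_id: str
    n_union: int
    fp_150: float
    fp_50: float
    zone_counts: dict


@dataclass
class FPRateResult:
    """Across-sample summary of the density experiment."""

    per_sample: list
    mean_n_cnv: float
    mean_fp_150: float
    mean_fp_50: float
    ci95: dict  # statistic -> (low, high)


def mask_panel(hd: MarkerPanel, target: MarkerPanel) -> MarkerPanel:
    """HD panel restricted to the markers shared with *target* (by name).

    Positions are taken from the HD map (the masked signal keeps HD
    coordinates).  An empty intersection signals mismatched manifests
    and raises.
    """
    shared = hd.marker_names & target.marker_names
    if not shared:
        raise ValueError(
            f"no shared markers between {hd.name!r} and {target.name!r}: mismatched manifests?"
        )
    return hd.subset_names(shared, name=target.name)


def mask_signal(signal: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Subset a per-sample signal table (Name, LRR, BAF) to a masked panel."""
    if "Name" not in signal.columns:
        raise ValueError("signal table must have a 'Name' column")
    return signal[signal["Name"].isin(panel.marker_names)].reset_index(drop=True)


def match_across_densities(profile: DensityCallProfile) -> list[Cluster]:
    """Cluster one sample's calls across densities by >=1 bp overlap.

    Clustering is transitive per chromosome; each cluster is one CNV
    event whose interval is the union span of its members.
    """
    items: list[tuple[str, CNVCall]] = []
    for density in DENSITIES:
        for call in profile.calls_by_density[density]:
            items.append((density, call))
    by_chrom: dict[str, list[tuple[str, CNVCall]]] = {}
    for density, call in items:
        by_chrom.setdefault(call.interval.chrom, []).append((density, call))
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        group = sorted(by_chrom[chrom], key=lambda dc: (dc[1].interval.start, dc[1].interval.end))
        cur = [group[0]]
        cur_end = group[0][1].interval.end
        for dc in group[1:]:
            if dc[1].interval.start <= cur_end:  # >=1 bp shared
                cur.append(dc)
                cur_end = max(cur_end, dc[1].interval.end)
            else:
                clusters.append(_make_cluster(cur))
                cur = [dc]
                cur_end = dc[1].interval.end
        clusters.append(_make_cluster(cur))
    return clusters


def _make_cluster(group: Sequence[tuple[str, CNVCall]]) -> Cluster:
    interval = GenomicInterval(
        group[0][1].interval.chrom,
        min(c.interval.start for _, c in group),
        max(c.interval.end for _, c in group),
    )
    return Cluster(
        interval=interval,
        densities=frozenset(d for d, _ in group),
        calls=tuple(c for _, c in group),
    )


def fp_rates(profile: DensityCallProfile) -> SampleFPRates:
    """Per-sample false-positive rates from the Venn zone counts.

    fp_150 = (|c| + |f|) / n_union and fp_50 = (|f| + |g|) / n_union,
    where n_union is the number of distinct events found at any density.
    """
    clusters = match_across_densities(profile)
    if not clusters:
        raise ValueError(f"sample {profile.sample_id!r} has no calls at any density")
    zone_counts = {z: 0 for z in "abcdefg"}
    for cl in clusters:
        zone_counts[cl.zone] += 1
    n = len(clusters)
    return SampleFPRates(
        sample_id=profile.sample_id,
        n_union=n,
        fp_150=(zone_counts["c"] + zone_counts["f"]) / n,
        fp_50=(zone_counts["f"] + zone_counts["g"]) / n,
        zone_counts=zone_counts,
    )


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> tuple[float, float]:
    """Percentile bootstrap interval of the mean of *values*.

    Resampling is with replacement at the element (sample) level;
    deterministic for a fixed seed.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("bootstrap_ci requires at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    means = arr[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high)


def density_experiment(
    profiles: Sequence[DensityCallProfile],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> FPRateResult:
    """Run the full density comparison: per-sample rates, means, bootstrap CIs."""
    per_sample = [fp_rates(p) for p in profiles]
    counts = [s.n_union for s in per_sample]
    f150 = [s.fp_150 for s in per_sample]
    f50 = [s.fp_50 for s in per_sample]
    sub = np.random.SeedSequence(seed).spawn(3)
    ci95 = {
        "n_cnv": bootstrap_ci(counts, n_boot, level, seed=int(sub[0].generate_state(1)[0] % 2**31)),
        "fp_150": bootstrap_ci(f150, n_boot, level, seed=int(sub[1].generate_state(1)[0] % 2**31)),
        "fp_50": bootstrap_ci(f50, n_boot, level, seed=int(sub[2].generate_state(1)[0] % 2**31)),
    }
    return FPRateResult(
        per_sample=per_sample,
        mean_n_cnv=float(np.mean(counts)),
        mean_fp_150=float(np.mean(f150)),
        mean_fp_50=float(np.mean(f50)),
        ci95=ci95,
    )
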