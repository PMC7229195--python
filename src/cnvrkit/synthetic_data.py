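"""Seeded generators for every input the pipeline consumes.

The generator emulates the study design end to end: true CNV regions
with population frequencies are placed on a genome, marker panels of
four densities are laid down (the lower densities are nested marker
subsets of the HD panel, mirroring the masking design), and per-sample
call sets are derived from the truth with source-specific noise —
sequence calls get breakpoint jitter, array calls get breakpoints
snapped to the outermost panel markers inside the event and are
silently undetectable when they span fewer markers than the panel's
minimum (the same mechanism that produces density-dependent false
positives).  Configurable false-call and dropout rates stress the
consensus stages; a filter-stress mode emits false calls that violate
the quality filters instead of passing them.

All randomness flows from the single configuration seed; every
generator is deterministic given that seed, and each stage derives its
own stream so stages can be re-run independently.
"""

from __future__ import annotations

import hashlib
import math
from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .consensus import reciprocal_overlap
from .density_fp import DENSITIES, DensityCallProfile
from .io_formats import (
    write_chrom_sizes,
    write_cnvnator,
    write_marker_panel,
    write_penncnv,
    write_sample_qc,
)
from .types import (
    CNVCall,
    CNVRegion,
    Event,
    GenomicInterval,
    MarkerPanel,
    SampleQC,
    Source,
    min_markers_for_panel,
)

#: Mean inter-marker gaps (bp) of the four array densities.
DEFAULT_PANEL_SPACINGS: Mapping[str, int] = {
    "HD": 3_980,
    "150K": 21_830,
    "GGPHD": 39_660,
    "50K": 66_750,
}

DEFAULT_GENOME: tuple = tuple((str(i), 40_000_000) for i in range(1, 6))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic run.

    Defaults: 30 samples, 200 true CNVRs with log-uniform lengths
    between 1.2 kb and 1.3 Mb (the span of call lengths the two sources
    produce), uniform population frequencies on (0.02, 1.0), 70% losses,
    5% breakpoint jitter on sequence calls, one false call per sample
    and source, 10% per-source dropout of carried events, and panel
    spacings matching the four array densities.
    """

    seed: int = 20200515
    genome: tuple = DEFAULT_GENOME
    n_samples: int = 30
    n_true_cnvr: int = 200
    length_bounds: tuple = (1_200, 1_300_000)
    freq_bounds: tuple = (0.02, 1.0)
    p_loss: float = 0.7
    panel_spacings: tuple = tuple(DEFAULT_PANEL_SPACINGS.items())
    wgs_jitter_sd: float = 0.05
    gen_fp_rate: float = 1.0
    wgs_fp_rate: float = 1.0
    gen_dropout: float = 0.1
    wgs_dropout: float = 0.1
    qc_fail_fraction: float = 0.1
    sample_panel: str = "HD"
    filter_stress: bool = False

    def __post_init__(self) -> None:
        for p in (self.p_loss, self.gen_dropout, self.wgs_dropout, self.qc_fail_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability outside [0,1]: {p}")
        if self.length_bounds[0] > self.length_bounds[1]:
            raise ValueError("length_bounds must be ordered")
        if self.freq_bounds[0] > self.freq_bounds[1]:
            raise ValueError("freq_bounds must be ordered")

    @property
    def genome_dict(self) -> dict:
        return dict(self.genome)

    @property
    def spacings(self) -> dict:
        return dict(self.panel_spacings)

    @property
    def sample_ids(self) -> list:
        return [f"S{i:03d}" for i in range(1, self.n_samples + 1)]


@dataclass(frozen=True)
class TruthRegion:
    interval: GenomicInterval
    event: Event
    frequency: float


@dataclass
class TruthSet:
    """True CNVRs and their carrier samples."""

    regions: list
    carriers: list  # parallel list of frozenset of sample ids
    sample_ids: list


@dataclass
class SimulatedCallSet:
    """Raw caller output emulations plus the per-sample QC table."""

    gen_calls: list
    wgs_calls: list
    qc: list
    sample_ids: list
    panel_of_sample: dict


def _stage_rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def simulate_truth(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> TruthSet:
    """Place non-overlapping truth regions uniformly and draw carriers.

    The carrier count of a region is round(frequency * n_samples),
    floored at one sample.
    """
    rng = rng or _stage_rng(cfg, 1)
    chroms = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, list] = {c: [] for c in chroms}  # sorted (start, end)

    lo, hi = cfg.length_bounds
    regions: list[TruthRegion] = []
    attempts = 0
    max_attempts = max(1000, 200 * cfg.n_true_cnvr)
    while len(regions) < cfg.n_true_cnvr:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {cfg.n_true_cnvr} disjoint regions on the genome "
                f"(placed {len(regions)})"
            )
        length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        ci = rng.choice(len(chroms), p=weights)
        chrom, chrom_len = chroms[ci], int(lengths[ci])
        if length >= chrom_len:
            continue
        start = int(rng.integers(1, chrom_len - length + 1))
        end = start + length - 1
        spans = placed[chrom]
        i = bisect_right(spans, (start, end))
        if i > 0 and spans[i - 1][1] >= start:
            continue
        if i < len(spans) and spans[i][0] <= end:
            continue
        insort(spans, (start, end))
        event = Event.LOSS if rng.random() < cfg.p_loss else Event.GAIN
        freq = float(rng.uniform(*cfg.freq_bounds))
        regions.append(TruthRegion(GenomicInterval(chrom, start, end), event, freq))

    sample_ids = cfg.sample_ids
    carriers = []
    for reg in regions:
        n_c = max(1, int(round(reg.frequency * cfg.n_samples)))
        n_c = min(n_c, cfg.n_samples)
        chosen = rng.choice(cfg.n_samples, size=n_c, replace=False)
        carriers.append(frozenset(sample_ids[i] for i in chosen))
    return TruthSet(regions=regions, carriers=carriers, sample_ids=sample_ids)


def simulate_panels(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, MarkerPanel]:
    """Marker maps for all densities; lower densities are nested HD subsets.

    HD inter-marker gaps are exponential with the configured mean; each
    lower-density panel keeps markers of the next denser panel with the
    probability that preserves the target mean gap (thinning a renewal
    process divides its rate).
    """
    import pandas as pd

    rng = rng or _stage_rng(cfg, 2)
    spacings = cfg.spacings
    order = sorted(spacings, key=spacings.get)  # densest first
    hd_name = order[0]

    rows = {"name": [], "chrom": [], "pos": []}
    for chrom, chrom_len in cfg.genome:
        n_est = int(chrom_len / spacings[hd_name] * 1.3) + 10
        gaps = rng.exponential(spacings[hd_name], size=n_est)
        pos = np.cumsum(gaps).astype(np.int64) + 1
        pos = pos[pos <= chrom_len]
        pos = np.unique(pos)
        rows["name"].extend(f"M{chrom}_{i:06d}" for i in range(len(pos)))
        rows["chrom"].extend([chrom] * len(pos))
        rows["pos"].extend(pos.tolist())
    panels = {hd_name: MarkerPanel(hd_name, pd.DataFrame(rows))}

    prev = panels[hd_name]
    prev_gap = spacings[hd_name]
    for name in order[1:]:
        p_keep = prev_gap / spacings[name]
        keep = rng.random(len(prev)) < p_keep
        panels[name] = MarkerPanel(name, prev.table[keep])
        prev, prev_gap = panels[name], spacings[name]
    return panels


def _snap_to_panel(
    truth_interval: GenomicInterval, panel: MarkerPanel, min_markers: int
) -> Optional[tuple[GenomicInterval, int]]:
    """Array view of a truth event: outermost markers inside, or None."""
    span = panel.span_within(truth_interval)
    if span is None:
        return None
    first, last, n = span
    if n < min_markers:
        return None
    return GenomicInterval(truth_interval.chrom, first, last), n


def _wgs_fields(rng: np.random.Generator, event: Event) -> dict:
    return {
        "copy_number": float(rng.uniform(0.2, 0.8) if event == Event.LOSS else rng.uniform(1.3, 2.5)),
        "rd_pvalue": float(rng.uniform(0.0, 0.0499)),
        "q0": float(rng.uniform(0.0, 0.499)),
    }


def simulate_calls(
    truth: TruthSet,
    panels: Mapping[str, MarkerPanel],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCallSet:
    """Derive per-sample GEN and WGS call sets from the truth.

    Each carried event is emitted per source with probability
    1 - dropout; sequence breakpoints are jittered by
    Normal(0, jitter_sd * length), array breakpoints are snapped to the
    outermost panel markers inside the event (dropped when fewer than
    the panel minimum).  False calls are added as Poisson(rate) per
    sample and source; their fields pass every filter unless
    ``filter_stress`` is set, in which case each violates one rule.
    """
    rng = rng or _stage_rng(cfg, 3)
    genome = cfg.genome_dict
    panel = panels[cfg.sample_panel]
    min_markers = min_markers_for_panel(cfg.sample_panel)
    sample_ids = truth.sample_ids

    # QC table: a configurable fraction of samples violates one rule.
    n_fail = int(round(cfg.qc_fail_fraction * len(sample_ids)))
    failing = set(rng.choice(len(sample_ids), size=n_fail, replace=False).tolist())
    qc: list[SampleQC] = []
    for i, sid in enumerate(sample_ids):
        lrr = float(rng.uniform(0.05, 0.25))
        baf = float(rng.uniform(0.0, 0.008))
        wave = float(rng.uniform(-0.04, 0.04))
        if i in failing:
            rule = int(rng.integers(0, 3))
            if rule == 0:
                lrr = float(rng.uniform(0.31, 0.6))
            elif rule == 1:
                baf = float(rng.uniform(0.011, 0.05))
            else:
                wave = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.051, 0.15))
        qc.append(SampleQC(sid, cfg.sample_panel, lrr, baf, wave))

    carried: dict[str, list[TruthRegion]] = {sid: [] for sid in sample_ids}
    for reg, carrier_set in zip(truth.regions, truth.carriers):
        for sid in carrier_set:
            carried[sid].append(reg)

    gen_calls: list[CNVCall] = []
    wgs_calls: list[CNVCall] = []
    for sid in sample_ids:
        for reg in sorted(carried[sid], key=lambda r: (r.interval.chrom, r.interval.start)):
            if rng.random() >= cfg.gen_dropout:
                snapped = _snap_to_panel(reg.interval, panel, min_markers)
                if snapped is not None:
                    iv, n = snapped
                    gen_calls.append(
                        CNVCall(
                            interval=iv,
                            sample_id=sid,
                            source=Source.GEN,
                            event=reg.event,
                            copy_number=1 if reg.event == Event.LOSS else 3,
                            n_markers=n,
                        )
                    )
            if rng.random() >= cfg.wgs_dropout:
                sd = cfg.wgs_jitter_sd * reg.interval.length
                start = reg.interval.start + int(round(rng.normal(0.0, sd))) if sd > 0 else reg.interval.start
                end = reg.interval.end + int(round(rng.normal(0.0, sd))) if sd > 0 else reg.interval.end
                start = max(1, min(start, genome[reg.interval.chrom] - 1))
                end = max(start + 1, min(end, genome[reg.interval.chrom]))
                wgs_calls.append(
                    CNVCall(
                        interval=GenomicInterval(reg.interval.chrom, start, end),
                        sample_id=sid,
                        source=Source.WGS,
                        event=reg.event,
                        **_wgs_fields(rng, reg.event),
                    )
                )
        gen_calls.extend(_false_gen_calls(sid, panel, min_markers, cfg, rng))
        wgs_calls.extend(_false_wgs_calls(sid, cfg, rng))
    return SimulatedCallSet(
        gen_calls=gen_calls,
        wgs_calls=wgs_calls,
        qc=qc,
        sample_ids=sample_ids,
        panel_of_sample={sid: cfg.sample_panel for sid in sample_ids},
    )


def _false_gen_calls(
    sid: str,
    panel: MarkerPanel,
    min_markers: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[CNVCall]:
    chroms = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    weights = lengths / lengths.sum()
    out = []
    for _ in range(rng.poisson(cfg.gen_fp_rate)):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = panel.positions(chrom)
        if cfg.filter_stress and min_markers > 1:
            m = int(rng.integers(1, min_markers))
        else:
            m = int(rng.integers(min_markers, min_markers + 21))
        if len(pos) < m:
            continue
        i = int(rng.integers(0, len(pos) - m + 1))
        event = Event.LOSS if rng.random() < cfg.p_loss else Event.GAIN
        out.append(
            CNVCall(
                interval=GenomicInterval(chrom, int(pos[i]), int(pos[i + m - 1])),
                sample_id=sid,
                source=Source.GEN,
                event=event,
                copy_number=1 if event == Event.LOSS else 3,
                n_markers=m,
            )
        )
    return out


def _false_wgs_calls(sid: str, cfg: SimulationConfig, rng: np.random.Generator) -> list[CNVCall]:
    chroms = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    weights = lengths / lengths.sum()
    lo = max(1_000, cfg.length_bounds[0])
    hi = min(4_999_999, cfg.length_bounds[1])
    out = []
    for _ in range(rng.poisson(cfg.wgs_fp_rate)):
        chrom_i = rng.choice(len(chroms), p=weights)
        chrom, chrom_len = chroms[chrom_i], int(lengths[chrom_i])
        event = Event.LOSS if rng.random() < cfg.p_loss else Event.GAIN
        fields = _wgs_fields(rng, event)
        length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        if cfg.filter_stress:
            rule = int(rng.integers(0, 3))
            if rule == 0:
                length = int(rng.integers(100, 1_000))
            elif rule == 1:
                fields["rd_pvalue"] = float(rng.uniform(0.05, 1.0))
            else:
                fields["q0"] = float(rng.uniform(0.5, 1.0))
        length = min(length, chrom_len - 1)
        start = int(rng.integers(1, chrom_len - length + 1))
        out.append(
            CNVCall(
                interval=GenomicInterval(chrom, start, start + length - 1),
                sample_id=sid,
                source=Source.WGS,
                event=event,
                **fields,
            )
        )
    return out


def simulate_density_profiles(
    truth: TruthSet,
    panels: Mapping[str, MarkerPanel],
    cfg: SimulationConfig,
    fp_inject: Optional[Mapping[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[DensityCallProfile]:
    """Per-sample call sets at the three densities for the FP experiment.

    The HD set holds each carried event spanning >= 10 HD markers; a
    lower-density set holds the same event when it spans >= 3 markers at
    that density.  Density-only false calls are injected per sample with
    Poisson counts whose mean is r_d / (1 - sum(r)) times the sample's
    HD event count, so the expected FP proportion of the final union
    equals the requested rate r_d.  Injected calls avoid the truth
    regions and each other.
    """
    fp_inject = dict(fp_inject or {})
    rng = rng or _stage_rng(cfg, 4)
    total_rate = sum(fp_inject.values())
    if not (0.0 <= total_rate < 1.0):
        raise ValueError("sum of injection rates must be in [0, 1)")

    hd = panels["HD"]
    low = {d: panels[d] for d in DENSITIES if d != "HD"}
    truth_by_chrom: dict[str, list] = {}
    for reg in truth.regions:
        truth_by_chrom.setdefault(reg.interval.chrom, []).append(
            (reg.interval.start, reg.interval.end)
        )
    for chrom in truth_by_chrom:
        truth_by_chrom[chrom].sort()

    carried: dict[str, list[TruthRegion]] = {sid: [] for sid in truth.sample_ids}
    for reg, carrier_set in zip(truth.regions, truth.carriers):
        for sid in carrier_set:
            carried[sid].append(reg)

    profiles = []
    for sid in truth.sample_ids:
        calls_by_density: dict[str, list] = {d: [] for d in DENSITIES}
        events = sorted(carried[sid], key=lambda r: (r.interval.chrom, r.interval.start))
        for reg in events:
            hd_snap = _snap_to_panel(reg.interval, hd, min_markers_for_panel("HD"))
            if hd_snap is None:
                continue
            calls_by_density["HD"].append(_profile_call(hd_snap, sid, reg.event))
            for d, p in low.items():
                snap = _snap_to_panel(reg.interval, p, min_markers_for_panel(d))
                if snap is not None:
                    calls_by_density[d].append(_profile_call(snap, sid, reg.event))
        n_base = len(calls_by_density["HD"])
        occupied = {c: list(spans) for c, spans in truth_by_chrom.items()}
        for d, rate in fp_inject.items():
            k = rng.poisson(rate / (1.0 - total_rate) * n_base)
            for _ in range(k):
                iv = _inject_interval(panels[d], cfg, occupied, rng)
                if iv is None:
                    continue
                interval, m = iv
                event = Event.LOSS if rng.random() < cfg.p_loss else Event.GAIN
                calls_by_density[d].append(
                    _profile_call((interval, m), sid, event)
                )
        if all(calls_by_density[d] for d in DENSITIES):
            profiles.append(DensityCallProfile(sample_id=sid, calls_by_density=calls_by_density))
    return profiles


def _profile_call(snap: tuple[GenomicInterval, int], sid: str, event: Event) -> CNVCall:
    interval, n = snap
    return CNVCall(
        interval=interval,
        sample_id=sid,
        source=Source.GEN,
        event=event,
        copy_number=1 if event == Event.LOSS else 3,
        n_markers=n,
    )


def _inject_interval(
    panel: MarkerPanel,
    cfg: SimulationConfig,
    occupied: dict,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> Optional[tuple[GenomicInterval, int]]:
    """A random marker-backed interval avoiding occupied spans."""
    chroms = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = panel.positions(chrom)
        m = int(rng.integers(3, 9))
        if len(pos) < m:
            continue
        i = int(rng.integers(0, len(pos) - m + 1))
        start, end = int(pos[i]), int(pos[i + m - 1])
        spans = occupied.setdefault(chrom, [])
        j = bisect_right(spans, (start, end))
        if j > 0 and spans[j - 1][1] >= start:
            continue
        if j < len(spans) and spans[j][0] <= end:
            continue
        insort(spans, (start, end))
        return GenomicInterval(chrom, start, end), m
    return None


# ---------------------------------------------------------------------------
# Truth-recovery evaluation


def truth_assayable(region: TruthRegion, panel: MarkerPanel, min_markers: int) -> bool:
    """Whether the array design can represent the event at all."""
    return panel.count_in(region.interval) >= min_markers


def recovery_metrics(
    truth: TruthSet,
    regions: Sequence[CNVRegion],
    reciprocal: float = 0.5,
    freq_min: float = 0.1,
    panel: Optional[MarkerPanel] = None,
    min_markers: int = 10,
) -> dict:
    """Sensitivity and precision of a region set against the truth.

    A truth region is *recovered* when some reported region reciprocally
    overlaps it at >= ``reciprocal``.  Sensitivity is reported both over
    all truth regions with frequency >= ``freq_min`` and (when a panel
    is given) over the subset additionally spanning >= ``min_markers``
    panel markers — the events the array design can represent.
    Precision is the fraction of reported regions recovered by *some*
    truth region under the same rule.
    """
    regions_by_chrom: dict[str, list[CNVRegion]] = {}
    for r in regions:
        regions_by_chrom.setdefault(r.interval.chrom, []).append(r)
    for chrom in regions_by_chrom:
        regions_by_chrom[chrom].sort(key=lambda r: r.interval.start)

    def recovered(iv: GenomicInterval) -> bool:
        for r in regions_by_chrom.get(iv.chrom, ()):
            if r.interval.start > iv.end:
                return False
            fa, fb = reciprocal_overlap(iv, r.interval)
            if min(fa, fb) >= reciprocal:
                return True
        return False

    eligible = [t for t in truth.regions if t.frequency >= freq_min]
    n_rec_all = sum(recovered(t.interval) for t in eligible)
    out = {
        "n_truth_eligible": len(eligible),
        "n_recovered": n_rec_all,
        "sensitivity": n_rec_all / len(eligible) if eligible else float("nan"),
    }
    if panel is not None:
        assayable = [t for t in eligible if truth_assayable(t, panel, min_markers)]
        n_rec = sum(recovered(t.interval) for t in assayable)
        out["n_truth_assayable"] = len(assayable)
        out["n_recovered_assayable"] = n_rec
        out["sensitivity_assayable"] = n_rec / len(assayable) if assayable else float("nan")

    truth_by_chrom: dict[str, list[TruthRegion]] = {}
    for t in truth.regions:
        truth_by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom in truth_by_chrom:
        truth_by_chrom[chrom].sort(key=lambda t: t.interval.start)

    n_matched = 0
    for r in regions:
        for t in truth_by_chrom.get(r.interval.chrom, ()):
            if t.interval.start > r.interval.end:
                break
            fa, fb = reciprocal_overlap(r.interval, t.interval)
            if min(fa, fb) >= reciprocal:
                n_matched += 1
                break
    out["n_regions"] = len(regions)
    out["n_regions_matched"] = n_matched
    out["precision"] = n_matched / len(regions) if regions else float("nan")
    return out


# ---------------------------------------------------------------------------
# File output


def write_simulation(
    outdir: Path,
    cfg: SimulationConfig,
    truth: TruthSet,
    panels: Mapping[str, MarkerPanel],
    calls: SimulatedCallSet,
) -> dict:
    """Write every pipeline input to *outdir*; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "truth.bed", "w") as fh:
        fh.write("#chrom\tstart\tend\tevent\tfrequency\tcarriers\n")
        for reg, carrier_set in zip(truth.regions, truth.carriers):
            fh.write(
                f"{reg.interval.chrom}\t{reg.interval.start - 1}\t{reg.interval.end}\t"
                f"{reg.event.value}\t{reg.frequency:.4f}\t{','.join(sorted(carrier_set))}\n"
            )

    panel_dir = outdir / "panels"
    panel_dir.mkdir(exist_ok=True)
    for name, panel in panels.items():
        write_marker_panel(panel, panel_dir / f"{name}.map")

    write_penncnv(calls.gen_calls, outdir / "gen_calls.rawcnv")
    wgs_dir = outdir / "wgs"
    wgs_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list] = {}
    for c in calls.wgs_calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    for sid in calls.sample_ids:
        write_cnvnator(by_sample.get(sid, []), wgs_dir / f"{sid}.cnvnator.txt")

    write_sample_qc(calls.qc, outdir / "sample_qc.tsv")
    write_chrom_sizes(cfg.genome_dict, outdir / "genome.chrom.sizes")

    manifest = {
        "config": _config_for_manifest(cfg),
        "n_truth_regions": len(truth.regions),
        "n_gen_calls": len(calls.gen_calls),
        "n_wgs_calls": len(calls.wgs_calls),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def _config_for_manifest(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["genome"] = [list(x) for x in cfg.genome]
    d["panel_spacings"] = dict(cfg.panel_spacings)
    return d


def simulate(cfg: SimulationConfig) -> tuple[TruthSet, dict, SimulatedCallSet]:
    """Run every generator stage with streams derived from the one seed."""
    truth = simulate_truth(cfg)
    panels = simulate_panels(cfg)
    calls = simulate_calls(truth, panels, cfg)
    return truth, panels, calls
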