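"""Quality filters applied to raw call sets before any consensus step.

Boundary semantics follow the filtering rules literally:

* samples are *removed* when LRR SD > 0.3, BAF drift > 0.01, or
  |wave factor| > 0.05 (the wave factor is signed in the array-QC
  convention; the cutoff is a magnitude);
* array calls are removed when they span fewer than 10 markers (HD
  samples) or fewer than 3 markers (all other panels);
* read-depth calls are *kept* when 1 kb <= length <= 5 Mb, the RD
  t-test p-value is < 0.05 and the fraction of MQ0 reads is < 0.5;
* markers are removed per sample when their GenCall score is < 0.15.

All filters are idempotent, and each :class:`FilterReport` partitions
the removed records by the first violated rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .types import (
    CNVCall,
    FilterReport,
    MarkerPanel,
    SampleQC,
    Source,
    min_markers_for_panel,
)


@dataclass(frozen=True)
class QCThresholds:
    """Sample-exclusion cutoffs (a sample exceeding any is removed)."""

    lrr_sd: float = 0.3
    baf_drift: float = 0.01
    wave_factor: float = 0.05

    def __post_init__(self) -> None:
        if min(self.lrr_sd, self.baf_drift, self.wave_factor) <= 0:
            raise ValueError("QC thresholds must be positive")


def filter_gen_samples(
    qc: Sequence[SampleQC], thresholds: QCThresholds = QCThresholds()
) -> tuple[list[str], FilterReport]:
    """Return ids of samples passing all three array-QC cutoffs.

    A sample passes iff lrr_sd <= 0.3 AND baf_drift <= 0.01 AND
    |wave_factor| <= 0.05 (defaults).  Removals are bucketed by the
    first violated rule in that order.
    """
    passed: list[str] = []
    removals = {"lrr_sd": 0, "baf_drift": 0, "wave_factor": 0}
    for rec in qc:
        if rec.lrr_sd > thresholds.lrr_sd:
            removals["lrr_sd"] += 1
        elif rec.baf_drift > thresholds.baf_drift:
            removals["baf_drift"] += 1
        elif abs(rec.wave_factor) > thresholds.wave_factor:
            removals["wave_factor"] += 1
        else:
            passed.append(rec.sample_id)
    return passed, FilterReport(len(qc), len(passed), removals)


def filter_gen_calls(
    calls: Sequence[CNVCall], panel_of_sample: Mapping[str, str]
) -> tuple[list[CNVCall], FilterReport]:
    """Drop array calls spanning fewer markers than their panel's minimum.

    HD-genotyped samples require >= 10 markers per call; every other
    panel requires >= 3.
    """
    kept: list[CNVCall] = []
    removals = {"min_markers": 0}
    for call in calls:
        if call.source != Source.GEN:
            raise ValueError(f"filter_gen_calls got a {call.source.value} call")
        if call.sample_id not in panel_of_sample:
            raise KeyError(f"no panel recorded for sample {call.sample_id!r}")
        if call.n_markers is None:
            raise ValueError(f"GEN call without n_markers in sample {call.sample_id!r}")
        if call.n_markers >= min_markers_for_panel(panel_of_sample[call.sample_id]):
            kept.append(call)
        else:
            removals["min_markers"] += 1
    return kept, FilterReport(len(calls), len(kept), removals)


def filter_wgs_calls(
    calls: Sequence[CNVCall],
    min_len: int = 1_000,
    max_len: int = 5_000_000,
    p_max: float = 0.05,
    q0_max: float = 0.5,
) -> tuple[list[CNVCall], FilterReport]:
    """Keep read-depth calls with min_len <= length <= max_len,
    rd_pvalue < p_max and q0 < q0_max.

    Boundary behavior: a call of exactly 1 kb or exactly 5 Mb is kept
    ("shorter than" / "longer than" are strict); the p-value and q0
    gates are strict keeps (p < 0.05, q0 < 0.5).
    """
    kept: list[CNVCall] = []
    removals = {"too_short": 0, "too_long": 0, "rd_pvalue": 0, "q0": 0}
    for call in calls:
        if call.source != Source.WGS:
            raise ValueError(f"filter_wgs_calls got a {call.source.value} call")
        if call.length < min_len:
            removals["too_short"] += 1
        elif call.length > max_len:
            removals["too_long"] += 1
        elif not (call.rd_pvalue < p_max):
            removals["rd_pvalue"] += 1
        elif not (call.q0 < q0_max):
            removals["q0"] += 1
        else:
            kept.append(call)
    return kept, FilterReport(len(calls), len(kept), removals)


def filter_markers_gc(
    panel: MarkerPanel,
    gc_scores: Mapping[str, Mapping[str, float]],
    gc_min: float = 0.15,
) -> dict[str, MarkerPanel]:
    """Per-sample marker subsets after the GenCall-score filter.

    Markers with a score < gc_min are removed in that sample only; a
    marker with no recorded score is kept (no evidence against it).
    """
    out: dict[str, MarkerPanel] = {}
    for sample, scores in gc_scores.items():
        for marker, score in scores.items():
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"GC score outside [0,1] for {marker!r} in {sample!r}: {score}")
        keep = [
            n for n in panel.table["name"] if scores.get(n, 1.0) >= gc_min
        ]
        out[sample] = panel.subset_names(keep)
    return out


def check_qc_coverage(calls: Sequence[CNVCall], qc: Sequence[SampleQC]) -> None:
    """Raise if any sample with calls lacks a QC record."""
    known = {q.sample_id for q in qc}
    missing = sorted({c.sample_id for c in calls} - known)
    if missing:
        raise KeyError(f"samples with calls but no QC record: {missing}")
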