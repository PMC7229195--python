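"""Readers and writers for the external text formats.

Supported dialects:

* PennCNV ``rawcnv`` lines (array calls),
* CNVnator tab-separated call lines (read-depth calls),
* three-column SNP map files (marker name, chromosome, position),
* BED3+ region export (0-based half-open),
* sample-QC and known-catalogue TSV tables,
* UCSC ``chrom.sizes`` tables.

Every reader normalizes chromosome labels (``chr`` prefix stripped) and
returns 1-based inclusive coordinates.  Parsers are strict by default:
a malformed line raises :class:`ParseError` naming the line number.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .types import (
    AUTOSOMES,
    CNVCall,
    CNVRegion,
    Event,
    GenomicInterval,
    KnownRegion,
    MarkerPanel,
    RegionType,
    SampleQC,
    Source,
    SourceSet,
    chrom_sort_key,
    event_from_copy_number,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]


class ParseError(ValueError):
    """A line of an input file does not follow its dialect."""


class RejectedRecordError(ValueError):
    """A well-formed record that is not a valid variant (e.g. cn=2)."""


_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+(?P<file>\S+)\s+"
    r"startsnp=(?P<startsnp>\S+)\s+endsnp=(?P<endsnp>\S+)"
)


def _sample_from_file_token(token: str) -> str:
    """Basename of the signal-file token with its extension stripped."""
    base = os.path.basename(token)
    stem, _ = os.path.splitext(base)
    return stem


def read_penncnv(
    path: PathLike,
    strict: bool = True,
    sample_map: Optional[dict] = None,
) -> list[CNVCall]:
    """Read a PennCNV ``rawcnv`` file into GEN calls.

    ``sample_map`` optionally overrides the sample id derived from the
    signal-file token.  With ``strict=True`` (default) a copy-neutral
    record (cn=2) raises :class:`RejectedRecordError`; with
    ``strict=False`` it is logged and skipped, so that
    records_in == records_out + records_rejected.
    """
    calls: list[CNVCall] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                raise ParseError(f"{path}: line {lineno}: not a rawcnv record: {line!r}")
            cn = int(m["cn"])
            if cn == 2:
                if strict:
                    raise RejectedRecordError(
                        f"{path}: line {lineno}: cn=2 is copy-neutral, not a variant"
                    )
                n_rejected += 1
                logger.warning("%s: line %d rejected (cn=2)", path, lineno)
                continue
            sample = _sample_from_file_token(m["file"])
            if sample_map:
                sample = sample_map.get(sample, sample)
            interval = GenomicInterval(normalize_chrom(m["chrom"]), int(m["start"]), int(m["end"]))
            calls.append(
                CNVCall(
                    interval=interval,
                    sample_id=sample,
                    source=Source.GEN,
                    event=event_from_copy_number(cn, Source.GEN),
                    copy_number=cn,
                    n_markers=int(m["numsnp"]),
                )
            )
    if n_rejected:
        logger.info("%s: %d records read, %d rejected", path, len(calls), n_rejected)
    return calls


def write_penncnv(calls: Sequence[CNVCall], path: PathLike) -> None:
    """Write GEN calls as rawcnv lines (inverse of :func:`read_penncnv`)."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            state = int(c.copy_number) + 1  # PennCNV state index convention
            fh.write(
                f"chr{iv.chrom}:{iv.start}-{iv.end} numsnp={c.n_markers} "
                f"length={iv.length} state{state},cn={int(c.copy_number)} "
                f"{c.sample_id}.txt startsnp=snpA endsnp=snpB\n"
            )


_CNVNATOR_TYPES = {"deletion": Event.LOSS, "duplication": Event.GAIN}


def read_cnvnator(path: PathLike, sample_id: str) -> list[CNVCall]:
    """Read a CNVnator call file into WGS calls for one sample.

    Expected columns: TYPE, chr:start-end, SIZE, normalized RD, four
    e-values, q0.  The first e-value (t-test significance of the
    region's RD) is used as ``rd_pvalue``.
    """
    calls: list[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 fields, got {len(fields)}")
            ctype, coords, size, norm_rd, e1, _e2, _e3, _e4, q0 = fields
            if ctype not in _CNVNATOR_TYPES:
                raise ParseError(f"{path}: line {lineno}: unknown variant type {ctype!r}")
            if float(size) <= 0:
                raise ParseError(f"{path}: line {lineno}: non-positive size {size}")
            m = re.match(r"^(\S+):(\d+)-(\d+)$", coords)
            if m is None:
                raise ParseError(f"{path}: line {lineno}: bad coordinates {coords!r}")
            interval = GenomicInterval(normalize_chrom(m.group(1)), int(m.group(2)), int(m.group(3)))
            calls.append(
                CNVCall(
                    interval=interval,
                    sample_id=sample_id,
                    source=Source.WGS,
                    event=_CNVNATOR_TYPES[ctype],
                    copy_number=float(norm_rd),
                    rd_pvalue=float(e1),
                    q0=float(q0),
                )
            )
    return calls


def write_cnvnator(calls: Sequence[CNVCall], path: PathLike) -> None:
    """Write WGS calls in the CNVnator tab dialect (one sample per file)."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            ctype = "deletion" if c.event == Event.LOSS else "duplication"
            fh.write(
                "\t".join(
                    [
                        ctype,
                        f"chr{iv.chrom}:{iv.start}-{iv.end}",
                        str(iv.length),
                        f"{c.copy_number:.6g}",
                        f"{c.rd_pvalue:.6g}",
                        "1",
                        "1",
                        "1",
                        f"{c.q0:.6g}",
                    ]
                )
                + "\n"
            )


_BED_HEADER = "#chrom\tstart\tend\ttype\tn_samples\tsource_set\tsamples"


def write_regions_bed(regions: Sequence[CNVRegion], path: PathLike) -> None:
    """Write regions as BED3+ (0-based half-open), sorted by (chrom, start)."""
    rows = sorted(regions, key=lambda r: (chrom_sort_key(r.interval.chrom), r.interval.start))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for r in rows:
            samples = ",".join(sorted(r.samples)) if r.samples else "."
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end}\t"
                f"{r.rtype.value}\t{r.n_samples}\t{r.source_set.value}\t{samples}\n"
            )


def read_regions_bed(path: PathLike) -> list[CNVRegion]:
    """Read regions written by :func:`write_regions_bed` (member calls are not stored)."""
    regions: list[CNVRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}: line {lineno}: expected 7 columns")
            chrom, start0, end, rtype, _n, source_set, samples = fields[:7]
            sample_set = frozenset() if samples == "." else frozenset(samples.split(","))
            regions.append(
                CNVRegion(
                    interval=GenomicInterval(normalize_chrom(chrom), int(start0) + 1, int(end)),
                    rtype=RegionType(rtype),
                    samples=sample_set,
                    source_set=SourceSet(source_set),
                )
            )
    return regions


def read_marker_panel(path: PathLike, name: Optional[str] = None) -> MarkerPanel:
    """Read a three-column map file (marker_name, chrom, pos) into a panel.

    Markers with unknown position (pos 0 or chromosome "0") and markers
    outside the autosomes are dropped; only autosomes with known
    positions enter any analysis.  Duplicate marker names are an error.
    """
    try:
        table = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["name", "chrom", "pos"],
            comment="#",
            dtype={"name": str, "chrom": str},
        )
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=["name", "chrom", "pos"])
    if table.empty:
        return MarkerPanel(name or Path(path).stem, pd.DataFrame(columns=["name", "chrom", "pos"]))
    dup = table["name"][table["name"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate marker names: {sorted(set(dup))[:10]}")
    table["chrom"] = table["chrom"].map(normalize_chrom)
    table["pos"] = table["pos"].astype("int64")
    keep = table["chrom"].isin(AUTOSOMES) & (table["pos"] > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d non-autosomal or unplaced markers", path, dropped)
    return MarkerPanel(name or Path(path).stem, table[keep])


def write_marker_panel(panel: MarkerPanel, path: PathLike) -> None:
    panel.table.to_csv(path, sep="\t", header=False, index=False)


def read_sample_qc(path: PathLike) -> list[SampleQC]:
    """Read the per-sample array QC table (TSV with header)."""
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "panel", "lrr_sd", "baf_drift", "wave_factor"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing QC columns: {sorted(missing)}")
    return [
        SampleQC(
            sample_id=str(row.sample_id),
            panel=str(row.panel),
            lrr_sd=float(row.lrr_sd),
            baf_drift=float(row.baf_drift),
            wave_factor=float(row.wave_factor),
        )
        for row in table.itertuples()
    ]


def write_sample_qc(qc: Sequence[SampleQC], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "panel": q.panel,
                "lrr_sd": q.lrr_sd,
                "baf_drift": q.baf_drift,
                "wave_factor": q.wave_factor,
            }
            for q in qc
        ]
    ).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    """Read a UCSC chrom.sizes table into {chrom: length}."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected chrom<TAB>length")
            sizes[normalize_chrom(fields[0])] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes, key=chrom_sort_key):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_known_table(path: PathLike) -> pd.DataFrame:
    """Read a published-CNVR table: study, chrom, start, end, type[, frequency].

    Coordinates must already be on the working assembly (1-based inclusive).
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "study": str})
    required = {"study", "chrom", "start", "end", "type"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns: {sorted(missing)}")
    for i, row in enumerate(table.itertuples(), start=2):
        if int(row.end) < int(row.start) or int(row.start) < 1:
            raise ParseError(f"{path}: row {i}: bad coordinates {row.start}-{row.end}")
    table["chrom"] = table["chrom"].map(normalize_chrom)
    if "frequency" not in table.columns:
        table["frequency"] = float("nan")
    return table
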