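"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's sweep-based collation:
regions are recovered from per-base coverage masks and calls are
clustered with pairwise union-find, so agreement is a genuine
cross-check rather than the same algorithm twice.
"""

from __future__ import annotations

import numpy as np
import pytest

from cnvrkit.types import CNVCall, Event, GenomicInterval, Source


@pytest.fixture
def rng():
    return np.random.default_rng(20200515)


def make_gen_call(chrom, start, end, sample="S001", event=Event.LOSS, n_markers=12):
    return CNVCall(
        interval=GenomicInterval(str(chrom), start, end),
        sample_id=sample,
        source=Source.GEN,
        event=event,
        copy_number=1 if event == Event.LOSS else 3,
        n_markers=n_markers,
    )


def make_wgs_call(chrom, start, end, sample="S001", event=Event.LOSS, rd_pvalue=0.01, q0=0.1):
    return CNVCall(
        interval=GenomicInterval(str(chrom), start, end),
        sample_id=sample,
        source=Source.WGS,
        event=event,
        copy_number=0.5 if event == Event.LOSS else 1.8,
        rd_pvalue=rd_pvalue,
        q0=q0,
    )


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def oracle_components(intervals, contiguity_gap=0):
    """Pairwise union-find clustering of (chrom, start, end) triples.

    Two intervals join when they share a base or their gap is at most
    ``contiguity_gap``; components are the transitive closure.  Returns
    a list of sorted member-index tuples plus each component's span.
    """
    n = len(intervals)
    uf = UnionFind(n)
    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci != cj:
                continue
            gap = max(si, sj) - min(ei, ej) - 1
            if gap <= contiguity_gap:
                uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    out = []
    for members in comps.values():
        chrom = intervals[members[0]][0]
        span = (
            chrom,
            min(intervals[i][1] for i in members),
            max(intervals[i][2] for i in members),
        )
        out.append((tuple(sorted(members)), span))
    return sorted(out, key=lambda x: (x[1][0], x[1][1]))


def oracle_components_per_base(intervals):
    """Per-base coverage oracle for contiguity_gap=0.

    Marks coverage on a doubled axis where base b occupies positions 2b
    and 2b+1: directly adjacent intervals (e + 1 == s') touch there, but
    a 1-bp gap leaves an uncovered position, so maximal covered runs are
    exactly the "overlap or adjacent" components.
    """
    by_chrom: dict[str, list[int]] = {}
    for idx, (chrom, _s, _e) in enumerate(intervals):
        by_chrom.setdefault(chrom, []).append(idx)
    out = []
    for chrom, idxs in by_chrom.items():
        lo = 2 * min(intervals[i][1] for i in idxs)
        hi = 2 * max(intervals[i][2] for i in idxs) + 1
        cover = np.zeros(hi - lo + 1, dtype=bool)
        for i in idxs:
            s, e = intervals[i][1], intervals[i][2]
            cover[2 * s - lo : 2 * e + 1 - lo + 1] = True
        run_id = np.full(cover.size, -1, dtype=int)
        current = -1
        prev = False
        for k, covered in enumerate(cover.tolist()):
            if covered and not prev:
                current += 1
            if covered:
                run_id[k] = current
            prev = covered
        groups: dict[int, list[int]] = {}
        for i in idxs:
            groups.setdefault(int(run_id[2 * intervals[i][1] - lo]), []).append(i)
        for members in groups.values():
            span = (
                chrom,
                min(intervals[i][1] for i in members),
                max(intervals[i][2] for i in members),
            )
            out.append((tuple(sorted(members)), span))
    return sorted(out, key=lambda x: (x[1][0], x[1][1]))


def random_instance(rng, n_calls=None, span=100_000, n_chroms=2, n_samples=4):
    """A random small call set for oracle comparisons."""
    n_calls = n_calls or int(rng.integers(1, 51))
    intervals = []
    calls = []
    for _ in range(n_calls):
        chrom = str(rng.integers(1, n_chroms + 1))
        start = int(rng.integers(1, span))
        length = int(rng.integers(1, max(2, span // 10)))
        end = min(start + length - 1, span)
        sample = f"S{int(rng.integers(1, n_samples + 1)):03d}"
        event = Event.LOSS if rng.random() < 0.7 else Event.GAIN
        intervals.append((chrom, start, end))
        calls.append(make_gen_call(chrom, start, end, sample=sample, event=event))
    return calls, intervals
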