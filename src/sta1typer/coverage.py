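"""Read mapping, uniqueness filtering, window depth, and copy/zygosity calls.

The estimation procedure mirrors coverage-based STA1 genotyping from
short reads: align reads to a reference carrying the intact STA1 locus as
a separate contig, discard ambiguous alignments (reads shared between the
chimera and its parent genes), and compare the median depth of the two
diagnostic windows against the genome-wide median.  The copy number of a
window is ``round(ploidy x window_median / genome_median)``; the pair of
window copy numbers determines zygosity (e.g. a diploid with ratios
(0.5, 0.5) is hemizygous for the whole gene; (1.0, 0.5) carries the
promoter deletion heterozygously).

The built-in mapper is deliberately minimal: every read is placed at all
of its minimal-mismatch ungapped positions on either strand (up to
``max_mismatch``); a unique best placement gets MAPQ 60, tied placements
get MAPQ 0 each.  This reproduces exactly the semantics the MAPQ >= 50
filter relies on.  Alignments from external aligners can be supplied as
SAM instead and are filtered against the same threshold.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pysam

from .dna import ascii_array, revcomp_ascii

DEFAULT_MAPQ_MIN = 50
DEFAULT_MAX_MISMATCH = 3


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    contig: str
    pos: int                 # 1-based leftmost
    strand: str
    mismatches: int
    mapq: int                # 60 unique best placement, 0 tied
    read_len: int


@dataclass
class DepthSummary:
    window_medians: dict[str, float]
    genome_median: float
    n_reads: int
    mapq_threshold: int


@dataclass(frozen=True)
class CopyCall:
    ratios: dict[str, float]         # window depth / genome depth
    copies: dict[str, int]           # round(ploidy x ratio)
    zygosity: str
    ploidy: int


class ReadMapper:
    """Exhaustive minimal-mismatch ungapped mapper (pigeonhole seeding).

    A read with at most ``max_mismatch`` mismatches must contain at least
    one exact segment when cut into ``max_mismatch + 1`` pieces, so exact
    lookups of the segments against a position index of the reference find
    every qualifying placement; each candidate is then verified by a full
    Hamming comparison.
    """

    def __init__(self, reference: dict[str, str],
                 max_mismatch: int = DEFAULT_MAX_MISMATCH):
        if not reference or all(len(s) == 0 for s in reference.values()):
            raise ValueError("empty reference")
        self.max_mismatch = max_mismatch
        self.contigs = list(reference)
        seqs = [reference[c].upper() for c in self.contigs]
        self._starts = []
        off = 0
        for s in seqs:
            self._starts.append(off)
            off += len(s)
        self._ends = [st + len(s) for st, s in zip(self._starts, seqs)]
        self._ref = ascii_array("".join(seqs)).copy()
        self._index_cache: dict[int, dict] = {}

    def _index(self, seg_len: int) -> dict[bytes, list[int]]:
        if seg_len in self._index_cache:
            return self._index_cache[seg_len]
        idx: dict[bytes, list[int]] = {}
        buf = self._ref.tobytes()
        for start, end in zip(self._starts, self._ends):
            for p in range(start, end - seg_len + 1):
                idx.setdefault(buf[p:p + seg_len], []).append(p)
        self._index_cache[seg_len] = idx
        return idx

    def _contig_of(self, s: int, L: int) -> int:
        """Contig index if [s, s+L) lies inside a single contig, else -1."""
        i = bisect_right(self._starts, s) - 1
        if i < 0 or s + L > self._ends[i]:
            return -1
        return i

    def map_reads(self, reads) -> list[AlignmentRecord]:
        """Map ``(read_id, sequence)`` pairs; unplaceable reads are dropped."""
        ref = self._ref
        mm_max = self.max_mismatch
        out: list[AlignmentRecord] = []
        by_len: dict[int, list[tuple[str, str]]] = {}
        for rid, seq in reads:
            by_len.setdefault(len(seq), []).append((rid, seq))
        for L, group in by_len.items():
            n_seg = mm_max + 1
            seg_len = L // n_seg
            if seg_len < 12:     # avoid flooding the index with short seeds
                n_seg = max(1, L // 12)
                seg_len = L // n_seg
            idx = self._index(seg_len)
            offsets = [i * seg_len for i in range(n_seg)]
            empty: list[int] = []
            for rid, seq in group:
                fwd = ascii_array(seq)
                rev = revcomp_ascii(fwd)
                placements: list[tuple[int, int, str]] = []
                best = mm_max
                seen: set[tuple[int, str]] = set()
                for arr, strand in ((fwd, "+"), (rev, "-")):
                    buf = arr.tobytes()
                    for o in offsets:
                        for p in idx.get(buf[o:o + seg_len], empty):
                            s = p - o
                            if (s, strand) in seen:
                                continue
                            seen.add((s, strand))
                            if self._contig_of(s, L) < 0:
                                continue
                            d = int(np.count_nonzero(ref[s:s + L] != arr))
                            if d <= mm_max:
                                placements.append((d, s, strand))
                if not placements:
                    continue
                best = min(d for d, _, _ in placements)
                hits = [(s, strand) for d, s, strand in placements if d == best]
                mapq = 60 if len(hits) == 1 else 0
                for s, strand in hits:
                    ci = self._contig_of(s, L)
                    out.append(AlignmentRecord(
                        rid, self.contigs[ci], s - self._starts[ci] + 1,
                        strand, best, mapq, L))
        return out


def map_reads(reads, reference: dict[str, str],
              max_mismatch: int = DEFAULT_MAX_MISMATCH) -> list[AlignmentRecord]:
    """Convenience wrapper around :class:`ReadMapper`."""
    return ReadMapper(reference, max_mismatch).map_reads(reads)


def filter_unique(alignments, mapq_min: int = DEFAULT_MAPQ_MIN):
    """Keep alignments with MAPQ >= mapq_min (drops chimera/parent-shared
    reads, which the binary 60/0 model marks with MAPQ 0)."""
    return [a for a in alignments if a.mapq >= mapq_min]


def window_depth(alignments, windows: dict[str, tuple[str, int, int]],
                 reference: dict[str, str],
                 mapq_threshold: int | None = None) -> DepthSummary:
    """Median per-base depth over named windows and the whole reference.

    ``windows`` maps a name to (contig, start, end), 1-based inclusive.
    Depth counts full read overlap from the supplied (already filtered)
    alignments; no quality weighting.
    """
    depth: dict[str, np.ndarray] = {}
    for contig, seq in reference.items():
        diff = np.zeros(len(seq) + 1, dtype=np.int64)
        depth[contig] = diff
    n = 0
    for a in alignments:
        d = depth.get(a.contig)
        if d is None:
            raise ValueError(f"alignment contig {a.contig!r} not in reference")
        start = a.pos - 1
        end = min(start + a.read_len, len(d) - 1)
        d[start] += 1
        d[end] -= 1
        n += 1
    for contig in depth:
        depth[contig] = np.cumsum(depth[contig][:-1])
    medians = {}
    for name, (contig, start, end) in windows.items():
        if end < start:
            raise ValueError(f"window {name} has non-positive length")
        if contig not in depth or end > len(depth[contig]):
            raise ValueError(f"window {name} outside reference bounds")
        medians[name] = float(np.median(depth[contig][start - 1:end]))
    genome_median = float(np.median(np.concatenate(list(depth.values()))))
    return DepthSummary(medians, genome_median, n,
                        mapq_threshold if mapq_threshold is not None else -1)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def zygosity_from_copies(orf: int, prom: int, ploidy: int) -> str:
    """Zygosity vocabulary for the (ORF, promoter) copy pair.

    Diploid labels follow the published usage: hemizygous = gene on one of
    two haplotypes; heterozygous deletion = both haplotypes carry the gene
    but only one the full promoter.  Above ploidy 2 the raw copy vector is
    reported instead of a diploid label.
    """
    if orf == 0:
        return "absent"
    if orf > ploidy:
        return "multi_copy"
    if ploidy > 2:
        return f"copies_{orf}_{prom}"
    if ploidy == 2 and orf == 1:
        return "hemizygous_sta1"
    if orf == ploidy and prom == ploidy:
        return "homozygous_intact"
    if orf == ploidy and prom == 0:
        return "homozygous_deletion"
    if orf == ploidy and 0 < prom < ploidy:
        return "heterozygous_deletion"
    return f"copies_{orf}_{prom}"


def estimate_copies(summary: DepthSummary, ploidy: int = 2) -> CopyCall:
    """Depth-ratio copy number and zygosity.

    Raw ratios are always reported alongside the rounded copies (nearest
    integer, exact halves away from zero) since the binning of fractional
    ratios is a policy, not a measurement.
    """
    if summary.genome_median <= 0:
        raise ValueError("genome-wide median depth is zero; data unusable")
    ratios = {w: m / summary.genome_median
              for w, m in summary.window_medians.items()}
    copies = {w: _round_half_away(ploidy * r) for w, r in ratios.items()}
    zyg = zygosity_from_copies(copies.get("orf_marker", 0),
                               copies.get("promoter_marker", 0), ploidy)
    return CopyCall(ratios, copies, zyg, ploidy)


def genotype_from_reads(reads, reference: dict[str, str],
                        windows: dict[str, tuple[str, int, int]],
                        ploidy: int = 2,
                        mapq_min: int = DEFAULT_MAPQ_MIN,
                        max_mismatch: int = DEFAULT_MAX_MISMATCH
                        ) -> tuple[CopyCall, DepthSummary]:
    """End-to-end: map, filter to unique placements, depth, copy call."""
    alignments = map_reads(reads, reference, max_mismatch)
    kept = filter_unique(alignments, mapq_min)
    summary = window_depth(kept, windows, reference, mapq_threshold=mapq_min)
    return estimate_copies(summary, ploidy), summary


# ---------------------------------------------------------------------------
# SAM interchange (minimal dialect via pysam)
# ---------------------------------------------------------------------------

def write_sam(path, alignments, reference: dict[str, str]) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.items()]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(reference)}
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.reference_id = tid[a.contig]
            seg.reference_start = a.pos - 1
            seg.mapping_quality = a.mapq
            seg.cigarstring = f"{a.read_len}M"
            seg.flag = 16 if a.strand == "-" else 0
            seg.set_tag("NM", a.mismatches)
            out.write(seg)


def read_sam(path) -> list[AlignmentRecord]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            out.append(AlignmentRecord(
                seg.query_name, seg.reference_name, seg.reference_start + 1,
                "-" if seg.is_reverse else "+",
                int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                seg.mapping_quality, seg.query_length or seg.infer_query_length()))
    return out
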