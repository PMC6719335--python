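"""Assembly-level STA1 genotyping from diagnostic marker sequences.

A strain is called STA1-positive when its assembly contains the 79-bp
ORF marker (the Sdia-f/Sdia-r amplicon, which spans the chimera junction
and occurs in neither parent gene); the promoter is called intact when
the 101-bp promoter marker (inside the 1162-bp deletable region) is also
found.  Default thresholds are a perfect full-length match — the published
survey criterion — with identity relaxable for divergent strains.

Because the chimeric locus confuses short-read assemblers, an ORF hit too
close to a contig edge cannot distinguish a real promoter deletion from
assembly truncation; such samples are called ``indeterminate``.  A
separate contiguity check reports whether the full locus is captured on a
single contig (long-read assemblies) or fragmented (short-read ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dna import ascii_array, revcomp, template_mask, primer_mask


@dataclass(frozen=True)
class MarkerHit:
    contig: str
    start: int                  # 1-based inclusive
    end: int
    strand: str
    identity: float             # percent
    query_coverage: float       # percent of the marker aligned


@dataclass(frozen=True)
class AssemblyCall:
    sta1_present: bool
    promoter_intact: str        # 'intact' | 'deleted' | 'indeterminate' | 'n/a'
    hits: tuple[MarkerHit, ...] = ()


def _full_length_hits(contig_id: str, seq: str, marker: str,
                      min_identity: float) -> list[MarkerHit]:
    """Ungapped full-length placements of the marker at >= min_identity."""
    m = len(marker)
    t = ascii_array(seq)
    hits = []
    max_mm = int(np.floor(m * (1 - min_identity / 100.0) + 1e-9))
    for strand, query in (("+", marker), ("-", revcomp(marker))):
        q = ascii_array(query)
        if m > len(t):
            continue
        n_pos = len(t) - m + 1
        mism = np.zeros(n_pos, dtype=np.int32)
        for j in range(m):
            mism += t[j:j + n_pos] != q[j]
        for pos in np.nonzero(mism <= max_mm)[0]:
            ident = 100.0 * (m - int(mism[pos])) / m
            hits.append(MarkerHit(contig_id, int(pos) + 1, int(pos) + m,
                                  strand, ident, 100.0))
    return hits


def _edge_hits(contig_id: str, seq: str, marker: str, min_identity: float,
               min_query_coverage: float) -> list[MarkerHit]:
    """Partial marker matches hanging off contig ends (fragmented loci)."""
    m = len(marker)
    min_len = int(np.ceil(m * min_query_coverage / 100.0))
    hits = []
    for strand, query in (("+", marker), ("-", revcomp(marker))):
        for keep in range(min_len, min(m, len(seq) + 1)):
            max_mm = int(np.floor(keep * (1 - min_identity / 100.0) + 1e-9))
            # marker suffix at contig start
            d = int(np.count_nonzero(ascii_array(seq[:keep])
                                     != ascii_array(query[m - keep:])))
            if d <= max_mm:
                hits.append(MarkerHit(contig_id, 1, keep, strand,
                                      100.0 * (keep - d) / keep,
                                      100.0 * keep / m))
            # marker prefix at contig end
            d = int(np.count_nonzero(ascii_array(seq[-keep:])
                                     != ascii_array(query[:keep])))
            if d <= max_mm:
                hits.append(MarkerHit(contig_id, len(seq) - keep + 1, len(seq),
                                      strand, 100.0 * (keep - d) / keep,
                                      100.0 * keep / m))
    return hits


def scan_for_marker(assembly: dict[str, str], marker: str,
                    min_identity: float = 100.0,
                    min_query_coverage: float = 100.0) -> list[MarkerHit]:
    """Find a marker in an assembly (both strands).

    At the 100/100 defaults this is equivalent to exact substring search on
    both strands.  ``min_query_coverage`` below 100 additionally reports
    partial matches overhanging contig edges.
    """
    if len(marker) < 20:
        raise ValueError("marker must be at least 20 nt")
    hits: list[MarkerHit] = []
    for contig_id, seq in assembly.items():
        hits += _full_length_hits(contig_id, seq, marker, min_identity)
        if min_query_coverage < 100.0:
            hits += _edge_hits(contig_id, seq, marker, min_identity,
                               min_query_coverage)
    return sorted(hits, key=lambda h: (h.contig, h.start, h.strand))


def call_assembly_genotype(assembly: dict[str, str], orf_marker: str,
                           promoter_marker: str,
                           min_identity: float = 100.0,
                           edge_distance: int = 1500) -> AssemblyCall:
    """Presence/absence genotype of STA1 and its promoter deletion.

    The promoter marker sits ~1 kb upstream of the ORF marker, so when the
    ORF hit has less than ``edge_distance`` of assembled sequence on its
    upstream side the missing promoter marker is uninformative and the
    promoter status is ``indeterminate``.
    """
    orf_hits = scan_for_marker(assembly, orf_marker, min_identity)
    if not orf_hits:
        return AssemblyCall(False, "n/a", ())
    prom_hits = scan_for_marker(assembly, promoter_marker, min_identity)
    if prom_hits:
        return AssemblyCall(True, "intact", tuple(orf_hits + prom_hits))
    # Deleted vs truncated: does any ORF hit have enough upstream flank?
    for hit in orf_hits:
        contig_len = len(assembly[hit.contig])
        upstream = hit.start - 1 if hit.strand == "+" else contig_len - hit.end
        if upstream >= edge_distance:
            return AssemblyCall(True, "deleted", tuple(orf_hits))
    return AssemblyCall(True, "indeterminate", tuple(orf_hits))


def contiguity_check(assembly: dict[str, str], full_query: str,
                     min_fraction: float = 0.99,
                     tile: int = 100) -> tuple[bool, dict[str, float]]:
    """Is the full locus captured on a single contig?

    The query is cut into non-overlapping ``tile``-bp pieces; per contig
    and strand, the fraction of tiles found verbatim is reported.  True
    when some contig carries >= ``min_fraction`` of the tiles on one
    strand — the long-read-assembly situation; fragmented (short-read)
    assemblies split the tiles over contigs and fail.
    """
    tiles = [full_query[i:i + tile]
             for i in range(0, len(full_query) - tile + 1, tile)]
    report: dict[str, float] = {}
    for contig_id, seq in assembly.items():
        rc = revcomp(seq)
        best = 0.0
        for strand_seq in (seq, rc):
            found = sum(1 for t in tiles if t in strand_seq)
            best = max(best, found / len(tiles))
        report[contig_id] = best
    return (max(report.values(), default=0.0) >= min_fraction, report)
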