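"""Diagnostic-window discovery by k-mer uniqueness profiling.

Copy-number estimation over a chimeric gene cannot use whole-gene
coverage: reads from the parent-homologous stretches map ambiguously.
This module generalises the choice of the two published diagnostic
windows by profiling, for every position of a target sequence, how many
background sequences contain the k-mer starting there (canonical-form
matching, so uniqueness holds against both strands), then reporting
maximal runs of background-free k-mers as diagnostic windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import CoordMap
from .dna import revcomp

DEFAULT_K = 21
DEFAULT_MIN_LEN = 79     # length of the shortest published diagnostic window

_ACGT = frozenset("ACGT")


@dataclass
class UniquenessProfile:
    target_id: str
    k: int
    counts: np.ndarray       # backgrounds containing each k-mer, len = L-k+1
    n_backgrounds: int

    def to_tsv(self, path) -> None:
        """Wiggle-like (position, count) table; position is 1-based."""
        with open(path, "w") as fh:
            fh.write("position\tcount\n")
            for i, c in enumerate(self.counts, 1):
                fh.write(f"{i}\t{int(c)}\n")


@dataclass(frozen=True)
class DiagnosticWindow:
    start: int               # 1-based inclusive on the target
    end: int
    length: int
    rel_start: int | None = None   # start-codon-relative, when a map is given
    rel_end: int | None = None

    def to_bed_fields(self, name: str = "window") -> tuple:
        return (name, self.start - 1, self.end)   # 0-based half-open


def _contigs_of(background) -> list[str]:
    """Normalise one background (str, dict, or list of str) to contigs."""
    if isinstance(background, str):
        return [background.upper()]
    if isinstance(background, dict):
        return [s.upper() for s in background.values()]
    return [s.upper() for s in background]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def background_kmer_set(background, k: int) -> set[str]:
    """Canonical k-mer set of one background genome (any chunking of the
    same sequence content that preserves k-mers yields the same set)."""
    out: set[str] = set()
    for contig in _contigs_of(background):
        for i in range(len(contig) - k + 1):
            kmer = contig[i:i + k]
            if _ACGT.issuperset(kmer):
                out.add(canonical(kmer))
    return out


def uniqueness_profile(target: str, backgrounds: list, k: int = DEFAULT_K,
                       target_id: str = "target") -> UniquenessProfile:
    """Per-position count of backgrounds containing the target's k-mer.

    A target k-mer containing an ambiguous base is conservatively marked
    as present in every background (it can never be called unique).
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    target = target.upper()
    if len(target) <= k:
        raise ValueError("target must be longer than k")
    sets = [background_kmer_set(b, k) for b in backgrounds]
    n = len(sets)
    counts = np.zeros(len(target) - k + 1, dtype=np.int32)
    for i in range(len(counts)):
        kmer = target[i:i + k]
        if not _ACGT.issuperset(kmer):
            counts[i] = n
            continue
        canon = canonical(kmer)
        counts[i] = sum(canon in s for s in sets)
    return UniquenessProfile(target_id, k, counts, n)


def diagnostic_windows(profile: UniquenessProfile,
                       min_len: int = DEFAULT_MIN_LEN,
                       coord_map: CoordMap | None = None
                       ) -> list[DiagnosticWindow]:
    """Maximal zero-count runs as base intervals, filtered to >= min_len.

    A run of background-free k-mers starting at positions p..q covers the
    bases p..q+k-1: every k-mer fully inside the reported window is absent
    from all backgrounds.
    """
    counts = profile.counts
    k = profile.k
    windows = []
    i = 0
    while i < len(counts):
        if counts[i] != 0:
            i += 1
            continue
        j = i
        while j + 1 < len(counts) and counts[j + 1] == 0:
            j += 1
        start, end = i + 1, j + 1 + k - 1   # 1-based bases
        if end - start + 1 >= min_len:
            rel = (None, None)
            if coord_map is not None:
                rel = (coord_map.to_rel(start - 1), coord_map.to_rel(end - 1))
            windows.append(DiagnosticWindow(start, end, end - start + 1,
                                            rel[0], rel[1]))
        i = j + 1
    return windows


def unique_base_positions(profile: UniquenessProfile) -> set[int]:
    """1-based base positions covered by some background-free k-mer."""
    out: set[int] = set()
    for i in np.nonzero(profile.counts == 0)[0]:
        out.update(range(int(i) + 1, int(i) + profile.k + 1))
    return out
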