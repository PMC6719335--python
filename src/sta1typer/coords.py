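"""Start-codon-anchored coordinate arithmetic.

The locus coordinate convention follows how promoter intervals are printed
in the molecular-biology literature: 1-based inclusive *relative*
coordinates anchored at the start codon, with no position 0.  Position +1
is the first base of the ATG; position -1 is the base immediately upstream.
The promoter deletion spans -1370..-209 inclusive, which is exactly
1162 bases; the ORF diagnostic interval +65..+143 spans 79 bases.

Internally sequences are stored 0-based half-open; :class:`CoordMap`
converts between the two and survives the excision of the promoter
deletion (deleted relative positions simply have no offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field


def rel_span(start: int, end: int) -> int:
    """Number of bases in the inclusive relative interval ``start..end``.

    There is no position 0: an interval crossing the anchor (start < 0 < end)
    contains ``end - start`` bases, otherwise ``end - start + 1``.
    """
    if start == 0 or end == 0:
        raise ValueError("relative coordinates have no position 0")
    if end < start:
        raise ValueError(f"empty interval {start}..{end}")
    return end - start if start < 0 < end else end - start + 1


@dataclass(frozen=True)
class CoordMap:
    """Piecewise-linear map between relative coordinates and 0-based offsets.

    ``blocks`` is a sorted list of ``(rel_start, rel_end, offset_start)``
    triples; each block is an unbroken stretch of the locus.  Relative
    positions not covered by any block (e.g. inside an excised deletion)
    raise ``KeyError``.
    """

    blocks: tuple[tuple[int, int, int], ...]
    length: int = field(default=0)

    @classmethod
    def contiguous(cls, upstream: int, downstream: int) -> "CoordMap":
        """Map for an intact locus spanning ``-upstream..+downstream``."""
        blocks = []
        if upstream > 0:
            blocks.append((-upstream, -1, 0))
        if downstream > 0:
            blocks.append((1, downstream, upstream))
        return cls(tuple(blocks), length=upstream + downstream)

    def to_offset(self, rel: int) -> int:
        """0-based sequence offset of a relative position."""
        if rel == 0:
            raise KeyError("relative coordinates have no position 0")
        for rel_start, rel_end, off in self.blocks:
            if rel_start <= rel <= rel_end:
                return off + rel_span(rel_start, rel) - 1
        raise KeyError(f"relative position {rel} is not present in this locus")

    def to_rel(self, offset: int) -> int:
        """Relative position of a 0-based sequence offset."""
        for rel_start, rel_end, off in self.blocks:
            span = rel_span(rel_start, rel_end)
            if off <= offset < off + span:
                delta = offset - off
                rel = rel_start + delta
                if rel_start < 0 <= rel:  # skip nonexistent position 0
                    rel += 1
                return rel
        raise KeyError(f"offset {offset} outside locus (length {self.length})")

    def contains(self, rel: int) -> bool:
        try:
            self.to_offset(rel)
            return True
        except KeyError:
            return False

    def slice_offsets(self, rel_start: int, rel_end: int) -> tuple[int, int]:
        """0-based half-open offsets of an inclusive relative interval.

        The interval must lie within a single unbroken block.
        """
        a = self.to_offset(rel_start)
        b = self.to_offset(rel_end)
        if b - a + 1 != rel_span(rel_start, rel_end):
            raise KeyError(f"interval {rel_start}..{rel_end} is broken in this locus")
        return a, b + 1

    def excise(self, rel_start: int, rel_end: int) -> "CoordMap":
        """Map after deleting the inclusive relative interval."""
        a, b = self.slice_offsets(rel_start, rel_end)
        removed = b - a
        out = []
        for rel_s, rel_e, off in self.blocks:
            span = rel_span(rel_s, rel_e)
            cut_lo = max(off, a)
            cut_hi = min(off + span, b)
            if cut_hi <= cut_lo:  # untouched block
                out.append((rel_s, rel_e, off - (removed if off >= b else 0)))
                continue
            if cut_lo > off:  # left remainder
                left_end = self.to_rel(cut_lo - 1)
                out.append((rel_s, left_end, off))
            if cut_hi < off + span:  # right remainder
                right_start = self.to_rel(cut_hi)
                out.append((right_start, rel_e, cut_lo if off < a else off - removed))
        return CoordMap(tuple(sorted(out, key=lambda blk: blk[2])),
                        length=self.length - removed)
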