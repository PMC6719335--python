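"""In-silico PCR: primer annealing, amplicon prediction, multiplex genotyping.

The annealing model is deliberately simple and exhaustive rather than
thermodynamic: a primer binds wherever it aligns ungapped with at most
``max_mismatch`` mismatches *and* its 3'-terminal ``clamp_len`` bases match
exactly (polymerases do not extend a mismatched 3' end).  IUPAC degeneracy
in the primer counts as a match when the template base is in the code's
set; ambiguous template bases never match.  Defaults are exact matching
(max_mismatch=0, clamp_len=3) — the published screening primers match
their targets perfectly — with tolerance available for divergent strains.

Genotype classification implements the published multiplex decision table:
the SD pair (SD-5A/SD-6B, 868 bp) reports the presence of the STA1 gene,
the UAS pair (STA1_UAS_Fw/Rv, 599 bp) binds inside the deletable promoter
region and reports an intact promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import primer_mask, revcomp, template_mask
from .primers import PRIMERS, _MIN_PRIMER_LEN

DEFAULT_MAX_AMPLICON = 10_000   # accommodates the 5.2-kb nested-PCR outer product
DEFAULT_CLAMP_LEN = 3
DEFAULT_MAX_MISMATCH = 0


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < _MIN_PRIMER_LEN:
            raise ValueError(f"primer {self.name} shorter than {_MIN_PRIMER_LEN} nt")
        primer_mask(self.sequence)  # validates the alphabet

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: Primer
    reverse: Primer

    @classmethod
    def from_names(cls, pair_name: str, fwd: str, rev: str,
                   table: dict[str, str] | None = None) -> "PrimerPair":
        table = table if table is not None else PRIMERS
        return cls(pair_name, Primer(fwd, table[fwd]), Primer(rev, table[rev]))


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing position.

    ``pos5`` is the 1-based forward-strand coordinate of the primer's
    5' end: the leftmost base of the site on '+', the rightmost on '-'.
    """

    template_id: str
    strand: str
    pos5: int
    mismatches: int
    clamp_exact: bool = True


@dataclass(frozen=True)
class Amplicon:
    forward_site: BindingSite
    reverse_site: BindingSite
    start: int                  # 1-based inclusive, forward primer 5' end
    end: int                    # 1-based inclusive, reverse primer 5' end
    length: int
    pair_name: str
    is_cross: bool = False

    @property
    def template_id(self) -> str:
        return self.forward_site.template_id


@dataclass
class MultiplexResult:
    template_id: str
    amplicons: list[Amplicon]   # sorted by length, cross-products flagged

    @property
    def primary(self) -> list[Amplicon]:
        return [a for a in self.amplicons if not a.is_cross]

    def by_pair(self) -> dict[str, list[Amplicon]]:
        out: dict[str, list[Amplicon]] = {}
        for a in self.primary:
            out.setdefault(a.pair_name, []).append(a)
        return out


@dataclass(frozen=True)
class GenotypeCall:
    status: str                 # STA1_intact_promoter | STA1_promoter_deleted
    #                           | STA1_negative | anomalous
    evidence: tuple = ()


def _scan(t_mask: np.ndarray, p_mask: np.ndarray, max_mismatch: int,
          clamp_slice: slice) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch counts for every ungapped placement of a pattern.

    Returns (positions, mismatches) for placements with <= max_mismatch
    mismatches and an exact clamp region (given as a slice over pattern
    positions).  Vectorised over the template; equivalent to a sliding
    Hamming scan.
    """
    k, n = len(p_mask), len(t_mask)
    if k > n:
        return np.array([], dtype=int), np.array([], dtype=int)
    n_pos = n - k + 1
    mismatches = np.zeros(n_pos, dtype=np.int32)
    clamp_ok = np.ones(n_pos, dtype=bool)
    clamp_idx = set(range(*clamp_slice.indices(k)))
    for j in range(k):
        hit = (t_mask[j:j + n_pos] & p_mask[j]) != 0
        mismatches += ~hit
        if j in clamp_idx:
            clamp_ok &= hit
    keep = (mismatches <= max_mismatch) & clamp_ok
    pos = np.nonzero(keep)[0]
    return pos, mismatches[pos]


def find_binding_sites(template: str, primer: Primer,
                       max_mismatch: int = DEFAULT_MAX_MISMATCH,
                       clamp_len: int = DEFAULT_CLAMP_LEN,
                       template_id: str = "template") -> list[BindingSite]:
    """All annealing sites of a primer on both strands of a template."""
    if not template:
        raise ValueError("empty template")
    if not (0 <= max_mismatch < len(primer)):
        raise ValueError("max_mismatch must be in [0, primer length)")
    t_mask = template_mask(template)
    k = len(primer)
    sites = []
    # '+' strand: primer as-is, 3' clamp = last clamp_len pattern positions.
    fwd = primer_mask(primer.sequence)
    for pos, mm in zip(*_scan(t_mask, fwd, max_mismatch, slice(k - clamp_len, k))):
        sites.append(BindingSite(template_id, "+", int(pos) + 1, int(mm)))
    # '-' strand: the forward strand carries the primer's reverse complement;
    # the primer 3' end maps to the leftmost pattern position.
    rev = primer_mask(revcomp(primer.sequence))
    for pos, mm in zip(*_scan(t_mask, rev, max_mismatch, slice(0, clamp_len))):
        sites.append(BindingSite(template_id, "-", int(pos) + k, int(mm)))
    return sorted(sites, key=lambda s: (s.pos5, s.strand))


def predict_amplicons(template: str, pair: PrimerPair,
                      max_amplicon: int = DEFAULT_MAX_AMPLICON,
                      max_mismatch: int = DEFAULT_MAX_MISMATCH,
                      clamp_len: int = DEFAULT_CLAMP_LEN,
                      template_id: str = "template",
                      is_cross: bool = False) -> list[Amplicon]:
    """Convergent products of a primer pair, length <= max_amplicon.

    Both orientations are considered (either primer may prime the plus
    strand), so predictions are symmetric under reverse complementation of
    the template.  Amplicon length is the inclusive distance between the
    two primers' 5' ends.
    """
    sites = {p.name: find_binding_sites(template, p, max_mismatch, clamp_len,
                                        template_id)
             for p in (pair.forward, pair.reverse)}
    out = []
    seen = set()
    for left_primer, right_primer in ((pair.forward, pair.reverse),
                                      (pair.reverse, pair.forward)):
        for fs in sites[left_primer.name]:
            if fs.strand != "+":
                continue
            for rs in sites[right_primer.name]:
                if rs.strand != "-" or rs.pos5 <= fs.pos5:
                    continue
                length = rs.pos5 - fs.pos5 + 1
                if length > max_amplicon:
                    continue
                key = (fs.pos5, rs.pos5)
                if key in seen:
                    continue
                seen.add(key)
                out.append(Amplicon(fs, rs, fs.pos5, rs.pos5, length,
                                    pair.name, is_cross))
    return sorted(out, key=lambda a: a.length)


def run_multiplex(template: str, pairs: list[PrimerPair],
                  max_amplicon: int = DEFAULT_MAX_AMPLICON,
                  max_mismatch: int = DEFAULT_MAX_MISMATCH,
                  clamp_len: int = DEFAULT_CLAMP_LEN,
                  template_id: str = "template") -> MultiplexResult:
    """All primary products of each pair plus flagged cross-pair products."""
    if not pairs:
        raise ValueError("at least one primer pair required")
    amps: list[Amplicon] = []
    for pair in pairs:
        amps += predict_amplicons(template, pair, max_amplicon, max_mismatch,
                                  clamp_len, template_id)
    primary_keys = {(a.start, a.end) for a in amps}
    for i, pa in enumerate(pairs):
        for pb in pairs[i + 1:]:
            for fwd, rev in ((pa.forward, pb.reverse), (pb.forward, pa.reverse),
                             (pa.forward, pb.forward), (pa.reverse, pb.reverse)):
                cross = PrimerPair(f"{pa.name}x{pb.name}", fwd, rev)
                for a in predict_amplicons(template, cross, max_amplicon,
                                           max_mismatch, clamp_len,
                                           template_id, is_cross=True):
                    if (a.start, a.end) not in primary_keys:
                        amps.append(a)
    return MultiplexResult(template_id, sorted(amps, key=lambda a: a.length))


def run_multiplex_fasta(records: dict[str, str], pairs: list[PrimerPair],
                        **kwargs) -> MultiplexResult:
    """Multiplex over a multi-FASTA sample: records scanned independently,
    evidence aggregated (a sample is positive if any record is)."""
    amps: list[Amplicon] = []
    for rid, seq in records.items():
        amps += run_multiplex(seq, pairs, template_id=rid, **kwargs).amplicons
    return MultiplexResult("+".join(records), sorted(amps, key=lambda a: a.length))


def classify_sta1(result: MultiplexResult, sd_pair: str = "SD",
                  uas_pair: str = "UAS") -> GenotypeCall:
    """Published multiplex decision table.

    SD & UAS products -> intact promoter; SD only -> promoter deleted;
    neither -> STA1-negative; UAS only -> anomalous (should not occur,
    the UAS site lies inside the gene's own promoter).
    """
    by_pair = result.by_pair()
    known = {a.pair_name for a in result.primary} | {sd_pair, uas_pair}
    unknown = {a.pair_name for a in result.primary} - {sd_pair, uas_pair}
    if unknown:
        raise ValueError(f"result contains unknown primer pairs: {sorted(unknown)}; "
                         f"classification expects the {sd_pair}+{uas_pair} set")
    sd = bool(by_pair.get(sd_pair))
    uas = bool(by_pair.get(uas_pair))
    evidence = tuple(result.primary)
    if sd and uas:
        return GenotypeCall("STA1_intact_promoter", evidence)
    if sd:
        return GenotypeCall("STA1_promoter_deleted", evidence)
    if uas:
        return GenotypeCall("anomalous", evidence)
    return GenotypeCall("STA1_negative", evidence)


def default_detection_pairs() -> list[PrimerPair]:
    """The multiplex set: SD (gene presence) + UAS (intact promoter)."""
    return [PrimerPair.from_names("SD", "SD-5A", "SD-6B"),
            PrimerPair.from_names("UAS", "STA1_UAS_Fw", "STA1_UAS_Rv")]


def qpcr_pairs() -> list[PrimerPair]:
    """The qPCR set: Sdia (79-bp ORF marker) + UAS_Q (223-bp promoter)."""
    return [PrimerPair.from_names("Sdia", "Sdia-f", "Sdia-r"),
            PrimerPair.from_names("UAS_Q", "STA1_UAS_Q_Fw", "STA1_UAS_Rv")]
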