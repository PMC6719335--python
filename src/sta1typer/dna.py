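"""Low-level DNA utilities shared across the package.

Sequences are plain Python ``str`` over the DNA alphabet; numerical code
paths encode them as ``uint8`` arrays, either as raw ASCII (for Hamming
comparisons) or as 4-bit IUPAC membership masks (for degeneracy-aware
primer matching, where a match means the template base is a member of the
primer code's base set).
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes as bitmasks over {A=1, C=2, G=4, T=8}.
IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

BASES = "ACGT"

# ASCII complement table for uint8-encoded ACGT arrays.
_COMP_TAB = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP_TAB[_a] = _b

# Template base -> bitmask; anything that is not an unambiguous ACGT gets
# mask 0 and therefore never matches a primer base (conservative on drafts).
_TMPL_MASK_TAB = np.zeros(256, dtype=np.uint8)
for _c, _m in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
    _TMPL_MASK_TAB[ord(_c)] = _m
    _TMPL_MASK_TAB[ord(_c.lower())] = _m


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def ascii_array(seq: str) -> np.ndarray:
    """Uppercased sequence as a uint8 ASCII array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def revcomp_ascii(arr: np.ndarray) -> np.ndarray:
    return _COMP_TAB[arr][::-1]


def template_mask(seq: str) -> np.ndarray:
    """Template as 4-bit base-set masks; non-ACGT bases become 0 (never match)."""
    return _TMPL_MASK_TAB[ascii_array(seq)]


def primer_mask(seq: str) -> np.ndarray:
    """Primer as 4-bit IUPAC masks. Raises on non-IUPAC characters."""
    try:
        return np.array([IUPAC_MASK[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"non-IUPAC base in primer: {exc.args[0]!r}") from None


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform-random ACGT sequence of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(ascii_array(a) != ascii_array(b)))


# ---------------------------------------------------------------------------
# FASTA / FASTQ round trips (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_fastq(path) -> list[tuple[str, str]]:
    """Read FASTQ as ``[(read_id, sequence), ...]`` (qualities dropped)."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path, reads, quality_char: str = "I") -> None:
    """Write ``(read_id, sequence)`` pairs as Phred+33 FASTQ with a constant
    quality string (the simulator carries no per-base quality model)."""
    with open(path, "w") as handle:
        for rid, seq in reads:
            handle.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
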