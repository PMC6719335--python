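"""Synthetic chimeric-locus, genome, read and mixture generators.

The generators emulate the genetics of the *STA1* locus of diastatic
*S. cerevisiae*: a chimeric glucoamylase gene whose 5' end (promoter and
the start of the ORF) derives from a *FLO11*-like parent and whose 3' end
derives from a *SGA1*-like parent.  Two promoter variants exist — intact,
and a 1162-bp deletion spanning relative positions -1370..-209 that
removes the upstream activation sequence and with it most expression.

Two short regions are diagnostic for the chimera (absent from both
parents): a 79-bp ORF window at +65..+143 that spans the *FLO11*/*SGA1*
junction and is delimited by the Sdia-f/Sdia-r qPCR primers, and a 101-bp
window at -923..-823 inside the deletable promoter region.  The published
detection primers are planted at their published amplicon geometry
(SD-5A/SD-6B -> 868 bp, STA1_UAS_Fw/Rv -> 599 bp, STA1_UAS_Q_Fw/Rv ->
223 bp, Sdia-f/r -> 79 bp, full-locus nested pair -> 5104 bp), so every
downstream stage — PCR, marker scanning, uniqueness profiling, depth
genotyping — can be tested against a known truth without external data.

Backgrounds are uniform-random ACGT: the only homology in a simulated
genome is the designed parent/chimera relationship, which is the
confounder the downstream coverage filter has to defeat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .coords import CoordMap, rel_span
from .dna import random_dna, revcomp, write_fasta, write_fastq
from .primers import PRIMERS

# Locus architecture constants (relative coordinates, 1-based inclusive).
PROMOTER_LEN = 2500
DELETION_INTERVAL = (-1370, -209)          # 1162 bp promoter deletion
ORF_MARKER = (65, 143)                     # 79 bp, spans the chimera junction
PROMOTER_MARKER = (-923, -823)             # 101 bp, inside the deletion
JUNCTION_POS = 105                         # first SGA1-derived ORF base
_FLO11_CDS_USED = JUNCTION_POS - 1         # 104 bp of FLO11-like coding used

DEFAULT_FLO11_LEN = 3600                   # 2500 promoter + 1100 coding
DEFAULT_SGA1_LEN = 2500
DEFAULT_K_UNIQUE = 21

# Planted primer sites: (primer name, strand, relative 5' coordinate).
# On '+' the 5' coordinate is the leftmost base of the site; on '-' the
# rightmost.  Spacings reproduce the published amplicon sizes.
_PLANT_SITES = (
    ("STA1_Full_Fw", "+", -PROMOTER_LEN),
    ("STA1_1055_F", "+", -1446),
    ("STA1_UAS_Fw", "+", -870),
    ("STA1_UAS_Q_Fw", "+", -494),
    ("STA1_UAS_Rv", "-", -272),
    ("Sdia-f", "+", ORF_MARKER[0]),
    ("Sdia-r", "-", ORF_MARKER[1]),
    ("STA1_2951_R", "-", 451),
    ("SD-5A", "+", 1600),
    ("SD-6B", "-", 2467),
    ("STA1_Full_Rv", "-", None),           # None -> locus 3' end
)

STATES = ("absent", "intact", "promoter_deleted")


@dataclass(frozen=True)
class ParentGenes:
    """Stand-ins for the two parent genes of the chimera."""

    flo11_like: str
    sga1_like: str
    seed: int


@dataclass(frozen=True)
class LocusModel:
    """An annotated chimeric STA1 locus.

    ``windows`` holds the named diagnostic intervals in relative
    coordinates; on a promoter-deleted locus the promoter-side windows are
    still listed but have no offsets (``coord_map`` raises for them).
    """

    sequence: str
    promoter_variant: str                   # 'intact' | 'deleted'
    coord_map: CoordMap
    junction_pos: int
    windows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def window_sequence(self, name: str) -> str:
        start, end = self.windows[name]
        a, b = self.coord_map.slice_offsets(start, end)
        return self.sequence[a:b]

    @property
    def orf_marker_seq(self) -> str:
        return self.window_sequence("orf_marker")

    @property
    def promoter_marker_seq(self) -> str:
        return self.window_sequence("promoter_marker")


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        out.add(min(kmer, revcomp(kmer)))
    return out


def generate_parent_genes(seed: int,
                          flo11_len: int = DEFAULT_FLO11_LEN,
                          sga1_len: int = DEFAULT_SGA1_LEN,
                          k_unique: int = DEFAULT_K_UNIQUE) -> ParentGenes:
    """Draw the two parent sequences, guaranteed to share no ``k_unique``-mer.

    ``flo11_len`` must cover the 2500-bp promoter plus the 104 bp of coding
    sequence donated to the chimera; ``sga1_len`` must reach the most
    distal planted primer site (2500 bp).
    """
    if flo11_len < PROMOTER_LEN + _FLO11_CDS_USED:
        raise ValueError(f"flo11_len must be >= {PROMOTER_LEN + _FLO11_CDS_USED}")
    if sga1_len < DEFAULT_SGA1_LEN:
        raise ValueError(f"sga1_len must be >= {DEFAULT_SGA1_LEN} to carry the "
                         "planted detection-primer sites")
    rng = np.random.default_rng(seed)
    flo11 = random_dna(rng, flo11_len)
    flo11_kmers = _canonical_kmers(flo11, k_unique)
    while True:  # collision probability ~1e-6 per draw; loop is formal
        sga1 = random_dna(rng, sga1_len)
        if not (flo11_kmers & _canonical_kmers(sga1, k_unique)):
            break
    return ParentGenes(flo11_like=flo11, sga1_like=sga1, seed=seed)


def _plant(seq: list[str], cmap: CoordMap, name: str, strand: str, rel5) -> None:
    primer = PRIMERS[name]
    if strand == "+":
        rel_start = rel5
        site = primer
    else:
        end = rel5 if rel5 is not None else cmap.to_rel(cmap.length - 1)
        rel_start = cmap.to_rel(cmap.to_offset(end) - len(primer) + 1)
        site = revcomp(primer)
    a = cmap.to_offset(rel_start)
    if a + len(site) > cmap.length:
        raise ValueError(f"primer site {name} falls outside the constructed locus")
    seq[a:a + len(site)] = site


def build_sta1_locus(parents: ParentGenes, variant: str = "intact") -> LocusModel:
    """Assemble the chimeric locus from the parents.

    Intact layout: positions -2500..-1 are the FLO11-like promoter, the ORF
    is FLO11-like up to the junction and SGA1-like after it.  The two
    diagnostic marker windows are then overwritten with locus-private
    (seeded random) sequence and all detection-primer sites are planted.
    The 'deleted' variant excises relative positions -1370..-209.
    """
    if variant not in ("intact", "deleted"):
        raise ValueError(f"unknown promoter variant {variant!r}")
    orf_len = _FLO11_CDS_USED + len(parents.sga1_like)
    cmap = CoordMap.contiguous(PROMOTER_LEN, orf_len)
    seq = list(parents.flo11_like[:PROMOTER_LEN + _FLO11_CDS_USED]
               + parents.sga1_like)

    # Locus-private marker windows (divergence of the chimera from its
    # parents), drawn deterministically from the parent seed.
    rng = np.random.default_rng(np.random.SeedSequence([parents.seed, 0xC1A]))
    for start, end in (PROMOTER_MARKER, ORF_MARKER):
        a, b = cmap.slice_offsets(start, end)
        seq[a:b] = random_dna(rng, b - a)
    for name, strand, rel5 in _PLANT_SITES:
        _plant(seq, cmap, name, strand, rel5)

    windows = {
        "orf_marker": ORF_MARKER,
        "promoter_marker": PROMOTER_MARKER,
        "deletion": DELETION_INTERVAL,
    }
    locus = LocusModel("".join(seq), "intact", cmap, JUNCTION_POS, windows)
    return locus if variant == "intact" else delete_promoter(locus)


def delete_promoter(locus: LocusModel) -> LocusModel:
    """Excise the 1162-bp promoter deletion from an intact locus."""
    if locus.promoter_variant != "intact":
        raise ValueError("promoter already deleted")
    a, b = locus.coord_map.slice_offsets(*DELETION_INTERVAL)
    return LocusModel(
        sequence=locus.sequence[:a] + locus.sequence[b:],
        promoter_variant="deleted",
        coord_map=locus.coord_map.excise(*DELETION_INTERVAL),
        junction_pos=locus.junction_pos,
        windows=dict(locus.windows),
    )


# ---------------------------------------------------------------------------
# Whole-genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """Ground-truth genotype of one simulated strain.

    ``states`` holds one STA1 state per haplotype; ``extra_copies`` adds
    head-to-tail tandem cassette copies on that haplotype.  The two
    haplotypes of a diploid share one background sequence (homologous
    chromosomes) and, when ``include_parents`` is set, one planted copy
    each of the FLO11-like and SGA1-like parents — the homology that makes
    naive whole-gene coverage uninterpretable.
    """

    states: tuple[str, ...] = ("intact", "intact")
    extra_copies: tuple[int, ...] = ()
    background_length: int = 200_000
    include_parents: bool = True
    seed: int = 0

    @property
    def ploidy(self) -> int:
        return len(self.states)

    def __post_init__(self):
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        for s in self.states:
            if s not in STATES:
                raise ValueError(f"unknown STA1 state {s!r}")
        extras = self.extra_copies or (0,) * self.ploidy
        if len(extras) != self.ploidy or any(e < 0 for e in extras):
            raise ValueError("extra_copies must give one value >= 0 per haplotype")
        object.__setattr__(self, "extra_copies", tuple(extras))


@dataclass
class TruthTable:
    """Simulator-emitted ground truth for recovery testing."""

    sample_id: str
    states: tuple[str, ...]
    ploidy: int
    copies: dict[str, int]                  # per diagnostic window
    zygosity: str
    mixture_fraction: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tploidy\tstates\torf_marker_copies\t"
                     "promoter_marker_copies\tzygosity\tmixture_fraction\n")
            fh.write(f"{self.sample_id}\t{self.ploidy}\t{','.join(self.states)}\t"
                     f"{self.copies['orf_marker']}\t{self.copies['promoter_marker']}\t"
                     f"{self.zygosity}\t{self.mixture_fraction or ''}\n")


@dataclass
class SimulatedGenome:
    """Haplotype sequences plus truth and the matching depth reference."""

    haplotypes: dict[str, str]
    truth: TruthTable
    reference: dict[str, str]               # background + cassette contig
    windows: dict[str, tuple[str, int, int]]  # name -> (contig, start, end) 1-based
    locus: LocusModel

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.haplotypes.values())

    def write_fasta(self, path) -> None:
        write_fasta(path, self.haplotypes)

    def write_reference(self, path) -> None:
        write_fasta(path, self.reference)


def _zygosity_truth(orf: int, prom: int, ploidy: int) -> str:
    # Shared with the depth caller so truth and call use one vocabulary.
    from .coverage import zygosity_from_copies
    return zygosity_from_copies(orf, prom, ploidy)


def build_genome(spec: GenotypeSpec, locus: LocusModel,
                 parents: ParentGenes | None = None,
                 sample_id: str = "sample") -> SimulatedGenome:
    """Assemble haplotype sequences with known STA1 content.

    ``locus`` must be the intact LocusModel; the deleted variant is derived
    from it for promoter_deleted haplotypes.  When ``include_parents`` is
    set, one copy of each original parent gene is planted in the background
    (the parents differ from the cassette at the diverged marker windows,
    which is precisely what keeps those windows diagnostic).  The depth
    reference mirrors the published procedure of appending the intact locus
    to a STA1-free reference genome as a separate contig.
    """
    if locus.promoter_variant != "intact":
        raise ValueError("build_genome expects the intact locus model")
    if spec.include_parents and parents is None:
        raise ValueError("include_parents requires the ParentGenes object")
    deleted = delete_promoter(locus)
    cassette = {"absent": "", "intact": locus.sequence,
                "promoter_deleted": deleted.sequence}

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xBE]))
    bg = random_dna(rng, spec.background_length)
    inserts_len = (len(locus.sequence) * (1 + max(spec.extra_copies, default=0)))
    if spec.background_length < 2 * inserts_len:
        raise ValueError("background too short for the requested insertions")

    # Fixed fractional anchors keep layouts comparable across seeds.
    l = spec.background_length
    a_flo, a_sga, a_cas = int(0.25 * l), int(0.45 * l), int(0.70 * l)
    if spec.include_parents:
        flo11_copy, sga1_copy = parents.flo11_like, parents.sga1_like
    else:
        flo11_copy = sga1_copy = ""

    haplotypes = {}
    for h, (state, extra) in enumerate(zip(spec.states, spec.extra_copies), 1):
        cas = cassette[state] * (1 + extra) if state != "absent" else ""
        hap = (bg[:a_flo] + flo11_copy + bg[a_flo:a_sga] + sga1_copy
               + bg[a_sga:a_cas] + cas + bg[a_cas:])
        haplotypes[f"{sample_id}_hap{h}"] = hap

    orf_copies = sum((1 + e) for s, e in zip(spec.states, spec.extra_copies)
                     if s != "absent")
    prom_copies = sum((1 + e) for s, e in zip(spec.states, spec.extra_copies)
                      if s == "intact")
    truth = TruthTable(
        sample_id=sample_id, states=spec.states, ploidy=spec.ploidy,
        copies={"orf_marker": orf_copies, "promoter_marker": prom_copies},
        zygosity=_zygosity_truth(orf_copies, prom_copies, spec.ploidy),
    )

    ref_bg = bg[:a_flo] + flo11_copy + bg[a_flo:a_sga] + sga1_copy + bg[a_sga:]
    reference = {"background": ref_bg, "STA1_locus": locus.sequence}
    windows = {}
    for name in ("orf_marker", "promoter_marker"):
        a, b = locus.coord_map.slice_offsets(*locus.windows[name])
        windows[name] = ("STA1_locus", a + 1, b)  # 1-based inclusive
    return SimulatedGenome(haplotypes, truth, reference, windows, locus)


@dataclass(frozen=True)
class ReadSimParams:
    """Uniform-error short-read simulation parameters.

    ``target_coverage`` is the expected depth of each haplotype: every
    haplotype receives ``ceil(coverage x total_length / read_length /
    n_haplotypes)`` reads.  Mapped onto a single (haploid) reference the
    haplotypes stack, so a diploid simulated at 50x shows a genome-wide
    median depth near 100 — the usual situation for a diploid isolate
    sequenced at 50x per homolog.
    """

    read_length: int = 150
    target_coverage: float = 50.0
    substitution_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.substitution_rate < 0.1):
            raise ValueError("substitution_rate must be in [0, 0.1)")
        if self.target_coverage <= 0:
            raise ValueError("coverage must be positive")


def simulate_reads(haplotypes: dict[str, str] | list[str],
                   params: ReadSimParams) -> list[tuple[str, str]]:
    """Draw uniform single-end reads with per-base substitution errors.

    Reads come from both strands; read count per haplotype is proportional
    to haplotype length.  Deterministic for a given seed.
    """
    if isinstance(haplotypes, dict):
        haps = list(haplotypes.items())
    else:
        haps = [(f"hap{i+1}", s) for i, s in enumerate(haplotypes)]
    lengths = [len(s) for _, s in haps]
    if min(lengths) < params.read_length:
        raise ValueError("read_length exceeds the shortest haplotype")
    total = sum(lengths)
    n_hap = len(haps)
    n_per_hap = int(np.ceil(params.target_coverage * total
                            / (params.read_length * n_hap)))
    n_total = n_per_hap * n_hap

    rng = np.random.default_rng(params.seed)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate(b"ACGT"):
        code_of[c] = i
    comp = {65: 84, 67: 71, 71: 67, 84: 65}
    comp_tab = np.arange(256, dtype=np.uint8)
    for k, v in comp.items():
        comp_tab[k] = v

    reads: list[tuple[str, str]] = []
    L = params.read_length
    # Largest-remainder split of n_total across haplotypes by length.
    quota = [n_total * ln / total for ln in lengths]
    counts = [int(q) for q in quota]
    for _ in range(n_total - sum(counts)):
        j = int(np.argmax([q - c for q, c in zip(quota, counts)]))
        counts[j] += 1

    for (name, seq), n_reads in zip(haps, counts):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        starts = rng.integers(0, len(seq) - L + 1, size=n_reads)
        mat = arr[starts[:, None] + np.arange(L)]
        if params.substitution_rate > 0:
            err = rng.random(mat.shape) < params.substitution_rate
            # substitute with one of the three other bases, uniformly
            shift = rng.integers(1, 4, size=int(err.sum()))
            codes = code_of[mat[err]]
            mat[err] = base_codes[(codes + shift) % 4]
        flip = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            row = mat[i]
            if flip[i]:
                row = comp_tab[row][::-1]
                strand = "-"
            else:
                strand = "+"
            reads.append((f"{name}:{starts[i]+1}:{strand}:{i}",
                          row.tobytes().decode()))
    return reads


def simulate_mixture(reads_background: list[tuple[str, str]],
                     reads_diastatic: list[tuple[str, str]],
                     fraction: float, seed: int = 0,
                     n_out: int | None = None
                     ) -> tuple[list[tuple[str, str]], dict]:
    """Contaminate a background read pool with a diastatic strain.

    Draws ``k ~ Binomial(n_out, fraction)`` diastatic reads and
    ``n_out - k`` background reads, each without replacement, emulating a
    fixed-size sequencing aliquot of a contaminated culture.  Returns the
    shuffled pool and a truth record with the realised composition.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if fraction == 1:
        return list(reads_diastatic), {"fraction": 1.0,
                                       "n_diastatic": len(reads_diastatic),
                                       "n_total": len(reads_diastatic)}
    n = n_out if n_out is not None else len(reads_background)
    k = min(int(rng.binomial(n, fraction)), len(reads_diastatic))
    if n - k > len(reads_background):
        raise ValueError("not enough background reads for the requested pool")
    dia_idx = rng.choice(len(reads_diastatic), size=k, replace=False)
    bg_idx = rng.choice(len(reads_background), size=n - k, replace=False)
    pool = [reads_diastatic[i] for i in dia_idx] + \
           [reads_background[i] for i in bg_idx]
    order = rng.permutation(len(pool))
    mixed = [pool[i] for i in order]
    return mixed, {"fraction": fraction, "n_diastatic": int(k), "n_total": n}


def simulate_ct_table(fold_changes: dict[str, float],
                      target: str = "STA1",
                      refs: tuple[str, ...] = ("ALG9", "UBC6"),
                      n_bio: int = 4, n_tech: int = 2,
                      noise_sd: float = 0.2, seed: int = 0,
                      base_ct: float = 25.0, ref_ct: float = 18.0):
    """Synthesise a qPCR Ct table encoding known expression fold changes.

    The first listed sample with fold 1 is a natural calibrator.  Gaussian
    cycle noise of ``noise_sd`` is added independently to every technical
    measurement.  Returns a tidy DataFrame (sample, bio_rep, gene, ct).
    """
    import pandas as pd
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fold in fold_changes.items():
        for rep in range(1, n_bio + 1):
            for gene in (target, *refs):
                true_ct = ref_ct if gene != target else base_ct - np.log2(fold)
                for _ in range(n_tech):
                    rows.append((sample, rep, gene,
                                 float(true_ct + rng.normal(0, noise_sd))))
    return pd.DataFrame(rows, columns=["sample", "bio_rep", "gene", "ct"])


def write_reads(path, reads) -> None:
    write_fastq(path, reads)
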