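"""Synthetic transgenic-genome and paired-end read simulator.

Emulates the sequencing design behind the integration-site mapping pipeline:
a hemizygous diploid host (one wild-type haplotype, one carrying the
insertions), a multi-copy transgene concatemer inserted at two nearby loci
with a target-site deletion at one and a target-site duplication at the
other, short homologies to the I-SceI site planted at the junctions, and
2x101 bp paired-end reads from ~350 bp fragments.

Depth convention: ``depth`` is the fold-coverage observed at an ordinary
diploid position of the (haploid) reference, i.e. total sequenced bases
divided by the haploid genome length.  Fragments are spread across both
haplotypes in proportion to their lengths, so each haplotype contributes
about ``depth/2`` and a normal host base shows ``depth``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .reference import (
    Assembly,
    CombinedReference,
    Contig,
    GenomicInterval,
    TransgeneConstruct,
    build_combined_reference,
    encode_seq,
    decode_seq,
    revcomp,
)

I_SCEI_SITE = "TAGGGATAACAGGGTAAT"  # canonical 18-bp recognition sequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b
_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_IDX[_a] = _i


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class InsertionEvent:
    """One insertion: payload DNA spliced between host boundaries L and R.

    ``left_boundary`` (L) is the 1-based position of the last host base before
    the inserted DNA; ``right_boundary`` (R) the first host base after it.
    R = L+1 is a blunt insertion, R > L+1 deletes host bases L+1..R-1, and
    R <= L duplicates host bases R..L in tandem around the payload.
    """

    contig: str
    left_boundary: int
    right_boundary: int
    payload: str
    copies: int = 1
    orientations: tuple[str, ...] = ("+",)

    def __post_init__(self) -> None:
        if self.left_boundary < 1 or self.right_boundary < 1:
            raise SimulationError("boundaries must be >= 1")
        if self.copies < 1:
            raise SimulationError("copies must be >= 1")
        if len(self.orientations) != self.copies:
            raise SimulationError("one orientation per copy required")


def make_event(
    contig: str,
    left: int,
    right: int,
    construct: TransgeneConstruct,
    copies: int,
    orientations: Sequence[str] | None = None,
) -> InsertionEvent:
    """Build an InsertionEvent whose payload is a concatemer of construct copies."""
    orients = tuple(orientations) if orientations else ("+",) * copies
    parts = [construct.sequence if o == "+" else revcomp(construct.sequence) for o in orients]
    return InsertionEvent(contig, left, right, "".join(parts), copies, orients)


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 101
    fragment_mean: float = 350.0
    fragment_sd: float = 35.0
    depth: float = 19.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.depth <= 0 or self.fragment_mean <= 0:
            raise SimulationError("read_length, fragment_mean and depth must be positive")
        if self.read_length > self.fragment_mean:
            raise SimulationError("read_length must not exceed fragment_mean")
        if not (0.0 <= self.error_rate < 1.0):
            raise SimulationError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class Segment:
    """Maps a run of haplotype coordinates onto the combined reference.

    ``allele_start0`` is 0-based on the haplotype contig; ``ref_start0`` is
    0-based on ``ref_contig``.  For strand '-' the run is the reverse
    complement of the reference slice.
    """

    allele_start0: int
    length: int
    ref_contig: str
    ref_start0: int
    strand: str = "+"

    @property
    def allele_end0(self) -> int:
        return self.allele_start0 + self.length


@dataclass
class Haplotype:
    label: str
    assembly: Assembly
    segments: dict[str, list[Segment]]  # per haplotype contig


def make_wildtype_haplotype(host: Assembly, label: str = "wt") -> Haplotype:
    segs = {c.name: [Segment(0, len(c), c.name, 0, "+")] for c in host}
    return Haplotype(label, host, segs)


def simulate_host_genome(
    length: int,
    gc: float = 0.4,
    plant: Sequence[tuple[int, str]] = (),
    seed: int = 0,
    name: str = "chr1",
) -> Assembly:
    """An i.i.d. random host contig at the requested GC, with optional planted
    motifs (e.g. the construct's promoter at its endogenous locus).

    ``plant`` is a sequence of (1-based start, sequence) to overwrite.
    """
    if length < 1:
        raise SimulationError("length must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    for start1, seq in plant:
        if start1 < 1 or start1 - 1 + len(seq) > length:
            raise SimulationError(
                f"planted motif at {start1} (len {len(seq)}) exceeds contig of {length}"
            )
        arr[start1 - 1 : start1 - 1 + len(seq)] = encode_seq(seq)
    return Assembly([Contig(name, decode_seq(arr))])


def apply_insertion_events(
    host: Assembly,
    events: Sequence[InsertionEvent],
    construct: TransgeneConstruct | None = None,
    label: str = "tg",
) -> Haplotype:
    """Splice insertion payloads into one haplotype of the host.

    The sister haplotype is left wild-type by the caller (hemizygosity).
    Returns the transgenic haplotype with its coordinate segment map; payload
    segments map to the construct contig when ``construct`` is given.
    """
    by_contig: dict[str, list[InsertionEvent]] = {}
    for ev in events:
        if ev.contig not in host:
            raise SimulationError(f"event contig {ev.contig!r} not in host")
        clen = len(host[ev.contig])
        if ev.left_boundary > clen or ev.right_boundary > clen:
            raise SimulationError("event boundaries outside contig")
        by_contig.setdefault(ev.contig, []).append(ev)

    contigs: list[Contig] = []
    segmaps: dict[str, list[Segment]] = {}
    for c in host:
        evs = sorted(by_contig.get(c.name, []), key=lambda e: e.left_boundary)
        for a, b in zip(evs, evs[1:]):
            if b.left_boundary < a.right_boundary:
                raise SimulationError("overlapping insertion events")
        parts: list[str] = []
        segs: list[Segment] = []
        cursor1 = 1  # next host base (1-based) to emit
        pos0 = 0  # current haplotype length
        for ev in evs:
            host_part = c.sequence[cursor1 - 1 : ev.left_boundary]
            if host_part:
                segs.append(Segment(pos0, len(host_part), c.name, cursor1 - 1, "+"))
                parts.append(host_part)
                pos0 += len(host_part)
            if construct is not None and len(ev.payload) == ev.copies * len(construct):
                clen = len(construct)
                for j, o in enumerate(ev.orientations):
                    segs.append(Segment(pos0 + j * clen, clen, construct.name, 0, o))
            elif construct is not None:
                raise SimulationError("payload length inconsistent with construct copies")
            parts.append(ev.payload)
            pos0 += len(ev.payload)
            cursor1 = ev.right_boundary
        tail = c.sequence[cursor1 - 1 :]
        if tail:
            segs.append(Segment(pos0, len(tail), c.name, cursor1 - 1, "+"))
            parts.append(tail)
            pos0 += len(tail)
        contigs.append(Contig(c.name, "".join(parts)))
        segmaps[c.name] = segs
    return Haplotype(label, Assembly(contigs), segmaps)


@dataclass
class ReadSet:
    """In-memory paired reads with their ground-truth origins.

    ``r1``/``r2`` are (n_pairs, read_length) uint8 base matrices as sequenced.
    Origins are per pair: haplotype index, contig, 0-based start of each
    read's span on the haplotype forward strand, and the read's strand
    relative to the haplotype.
    """

    read_length: int
    r1: np.ndarray
    r2: np.ndarray
    hap_idx: np.ndarray
    contig: np.ndarray  # object array of contig names
    r1_start0: np.ndarray
    r1_strand: np.ndarray  # bool: True = '-'
    r2_start0: np.ndarray
    r2_strand: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def name(self, i: int) -> str:
        return f"sim{i:07d}"

    def r1_seq(self, i: int) -> str:
        return decode_seq(self.r1[i])

    def r2_seq(self, i: int) -> str:
        return decode_seq(self.r2[i])


def _revcomp_rows(mat: np.ndarray, rows: np.ndarray) -> None:
    mat[rows] = _COMP_LUT[mat[rows]][:, ::-1]


def simulate_reads(haplotypes: Sequence[Haplotype], params: ReadSimParams) -> ReadSet:
    """Draw paired-end reads from the diploid pair of haplotypes.

    Fragment starts are uniform over each haplotype; lengths are
    Normal(fragment_mean, fragment_sd) truncated to >= read_length; read 1 is
    the fragment prefix and read 2 the reverse complement of the suffix, on a
    uniformly random fragment strand; substitution errors are i.i.d. at
    ``error_rate``.  Seeded and reproducible.
    """
    if not haplotypes or any(len(h.assembly) == 0 for h in haplotypes):
        raise SimulationError("need nonempty haplotypes")
    rng = np.random.default_rng(params.seed)
    rl = params.read_length

    units = []  # (hap_idx, contig_name, length)
    for hi, hap in enumerate(haplotypes):
        for c in hap.assembly:
            if len(c) < rl:
                raise SimulationError(f"contig {c.name} shorter than read length")
            units.append((hi, c.name, len(c)))
    lengths = np.array([u[2] for u in units], dtype=np.float64)
    total_len = lengths.sum()
    haploid_len = total_len / len(haplotypes)
    n_pairs = int(round(params.depth * haploid_len / (2 * rl)))

    unit_idx = rng.choice(len(units), size=n_pairs, p=lengths / total_len)
    frag_len = np.rint(rng.normal(params.fragment_mean, params.fragment_sd, n_pairs)).astype(np.int64)
    frag_len = np.clip(frag_len, rl, lengths[unit_idx].astype(np.int64))
    max_start = lengths[unit_idx].astype(np.int64) - frag_len
    start = np.floor(rng.random(n_pairs) * (max_start + 1)).astype(np.int64)
    flip = rng.random(n_pairs) < 0.5

    # per-pair spans on the haplotype forward strand
    fwd_start = np.where(flip, start + frag_len - rl, start)
    rev_start = np.where(flip, start, start + frag_len - rl)
    r1_start0, r1_neg = fwd_start, flip.copy()
    r2_start0, r2_neg = rev_start, ~flip

    arrs = {ui: encode_seq(haplotypes[hi].assembly[cn].sequence) for ui, (hi, cn, _) in enumerate(units)}
    offs = np.zeros(len(units), dtype=np.int64)
    acc = 0
    big_parts = []
    for ui in range(len(units)):
        offs[ui] = acc
        big_parts.append(arrs[ui])
        acc += len(arrs[ui])
    big = np.concatenate(big_parts) if big_parts else np.empty(0, dtype=np.uint8)

    def gather(start0: np.ndarray, neg: np.ndarray) -> np.ndarray:
        idx = offs[unit_idx][:, None] + start0[:, None] + np.arange(rl)[None, :]
        mat = big[idx]
        negrows = np.flatnonzero(neg)
        if negrows.size:
            _revcomp_rows(mat, negrows)
        return mat

    r1 = gather(r1_start0, r1_neg)
    r2 = gather(r2_start0, r2_neg)

    if params.error_rate > 0:
        for mat in (r1, r2):
            err = rng.random(mat.shape) < params.error_rate
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                old = _BASE_IDX[mat[err]]
                mat[err] = _BASES[(old + shift) % 4]

    return ReadSet(
        read_length=rl,
        r1=r1,
        r2=r2,
        hap_idx=np.array([units[u][0] for u in unit_idx], dtype=np.int64),
        contig=np.array([units[u][1] for u in unit_idx], dtype=object),
        r1_start0=r1_start0,
        r1_strand=r1_neg,
        r2_start0=r2_start0,
        r2_strand=r2_neg,
    )


def write_fastq_pair(reads: ReadSet, path1: str | Path, path2: str | Path) -> tuple[Path, Path]:
    """Write the pair as Phred+33 FASTQ with fixed quality 'I'."""
    qual = "I" * reads.read_length
    for path, mat in ((path1, reads.r1), (path2, reads.r2)):
        with open(path, "w") as fh:
            out = []
            for i in range(reads.n_pairs):
                out.append(f"@{reads.name(i)}\n{decode_seq(mat[i])}\n+\n{qual}\n")
            fh.write("".join(out))
    return Path(path1), Path(path2)


def _locate(segs: list[Segment], s0: int, e0: int) -> tuple[Segment, int, int]:
    """Anchor segment (max overlap with [s0, e0)) and the overlap interval."""
    best = None
    for seg in segs:
        o1 = max(s0, seg.allele_start0)
        o2 = min(e0, seg.allele_end0)
        if o2 - o1 > 0 and (best is None or o2 - o1 > best[2] - best[1]):
            best = (seg, o1, o2)
    if best is None:
        raise SimulationError("read span outside haplotype segments")
    return best


def emit_truth_sam(
    reads: ReadSet,
    haplotypes: Sequence[Haplotype],
    reference: CombinedReference,
    path: str | Path,
    promoter_equiv: tuple[GenomicInterval, GenomicInterval] | None = None,
) -> Path:
    """Write the alignments each read would receive against the combined
    reference under perfect local alignment.

    Reads wholly inside host or construct segments map contiguously;
    junction-spanning reads are soft-clipped at the true breakpoint.  When
    ``promoter_equiv`` gives the (host interval, construct interval) pair of
    identical promoter copies, reads falling entirely inside either copy are
    multi-mapping by construction: they are placed at the host copy (the
    lexicographically smallest placement) and flagged MAPQ 0, mirroring a
    deterministic tie-breaking aligner.
    """
    rl = reads.read_length
    lines = [f"@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in reference.contig_items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")

    equiv = None
    if promoter_equiv is not None:
        hiv, civ = promoter_equiv
        if hiv.length != civ.length:
            raise SimulationError("promoter equivalence intervals differ in length")
        equiv = (hiv, civ)

    recs: list[list] = []  # [qname, flag, rname, pos1, mapq, cigar, seq, is_read1, strand]
    qual = "I" * rl
    for i in range(reads.n_pairs):
        hap = haplotypes[reads.hap_idx[i]]
        cn = reads.contig[i]
        segs = hap.segments[cn]
        for is_r1, s0, neg, mat in (
            (True, int(reads.r1_start0[i]), bool(reads.r1_strand[i]), reads.r1),
            (False, int(reads.r2_start0[i]), bool(reads.r2_strand[i]), reads.r2),
        ):
            seg, o1, o2 = _locate(segs, s0, s0 + rl)
            m = o2 - o1
            left_clip = o1 - s0  # in haplotype-forward orientation
            right_clip = s0 + rl - o2
            if seg.strand == "+":
                ref0 = seg.ref_start0 + (o1 - seg.allele_start0)
                lclip, rclip = left_clip, right_clip
                seq_fwd = True
            else:
                ref0 = seg.ref_start0 + (seg.allele_end0 - o2)
                lclip, rclip = right_clip, left_clip
                seq_fwd = False
            rname, pos1, mapq = seg.ref_contig, ref0 + 1, 60
            if equiv is not None:
                hiv, civ = equiv
                s1, e1 = pos1, pos1 + m - 1
                in_host = rname == hiv.contig and s1 >= hiv.start and e1 <= hiv.end
                in_con = rname == civ.contig and s1 >= civ.start and e1 <= civ.end
                if lclip == 0 and rclip == 0 and (in_host or in_con):
                    if in_con:  # relocate to the host copy (canonical tie-break)
                        pos1 = hiv.start + (pos1 - civ.start)
                        rname = hiv.contig
                    mapq = 0
            # sequence oriented to the reference forward strand
            row = mat[i]
            allele_fwd = _COMP_LUT[row][::-1] if neg else row
            seq_arr = allele_fwd if seq_fwd else _COMP_LUT[allele_fwd][::-1]
            rec_neg = neg if seq_fwd else not neg
            cigar = ""
            if lclip:
                cigar += f"{lclip}S"
            cigar += f"{m}M"
            if rclip:
                cigar += f"{rclip}S"
            flag = 0x1 | 0x40 if is_r1 else 0x1 | 0x80
            if rec_neg:
                flag |= 0x10
            recs.append([reads.name(i), flag, rname, pos1, mapq, cigar, decode_seq(seq_arr), rec_neg, m])

    # mate fields and proper-pair flags
    out = []
    for j in range(0, len(recs), 2):
        a, b = recs[j], recs[j + 1]
        for rec, mate in ((a, b), (b, a)):
            flag = rec[1]
            if mate[7]:
                flag |= 0x20
            same = rec[2] == mate[2]
            if same and rec[7] != mate[7]:
                span = abs(rec[3] - mate[3]) + rl
                if span <= 350 + 4 * 35 + rl:
                    flag |= 0x2
            rnext = "=" if same else mate[2]
            tlen = 0
            if same:
                tlen = (mate[3] + mate[8]) - rec[3] if mate[3] >= rec[3] else -((rec[3] + rec[8]) - mate[3])
            out.append(
                f"{rec[0]}\t{flag}\t{rec[2]}\t{rec[3]}\t{rec[4]}\t{rec[5]}\t{rnext}\t{mate[3]}\t{tlen}\t{rec[6]}\t{qual}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines + out) + "\n")
    return Path(path)


def default_construct(name: str = "transgene", seed: int = 1729) -> TransgeneConstruct:
    """An 8 kb stand-in cassette: I-SceI site, ~3.9 kb promoter, ~700 bp eGFP
    coding sequence, ~3 kb vector backbone, inverted I-SceI site.

    Deterministic and independent of scenario seeds, so the same construct is
    shared by all simulations.
    """
    rng = np.random.default_rng(seed)
    length = 8000
    arr = rng.choice(_BASES, size=length)
    feats = {
        "isce1_site_left": GenomicInterval(name, 1, 18, "+"),
        "promoter": GenomicInterval(name, 101, 4000, "+"),
        "egfp": GenomicInterval(name, 4101, 4800, "+"),
        "vector": GenomicInterval(name, 4901, 7900, "+"),
        "isce1_site_right": GenomicInterval(name, 7983, 8000, "-"),
    }
    arr[0:18] = encode_seq(I_SCEI_SITE)
    arr[7982:8000] = encode_seq(revcomp(I_SCEI_SITE))
    return TransgeneConstruct(decode_seq(arr), feats, name)


@dataclass
class PaperScenario:
    """One-call fixture: toy chromosome with the reference two-locus geometry.

    Two insertion events 108 bp apart — an 11-bp target-site deletion at the
    first and a 15-bp target-site duplication at the second — carrying six
    construct copies in total, the endogenous promoter planted elsewhere on
    the chromosome, and I-SceI-homologous microhomology at the junctions.
    """

    reference: CombinedReference
    construct: TransgeneConstruct
    haplotypes: list[Haplotype]
    reads: ReadSet
    events: list[InsertionEvent]
    promoter_host_interval: GenomicInterval
    expected_copies: dict[str, int]
    params: ReadSimParams
    planted_motifs: dict[str, GenomicInterval] = field(default_factory=dict)

    @property
    def truth_boundaries(self) -> list[tuple[int, int]]:
        return [(e.left_boundary, e.right_boundary) for e in self.events]

    def truth_json(self) -> dict:
        return {
            "events": [
                {
                    "contig": e.contig,
                    "left_boundary": e.left_boundary,
                    "right_boundary": e.right_boundary,
                    "copies": e.copies,
                    "orientations": list(e.orientations),
                }
                for e in self.events
            ],
            "expected_copies": self.expected_copies,
            "promoter_host_interval": [
                self.promoter_host_interval.start,
                self.promoter_host_interval.end,
            ],
            "n_pairs": self.reads.n_pairs,
            "params": {
                "read_length": self.params.read_length,
                "fragment_mean": self.params.fragment_mean,
                "fragment_sd": self.params.fragment_sd,
                "depth": self.params.depth,
                "error_rate": self.params.error_rate,
                "seed": self.params.seed,
            },
        }

    def write_truth(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            json.dump(self.truth_json(), fh, indent=1)
        return Path(path)


# inter-site flank homology motif ("purple box" stand-in)
_FLANK_HOMOLOGY_MOTIF = "GCTGAGGC"


def paper_scenario(
    seed: int = 1,
    host_length: int = 1_000_000,
    depth: float = 20.0,
    read_length: int = 101,
    fragment_mean: float = 350.0,
    fragment_sd: float = 35.0,
    error_rate: float = 0.001,
    copies_per_site: tuple[int, int] = (3, 3),
) -> PaperScenario:
    """Build the full fixture: combined reference, diploid haplotypes and reads.

    The insertion geometry reproduces, on a toy chromosome, the reference
    offsets: I1 left/right boundaries L and L+12 (11-bp deletion), I2
    boundaries L+134/L+120 (15-bp duplication), closest boundaries 108 bp
    apart; six construct copies split between the two payloads (3+3
    head-to-tail by default).  Junction microhomology is planted in the host:
    a recognition-site fragment upstream of I1, the 4-nt 3' overhang (ATAA)
    downstream of I2, and a shared 8-mer upstream of both sites.
    """
    if host_length < 50_000:
        raise SimulationError("paper_scenario needs a host of at least 50 kb")
    construct = default_construct()
    overhang = "ATAA"
    # insertion loci at 60% of the toy chromosome, promoter at 20%; the
    # boundary offsets around the site base fix the reference geometry
    site_base = int(host_length * 0.6)
    promoter_start = int(host_length * 0.2) + 1
    L1, R1 = site_base, site_base + 12
    L2, R2 = site_base + 134, site_base + 120

    # Guard bases: the host base immediately inside each lesion must differ
    # from the construct base a junction-crossing read continues into.  If
    # they matched, the breakpoint would be genuinely ambiguous (the same
    # read admits two equal-scoring placements one base apart), so no caller
    # could recover the generating coordinates exactly.  The planted
    # homology motifs sit in the flanks, not across the cut.
    guard_in = "C" if construct.sequence[0] != "C" else "A"   # vs construct 5' base
    guard_out = "C" if construct.sequence[-1] != "C" else "A"  # vs construct 3' base
    plants = [
        (promoter_start, construct.feature_seq("promoter")),
        (L1 - 5, I_SCEI_SITE[:6]),  # recognition-site remnant upstream of I1
        (R2, overhang),  # overhang homology downstream of I2
        (L1 - 28, _FLANK_HOMOLOGY_MOTIF),  # shared upstream flank motif
        (L2 - 28, _FLANK_HOMOLOGY_MOTIF),
        (L1 + 1, guard_in),
        (R1 - 1, guard_out),
        (L2 + 1, guard_in),
        (R2 - 1, guard_out),
    ]
    host = simulate_host_genome(host_length, gc=0.4, plant=plants, seed=seed, name="chr1")

    c1, c2 = copies_per_site
    events = [
        make_event("chr1", L1, R1, construct, c1),
        make_event("chr1", L2, R2, construct, c2),
    ]
    tg = apply_insertion_events(host, events, construct=construct)
    wt = make_wildtype_haplotype(host)

    params = ReadSimParams(
        read_length=read_length,
        fragment_mean=fragment_mean,
        fragment_sd=fragment_sd,
        depth=depth,
        error_rate=error_rate,
        seed=seed,
    )
    reads = simulate_reads([wt, tg], params)
    reference = build_combined_reference(host, construct)
    prom_len = construct.features["promoter"].length
    prom_iv = GenomicInterval("chr1", promoter_start, promoter_start + prom_len - 1)

    planted = {
        "recognition_site_remnant": GenomicInterval("chr1", L1 - 5, L1),
        "overhang": GenomicInterval("chr1", R2, R2 + 3),
        "flank_homology_I1": GenomicInterval("chr1", L1 - 28, L1 - 21),
        "flank_homology_I2": GenomicInterval("chr1", L2 - 28, L2 - 21),
    }
    return PaperScenario(
        reference=reference,
        construct=construct,
        haplotypes=[wt, tg],
        reads=reads,
        events=events,
        promoter_host_interval=prom_iv,
        expected_copies={"promoter": c1 + c2, "egfp": c1 + c2, "vector": c1 + c2},
        params=params,
        planted_motifs=planted,
    )


def promoter_equivalence(scenario: PaperScenario) -> tuple[GenomicInterval, GenomicInterval]:
    """The (host, construct) interval pair of the two identical promoter copies."""
    return scenario.promoter_host_interval, scenario.construct.features["promoter"]
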