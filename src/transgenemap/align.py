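"""Desk-scale paired-end aligner with end-to-end and local (soft-clipping) modes.

Seed-and-verify design: exact k-mer seeds (packed 2-bit rolling hash over the
forward strand of the combined reference; the read and its reverse complement
are both queried) nominate candidate diagonals, which are scored by
vectorised ungapped comparison.  Local mode finds the best-scoring contiguous
sub-segment of each diagonal (maximum-sum subarray), so terminal read bases
that cross an integration junction are soft-clipped exactly at the
breakpoint.  An affine-gap dynamic-programming rescue on the candidate window
handles the rare read whose ungapped score falls below threshold.

SAM interop goes through pysam, so an externally produced SAM can be
substituted for this aligner at any point downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .reference import CombinedReference, encode_seq, decode_seq
from .simulate import ReadSet

_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _a in enumerate(b"ACGT"):
    _CODE[_a] = _i


class AlignerError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_local_score: int = 20
    # end-to-end alignments scoring below this fraction of the perfect score
    # are reported unmapped
    min_e2e_frac: float = 0.4
    # best placement must beat the runner-up by this margin to count as unique
    unique_margin: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise AlignerError("match must be positive, penalties nonpositive")


@dataclass
class AlignmentRecord:
    """One read's placement on the combined reference (or unmapped).

    ``pos`` is 1-based leftmost; ``cigar`` is a list of (op, length) with op in
    {M,S,I,D}, expressed in reference-forward (SEQ) orientation; ``seq`` is the
    read sequence in that same orientation.
    """

    query_name: str
    is_read1: bool
    contig: str | None
    pos: int
    strand: str
    cigar: list[tuple[str, int]]
    score: int
    unique: bool
    seq: str
    mate_contig: str | None = None
    mate_pos: int = 0
    proper_pair: bool = False

    @property
    def is_mapped(self) -> bool:
        return self.contig is not None

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position."""
        return self.pos + self.ref_span - 1

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"


def parse_cigar(text: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string like '60M41S' into [(op, length), ...]."""
    if text == "*":
        return []
    out: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in "MSIDH":
                raise AlignerError(f"bad CIGAR {text!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise AlignerError(f"bad CIGAR {text!r}")
    return out


def _hash_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit hashes of all length-k windows along the last axis.

    Returns (hashes, valid) where windows containing non-ACGT bases are
    flagged invalid.
    """
    n = codes.shape[-1] - k + 1
    if n <= 0:
        raise AlignerError("sequence shorter than k")
    h = np.zeros(codes.shape[:-1] + (n,), dtype=np.int64)
    bad = np.zeros_like(h, dtype=bool)
    for i in range(k):
        sl = codes[..., i : i + n]
        h = (h << 2) | np.maximum(sl, 0)
        bad |= sl < 0
    return h, ~bad


class SeedIndex:
    """Sorted-hash exact k-mer index over the forward strand of the reference."""

    def __init__(self, reference: CombinedReference, k: int = 21):
        if k < 2 or k > 31:
            raise AlignerError("k must be in [2, 31]")
        items = reference.contig_items()
        shortest = min(len(seq) for _, seq in items)
        if k > shortest:
            raise AlignerError(f"k={k} exceeds shortest contig length {shortest}")
        self.reference = reference
        self.k = k
        self.names = [name for name, _ in items]
        self.lengths = np.array([len(seq) for _, seq in items], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.big = np.concatenate([encode_seq(seq) for _, seq in items])
        codes = _CODE[self.big]
        h, valid = _hash_windows(codes, k)
        # windows crossing a contig boundary must not seed
        for off in self.offsets[1:-1]:
            valid[max(0, off - k + 1) : off] = False
        pos = np.flatnonzero(valid)
        hv = h[pos]
        order = np.argsort(hv, kind="stable")
        self.sorted_hash = hv[order]
        self.sorted_pos = pos[order]

    def lookup_hash(self, h: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_hash, h, side="left")
        hi = np.searchsorted(self.sorted_hash, h, side="right")
        return self.sorted_pos[lo:hi]

    def positions(self, kmer: str) -> np.ndarray:
        """Forward-strand global positions of an exact k-mer."""
        codes = _CODE[encode_seq(kmer.upper())]
        if len(codes) != self.k or (codes < 0).any():
            raise AlignerError("kmer length/content mismatch")
        h = 0
        for c in codes:
            h = (h << 2) | int(c)
        return np.sort(self.lookup_hash(h))

    def contig_of(self, gpos: int) -> tuple[int, str, int]:
        """(contig index, contig name, 0-based local position) of a global offset."""
        ci = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return ci, self.names[ci], gpos - int(self.offsets[ci])


def build_index(reference: CombinedReference, k: int = 21) -> SeedIndex:
    """Exact k-mer lookup table over the combined reference (both strands are
    served by querying the read and its reverse complement)."""
    return SeedIndex(reference, k)


def _best_local_segment(scores: np.ndarray) -> tuple[int, int, int]:
    """Maximum-sum contiguous segment (half-open [i0, i1)) of a score array."""
    cm = np.concatenate([[0], np.cumsum(scores)])
    pm = np.minimum.accumulate(cm[:-1])
    gains = cm[1:] - pm
    j = int(np.argmax(gains))
    score = int(gains[j])
    i1 = j + 1
    i0 = int(np.argmin(cm[: i1]))
    return i0, i1, score


def sw_affine(
    query: np.ndarray,
    ref: np.ndarray,
    scoring: ScoringScheme,
    local: bool = True,
) -> tuple[int, list[tuple[str, int]], int, int, int]:
    """Affine-gap dynamic programming on small instances.

    Returns (score, cigar, ref_start, query_start, query_end) with the cigar
    in query orientation (terminal S ops are added by the caller).  In
    end-to-end mode the full query must be consumed but the reference window
    start remains free (glocal), matching how reads sit inside a candidate
    window.
    """
    n, m = len(query), len(ref)
    NEG = -(10 ** 9)
    go, ge, ma, mi = scoring.gap_open, scoring.gap_extend, scoring.match, scoring.mismatch
    # H: aligned state; E: gap in query (consumes ref -> D); F: gap in ref (I)
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, :] = 0  # free ref start in both modes
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(m + 1):
            F[i, j] = max(H[i - 1, j] + go, F[i - 1, j] + ge)
            if j > 0:
                E[i, j] = max(H[i, j - 1] + go, E[i, j - 1] + ge)
                s = ma if ref[j - 1] == qi else mi
                h = max(H[i - 1, j - 1] + s, E[i, j], F[i, j])
            else:
                h = F[i, j]
            if local:
                h = max(h, 0)
            H[i, j] = h
    if local:
        i_best, j_best = np.unravel_index(int(np.argmax(H)), H.shape)
    else:
        i_best, j_best = n, int(np.argmax(H[n]))
    score = int(H[i_best, j_best])
    # traceback through explicit state checks
    ops: list[str] = []
    i, j = int(i_best), int(j_best)
    state = "H"
    while i > 0:
        if local and state == "H" and H[i, j] == 0:
            break
        if state == "H":
            if j > 0 and H[i, j] == H[i - 1, j - 1] + (ma if ref[j - 1] == query[i - 1] else mi):
                ops.append("M")
                i, j = i - 1, j - 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                break
        elif state == "E":
            ops.append("D")
            if E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            ops.append("I")
            if F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    q0, r0 = i, j
    cigar: list[tuple[str, int]] = []
    for op in reversed(ops):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return score, cigar, r0, q0, int(i_best)


_CODE_MAP = {65: 0, 67: 1, 71: 2, 84: 3}


def _kmer_hash(b: bytes, off: int, k: int) -> int | None:
    """Packed 2-bit hash of b[off:off+k]; None if it contains non-ACGT."""
    h = 0
    get = _CODE_MAP.get
    for c in b[off : off + k]:
        v = get(c)
        if v is None:
            return None
        h = (h << 2) | v
    return h


@dataclass
class _Candidate:
    gstart: int  # global position of read base 0 on the diagonal
    strand: str


class _ReadAligner:
    """Shared seed-and-verify machinery for both alignment modes."""

    def __init__(self, index: SeedIndex, scoring: ScoringScheme):
        self.index = index
        self.scoring = scoring

    def _seed_offsets(self, read_len: int) -> list[int]:
        k = self.index.k
        if read_len < k:
            raise AlignerError("read shorter than k")
        mids = [0, (read_len - k) // 2, read_len - k]
        return sorted(set(mids))

    def candidates(self, arr: np.ndarray) -> list[_Candidate]:
        k = self.index.k
        L = len(arr)
        rc = _COMP_LUT[arr][::-1]
        out: dict[tuple[int, str], None] = {}
        offsets = self._seed_offsets(L)
        for strand, a in (("+", arr), ("-", rc)):
            b = a.tobytes()
            for o in offsets:
                h = _kmer_hash(b, o, k)
                if h is None:
                    continue
                for p in self.index.lookup_hash(h):
                    out[(int(p) - o, strand)] = None
        return [_Candidate(g, s) for (g, s) in out]

    def _diag_scores(self, arr: np.ndarray, cand: _Candidate) -> tuple[np.ndarray, int, int, int]:
        """Per-base +match/-mismatch scores along the candidate diagonal,
        restricted to the containing contig; returns (scores, lo, hi, ci)."""
        L = len(arr)
        a = arr if cand.strand == "+" else _COMP_LUT[arr][::-1]
        idx = self.index
        ci, _, local0 = idx.contig_of(min(max(cand.gstart, 0), len(idx.big) - 1))
        c_lo = int(idx.offsets[ci])
        c_hi = int(idx.offsets[ci + 1])
        lo = max(0, c_lo - cand.gstart)
        hi = min(L, c_hi - cand.gstart)
        if hi <= lo:
            return np.empty(0, dtype=np.int64), lo, lo, ci
        ref = idx.big[cand.gstart + lo : cand.gstart + hi]
        eq = ref == a[lo:hi]
        scores = np.where(eq, self.scoring.match, self.scoring.mismatch).astype(np.int64)
        return scores, lo, hi, ci

    def align(self, name: str, seq: str, is_read1: bool, local: bool) -> AlignmentRecord:
        arr = encode_seq(seq.upper())
        L = len(arr)
        sc = self.scoring
        results = []  # (score, contig_name, pos1, strand, cigar, ci)
        for cand in self.candidates(arr):
            scores, lo, hi, ci = self._diag_scores(arr, cand)
            if hi - lo <= 0:
                continue
            if local:
                i0, i1, s = _best_local_segment(scores)
                i0, i1 = i0 + lo, i1 + lo
                cigar = []
                if i0:
                    cigar.append(("S", i0))
                cigar.append(("M", i1 - i0))
                if L - i1:
                    cigar.append(("S", L - i1))
                pos0 = cand.gstart + i0 - int(self.index.offsets[ci])
            else:
                if lo != 0 or hi != L:
                    continue  # would run off the contig: no end-to-end placement here
                s = int(scores.sum())
                cigar = [("M", L)]
                pos0 = cand.gstart - int(self.index.offsets[ci])
            results.append((s, self.index.names[ci], pos0 + 1, cand.strand, cigar))

        threshold = sc.min_local_score if local else int(np.ceil(sc.min_e2e_frac * sc.match * L))
        if not results:
            return _unmapped(name, seq, is_read1)

        results.sort(key=lambda r: (-r[0], r[1], r[2], r[3]))
        best = results[0]
        # DP rescue: a gapped alignment on the best candidate window may beat
        # the ungapped score when the read carries an indel.  In local mode a
        # lone substitution can clip at most ~5 terminal bases, so a larger
        # clip on an imperfect alignment is an indel suspect worth the DP;
        # genuine chimeric clips simply fail to improve and are kept as-is.
        clips = sum(n for op, n in best[4] if op == "S")
        indel_suspect = local and best[0] < sc.match * L and clips >= 6
        if best[0] < threshold or indel_suspect:
            best = self._dp_rescue(arr, results, local) or best
        if best[0] < threshold:
            return _unmapped(name, seq, is_read1)
        second = None
        for r in results[1:]:
            if (r[1], r[2], r[3]) != (best[1], best[2], best[3]):
                second = r
                break
        unique = second is None or best[0] >= second[0] + sc.unique_margin
        a = arr if best[3] == "+" else _COMP_LUT[arr][::-1]
        return AlignmentRecord(
            query_name=name,
            is_read1=is_read1,
            contig=best[1],
            pos=best[2],
            strand=best[3],
            cigar=best[4],
            score=best[0],
            unique=unique,
            seq=decode_seq(a),
        )

    def _dp_rescue(self, arr: np.ndarray, results: list, local: bool, pad: int = 12):
        sc = self.scoring
        s0, cname, pos1, strand, cig0 = results[0]
        idx = self.index
        ci = idx.names.index(cname)
        c_lo, c_hi = int(idx.offsets[ci]), int(idx.offsets[ci + 1])
        # pos1 locates the first M base; step back over a leading soft clip so
        # the DP window covers the whole read
        lead = cig0[0][1] if cig0 and cig0[0][0] == "S" else 0
        g = c_lo + pos1 - 1 - lead
        L = len(arr)
        w_lo = max(c_lo, g - pad)
        w_hi = min(c_hi, g + L + pad)
        ref = idx.big[w_lo:w_hi]
        a = arr if strand == "+" else _COMP_LUT[arr][::-1]
        score, cigar, r0, q0, q1 = sw_affine(a, ref, sc, local=local)
        if score <= s0 or not cigar:
            return None
        full = []
        if local and q0:
            full.append(("S", q0))
        full.extend(cigar)
        if local and L - q1:
            full.append(("S", L - q1))
        if not local and (q0 != 0 or q1 != L):
            return None
        pos0 = w_lo + r0 - c_lo
        return (score, cname, pos0 + 1, strand, full)


def _unmapped(name: str, seq: str, is_read1: bool) -> AlignmentRecord:
    return AlignmentRecord(name, is_read1, None, 0, ".", [], 0, False, seq)


def align_end_to_end(
    read: str | tuple[str, str], index: SeedIndex, scoring: ScoringScheme = ScoringScheme()
) -> AlignmentRecord:
    """Best full-length alignment (no soft clips), or unmapped."""
    name, seq = read if isinstance(read, tuple) else ("read", read)
    return _ReadAligner(index, scoring).align(name, seq, True, local=False)


def align_local(
    read: str | tuple[str, str], index: SeedIndex, scoring: ScoringScheme = ScoringScheme()
) -> AlignmentRecord:
    """Best local alignment; flanks may be soft-clipped."""
    name, seq = read if isinstance(read, tuple) else ("read", read)
    return _ReadAligner(index, scoring).align(name, seq, True, local=True)


@dataclass(frozen=True)
class InsertModel:
    fragment_mean: float = 350.0
    fragment_sd: float = 35.0

    @property
    def max_span(self) -> float:
        return self.fragment_mean + 4 * self.fragment_sd


def _pair_flags(a: AlignmentRecord, b: AlignmentRecord, insert: InsertModel) -> None:
    for rec, mate in ((a, b), (b, a)):
        rec.mate_contig = mate.contig
        rec.mate_pos = mate.pos
    proper = False
    if a.is_mapped and b.is_mapped and a.contig == b.contig and a.strand != b.strand:
        span = max(a.end, b.end) - min(a.pos, b.pos) + 1
        proper = span <= insert.max_span
    a.proper_pair = b.proper_pair = proper


def align_pairs(
    reads: ReadSet | Iterable[tuple[str, str, str]],
    index: SeedIndex,
    scoring: ScoringScheme = ScoringScheme(),
    insert: InsertModel = InsertModel(),
    mode: str = "local",
) -> list[AlignmentRecord]:
    """Align mate pairs and set mate/proper-pair flags.

    ``reads`` is either a simulator ReadSet or an iterable of
    (name, seq1, seq2).  Proper pairs map to the same contig on opposite
    strands with an implied fragment within mean + 4 sd.
    """
    if mode not in ("local", "end_to_end"):
        raise AlignerError(f"unknown mode {mode!r}")
    local = mode == "local"
    aligner = _ReadAligner(index, scoring)
    out: list[AlignmentRecord] = []
    if isinstance(reads, ReadSet):
        items = ((reads.name(i), reads.r1_seq(i), reads.r2_seq(i)) for i in range(reads.n_pairs))
    else:
        items = reads
    for name, s1, s2 in items:
        if s1 is None or s2 is None:
            raise AlignerError("desynchronised mate input")
        a = aligner.align(name, s1, True, local)
        b = aligner.align(name, s2, False, local)
        _pair_flags(a, b, insert)
        out.extend((a, b))
    return out


_OP_TO_PYSAM = {"M": 0, "I": 1, "D": 2, "S": 4}
_PYSAM_TO_OP = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def write_sam(
    records: Sequence[AlignmentRecord], reference: CombinedReference, path: str | Path
) -> Path:
    """Write records as headered SAM.  MAPQ encodes the unique flag (60/0)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.contig_items()],
    }
    names = [sq["SN"] for sq in header["SQ"]]
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = rec.query_name
            flag = 0x1
            flag |= 0x40 if rec.is_read1 else 0x80
            if not rec.is_mapped:
                flag |= 0x4
            elif rec.strand == "-":
                flag |= 0x10
            if rec.proper_pair:
                flag |= 0x2
            if rec.mate_contig is None:
                flag |= 0x8
            seg.flag = flag
            if rec.is_mapped:
                seg.reference_id = names.index(rec.contig)
                seg.reference_start = rec.pos - 1
                seg.mapping_quality = 60 if rec.unique else 0
                seg.cigartuples = [(_OP_TO_PYSAM[op], n) for op, n in rec.cigar]
                seg.set_tag("AS", rec.score)
            else:
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            if rec.mate_contig is not None:
                seg.next_reference_id = names.index(rec.mate_contig)
                seg.next_reference_start = rec.mate_pos - 1
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            seg.query_sequence = rec.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            fh.write(seg)
    return Path(path)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read a SAM file (ours or third-party) into AlignmentRecords.

    The unique flag is taken as MAPQ > 0; the score from the AS tag when
    present.
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            mapped = not seg.is_unmapped
            cigar = []
            if mapped and seg.cigartuples:
                for code, n in seg.cigartuples:
                    if code == 5:  # hard clips carry no sequence
                        continue
                    if code not in _PYSAM_TO_OP:
                        raise AlignerError(f"unsupported CIGAR op code {code}")
                    op = _PYSAM_TO_OP[code]
                    if cigar and cigar[-1][0] == op:
                        cigar[-1] = (op, cigar[-1][1] + n)
                    else:
                        cigar.append((op, n))
            score = seg.get_tag("AS") if seg.has_tag("AS") else 0
            out.append(
                AlignmentRecord(
                    query_name=seg.query_name,
                    is_read1=not seg.is_read2,
                    contig=seg.reference_name if mapped else None,
                    pos=(seg.reference_start + 1) if mapped else 0,
                    strand=("-" if seg.is_reverse else "+") if mapped else ".",
                    cigar=[(op, n) for op, n in cigar],
                    score=int(score),
                    unique=mapped and seg.mapping_quality > 0,
                    seq=seg.query_sequence or "",
                    mate_contig=seg.next_reference_name,
                    mate_pos=(seg.next_reference_start + 1) if seg.next_reference_id >= 0 else 0,
                    proper_pair=seg.is_proper_pair,
                )
            )
    return out
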