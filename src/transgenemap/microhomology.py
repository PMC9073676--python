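"""Junction microhomology annotation for the MMEJ integration model.

I-SceI cleaves its 18-bp nonpalindromic recognition site leaving a 4-nt
3' overhang, so a linearised cassette carries recognition-site remnants at
its termini.  Microhomology-mediated end joining (MMEJ) anneals resected
double-strand-break ends over short (>= 2 bp) exact homologies, leaving
deletions and sometimes tandem duplications at the repaired junction.  This
module scans the genomic flanks of called integration boundaries for exact
matches to the construct termini (recognition site and overhang) and for
flank-flank homology between adjacent sites — the sequence evidence behind
an MMEJ-insertion-plus-tandem-duplication model.

Matches are exact only: the motifs involved are a handful of bases long, and
at that scale a fuzzy match is indistinguishable from chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .junctions import IntegrationSite
from .reference import Assembly, CombinedReference, GenomicInterval, TransgeneConstruct, revcomp

I_SCEI_RECOGNITION = "TAGGGATAACAGGGTAAT"


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class CleavageModel:
    """A nuclease cut model: where the two strands are cut within the site.

    ``top_cut``/``bottom_cut`` count bases of the recognition sequence to the
    left of each strand's cut (bottom offsets expressed in top-strand
    coordinates).  top_cut > bottom_cut leaves a 3' overhang, the reverse a
    5' overhang, equality a blunt end.
    """

    recognition_sequence: str = I_SCEI_RECOGNITION
    top_cut: int = 9
    bottom_cut: int = 5

    def __post_init__(self) -> None:
        n = len(self.recognition_sequence)
        if not (0 <= self.top_cut <= n and 0 <= self.bottom_cut <= n):
            raise ModelError("cut offsets outside the recognition site")

    @property
    def overhang_kind(self) -> str:
        if self.top_cut == self.bottom_cut:
            return "blunt"
        return "3prime" if self.top_cut > self.bottom_cut else "5prime"


def cleavage_overhang(model: CleavageModel) -> tuple[str, int]:
    """The single-stranded overhang left by cutting at the model's offsets."""
    lo, hi = sorted((model.top_cut, model.bottom_cut))
    seq = model.recognition_sequence[lo:hi]
    return seq, len(seq)


@dataclass(frozen=True)
class MicrohomologyHit:
    """One maximal exact match between a genomic flank and a target sequence.

    Offsets are 0-based into the forward flank and the target; ``strand`` is
    the flank strand on which the match lies.
    """

    flank_offset: int
    target_offset: int
    length: int
    seq: str
    strand: str = "+"
    label: str = ""


def _maximal_matches(a: str, b: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact common substrings (offset_a, offset_b, length).

    Seeded on shared ``min_len``-mers and extended to maximality; a match is
    kept only if it cannot be extended on either end.
    """
    if min_len < 2:
        raise ModelError("min_len must be >= 2")
    k = min_len
    seeds: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        seeds.setdefault(b[j : j + k], []).append(j)
    out: set[tuple[int, int, int]] = set()
    for i in range(len(a) - k + 1):
        for j in seeds.get(a[i : i + k], ()):
            li, lj = i, j
            while li > 0 and lj > 0 and a[li - 1] == b[lj - 1]:
                li, lj = li - 1, lj - 1
            ri, rj = i + k, j + k
            while ri < len(a) and rj < len(b) and a[ri] == b[rj]:
                ri, rj = ri + 1, rj + 1
            out.add((li, lj, ri - li))
    return sorted(out, key=lambda t: (-t[2], t[0], t[1]))


def scan_microhomology(
    flank_seq: str,
    construct_terminal_seq: str,
    min_len: int = 3,
    label: str = "",
) -> list[MicrohomologyHit]:
    """Maximal exact matches between a genomic flank (both strands) and a
    construct terminal window, sorted by length then offset."""
    if not flank_seq or not construct_terminal_seq:
        raise ModelError("both sequences must be nonempty")
    flank = flank_seq.upper()
    target = construct_terminal_seq.upper()
    hits: list[MicrohomologyHit] = []
    for strand, f in (("+", flank), ("-", revcomp(flank))):
        for i, j, n in _maximal_matches(f, target, min_len):
            off = i if strand == "+" else len(flank) - (i + n)
            hits.append(MicrohomologyHit(off, j, n, f[i : i + n], strand, label))
    hits.sort(key=lambda h: (-h.length, h.flank_offset, h.target_offset, h.strand))
    return hits


def scan_flank_homology(upstream_flank: str, downstream_flank: str, min_len: int = 4) -> list[MicrohomologyHit]:
    """Maximal exact same-strand matches between two genomic flanks
    (duplication-mediating homology)."""
    if not upstream_flank or not downstream_flank:
        raise ModelError("both flanks must be nonempty")
    return [
        MicrohomologyHit(i, j, n, upstream_flank.upper()[i : i + n], "+", "flank")
        for i, j, n in _maximal_matches(upstream_flank.upper(), downstream_flank.upper(), min_len)
    ]


def _host_flank(host: Assembly | CombinedReference, contig: str, pos: int, side: str, flank_len: int) -> str:
    """Genomic flank adjacent to a boundary: upstream (ending at pos) for a
    left boundary, downstream (starting at pos) for a right boundary."""
    length = host.length(contig) if isinstance(host, CombinedReference) else len(host[contig])
    if side == "left":
        lo, hi = max(1, pos - flank_len + 1), pos
    else:
        lo, hi = pos, min(length, pos + flank_len - 1)
    iv = GenomicInterval(contig, lo, hi)
    return host.fetch(iv)


def _contains_overhang(seq: str, overhang: str) -> bool:
    return bool(overhang) and (overhang in seq or overhang in revcomp(seq))


def _classify_hit(hit: MicrohomologyHit, overhang: str, site_seq: str) -> str:
    if _contains_overhang(hit.seq, overhang):
        return "overhang"
    if hit.seq in site_seq or hit.seq in revcomp(site_seq):
        return "recognition-site"
    return "other"


def mmej_report(
    sites: Sequence[IntegrationSite],
    host: Assembly | CombinedReference,
    construct: TransgeneConstruct,
    model: CleavageModel = CleavageModel(),
    flank_len: int = 30,
    min_len: int = 3,
    dup_min_len: int = 4,
) -> dict:
    """Per-boundary homology to the construct termini and per-site-pair
    tandem-duplication signature.

    For each boundary: the junction flank sequence, whether the I-SceI
    overhang appears in the flank, and the longest recognition-site match.
    For each adjacent site pair: upstream-flank homology and a flag set when
    one site carries a target-site duplication and the inter-site flank
    homology reaches ``dup_min_len`` — the signature of an initial MMEJ
    insertion followed by tandem duplication.
    """
    overhang, ov_len = cleavage_overhang(model)
    left_terminal = construct.sequence[:flank_len]
    right_terminal = construct.sequence[-flank_len:]
    site_seq = model.recognition_sequence

    boundaries = []
    for si, site in enumerate(sites, 1):
        for b in (site.left, site.right):
            flank = _host_flank(host, b.contig, b.pos, b.side, flank_len)
            terminal = left_terminal if b.construct_terminus == "start" else right_terminal
            hits = scan_microhomology(flank, terminal, min_len=min_len)
            rec_hits = scan_microhomology(flank, site_seq, min_len=min_len)
            ov_in_flank = overhang in flank if ov_len else False
            ov_hit_len = max((h.length for h in hits if _contains_overhang(h.seq, overhang)), default=0)
            boundaries.append(
                {
                    "site": f"I{si}",
                    "side": b.side,
                    "contig": b.contig,
                    "pos": b.pos,
                    "junction_flank": flank,
                    "overhang_match": bool(ov_in_flank and ov_hit_len >= ov_len),
                    "overhang_match_length": ov_hit_len if ov_in_flank else 0,
                    "recognition_site_match_length": rec_hits[0].length if rec_hits else 0,
                    "top_hits": [
                        {
                            "seq": h.seq,
                            "length": h.length,
                            "flank_offset": h.flank_offset,
                            "target_offset": h.target_offset,
                            "strand": h.strand,
                            "matched_element": _classify_hit(h, overhang, site_seq),
                        }
                        for h in hits[:5]
                    ],
                }
            )

    pairs = []
    ordered = sorted(sites, key=lambda s: min(s.boundary_positions))
    for a, b in zip(ordered, ordered[1:]):
        up_a = _host_flank(host, a.left.contig, a.left.pos, "left", flank_len)
        up_b = _host_flank(host, b.left.contig, b.left.pos, "left", flank_len)
        hom = scan_flank_homology(up_a, up_b, min_len=dup_min_len)
        has_dup = any(s.lesion.kind == "duplication" for s in (a, b))
        pairs.append(
            {
                "sites": [f"I{ordered.index(a) + 1}", f"I{ordered.index(b) + 1}"],
                "upstream_flank_homology_length": hom[0].length if hom else 0,
                "upstream_flank_homology_seq": hom[0].seq if hom else "",
                "tandem_duplication_signature": bool(has_dup and hom and hom[0].length >= dup_min_len),
            }
        )

    return {
        "cleavage_model": {
            "recognition_sequence": model.recognition_sequence,
            "overhang": overhang,
            "overhang_length": ov_len,
            "overhang_kind": model.overhang_kind,
        },
        "boundaries": boundaries,
        "site_pairs": pairs,
    }
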