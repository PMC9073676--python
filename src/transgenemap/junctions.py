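"""Integration-site calling from discordant pairs and soft-clipped reads.

Evidence model:

* junction pairs — read pairs with one mate on the transgene contig (or in
  the promoter-homology region, whose reads cannot be told apart from the
  construct's promoter copy) and the other mate mapped uniquely elsewhere on
  the host.  They localise a site to within a fragment length.
* split reads — locally aligned reads with a terminal soft clip whose
  clipped portion realigns to the other side of the junction.  The clip
  point gives the boundary at base-pair resolution.

Boundaries cluster by position/side/terminus, pair into integration sites,
and the relative order of the left (last host base before the insert) and
right (first host base after it) boundaries classifies the target-site
lesion: R = L+1 blunt, R > L+1 deletion of L+1..R-1, R <= L tandem
duplication of R..L.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .align import AlignmentRecord, ScoringScheme, SeedIndex, align_local, build_index
from .reference import Assembly, CombinedReference, GenomicInterval, TransgeneConstruct, revcomp


class JunctionError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionPair:
    pair_id: str
    genome_anchor: GenomicInterval
    transgene_anchor: GenomicInterval
    genome_unique: bool
    transgene_unique: bool


@dataclass(frozen=True)
class SplitRead:
    read_id: str
    anchor_side: str  # 'host' | 'transgene'
    anchor: GenomicInterval
    clip_side: str  # 'left' | 'right' of the anchor in SEQ orientation
    clip_length: int
    remap: GenomicInterval
    host_pos: int  # 1-based breakpoint on the host
    host_contig: str
    boundary_side: str  # 'left' | 'right'
    construct_coord: int  # construct base adjacent to the junction
    construct_orient: str


@dataclass
class Boundary:
    contig: str
    pos: int
    side: str  # 'left' | 'right'
    construct_terminus: str  # 'start' | 'end' | 'internal'
    construct_orient: str
    split_support: int = 0
    pair_support: int = 0
    junction_seq: str = ""
    shift_range: tuple[int, int] | None = None

    @property
    def support(self) -> int:
        return self.split_support + self.pair_support


@dataclass(frozen=True)
class Lesion:
    kind: str  # 'blunt' | 'deletion' | 'duplication'
    start: int | None
    end: int | None
    length: int


@dataclass
class IntegrationSite:
    left: Boundary
    right: Boundary
    lesion: Lesion

    @property
    def contig(self) -> str:
        return self.left.contig

    @property
    def total_support(self) -> int:
        return self.left.support + self.right.support

    @property
    def boundary_positions(self) -> tuple[int, int]:
        return self.left.pos, self.right.pos


@dataclass
class ConcatemerJunction:
    joined: tuple[str, str]  # construct termini joined, e.g. ('end', 'start')
    orientation: str  # 'head-to-tail' | 'head-to-head' | 'tail-to-tail' | 'irregular'
    split_support: int = 0
    pair_support: int = 0
    breakpoints: tuple[int, int] = (0, 0)  # modal construct coordinates joined


def classify_target_site(left_pos: int, right_pos: int) -> Lesion:
    """Lesion class from the relative order of the boundary coordinates."""
    if left_pos < 1 or right_pos < 1:
        raise JunctionError("boundary positions must be >= 1")
    if right_pos == left_pos + 1:
        return Lesion("blunt", None, None, 0)
    if right_pos > left_pos + 1:
        return Lesion("deletion", left_pos + 1, right_pos - 1, right_pos - left_pos - 1)
    return Lesion("duplication", right_pos, left_pos, left_pos - right_pos + 1)


def _in_region(contig: str, pos: int, end: int, region: GenomicInterval | None) -> bool:
    return (
        region is not None
        and contig == region.contig
        and pos <= region.end
        and end >= region.start
    )


def find_junction_pairs(
    alignments: Sequence[AlignmentRecord],
    reference: CombinedReference,
    promoter_region: GenomicInterval | None = None,
) -> list[JunctionPair]:
    """Discordant pairs bridging host and transgene.

    Retains pairs with one mate on the transgene contig (or inside the
    promoter-homology region) and the other mapped uniquely elsewhere on the
    host; proper pairs and everything else are dropped.
    """
    by_name: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        by_name[rec.query_name].append(rec)
    tg = reference.transgene_contig_name
    out: list[JunctionPair] = []
    for name, recs in by_name.items():
        if len(recs) != 2:
            raise JunctionError(f"read {name!r} lacks exactly two mates")
        a, b = recs
        if not (a.is_mapped and b.is_mapped) or a.proper_pair:
            continue
        for t, g in ((a, b), (b, a)):
            t_side = t.contig == tg or _in_region(t.contig, t.pos, t.end, promoter_region)
            g_side = (
                g.unique
                and g.contig != tg
                and reference.is_host(g.contig)
                and not _in_region(g.contig, g.pos, g.end, promoter_region)
            )
            if t_side and g_side:
                out.append(
                    JunctionPair(
                        pair_id=name,
                        genome_anchor=GenomicInterval(g.contig, g.pos, g.end, g.strand),
                        transgene_anchor=GenomicInterval(t.contig, t.pos, t.end, t.strand),
                        genome_unique=g.unique,
                        transgene_unique=t.unique,
                    )
                )
                break
    return out


def _terminus(coord: int, construct_len: int, tol: int = 50) -> str:
    if coord <= tol:
        return "start"
    if coord > construct_len - tol:
        return "end"
    return "internal"


def _clip_seq(rec: AlignmentRecord, side: str) -> str:
    n = rec.left_clip if side == "left" else rec.right_clip
    return rec.seq[:n] if side == "left" else rec.seq[len(rec.seq) - n :]


def find_split_reads(
    alignments: Iterable[AlignmentRecord],
    reference: CombinedReference,
    min_clip: int = 20,
    min_remap_score: int = 18,
    index: SeedIndex | None = None,
    scoring: ScoringScheme | None = None,
    drop_log: list | None = None,
) -> list[SplitRead]:
    """Realign terminal soft clips and emit base-pair-resolution breakpoints.

    For every local-mode alignment with a terminal clip >= ``min_clip`` the
    clipped substring is realigned against the combined reference; when it
    places on the other side (host <-> transgene) with sufficient score, a
    SplitRead with the breakpoint at the clip junction is emitted.  Failures
    are silent drops, optionally tallied into ``drop_log``.
    """
    tg = reference.transgene_contig_name
    if scoring is None:
        scoring = ScoringScheme(min_local_score=min_remap_score)
    if index is None:
        index = build_index(reference, k=min(21, max(11, min_clip - 1)))
    out: list[SplitRead] = []
    for rec in alignments:
        if not rec.is_mapped or not rec.unique:
            continue  # ambiguous anchors (e.g. promoter-internal reads) give no breakpoints
        anchor_is_tg = rec.contig == tg
        for side in ("left", "right"):
            n = rec.left_clip if side == "left" else rec.right_clip
            if n < min_clip:
                continue
            clip = _clip_seq(rec, side)
            if len(clip) < index.k:
                _log(drop_log, rec, side, "clip shorter than seed")
                continue
            hit = align_local((f"{rec.query_name}/clip", clip), index, scoring)
            if not hit.is_mapped or hit.score < min_remap_score:
                _log(drop_log, rec, side, "clip unplaced")
                continue
            # the clip itself must align essentially end to end, otherwise the
            # clip point does not pinpoint the junction
            if hit.left_clip + hit.right_clip > 2:
                _log(drop_log, rec, side, "clip only partially placed")
                continue
            hit_is_tg = hit.contig == tg
            if hit_is_tg == anchor_is_tg:
                continue  # same side: concatemer evidence, handled separately
            if not hit_is_tg and not hit.unique:
                _log(drop_log, rec, side, "clip placement ambiguous on host")
                continue
            sr = _make_split(rec, side, hit, anchor_is_tg, len(reference.construct))
            if sr is not None:
                out.append(sr)
    return out


def _log(drop_log: list | None, rec: AlignmentRecord, side: str, reason: str) -> None:
    if drop_log is not None:
        drop_log.append({"read": rec.query_name, "clip_side": side, "reason": reason})


def _make_split(
    rec: AlignmentRecord,
    side: str,
    hit: AlignmentRecord,
    anchor_is_tg: bool,
    construct_len: int,
) -> SplitRead | None:
    """Geometry of one split read; coordinates follow the host-forward view."""
    c1, c2, s = hit.pos, hit.end, hit.strand
    if not anchor_is_tg:
        # host anchor, clip on the transgene
        if side == "right":
            host_pos, bside = rec.end, "left"
            coord = c1 if s == "+" else c2
        else:
            host_pos, bside = rec.pos, "right"
            coord = c2 if s == "+" else c1
        orient = s
        host_contig, anchor_iv = rec.contig, GenomicInterval(rec.contig, rec.pos, rec.end, rec.strand)
        remap_iv = GenomicInterval(hit.contig, c1, c2, s)
    else:
        # transgene anchor, clip on the host
        if side == "right":
            if s == "+":
                host_pos, bside, coord = c1, "right", rec.end
            else:
                host_pos, bside, coord = c2, "left", rec.end
        else:
            if s == "+":
                host_pos, bside, coord = c2, "left", rec.pos
            else:
                host_pos, bside, coord = c1, "right", rec.pos
        orient = "+" if s == "+" else "-"
        host_contig = hit.contig
        anchor_iv = GenomicInterval(rec.contig, rec.pos, rec.end, rec.strand)
        remap_iv = GenomicInterval(hit.contig, c1, c2, s)
    return SplitRead(
        read_id=rec.query_name,
        anchor_side="transgene" if anchor_is_tg else "host",
        anchor=anchor_iv,
        clip_side=side,
        clip_length=rec.left_clip if side == "left" else rec.right_clip,
        remap=remap_iv,
        host_pos=host_pos,
        host_contig=host_contig,
        boundary_side=bside,
        construct_coord=coord,
        construct_orient=orient,
    )


def cluster_boundaries(
    split_reads: Sequence[SplitRead],
    junction_pairs: Sequence[JunctionPair] = (),
    window: int = 10,
    min_support: int = 3,
    min_pair_support: int = 2,
    fragment_range: float = 490.0,
    reference: CombinedReference | None = None,
    flank: int = 30,
) -> tuple[list[Boundary], pd.DataFrame]:
    """Merge split-read breakpoints into boundaries and attach pair evidence.

    Breakpoints within ``window`` bp sharing contig/side/terminus/orientation
    merge at the modal position.  Junction pairs corroborate the nearest
    boundary within fragment range but never move its position.  Candidates
    below the support rule (splits >= min_support, or >= 1 split plus
    >= min_pair_support pairs) are returned in the dropped table.
    """
    construct_len = len(reference.construct) if reference is not None else None
    groups: dict[tuple, list[SplitRead]] = defaultdict(list)
    for sr in split_reads:
        term = (
            _terminus(sr.construct_coord, construct_len)
            if construct_len is not None
            else _terminus(sr.construct_coord, 10 ** 9)
        )
        groups[(sr.host_contig, sr.boundary_side, term, sr.construct_orient)].append(sr)

    candidates: list[Boundary] = []
    for (contig, side, term, orient), srs in groups.items():
        srs = sorted(srs, key=lambda r: r.host_pos)
        cluster: list[SplitRead] = []
        for sr in srs:
            if cluster and sr.host_pos - cluster[-1].host_pos > window:
                candidates.append(_finish_cluster(cluster, contig, side, term, orient))
                cluster = []
            cluster.append(sr)
        if cluster:
            candidates.append(_finish_cluster(cluster, contig, side, term, orient))

    for jp in junction_pairs:
        mid = (jp.genome_anchor.start + jp.genome_anchor.end) / 2
        best, bd = None, None
        for b in candidates:
            if b.contig != jp.genome_anchor.contig:
                continue
            d = abs(b.pos - mid)
            if d <= fragment_range and (best is None or d < best):
                best, bd = d, b
        if bd is not None:
            bd.pair_support += 1

    kept: list[Boundary] = []
    dropped_rows = []
    for b in candidates:
        if b.split_support >= min_support or (b.split_support >= 1 and b.pair_support >= min_pair_support):
            if reference is not None:
                lo = max(1, b.pos - flank)
                hi = min(reference.length(b.contig), b.pos + flank)
                b.junction_seq = reference.fetch(GenomicInterval(b.contig, lo, hi))
            kept.append(b)
        else:
            dropped_rows.append(
                {
                    "contig": b.contig,
                    "pos": b.pos,
                    "side": b.side,
                    "terminus": b.construct_terminus,
                    "orient": b.construct_orient,
                    "split_support": b.split_support,
                    "pair_support": b.pair_support,
                }
            )
    kept.sort(key=lambda b: (b.contig, b.pos, b.side))
    cols = ["contig", "pos", "side", "terminus", "orient", "split_support", "pair_support"]
    return kept, pd.DataFrame(dropped_rows, columns=cols)


def _finish_cluster(cluster: list[SplitRead], contig: str, side: str, term: str, orient: str) -> Boundary:
    positions = [sr.host_pos for sr in cluster]
    counts = Counter(positions)
    top = max(counts.values())
    modal = min(p for p, c in counts.items() if c == top)  # leftmost modal position
    return Boundary(
        contig=contig,
        pos=modal,
        side=side,
        construct_terminus=term,
        construct_orient=orient,
        split_support=len(cluster),
        shift_range=(min(positions), max(positions)),
    )


def _compatible(left: Boundary, right: Boundary) -> bool:
    if "internal" in (left.construct_terminus, right.construct_terminus):
        return False
    if left.construct_orient == right.construct_orient:
        return left.construct_terminus != right.construct_terminus
    return left.construct_terminus == right.construct_terminus


def pair_boundaries_into_sites(
    boundaries: Sequence[Boundary], max_span: int = 10_000
) -> tuple[list[IntegrationSite], list[Boundary]]:
    """Pair left with right boundaries into integration sites.

    Pairing requires consistent construct termini/orientation and host
    separation <= ``max_span``, and minimises the total |L - R| via optimal
    assignment.  Unpaired boundaries are returned as half-sites.
    """
    lefts = [b for b in boundaries if b.side == "left"]
    rights = [b for b in boundaries if b.side == "right"]
    if not lefts or not rights:
        return [], list(boundaries)
    BIG = 10 ** 9
    cost = np.full((len(lefts), len(rights)), BIG, dtype=np.int64)
    for i, lb in enumerate(lefts):
        for j, rb in enumerate(rights):
            if lb.contig == rb.contig and _compatible(lb, rb) and abs(lb.pos - rb.pos) <= max_span:
                cost[i, j] = abs(lb.pos - rb.pos)
    ri, ci = linear_sum_assignment(cost)
    sites: list[IntegrationSite] = []
    used_l, used_r = set(), set()
    for i, j in zip(ri, ci):
        if cost[i, j] >= BIG:
            continue
        lb, rb = lefts[i], rights[j]
        sites.append(IntegrationSite(lb, rb, classify_target_site(lb.pos, rb.pos)))
        used_l.add(i)
        used_r.add(j)
    half = [lb for i, lb in enumerate(lefts) if i not in used_l]
    half += [rb for j, rb in enumerate(rights) if j not in used_r]
    sites.sort(key=lambda s: (s.contig, min(s.boundary_positions)))
    return sites, half


def site_distance(site_a: IntegrationSite, site_b: IntegrationSite) -> int:
    """Closest-boundary gap between two coordinate-ordered sites (>= 0)."""
    a, b = sorted((site_a, site_b), key=lambda s: min(s.boundary_positions))
    return max(0, min(b.boundary_positions) - max(a.boundary_positions))


def find_concatemer_junctions(
    alignments: Iterable[AlignmentRecord],
    reference: CombinedReference,
    min_clip: int = 20,
    min_remap_score: int = 18,
    window: int = 10,
    index: SeedIndex | None = None,
    terminus_tol: int = 50,
) -> list[ConcatemerJunction]:
    """Construct-construct junctions between concatemer copies.

    Split reads whose anchor and clip both place on the transgene contig near
    its termini are clustered by joined-termini signature and relative
    orientation; discordant transgene-internal pairs spanning the termini add
    corroborating support.  Identical tandem junctions between indistinguishable
    copies collapse into one signature cluster.
    """
    tg = reference.transgene_contig_name
    clen = len(reference.construct)
    if index is None:
        index = build_index(reference, k=min(21, max(11, min_clip - 1)))
    scoring = ScoringScheme(min_local_score=min_remap_score)
    evid: list[tuple[int, int, bool]] = []  # (coordA, coordB, same_orientation)
    pair_mates: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        if not rec.is_mapped:
            continue
        if rec.contig == tg:
            pair_mates[rec.query_name].append(rec)
        if rec.contig != tg:
            continue
        for side in ("left", "right"):
            n = rec.left_clip if side == "left" else rec.right_clip
            if n < min_clip:
                continue
            clip = _clip_seq(rec, side)
            if len(clip) < index.k:
                continue
            hit = align_local((rec.query_name, clip), index, scoring)
            if not hit.is_mapped or hit.contig != tg or hit.score < min_remap_score:
                continue
            if side == "right":
                coord_a = rec.end
                coord_b = hit.pos if hit.strand == "+" else hit.end
            else:
                coord_a = rec.pos
                coord_b = hit.end if hit.strand == "+" else hit.pos
            evid.append((coord_a, coord_b, hit.strand == "+"))

    def kind_of(ca: int, cb: int, same: bool) -> tuple[str, tuple[str, str]]:
        ta, tb = _terminus(ca, clen, terminus_tol), _terminus(cb, clen, terminus_tol)
        if same:
            if {ta, tb} == {"start", "end"}:
                return "head-to-tail", (ta, tb)
            return "irregular", (ta, tb)
        if ta == tb == "end":
            return "tail-to-tail", (ta, tb)
        if ta == tb == "start":
            return "head-to-head", (ta, tb)
        return "irregular", (ta, tb)

    clusters: dict[tuple, list[tuple[int, int]]] = defaultdict(list)
    for ca, cb, same in evid:
        kind, joined = kind_of(ca, cb, same)
        clusters[(kind, joined)].append((ca, cb))

    out = []
    for (kind, joined), pts in clusters.items():
        ca = Counter(p[0] for p in pts).most_common(1)[0][0]
        cb = Counter(p[1] for p in pts).most_common(1)[0][0]
        out.append(
            ConcatemerJunction(
                joined=joined, orientation=kind, split_support=len(pts), breakpoints=(ca, cb)
            )
        )

    # discordant pair corroboration: mates on the transgene near opposite
    # termini with an invalid implied fragment
    for name, recs in pair_mates.items():
        if len(recs) != 2:
            continue
        a, b = recs
        if a.proper_pair:
            continue
        terms = {_terminus(a.pos, clen, 300), _terminus(b.pos, clen, 300)}
        if terms == {"start", "end"} and a.strand != b.strand:
            for cj in out:
                if cj.orientation == "head-to-tail":
                    cj.pair_support += 1
                    break
    out.sort(key=lambda c: -(c.split_support + c.pair_support))
    return out


def reconstruct_allele(
    sites: Sequence[IntegrationSite],
    host: Assembly,
    construct: TransgeneConstruct,
    copies_per_site: Sequence[int],
    orientations: Sequence[Sequence[str]] | None = None,
) -> str:
    """Splice construct concatemers into the host at the called sites.

    Sites must share one contig; lesions are honoured (deleted host bases
    omitted, duplicated bases emitted twice).  Returns the inferred
    transgenic-allele sequence.
    """
    if not sites:
        contigs = list(host)
        if len(contigs) != 1:
            raise JunctionError("reconstruction needs a single-contig host")
        return contigs[0].sequence
    contig = sites[0].contig
    if any(s.contig != contig for s in sites):
        raise JunctionError("all sites must be on one contig")
    seq = host[contig].sequence
    ordered = sorted(zip(sites, copies_per_site, orientations or [None] * len(sites)),
                     key=lambda t: t[0].left.pos)
    parts: list[str] = []
    cursor1 = 1
    for site, copies, orients in ordered:
        L, R = site.left.pos, site.right.pos
        orients = orients or ["+"] * copies
        payload = "".join(construct.sequence if o == "+" else revcomp(construct.sequence) for o in orients)
        parts.append(seq[cursor1 - 1 : L])
        parts.append(payload)
        cursor1 = R
    parts.append(seq[cursor1 - 1 :])
    return "".join(parts)


@dataclass(frozen=True)
class Amplicon:
    start: int  # 1-based position of the forward primer's 5' end on template
    end: int  # 1-based position of the reverse primer's 5' end on template
    length: int
    sequence: str


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str, max_len: int = 5000) -> list[Amplicon]:
    """Exact-match PCR products on one template strand pair.

    The forward primer must match the template's forward strand and the
    reverse primer the reverse strand downstream of it (and symmetrically
    with the roles swapped); products longer than ``max_len`` are not
    reported.
    """
    out: list[Amplicon] = []
    for p_f, p_r in ((fwd_primer.upper(), rev_primer.upper()), (rev_primer.upper(), fwd_primer.upper())):
        rc = revcomp(p_r)
        f_hits = _find_all(template, p_f)
        r_hits = _find_all(template, rc)
        for f in f_hits:
            for r in r_hits:
                end = r + len(rc)  # 0-based exclusive
                if end <= f:
                    continue
                length = end - f
                if length <= max_len:
                    out.append(Amplicon(f + 1, end, length, template[f:end]))
    uniq = {(a.start, a.end): a for a in out}
    return sorted(uniq.values(), key=lambda a: (a.start, a.end))


def _find_all(s: str, sub: str) -> list[int]:
    out, i = [], s.find(sub)
    while i != -1:
        out.append(i)
        i = s.find(sub, i + 1)
    return out


def sites_to_bed(sites: Sequence[IntegrationSite]) -> str:
    """Sites as BED text (0-based half-open over the spanned host interval)."""
    lines = []
    for i, s in enumerate(sites, 1):
        lo = min(s.boundary_positions) - 1
        hi = max(s.boundary_positions)
        lines.append(f"{s.contig}\t{lo}\t{hi}\tI{i}\t{s.total_support}\t+")
    return "\n".join(lines) + ("\n" if lines else "")


def sites_report(sites: Sequence[IntegrationSite], half_sites: Sequence[Boundary] = ()) -> dict:
    """JSON-ready report with 1-based printed coordinates."""
    def bnd(b: Boundary) -> dict:
        return {
            "contig": b.contig,
            "pos": b.pos,
            "side": b.side,
            "construct_terminus": b.construct_terminus,
            "construct_orient": b.construct_orient,
            "split_support": b.split_support,
            "pair_support": b.pair_support,
            "junction_seq": b.junction_seq,
            "shift_range": list(b.shift_range) if b.shift_range else None,
        }

    return {
        "sites": [
            {
                "name": f"I{i}",
                "left": bnd(s.left),
                "right": bnd(s.right),
                "lesion": {
                    "kind": s.lesion.kind,
                    "start": s.lesion.start,
                    "end": s.lesion.end,
                    "length": s.lesion.length,
                },
                "total_support": s.total_support,
            }
            for i, s in enumerate(sites, 1)
        ],
        "half_sites": [bnd(b) for b in half_sites],
    }
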