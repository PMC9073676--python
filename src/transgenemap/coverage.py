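"""Depth computation, GC-bias correction and coverage-ratio copy number.

Read depth at a locus is Poisson-distributed with mean proportional to how
many times the locus is present in the sample, so the transgene copy number
follows from the ratio of region depth to genome-wide background depth:

    copies = round(ploidy * region_depth / background_depth - endogenous)

where ``endogenous`` counts copies of the region already present per diploid
host genome (2 for the promoter, which exists at its endogenous locus on
both homologues; 0 for the reporter and vector).  Hemizygosity enters only
through these two integers, reproducing the 80x -> 6 (promoter) and
60x -> 6 (reporter) arithmetic at a 20x diploid background.

GC bias is removed with a binned ratio model: mean binned depth per GC
decile over the global mean, corrected depth = depth / ratio of the bin's
decile.  This is a deliberate simplification of fragment-level GC models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .reference import CombinedReference, GenomicInterval, encode_seq


class CoverageError(ValueError):
    pass


@dataclass
class DepthTrack:
    """Per-contig arrays of per-base read depth."""

    depth: dict[str, np.ndarray]

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.depth[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.depth

    def total(self) -> float:
        return float(sum(a.sum() for a in self.depth.values()))

    def region_mean(self, interval: GenomicInterval) -> float:
        a = self.depth[interval.contig][interval.start - 1 : interval.end]
        return float(a.mean())

    def region_median(self, interval: GenomicInterval) -> float:
        a = self.depth[interval.contig][interval.start - 1 : interval.end]
        return float(np.median(a))

    def copy(self) -> "DepthTrack":
        return DepthTrack({k: v.copy() for k, v in self.depth.items()})

    def write_bedgraph(self, path: str | Path) -> Path:
        """Export as bedGraph (0-based half-open runs of constant depth)."""
        with open(path, "w") as fh:
            for contig, arr in self.depth.items():
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(arr)]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")
        return Path(path)


def _overlaps_any(contig: str, start1: int, end1: int, regions: Sequence[GenomicInterval]) -> bool:
    return any(r.contig == contig and start1 <= r.end and end1 >= r.start for r in regions)


def compute_depth(
    alignments: Iterable[AlignmentRecord],
    reference: CombinedReference,
    require_unique: bool = True,
    homology_regions: Sequence[GenomicInterval] = (),
) -> DepthTrack:
    """Per-base count of reads whose M segments overlap each base.

    Non-unique alignments are excluded when ``require_unique`` is set, except
    within the designated promoter-homology regions: the endogenous promoter
    and the construct's promoter copy are identical, so reads internal to
    either are multi-mapping by construction and dropping them would carve a
    spurious coverage dip out of exactly the region whose depth carries the
    copy-number signal.
    """
    diffs = {name: np.zeros(len(seq) + 1, dtype=np.float64) for name, seq in reference.contig_items()}
    for rec in alignments:
        if not rec.is_mapped:
            continue
        if rec.contig not in diffs:
            raise CoverageError(f"alignment contig {rec.contig!r} not in reference")
        if require_unique and not rec.unique:
            if not _overlaps_any(rec.contig, rec.pos, rec.end, homology_regions):
                continue
        ref0 = rec.pos - 1
        d = diffs[rec.contig]
        for op, n in rec.cigar:
            if op == "M":
                d[ref0] += 1
                d[ref0 + n] -= 1
                ref0 += n
            elif op == "D":
                ref0 += n
    return DepthTrack({name: np.cumsum(d[:-1]) for name, d in diffs.items()})


@dataclass
class GCBiasModel:
    """Observed/expected depth ratio per GC decile of fixed-size bins."""

    bin_size: int
    decile_edges: np.ndarray  # 11 edges over GC fraction
    ratios: np.ndarray  # 10 ratios; deciles with too few bins carry 1.0
    n_bins: np.ndarray = field(default_factory=lambda: np.zeros(10, dtype=int))

    def ratio_for(self, gc: float) -> float:
        d = int(np.clip(np.searchsorted(self.decile_edges, gc, side="right") - 1, 0, 9))
        return float(self.ratios[d])


def _binned(arr: np.ndarray, bin_size: int) -> np.ndarray:
    n = len(arr) // bin_size
    if n == 0:
        return np.empty(0, dtype=np.float64)
    return arr[: n * bin_size].reshape(n, bin_size).mean(axis=1)


def _bin_gc(seq: str, bin_size: int) -> np.ndarray:
    arr = encode_seq(seq)
    is_gc = np.isin(arr, encode_seq("GC")).astype(np.float64)
    is_acgt = np.isin(arr, encode_seq("ACGT")).astype(np.float64)
    n = len(arr) // bin_size
    gc = is_gc[: n * bin_size].reshape(n, bin_size).sum(axis=1)
    tot = is_acgt[: n * bin_size].reshape(n, bin_size).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, gc / np.maximum(tot, 1), 0.0)
    return frac


def fit_gc_bias(
    depth: DepthTrack,
    reference: CombinedReference,
    bin_size: int = 1000,
    min_bins_per_decile: int = 3,
    mask: Sequence[GenomicInterval] = (),
) -> GCBiasModel:
    """Fit the binned GC ratio model over the host contigs.

    Bins overlapping ``mask`` are excluded from the fit: regions whose depth
    reflects copy number rather than GC bias (the endogenous promoter pileup,
    insertion-adjacent windows) would otherwise be attributed to their GC
    decile and skew the ratio every same-GC region is divided by.
    """
    for name, seq in reference.contig_items():
        if bin_size > len(seq) and reference.is_host(name):
            raise CoverageError(f"bin_size {bin_size} exceeds contig {name}")
    gcs, depths = [], []
    for name, seq in reference.contig_items():
        if not reference.is_host(name):
            continue  # the construct's depth reflects copy number, not GC bias
        g = _bin_gc(seq, bin_size)
        b = _binned(depth[name], bin_size)
        keep = np.ones(len(b), dtype=bool)
        for r in mask:
            if r.contig != name:
                continue
            lo = (r.start - 1) // bin_size
            hi = (r.end - 1) // bin_size
            keep[max(lo, 0) : min(hi + 1, len(b))] = False
        gcs.append(g[keep])
        depths.append(b[keep])
    gc = np.concatenate(gcs)
    dp = np.concatenate(depths)
    if len(gc) < 50:
        raise CoverageError("need >= 50 bins to fit the GC model")
    edges = np.quantile(gc, np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf
    global_mean = dp.mean()
    ratios = np.ones(10)
    counts = np.zeros(10, dtype=int)
    which = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, 9)
    for d in range(10):
        sel = which == d
        counts[d] = int(sel.sum())
        if counts[d] >= min_bins_per_decile and global_mean > 0:
            r = dp[sel].mean() / global_mean
            if r > 0:
                ratios[d] = r
    return GCBiasModel(bin_size, edges, ratios, counts)


def correct_gc(depth: DepthTrack, model: GCBiasModel, reference: CombinedReference) -> DepthTrack:
    """Divide each bin's depth by the ratio of its GC decile."""
    out = {}
    for name, seq in reference.contig_items():
        arr = depth[name].astype(np.float64).copy()
        if reference.is_host(name):
            gc = _bin_gc(seq, model.bin_size)
            which = np.clip(np.searchsorted(model.decile_edges, gc, side="right") - 1, 0, 9)
            for b, d in enumerate(which):
                s = b * model.bin_size
                arr[s : s + model.bin_size] /= model.ratios[d]
            # tail shorter than a bin inherits the last bin's ratio
            tail = len(which) * model.bin_size
            if tail < len(arr) and len(which):
                arr[tail:] /= model.ratios[which[-1]]
        else:
            # the construct is corrected with the genome-wide model too
            gc = _bin_gc(seq, min(model.bin_size, len(seq)))
            if len(gc):
                r = model.ratio_for(float(gc.mean()))
                arr /= r
        out[name] = arr
    return DepthTrack(out)


def background_depth(
    depth: DepthTrack,
    reference: CombinedReference,
    mask: Sequence[GenomicInterval] = (),
    bin_size: int = 1000,
) -> float:
    """Median binned depth over host bins, excluding masked bins.

    Mask out construct-homologous regions (the endogenous promoter) and
    insertion-adjacent windows so they cannot drag the genome-wide baseline.
    """
    vals = []
    for name, seq in reference.contig_items():
        if not reference.is_host(name):
            continue
        b = _binned(depth[name], bin_size)
        keep = np.ones(len(b), dtype=bool)
        for r in mask:
            if r.contig != name:
                continue
            lo = (r.start - 1) // bin_size
            hi = (r.end - 1) // bin_size
            keep[max(lo, 0) : min(hi + 1, len(b))] = False
        vals.append(b[keep])
    allv = np.concatenate(vals)
    if len(allv) == 0:
        raise CoverageError("no unmasked host bins for background depth")
    return float(np.median(allv))


@dataclass
class CopyNumberEstimate:
    region: GenomicInterval
    region_depth: float
    region_median_depth: float
    background_depth: float
    endogenous_copies: int
    ploidy: int
    copies: int
    copies_fractional: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "region": f"{self.region.contig}:{self.region.start}-{self.region.end}",
            "region_depth": self.region_depth,
            "region_median_depth": self.region_median_depth,
            "background_depth": self.background_depth,
            "endogenous_copies": self.endogenous_copies,
            "ploidy": self.ploidy,
            "copies": self.copies,
            "copies_fractional": self.copies_fractional,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _poisson_ci(count: float, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval on a total count."""
    alpha = 1 - conf
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (count + 1)) / 2
    return lo, hi


def estimate_copy_number(
    region_depth: float,
    background: float,
    endogenous_copies: int = 0,
    ploidy: int = 2,
    region: GenomicInterval | None = None,
    region_median_depth: float | None = None,
    region_length: int | None = None,
    read_length: int = 101,
) -> CopyNumberEstimate:
    """Coverage-ratio copy number with a Poisson uncertainty interval.

    The interval is propagated from the total read count implied by the
    region depth (depth * length / read_length) when the region length is
    known; otherwise the fractional estimate is reported without bounds.
    """
    if region_depth < 0 or background <= 0 or endogenous_copies < 0 or ploidy <= 0:
        raise CoverageError("negative or zero inputs to copy-number estimation")
    frac = ploidy * region_depth / background - endogenous_copies
    copies = max(0, int(round(frac)))
    lo = hi = frac
    if region_length:
        n_reads = region_depth * region_length / read_length
        clo, chi = _poisson_ci(n_reads)
        if n_reads > 0:
            lo = ploidy * region_depth * (clo / n_reads) / background - endogenous_copies
            hi = ploidy * region_depth * (chi / n_reads) / background - endogenous_copies
    return CopyNumberEstimate(
        region=region or GenomicInterval("region", 1, max(1, region_length or 1)),
        region_depth=float(region_depth),
        region_median_depth=float(region_median_depth if region_median_depth is not None else region_depth),
        background_depth=float(background),
        endogenous_copies=endogenous_copies,
        ploidy=ploidy,
        copies=copies,
        copies_fractional=float(frac),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def estimate_feature_copy_numbers(
    depth: DepthTrack,
    reference: CombinedReference,
    background: float,
    endogenous: Mapping[str, int],
    regions: Mapping[str, GenomicInterval],
    ploidy: int = 2,
    read_length: int = 101,
) -> dict[str, CopyNumberEstimate]:
    """Copy-number estimates for each named region (feature label -> interval)."""
    out = {}
    for label, iv in regions.items():
        out[label] = estimate_copy_number(
            region_depth=depth.region_mean(iv),
            background=background,
            endogenous_copies=endogenous.get(label, 0),
            ploidy=ploidy,
            region=iv,
            region_median_depth=depth.region_median(iv),
            region_length=iv.length,
            read_length=read_length,
        )
    return out


def copy_number_table(estimates: Mapping[str, CopyNumberEstimate]) -> pd.DataFrame:
    rows = [{"feature": k, **v.to_dict()} for k, v in estimates.items()]
    return pd.DataFrame(rows)
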