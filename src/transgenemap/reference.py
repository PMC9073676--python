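"""Sequence containers, the combined genome+transgene reference, and coordinate conventions.

The pipeline aligns reads against the host assembly with the transgene
construct appended as one extra contig, so that reads from the insertion can
be placed on either side of each junction.  All coordinates handled
internally are 0-based half-open; every coordinate that crosses the public
API boundary (``GenomicInterval``, reports, BED sidecars converted on read)
is 1-based inclusive, matching the convention genome browsers and the
wet-lab literature print.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def encode_seq(seq: str) -> np.ndarray:
    """Encode DNA as a uint8 array of ASCII codes (vectorised comparisons)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence, ignoring N bases."""
    arr = encode_seq(seq)
    acgt = np.isin(arr, encode_seq("ACGT"))
    n = int(acgt.sum())
    if n == 0:
        return 0.0
    gc = int(np.isin(arr, encode_seq("GC")).sum())
    return gc / n


class ReferenceError(ValueError):
    """Inconsistent reference construction (name collisions, bad intervals)."""


class FastaParseError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named contig.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def to_zero_based(interval: GenomicInterval) -> tuple[str, int, int, str]:
    """Convert a 1-based inclusive interval to (contig, start0, end0, strand)
    half-open coordinates."""
    return interval.contig, interval.start - 1, interval.end, interval.strand


def from_zero_based(contig: str, start0: int, end0: int, strand: str = ".") -> GenomicInterval:
    """Inverse of :func:`to_zero_based`."""
    return GenomicInterval(contig, start0 + 1, end0, strand)


@dataclass(frozen=True)
class Contig:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ReferenceError("contig name must be nonempty")
        if len(self.sequence) < 1:
            raise ReferenceError(f"contig {self.name!r} has empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ReferenceError(f"contig {self.name!r} has invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


class Assembly:
    """An ordered collection of uniquely named contigs."""

    def __init__(self, contigs: Iterable[Contig] = ()):  # noqa: D107
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.name in self._contigs:
            raise ReferenceError(f"duplicate contig name {contig.name!r}")
        self._contigs[contig.name] = contig

    def __getitem__(self, name: str) -> Contig:
        return self._contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def names(self) -> list[str]:
        return list(self._contigs)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self)

    def fetch(self, interval: GenomicInterval) -> str:
        """Extract the (forward-strand) sequence of a 1-based inclusive interval."""
        contig = self._contigs[interval.contig]
        if interval.end > len(contig):
            raise ReferenceError(
                f"interval {interval.contig}:{interval.start}-{interval.end} "
                f"exceeds contig length {len(contig)}"
            )
        seq = contig.sequence[interval.start - 1 : interval.end]
        return revcomp(seq) if interval.strand == "-" else seq


# labels the construct annotation understands
CONSTRUCT_FEATURES = (
    "promoter",
    "egfp",
    "vector",
    "isce1_site_left",
    "isce1_site_right",
)


@dataclass
class TransgeneConstruct:
    """The injected transgene cassette: promoter + reporter + vector backbone,
    flanked by I-SceI recognition-site remnants.

    ``features`` maps a label to a 1-based inclusive interval on the construct
    (the interval's contig field names the construct).
    """

    sequence: str
    features: dict[str, GenomicInterval] = field(default_factory=dict)
    name: str = "transgene"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ReferenceError(f"construct has invalid bases {sorted(bad)}")
        for label, iv in self.features.items():
            if iv.end > len(self.sequence):
                raise ReferenceError(
                    f"feature {label!r} interval {iv.start}-{iv.end} exceeds "
                    f"construct length {len(self.sequence)}"
                )
        # the cassette's functional elements must not overlap each other
        core = [self.features[k] for k in ("promoter", "egfp", "vector") if k in self.features]
        core.sort(key=lambda iv: iv.start)
        for a, b in zip(core, core[1:]):
            if b.start <= a.end:
                raise ReferenceError("promoter/egfp/vector features overlap")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, label: str) -> str:
        iv = self.features[label]
        return self.sequence[iv.start - 1 : iv.end]


class CombinedReference:
    """Host contigs plus the transgene construct appended as an extra contig."""

    def __init__(self, host: Assembly, construct: TransgeneConstruct):
        if construct.name in host:
            raise ReferenceError(
                f"construct name {construct.name!r} collides with a host contig"
            )
        if len(host) == 0:
            raise ReferenceError("host assembly is empty")
        self.host = host
        self.construct = construct

    @property
    def transgene_contig_name(self) -> str:
        return self.construct.name

    @property
    def names(self) -> list[str]:
        return self.host.names + [self.construct.name]

    def __contains__(self, name: str) -> bool:
        return name in self.host or name == self.construct.name

    def length(self, name: str) -> int:
        if name == self.construct.name:
            return len(self.construct)
        return len(self.host[name])

    @property
    def total_length(self) -> int:
        return self.host.total_length + len(self.construct)

    def sequence(self, name: str) -> str:
        if name == self.construct.name:
            return self.construct.sequence
        return self.host[name].sequence

    def fetch(self, interval: GenomicInterval) -> str:
        if interval.contig == self.construct.name:
            if interval.end > len(self.construct):
                raise ReferenceError("interval exceeds construct length")
            seq = self.construct.sequence[interval.start - 1 : interval.end]
            return revcomp(seq) if interval.strand == "-" else seq
        return self.host.fetch(interval)

    def contig_items(self) -> list[tuple[str, str]]:
        """(name, sequence) pairs, host contigs first, construct last."""
        return [(c.name, c.sequence) for c in self.host] + [
            (self.construct.name, self.construct.sequence)
        ]

    def is_host(self, name: str) -> bool:
        return name in self.host


def build_combined_reference(host: Assembly, construct: TransgeneConstruct) -> CombinedReference:
    """Append the construct to the host assembly as an extra contig."""
    return CombinedReference(host, construct)


def read_fasta(path: str | Path) -> Assembly:
    """Read a (wrapped or unwrapped) multi-record FASTA into an Assembly.

    Sequences are upper-cased on read; empty records and files raise
    :class:`FastaParseError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    assembly = Assembly()
    for rec in records:
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FastaParseError("FASTA record with empty header")
        if not seq:
            raise FastaParseError(f"FASTA record {rec.id!r} has empty sequence")
        assembly.add(Contig(rec.id, seq))
    return assembly


def write_fasta(assembly: Assembly | Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> Path:
    """Write contigs (an Assembly or (name, sequence) pairs) to FASTA."""
    if isinstance(assembly, Assembly):
        items = [(c.name, c.sequence) for c in assembly]
    else:
        items = list(assembly)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return Path(path)


def read_feature_bed(path: str | Path, contig_name: str | None = None) -> dict[str, GenomicInterval]:
    """Read a construct-feature sidecar BED (0-based half-open) into labelled
    1-based inclusive intervals."""
    features: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FastaParseError(f"BED line needs >= 4 columns: {line!r}")
            contig, start0, end0, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "."
            features[label] = from_zero_based(contig_name or contig, start0, end0, strand)
    return features


def write_feature_bed(features: Mapping[str, GenomicInterval], path: str | Path) -> Path:
    with open(path, "w") as fh:
        for label, iv in features.items():
            contig, s0, e0, strand = to_zero_based(iv)
            fh.write(f"{contig}\t{s0}\t{e0}\t{label}\t0\t{strand if strand != '.' else '+'}\n")
    return Path(path)
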