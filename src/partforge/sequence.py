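"""Annotated DNA sequences: Genbank I/O, reverse complement, region extraction.

Coordinates everywhere in the public API are 1-based inclusive, matching
Genbank convention. Sources may be circular; a feature on a circular
sequence may wrap the origin, represented as ``start > end``. Extraction
of a region that spans the origin of a circular source is supported and
always yields a linear result.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    FormatError,
    InvalidSourceError,
    RangeError,
    TopologyError,
)

DNA_ALPHABET = set("ACGTNacgtn")

FORWARD = 1
REVERSE = -1

TRUNCATED_SUFFIX = " (truncated)"


@dataclass
class Feature:
    """A positioned annotation on a source sequence.

    ``start``/``end`` are 1-based inclusive. ``start > end`` denotes an
    origin-wrapping feature and is only meaningful on a circular sequence.
    ``strand`` is +1 (forward) or -1 (reverse).
    """

    label: str
    feature_type: str = "misc_feature"
    start: int = 1
    end: int = 1
    strand: int = FORWARD
    truncated: bool = field(default=False, compare=False)

    def length_on(self, source_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return source_length - self.start + 1 + self.end


@dataclass
class AnnotatedSequence:
    """A named DNA string with topology flag and positioned features."""

    name: str
    residues: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.name!r} contains non-DNA characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def check_feature_bounds(self) -> None:
        L = len(self)
        for f in self.features:
            for pos in (f.start, f.end):
                if not 1 <= pos <= L:
                    raise RangeError(
                        f"feature {f.label!r}: position {pos} outside "
                        f"[1, {L}] on {self.name!r}"
                    )
            if f.start > f.end and not self.circular:
                raise TopologyError(
                    f"feature {f.label!r} wraps the origin of linear "
                    f"sequence {self.name!r}"
                )


def _record_to_annotated(record: SeqRecord) -> AnnotatedSequence:
    residues = str(record.seq)
    if not residues:
        raise InvalidSourceError(
            f"Genbank record {record.id!r} has an empty sequence"
        )
    topology = record.annotations.get("topology", "linear")
    L = len(residues)
    features: list[Feature] = []
    for sf in record.features:
        if sf.type == "source":
            continue
        label = (
            sf.qualifiers.get("label", [None])[0]
            or sf.qualifiers.get("gene", [None])[0]
            or sf.qualifiers.get("product", [None])[0]
            or sf.qualifiers.get("note", [None])[0]
            or sf.type
        )
        strand = REVERSE if sf.location.strand == -1 else FORWARD
        parts = (
            sf.location.parts
            if isinstance(sf.location, CompoundLocation)
            else [sf.location]
        )
        if (
            len(parts) == 2
            and int(parts[0].end) == L
            and int(parts[1].start) == 0
        ):
            # join(a..L,1..b): an origin-wrapping feature
            start, end = int(parts[0].start) + 1, int(parts[1].end)
            features.append(Feature(label, sf.type, start, end, strand))
        else:
            for p in parts:
                features.append(
                    Feature(label, sf.type, int(p.start) + 1, int(p.end), strand)
                )
    seq = AnnotatedSequence(
        name=record.name or record.id,
        residues=residues,
        circular=(topology == "circular"),
        features=features,
    )
    seq.check_feature_bounds()
    return seq


def read_genbank(path) -> AnnotatedSequence:
    """Read the first record of a Genbank flat file.

    Topology comes from the LOCUS line (default linear when absent); all
    features are captured with label, type, strand and 1-based coordinates.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad syntax
        raise FormatError(f"cannot parse {path} as Genbank: {exc}") from exc
    return _record_to_annotated(record)


def read_genbank_string(text: str) -> AnnotatedSequence:
    """Parse Genbank content held in memory (used for zip bundle entries)."""
    try:
        record = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:
        raise FormatError(f"cannot parse Genbank text: {exc}") from exc
    return _record_to_annotated(record)


def _annotated_to_record(seq: AnnotatedSequence) -> SeqRecord:
    L = len(seq)
    record = SeqRecord(
        Seq(seq.residues),
        id=seq.name,
        name=seq.name.replace(" ", "_"),
        description=seq.name,
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if seq.circular else "linear"
    for f in seq.features:
        strand = -1 if f.strand == REVERSE else 1
        if f.start <= f.end:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        else:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, L, strand=strand),
                    SimpleLocation(0, f.end, strand=strand),
                ]
            )
        record.features.append(
            SeqFeature(loc, type=f.feature_type, qualifiers={"label": [f.label]})
        )
    return record


def write_genbank(seq: AnnotatedSequence, path) -> None:
    """Write a minimal standard-compliant Genbank record.

    The emitted file re-reads (via :func:`read_genbank`) to an equal
    sequence: residues, topology, and every feature's
    (label, type, start, end, strand).
    """
    seq.check_feature_bounds()
    with open(str(path), "w") as fh:
        SeqIO.write(_annotated_to_record(seq), fh, "genbank")


def write_genbank_string(seq: AnnotatedSequence) -> str:
    seq.check_feature_bounds()
    buf = io.StringIO()
    SeqIO.write(_annotated_to_record(seq), buf, "genbank")
    return buf.getvalue()


def reverse_complement(seq: AnnotatedSequence) -> AnnotatedSequence:
    """Reverse-complement residues and mirror every feature.

    A feature at [s, e] maps to [L-e+1, L-s+1] with its strand flipped;
    origin-wrapping features stay origin-wrapping. Case is preserved.
    The operation is an involution.
    """
    L = len(seq)
    rc = str(Seq(seq.residues).reverse_complement())
    mirrored = []
    for f in seq.features:
        # p -> L-p+1 maps [s, e] to [L-e+1, L-s+1]; wrapped stays wrapped
        mirrored.append(
            replace(f, start=L - f.end + 1, end=L - f.start + 1, strand=-f.strand)
        )
    mirrored.sort(key=lambda f: (f.start, f.end, f.label))
    return AnnotatedSequence(seq.name, rc, seq.circular, mirrored)


def _check_coordinate(value: int, L: int, source_name: str) -> None:
    if not 1 <= value <= L:
        raise RangeError(
            f"position {value} outside [1, {L}] on source {source_name!r}"
        )


def extract_region(
    source: AnnotatedSequence,
    start: int,
    stop: int,
    reverse: bool = False,
) -> AnnotatedSequence:
    """Extract the region read 5'->3' from ``start`` through ``stop``.

    On a circular source ``start > stop`` selects the window wrapping
    through the origin (positions start..L then 1..stop). Features fully
    inside the window are remapped to window coordinates; features
    partially overlapping are truncated to the window, their label
    suffixed with ``(truncated)``. The result is always linear; if
    ``reverse`` it is reverse-complemented after extraction.
    """
    L = len(source)
    if L == 0:
        raise InvalidSourceError(f"source {source.name!r} is empty")
    _check_coordinate(start, L, source.name)
    _check_coordinate(stop, L, source.name)
    if start > stop and not source.circular:
        raise TopologyError(
            f"start {start} > stop {stop} on linear source {source.name!r}"
        )

    if start <= stop:
        residues = source.residues[start - 1 : stop]
    else:
        residues = source.residues[start - 1 :] + source.residues[:stop]
    wlen = len(residues)

    def window_offset(pos: int) -> int:
        """1-based offset of source position ``pos`` within the window,
        or 0 when outside."""
        if start <= stop:
            return pos - start + 1 if start <= pos <= stop else 0
        if pos >= start:
            return pos - start + 1
        if pos <= stop:
            return L - start + 1 + pos
        return 0

    remapped: list[Feature] = []
    for f in source.features:
        # split origin-wrapping features into linear segments first
        if f.start <= f.end:
            segments = [(f.start, f.end)]
        else:
            segments = [(f.start, L), (1, f.end)]
        whole = len(segments) == 1
        feat_len = f.length_on(L)
        for seg_start, seg_end in segments:
            hit = sorted(
                off
                for p in range(seg_start, seg_end + 1)
                if (off := window_offset(p))
            )
            if not hit:
                continue
            # a segment may intersect a wrapped window in disjoint pieces;
            # emit one (truncated) fragment per contiguous run of offsets
            runs: list[list[int]] = [[hit[0], hit[0]]]
            for off in hit[1:]:
                if off == runs[-1][1] + 1:
                    runs[-1][1] = off
                else:
                    runs.append([off, off])
            for lo, hi in runs:
                full = whole and len(runs) == 1 and (hi - lo + 1) == feat_len
                remapped.append(
                    Feature(
                        label=f.label if full else f.label + TRUNCATED_SUFFIX,
                        feature_type=f.feature_type,
                        start=lo,
                        end=hi,
                        strand=f.strand,
                        truncated=not full,
                    )
                )
    remapped.sort(key=lambda f: (f.start, f.end, f.label))
    region = AnnotatedSequence(source.name, residues, False, remapped)
    if reverse:
        region = reverse_complement(region)
    assert len(region) == wlen
    return region


def rotate(seq: AnnotatedSequence, offset: int) -> AnnotatedSequence:
    """Rotate a circular sequence so position ``offset+1`` becomes position 1."""
    if not seq.circular:
        raise TopologyError(f"cannot rotate linear sequence {seq.name!r}")
    L = len(seq)
    k = offset % L
    residues = seq.residues[k:] + seq.residues[:k]

    def shift(pos: int) -> int:
        return (pos - 1 - k) % L + 1

    features = [
        replace(f, start=shift(f.start), end=shift(f.end)) for f in seq.features
    ]
    features.sort(key=lambda f: (f.start, f.end, f.label))
    return AnnotatedSequence(seq.name, residues, True, features)
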