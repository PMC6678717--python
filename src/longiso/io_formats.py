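"""Domain types and readers/writers for the genomic formats the toolkit touches.

All coordinates are normalized at the boundary onto a single internal
convention: 0-based, half-open ``[start, end)`` intervals, as in BED.
GTF input (1-based, fully closed) is converted on read and back on write,
so no other module ever handles a 1-based coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Malformed record in an input file; message carries the line number."""


class ModelValidationError(ValueError):
    """A parsed record violates a structural invariant (coordinates, strand...)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ModelValidationError("interval with empty chrom")
        if not (0 <= self.start < self.end):
            raise ModelValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ModelValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class TranscriptModel:
    """One isoform: an exon chain on one chromosome and strand.

    ``read_support`` is the number of long reads collapsed into this model;
    it drives the isoform-diversity score and transcript labels in plots.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    read_support: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ModelValidationError(f"transcript {self.transcript_id}: no exons")
        if self.read_support < 0:
            raise ModelValidationError(
                f"transcript {self.transcript_id}: negative read support"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ModelValidationError(
                    f"transcript {self.transcript_id}: exon on {ex.chrom}, transcript on {self.chrom}"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start - a.end < 1:
                raise ModelValidationError(
                    f"transcript {self.transcript_id}: exons {a.start}-{a.end} and "
                    f"{b.start}-{b.end} overlap or are adjacent (intron length < 1)"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Ordered intron coordinates (end of one exon, start of the next)."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(self.introns)


@dataclass
class FeatureTrack:
    """A named set of genomic intervals (CAGE peaks, a histone mark...).

    Intervals are bucketed per chromosome and kept sorted by start so
    nearest-feature queries can binary-search.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelValidationError("feature track with empty name")
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in self._by_chrom.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class SampleTranscriptome:
    """Per-sample container of transcript models with unique ids."""

    sample_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.transcripts:
            if t.transcript_id in seen:
                raise ModelValidationError(
                    f"sample {self.sample_id}: duplicate transcript_id {t.transcript_id}"
                )
            seen.add(t.transcript_id)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path, read_support_key: str = "read_count") -> list[TranscriptModel]:
    """Read transcript models from GTF exon features.

    GTF 1-based inclusive coordinates become internal 0-based half-open ones
    (``start-1``, ``end``).  Attribute parsing accepts both the Ensembl
    ``key "value";`` and the ``key=value`` dialects.  ``read_support_key``
    names the per-transcript attribute holding the long-read count; when the
    attribute is absent the support defaults to 1 so count-free GTFs remain
    usable.  Transcripts without a '+' or '-' strand are dropped (a strand is
    required for TSS and splicing logic) and counted in a log message.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    strandless: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-delimited GTF columns")
            if fields[2] != "exon":
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted exceptions
                raise FormatError(f"{path}:{lineno}: unparseable GTF line ({exc})") from exc
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ModelValidationError(f"{path}:{lineno}: exon end {end1} < start {start1}")
            attrs = feat.attributes
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise FormatError(
                    f"{path}:{lineno}: exon feature lacks gene_id/transcript_id attributes"
                )
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
            strand = fields[6]
            if strand not in ("+", "-"):
                strandless.add(tid)
                continue
            interval = GenomicInterval(fields[0], start1 - 1, end1, strand)
            exons.setdefault(tid, []).append(interval)
            prev = meta.setdefault(tid, {"gene_id": gid, "chrom": fields[0], "strand": strand})
            if prev["chrom"] != fields[0] or prev["strand"] != strand:
                raise ModelValidationError(
                    f"{path}:{lineno}: transcript {tid} has exons on multiple chroms/strands"
                )
            if read_support_key in attrs:
                try:
                    prev["read_support"] = int(attrs[read_support_key][0])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer {read_support_key} attribute"
                    ) from exc
    if strandless:
        logger.warning("%s: dropped %d strandless transcript(s)", path, len(strandless))
    models = []
    for tid, ivs in exons.items():
        m = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=ivs,
                read_support=m.get("read_support", 1),
            )
        )
    models.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return models


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    read_support_key: str = "read_count",
    source: str = "longiso",
) -> None:
    """Write exon features in GTF (1-based inclusive), sorted by (chrom, start)."""
    path = Path(path)
    rows = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with path.open("w") as fh:
        for t in rows:
            for ex in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'{read_support_key} "{t.read_support}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a BED3+ file into a FeatureTrack (BED is natively 0-based half-open).

    Strand is taken from column 6 when present, else '.'.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ModelValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            intervals.append(GenomicInterval(fields[0], start, end, strand))
    return FeatureTrack(name=name or path.stem, intervals=intervals)


def write_bed(track: FeatureTrack, path: str | Path) -> None:
    """Write a FeatureTrack as BED6, sorted by (chrom, start)."""
    path = Path(path)
    with path.open("w") as fh:
        for iv in sorted(track.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# BED12 transcripts
# ---------------------------------------------------------------------------

def read_bed12_transcripts(path: str | Path, gene_id_from_name: bool = True) -> list[TranscriptModel]:
    """Read transcript models from BED12; blocks become exons, score read support.

    The name column is interpreted as ``transcript_id`` or, when it contains
    a '|' separator, as ``gene_id|transcript_id``.
    """
    path = Path(path)
    models: list[TranscriptModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom = fields[0]
            try:
                chrom_start, chrom_end = int(fields[1]), int(fields[2])
                score = int(float(fields[4])) if fields[4] not in (".", "") else 1
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED12 field") from exc
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ModelValidationError(
                    f"{path}:{lineno}: blockCount {block_count} does not match block lists"
                )
            strand = fields[5]
            name = fields[3]
            if gene_id_from_name and "|" in name:
                gid, tid = name.split("|", 1)
            else:
                gid, tid = name, name
            exons = []
            for bs, bo in zip(block_sizes, block_starts):
                s = chrom_start + bo
                exons.append(GenomicInterval(chrom, s, s + bs, strand))
            if exons[0].start != chrom_start or exons[-1].end != chrom_end:
                raise ModelValidationError(
                    f"{path}:{lineno}: blocks do not span chromStart..chromEnd"
                )
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    read_support=score,
                )
            )
    models.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return models


def write_bed12_transcripts(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as BED12; name column is ``gene_id|transcript_id``."""
    path = Path(path)
    rows = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with path.open("w") as fh:
        for t in rows:
            sizes = ",".join(str(len(e)) for e in t.exons)
            offsets = ",".join(str(e.start - t.start) for e in t.exons)
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene_id}|{t.transcript_id}\t"
                f"{t.read_support}\t{t.strand}\t{t.start}\t{t.end}\t0\t"
                f"{len(t.exons)}\t{sizes}\t{offsets}\n"
            )


def load_transcripts(path: str | Path, read_support_key: str = "read_count") -> list[TranscriptModel]:
    """Load transcript models from GTF or BED12, chosen by file extension."""
    p = Path(path)
    if p.suffix.lower() in (".bed", ".bed12"):
        return read_bed12_transcripts(p)
    return read_gtf(p, read_support_key=read_support_key)


def transcripts_by_id(transcripts: Sequence[TranscriptModel]) -> dict[str, TranscriptModel]:
    return {t.transcript_id: t for t in transcripts}
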