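"""Strand-aware TSS-to-feature distances and distance-cutoff transcript filtering.

Long-read transcript models can start at spurious positions (degraded RNA,
template switching).  A genuine transcription start site (TSS) is expected to
sit near independent regulatory evidence — a CAGE peak or an active-promoter
histone mark.  This module measures, for every transcript, the signed
distance from its TSS to the nearest feature of each evidence track, and
filters transcripts whose TSS has no supporting feature within a cutoff
(default 1 kb up- or downstream of the first transcribed nucleotide).

Sign convention: 0 means the TSS lies inside a feature; negative means the
nearest feature is upstream of the TSS in transcription direction, positive
downstream.  On the '-' strand "upstream" is genomically rightward.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io_formats import FeatureTrack, GenomicInterval, SampleTranscriptome, TranscriptModel

DEFAULT_BIN_EDGES = (0, 100, 500, 1000, 5000, 10000)
DEFAULT_CUTOFF_BP = 1000


@dataclass
class DistanceRecord:
    """Nearest-feature result for one (transcript, track) pair.

    ``nearest_feature`` is None — and ``distance`` undefined (None) — when the
    track has no interval on the transcript's chromosome.
    """

    transcript_id: str
    track_name: str
    distance: Optional[int]
    nearest_feature: Optional[GenomicInterval]


@dataclass
class FilterReport:
    kept: list[str]
    discarded: list[str]
    cutoff_bp: int
    tracks_used: list[str]
    min_abs_distance: dict[str, Optional[int]]  # per transcript, None = no feature anywhere


def tss_of(t: TranscriptModel) -> int:
    """Genomic position (0-based) of the first transcribed nucleotide."""
    if t.strand == "+":
        return t.exons[0].start
    return t.exons[-1].end - 1


def _gap(pos: int, iv: GenomicInterval) -> int:
    """Unsigned distance from a position to an interval's nearest base (0 if inside)."""
    if iv.start <= pos < iv.end:
        return 0
    return min(abs(pos - iv.start), abs(pos - (iv.end - 1)))


def nearest_feature_distance(
    tss: int, strand: str, chrom: str, track: FeatureTrack, transcript_id: str = ""
) -> DistanceRecord:
    """Signed distance from a TSS to the nearest interval of a track.

    Candidates are found by binary search on start-sorted intervals; because
    interval lengths vary, the search walks left until no remaining interval
    can beat the best gap.  Among equally distant upstream/downstream
    features the downstream one is reported (fixed tie-break; the magnitude
    is unaffected).
    """
    intervals = track.on_chrom(chrom)
    if not intervals:
        return DistanceRecord(transcript_id, track.name, None, None)
    starts = [iv.start for iv in intervals]
    i = bisect_left(starts, tss)
    best: GenomicInterval | None = None
    best_gap: int | None = None

    def consider(iv: GenomicInterval) -> None:
        nonlocal best, best_gap
        g = _gap(tss, iv)
        if best_gap is None or g < best_gap:
            best, best_gap = iv, g
        elif g == best_gap and _is_downstream(tss, strand, iv) and not _is_downstream(tss, strand, best):
            best = iv  # tie between upstream/downstream: report the downstream one

    # walk right: starts are sorted, so stop once start alone exceeds best gap
    j = i
    while j < len(intervals):
        if best_gap is not None and intervals[j].start - tss > best_gap:
            break
        consider(intervals[j])
        j += 1
    # walk left: intervals vary in length, so bound the scan by the longest one
    max_len = max(len(iv) for iv in intervals)
    j = i - 1
    while j >= 0:
        if best_gap is not None and tss - (intervals[j].start + max_len - 1) > best_gap:
            break
        consider(intervals[j])
        j -= 1
    assert best is not None and best_gap is not None
    sign = 0 if best_gap == 0 else (1 if _is_downstream(tss, strand, best) else -1)
    return DistanceRecord(transcript_id, track.name, sign * best_gap, best)


def _is_downstream(tss: int, strand: str, iv: GenomicInterval | None) -> bool:
    """True when the interval's nearest edge lies downstream of the TSS in transcription direction."""
    if iv is None:
        return False
    if iv.start <= tss < iv.end:
        return True
    if abs(tss - iv.start) <= abs(tss - (iv.end - 1)):
        edge = iv.start
    else:
        edge = iv.end - 1
    return (edge > tss) if strand == "+" else (edge < tss)


def distance_records(
    sample: SampleTranscriptome, tracks: Sequence[FeatureTrack]
) -> list[DistanceRecord]:
    """One DistanceRecord per (transcript, track)."""
    out = []
    for t in sample.transcripts:
        pos = tss_of(t)
        for track in tracks:
            out.append(nearest_feature_distance(pos, t.strand, t.chrom, track, t.transcript_id))
    return out


def distance_summary(
    sample: SampleTranscriptome,
    tracks: Sequence[FeatureTrack],
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Distance table plus per-track histogram of |distance| on the given bins.

    Bins are ``[e0,e1), [e1,e2), ..., [e_last, inf)``.  Records with no
    feature on the chromosome carry NA and do not enter any bin.
    """
    if not sample.transcripts or not tracks:
        raise ValueError("distance_summary needs >=1 transcript and >=1 track")
    recs = distance_records(sample, tracks)
    rows = []
    for r in recs:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "track": r.track_name,
                "distance": r.distance,
                "feature_chrom": r.nearest_feature.chrom if r.nearest_feature else None,
                "feature_start": r.nearest_feature.start if r.nearest_feature else None,
                "feature_end": r.nearest_feature.end if r.nearest_feature else None,
            }
        )
    table = pd.DataFrame(rows, columns=[
        "transcript_id", "track", "distance", "feature_chrom", "feature_start", "feature_end",
    ])
    edges = list(bin_edges)
    hists: dict[str, list[int]] = {}
    for track in tracks:
        counts = [0] * len(edges)
        for r in recs:
            if r.track_name != track.name or r.distance is None:
                continue
            d = abs(r.distance)
            k = 0
            for b, e in enumerate(edges[1:], start=1):
                if d >= e:
                    k = b
            if d < edges[0]:
                continue
            counts[k] += 1
        hists[track.name] = counts
    return table, hists


def filter_by_distance(
    sample: SampleTranscriptome,
    tracks: Sequence[FeatureTrack],
    cutoff_bp: int = DEFAULT_CUTOFF_BP,
    mode: str = "any",
) -> FilterReport:
    """Partition transcripts by TSS proximity to evidence tracks.

    mode 'any' (default): keep a transcript iff at least one track holds a
    feature with |distance| <= cutoff_bp; mode 'all': every track must.  The
    cutoff boundary is inclusive ("within" semantics).
    """
    if cutoff_bp <= 0:
        raise ValueError("cutoff_bp must be positive")
    if not tracks:
        raise ValueError("filter_by_distance requires at least one feature track")
    if mode not in ("any", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    kept, discarded = [], []
    min_abs: dict[str, Optional[int]] = {}
    for t in sample.transcripts:
        pos = tss_of(t)
        dists = [
            nearest_feature_distance(pos, t.strand, t.chrom, tr, t.transcript_id).distance
            for tr in tracks
        ]
        finite = [abs(d) for d in dists if d is not None]
        min_abs[t.transcript_id] = min(finite) if finite else None
        within = [d is not None and abs(d) <= cutoff_bp for d in dists]
        ok = any(within) if mode == "any" else all(within)
        (kept if ok else discarded).append(t.transcript_id)
    return FilterReport(
        kept=kept,
        discarded=discarded,
        cutoff_bp=cutoff_bp,
        tracks_used=[tr.name for tr in tracks],
        min_abs_distance=min_abs,
    )
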