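"""Alternative-splicing event classification, sample comparison and isoform diversity.

Events are local splicing variations defined over pairs of isoforms of one
gene, in the seven-type scheme standard for transcript-level analysis:

========  ==========================================================
SE        skipped exon: an internal exon present in one path, absent
          (direct flanking junction) in the other
RI        retained intron: a single exon spanning exactly what another
          isoform splits into two exons
A5 / A3   alternative 5'/3' splice site: two junctions sharing one
          boundary while the other shifts within overlapping exons
MX        mutually exclusive exons: two non-overlapping middle exons
          sharing both flanking junction partners
AF / AL   alternative first/last exon: non-overlapping terminal exons
          spliced to the same inner boundary
========  ==========================================================

All positions are genomic (0-based half-open exons).  A5/A3 and AF/AL are
strand-resolved: the same genomic configuration is an A5 on '+' and an A3 on
'-', and likewise AF/AL swap.

Per-gene isoform diversity is the Shannon entropy (bits) of the isoform
read-support proportions; the score difference D = |H_a - H_b| between two
samples ranks genes by differential isoform usage.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ModelValidationError, SampleTranscriptome, TranscriptModel

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")
#: fixed column/legend order for tables and stacked bars
EVENT_TYPE_ORDER = ("A3", "A5", "AF", "AL", "MX", "RI", "SE")


@dataclass
class ASEvent:
    """One classified local splicing event within a gene."""

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    coordinates: tuple[int, ...]
    inclusion_transcripts: set[str]
    exclusion_transcripts: set[str]

    @property
    def event_id(self) -> str:
        coords = "-".join(str(c) for c in self.coordinates)
        return f"{self.gene_id};{self.event_type}:{self.chrom}:{coords}:{self.strand}"


@dataclass
class GeneGroup:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def event_free(self) -> bool:
        return len(self.transcripts) < 2


@dataclass
class DiversityRecord:
    gene_id: str
    sample_id: str
    score: float
    n_isoforms: int


@dataclass
class ScoreDRecord:
    gene_id: str
    sample_a: str
    sample_b: str
    score_a: float
    score_b: float
    one_sample_only: bool = False

    @property
    def D(self) -> float:
        return abs(self.score_a - self.score_b)


def group_by_gene(transcripts: Iterable[TranscriptModel]) -> list[GeneGroup]:
    """Partition transcripts by gene_id, checking chrom/strand consistency."""
    buckets: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        buckets[t.gene_id].append(t)
    groups = []
    for gid in sorted(buckets):
        ts = buckets[gid]
        chroms = {t.chrom for t in ts}
        strands = {t.strand for t in ts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ModelValidationError(
                f"gene {gid}: transcripts on multiple chroms/strands "
                f"({sorted(chroms)}, {sorted(strands)})"
            )
        groups.append(GeneGroup(gid, ts[0].chrom, ts[0].strand, ts))
    return groups


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_events(gene: GeneGroup) -> list[ASEvent]:
    """Enumerate all distinct local splicing events among a gene's isoforms.

    Events found from different transcript pairs but with identical defining
    coordinates are merged: one event per event_id, inclusion/exclusion sets
    unioned over supporting pairs.  Output order is deterministic
    (type, then coordinates).
    """
    if gene.event_free:
        return []
    found: dict[str, ASEvent] = {}

    def emit(etype: str, coords: tuple[int, ...], inc: set[str], exc: set[str]) -> None:
        ev = ASEvent(etype, gene.gene_id, gene.chrom, gene.strand, coords, set(inc), set(exc))
        prev = found.get(ev.event_id)
        if prev is None:
            found[ev.event_id] = ev
        else:
            prev.inclusion_transcripts |= inc
            prev.exclusion_transcripts |= exc

    ts = gene.transcripts
    strand = gene.strand

    # indexes
    junctions: dict[tuple[int, int], set[str]] = defaultdict(set)  # (donor_end, acceptor_start)
    exon_set: dict[tuple[int, int], set[str]] = defaultdict(set)
    triples: dict[tuple[int, int], list[tuple[tuple[int, int], str]]] = defaultdict(list)
    split_pairs: dict[tuple[int, int], list[tuple[tuple[int, int, int, int], str]]] = defaultdict(list)
    for t in ts:
        ex = [(e.start, e.end) for e in t.exons]
        for a, b in zip(ex, ex[1:]):
            junctions[(a[1], b[0])].add(t.transcript_id)
            # outer span of a consecutive exon pair -> RI candidate
            split_pairs[(a[0], b[1])].append(((a[0], a[1], b[0], b[1]), t.transcript_id))
        for e in ex:
            exon_set[e].add(t.transcript_id)
        for i in range(1, len(ex) - 1):
            triples[(ex[i - 1][1], ex[i + 1][0])].append((ex[i], t.transcript_id))

    # SE: middle exon in a flank-junction triple vs direct flank junction
    for (e1, s3), middles in triples.items():
        direct = junctions.get((e1, s3))
        if not direct:
            continue
        for (s2, e2), tid in middles:
            emit("SE", (e1, s2, e2, s3), {tid}, set(direct))

    # RI: single exon with the same outer bounds as a consecutive exon pair
    for (s1, e2), pairs in split_pairs.items():
        retainers = exon_set.get((s1, e2))
        if not retainers:
            continue
        for (ps1, e1, s2, pe2), tid in pairs:
            emit("RI", (s1, e1, s2, e2), set(retainers), {tid})

    # MX: two non-overlapping middles sharing both flanks
    for (e1, s4), middles in triples.items():
        uniq = sorted({m for m, _ in middles})
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                (s2, e2), (s3, e3) = uniq[i], uniq[j]
                if e2 >= s3:  # middles overlap or touch: not mutually exclusive
                    continue
                left = {tid for m, tid in middles if m == uniq[i]}
                right = {tid for m, tid in middles if m == uniq[j]}
                if not left.isdisjoint(right):
                    continue
                # inclusion = path through the exon that comes first in
                # transcription direction
                inc, exc = (left, right) if strand == "+" else (right, left)
                emit("MX", (e1, s2, e2, s3, e3, s4), inc, exc)

    # A5/A3: junction pairs sharing one boundary, alternative sites within
    # overlapping exons.  AF/AL: same shared boundary but non-overlapping
    # *terminal* exons (in transcription direction).
    by_acceptor: dict[int, set[tuple[int, int]]] = defaultdict(set)
    by_donor: dict[int, set[tuple[int, int]]] = defaultdict(set)
    # exon immediately upstream (genomically left) of each junction, per transcript
    left_exon: dict[tuple[str, tuple[int, int]], tuple[int, int]] = {}
    right_exon: dict[tuple[str, tuple[int, int]], tuple[int, int]] = {}
    for t in ts:
        ex = [(e.start, e.end) for e in t.exons]
        for a, b in zip(ex, ex[1:]):
            j = (a[1], b[0])
            by_acceptor[j[1]].add(j)
            by_donor[j[0]].add(j)
            left_exon[(t.transcript_id, j)] = a
            right_exon[(t.transcript_id, j)] = b

    def overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    # shared genomic-right boundary (acceptor on '+'), varying left edge
    for s3, js in by_acceptor.items():
        js = sorted(js)
        for i in range(len(js)):
            for j in range(i + 1, len(js)):
                (e1, _), (e2, _) = js[i], js[j]
                sup1 = junctions[js[i]]
                sup2 = junctions[js[j]]
                ex1 = {left_exon[(tid, js[i])] for tid in sup1}
                ex2 = {left_exon[(tid, js[j])] for tid in sup2}
                if any(overlap(a, b) for a in ex1 for b in ex2):
                    # longer exon (larger end) = inclusion form
                    etype = "A5" if strand == "+" else "A3"
                    inc, exc = (sup2, sup1) if e2 > e1 else (sup1, sup2)
                    emit(etype, (min(e1, e2), max(e1, e2), s3), set(inc), set(exc))
                # non-overlapping alternative exons at a shared boundary are
                # handled by the terminal AF/AL pass below

    # shared genomic-left boundary (donor on '+'), varying right edge
    for e1, js in by_donor.items():
        js = sorted(js)
        for i in range(len(js)):
            for j in range(i + 1, len(js)):
                (_, s2), (_, s3) = js[i], js[j]
                sup1 = junctions[js[i]]
                sup2 = junctions[js[j]]
                ex1 = {right_exon[(tid, js[i])] for tid in sup1}
                ex2 = {right_exon[(tid, js[j])] for tid in sup2}
                if any(overlap(a, b) for a in ex1 for b in ex2):
                    etype = "A3" if strand == "+" else "A5"
                    # shorter intron (smaller start shift) = longer exonic form
                    inc, exc = (sup1, sup2) if s2 < s3 else (sup2, sup1)
                    emit(etype, (e1, min(s2, s3), max(s2, s3)), set(inc), set(exc))

    # AF/AL: non-overlapping alternative terminal exons spliced to the same
    # inner boundary.  '+' first exons share their downstream acceptor; '-'
    # first exons are genomically last and share their upstream donor.
    def terminal_events(terminal: str) -> None:
        # terminal 'first' or 'last' in transcription direction
        genomic_left = (terminal == "first") == (strand == "+")
        groups: dict[int, list[tuple[tuple[int, int], str]]] = defaultdict(list)
        for t in ts:
            ex = [(e.start, e.end) for e in t.exons]
            if len(ex) < 2:
                continue
            if genomic_left:
                groups[ex[1][0]].append((ex[0], t.transcript_id))  # shared acceptor start
            else:
                groups[ex[-2][1]].append((ex[-1], t.transcript_id))  # shared donor end
        etype = "AF" if terminal == "first" else "AL"
        for shared, items in groups.items():
            uniq = sorted({e for e, _ in items})
            for i in range(len(uniq)):
                for j in range(i + 1, len(uniq)):
                    a, b = uniq[i], uniq[j]
                    if overlap(a, b):
                        continue  # overlapping terminal exons are A5/A3 territory
                    supa = {tid for e, tid in items if e == a}
                    supb = {tid for e, tid in items if e == b}
                    if not supa.isdisjoint(supb):
                        continue
                    # inclusion = variant whose terminal exon is more distal
                    # (extends transcription span); for AF on '+' that is the
                    # genomically left exon
                    if genomic_left:
                        coords = (a[0], a[1], b[0], b[1], shared)
                        inc, exc = (supa, supb)
                    else:
                        coords = (shared, a[0], a[1], b[0], b[1])
                        inc, exc = (supb, supa)
                    emit(etype, coords, set(inc), set(exc))

    terminal_events("first")
    terminal_events("last")

    events = sorted(found.values(), key=lambda e: (e.event_type, e.coordinates))
    return events


def detect_all_events(transcripts: Iterable[TranscriptModel]) -> list[ASEvent]:
    """detect_events over every gene of a transcript collection."""
    out: list[ASEvent] = []
    for g in group_by_gene(transcripts):
        out.extend(detect_events(g))
    return out


# ---------------------------------------------------------------------------
# count tables and comparison
# ---------------------------------------------------------------------------

@dataclass
class ASCountTable:
    """samples x 7 matrix of distinct-event counts per splicing type."""

    samples: list[str]
    counts: pd.DataFrame  # index samples, columns EVENT_TYPE_ORDER

    @property
    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        props = self.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
        return props


def count_events(samples: Sequence[SampleTranscriptome]) -> ASCountTable:
    """Per-sample counts of distinct splicing events by type."""
    if not samples:
        raise ValueError("count_events needs at least one sample")
    rows = []
    for s in samples:
        events = detect_all_events(s.transcripts)
        ids_by_type: dict[str, set[str]] = defaultdict(set)
        for ev in events:
            ids_by_type[ev.event_type].add(ev.event_id)
        rows.append([len(ids_by_type.get(t, ())) for t in EVENT_TYPE_ORDER])
    df = pd.DataFrame(rows, index=[s.sample_id for s in samples], columns=list(EVENT_TYPE_ORDER))
    return ASCountTable(samples=[s.sample_id for s in samples], counts=df)


def compare_as_profiles(table: ASCountTable) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test on the samples x types table.

    Columns whose total is zero are dropped (they contribute no information
    and would make expected counts zero).  Returns (chi2, dof, p).
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValueError("degenerate table: need >=2 samples")
    col_keep = counts.sum(axis=0) > 0
    counts = counts[:, col_keep]
    row_keep = counts.sum(axis=1) > 0
    counts = counts[row_keep]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate table: need >=2 non-empty rows and columns")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# diversity score
# ---------------------------------------------------------------------------

def diversity_score(gene: GeneGroup, sample_id: str = "") -> DiversityRecord:
    """Shannon entropy (bits) of the gene's isoform-support proportions.

    Isoforms with zero read support are excluded from the distribution; a
    single expressed isoform scores 0, and n uniformly supported isoforms
    score log2(n).
    """
    supports = [t.read_support for t in gene.transcripts if t.read_support > 0]
    if not supports:
        raise ValueError(f"gene {gene.gene_id}: no expressed isoform")
    total = float(sum(supports))
    score = -sum((s / total) * math.log2(s / total) for s in supports)
    return DiversityRecord(
        gene_id=gene.gene_id,
        sample_id=sample_id,
        score=max(score, 0.0),
        n_isoforms=len(supports),
    )


def diversity_scores(sample: SampleTranscriptome) -> dict[str, DiversityRecord]:
    """Per-gene diversity for one sample, keyed by gene_id."""
    return {
        g.gene_id: diversity_score(g, sample.sample_id)
        for g in group_by_gene(sample.transcripts)
        if any(t.read_support > 0 for t in g.transcripts)
    }


def score_d(
    scores_a: dict[str, DiversityRecord],
    scores_b: dict[str, DiversityRecord],
    sample_a: str = "A",
    sample_b: str = "B",
) -> list[ScoreDRecord]:
    """Per-gene |score_a - score_b|, descending; ties broken by gene_id.

    A gene present in only one sample scores 0 in the other and is flagged
    ``one_sample_only`` so users can exclude such genes.
    """
    genes = sorted(set(scores_a) | set(scores_b))
    recs = []
    for g in genes:
        a = scores_a.get(g)
        b = scores_b.get(g)
        recs.append(
            ScoreDRecord(
                gene_id=g,
                sample_a=sample_a,
                sample_b=sample_b,
                score_a=a.score if a else 0.0,
                score_b=b.score if b else 0.0,
                one_sample_only=(a is None) != (b is None),
            )
        )
    recs.sort(key=lambda r: (-r.D, r.gene_id))
    return recs


def top_spliced_genes(
    records: Sequence[ScoreDRecord],
    k: int | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Top differentially spliced genes by rank prefix or D threshold."""
    if (k is None) == (threshold is None):
        raise ValueError("specify exactly one of k or threshold")
    if k is not None:
        if k <= 0:
            raise ValueError("k must be positive")
        return [r.gene_id for r in records[:k]]
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [r.gene_id for r in records if r.D >= threshold]


def events_to_table(events: Sequence[ASEvent]) -> pd.DataFrame:
    """Flat event export: one row per event, transcript sets semicolon-joined."""
    rows = [
        {
            "event_id": ev.event_id,
            "event_type": ev.event_type,
            "gene_id": ev.gene_id,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "coordinates": "-".join(map(str, ev.coordinates)),
            "inclusion_transcripts": ";".join(sorted(ev.inclusion_transcripts)),
            "exclusion_transcripts": ";".join(sorted(ev.exclusion_transcripts)),
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=[
        "event_id", "event_type", "gene_id", "chrom", "strand",
        "coordinates", "inclusion_transcripts", "exclusion_transcripts",
    ])
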