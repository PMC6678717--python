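"""Synthetic transcriptome fixtures with exact ground truth.

Every input the toolkit consumes — transcript GTF/BED12, feature-track BED,
coding-potential tables, lncRNA catalog with tissue labels, GO annotation —
can be generated here with a known construction plan, so every analysis
operation can be checked against what was implanted rather than against
another implementation.

Gene models are built by exon-template editing: a base isoform carries the
full exon chain and a variant isoform introduces exactly one local splicing
change (drop an internal exon for SE, merge two exons for RI, shift one
junction edge for A5/A3, swap the middle exon for MX, swap a terminal exon
for AF/AL).  The truth table lists each implanted event with its type and
defining coordinates in the same canonical form the classifier emits.

The generator models transcript *structure* only: no sequence, no alignment
error, no mono-exonic noise unless asked for.  Read supports are drawn from
a negative-binomial distribution (shifted to be >= 1) to mimic the skewed
per-isoform read counts of long-read libraries.

All randomness flows from ``numpy.random.default_rng(seed)``; identical
seed and spec give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    FeatureTrack,
    GenomicInterval,
    TranscriptModel,
    write_bed,
    write_gtf,
)
from .lncrna import CatalogEntry, PredictionSet

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")
DEFAULT_TRACKS = ("CAGE", "H3K4me1", "H3K4me3", "H3K27ac")
#: signed TSS distances (bp) the track generator draws from; spans the
#: histogram bins on both sides of the 1 kb filter cutoff
DISTANCE_PALETTE = (0, 50, -50, 200, -200, 800, -800, 1500, -1500, 5000, -5000)
FEATURE_WIDTH = 20
#: genomic spacing between genes; large enough that one transcript's planned
#: feature can never be the nearest feature of another transcript
GENE_SPACING = 100_000
BASE_OFFSET = 100_000


@dataclass
class FixtureSpec:
    """Construction plan for a synthetic transcriptome."""

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (5, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (400, 2000)
    #: (gene index, event type) pairs; None = cycle all seven types over genes
    event_plan: Optional[list[tuple[int, str]]] = None
    chroms: tuple[str, ...] = ("chr1", "chr2")
    track_names: tuple[str, ...] = DEFAULT_TRACKS
    distance_palette: tuple[int, ...] = DISTANCE_PALETTE
    tissues: tuple[str, ...] = ("liver", "brain", "heart")

    def resolved_event_plan(self) -> list[tuple[int, str]]:
        if self.event_plan is not None:
            return list(self.event_plan)
        return [(i, EVENT_TYPES[i % len(EVENT_TYPES)]) for i in range(self.n_genes)]


def _read_support(rng: np.random.Generator) -> int:
    # skewed integer counts, always >= 1 so entropy is defined
    return int(1 + rng.negative_binomial(2, 0.15))


def _build_exon_chain(
    rng: np.random.Generator, spec: FixtureSpec, chrom: str, start: int, strand: str
) -> list[GenomicInterval]:
    n = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
    exons = []
    pos = start
    for _ in range(n):
        length = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
    return exons


def _variant_for_event(
    rng: np.random.Generator,
    exons: list[GenomicInterval],
    strand: str,
    event_type: str,
) -> tuple[list[GenomicInterval], tuple[int, ...]]:
    """Edit the base exon chain to implant one event; return (variant exons, coords).

    Coordinates are returned in the classifier's canonical form for that
    event type so truth tables compare exactly.
    """
    chrom = exons[0].chrom
    ex = [(e.start, e.end) for e in exons]
    n = len(ex)
    if n < 4:
        raise ValueError(f"need >= 4 exons to implant {event_type}, got {n}")

    def iv(s: int, e: int) -> GenomicInterval:
        return GenomicInterval(chrom, s, e, strand)

    m = int(rng.integers(1, n - 2))  # internal exon index with internal neighbours
    if event_type == "SE":
        variant = [iv(s, e) for k, (s, e) in enumerate(ex) if k != m]
        e1, (s2, e2), s3 = ex[m - 1][1], ex[m], ex[m + 1][0]
        return variant, (e1, s2, e2, s3)
    if event_type == "RI":
        merged = (ex[m][0], ex[m + 1][1])
        variant = [iv(*merged) if k == m else iv(s, e) for k, (s, e) in enumerate(ex) if k != m + 1]
        return variant, (ex[m][0], ex[m][1], ex[m + 1][0], ex[m + 1][1])
    if event_type in ("A5", "A3"):
        # A5 varies the donor (transcription 5' side of the intron), A3 the
        # acceptor; on '-' the genomic edge to shift swaps
        shift_end = (event_type == "A5") == (strand == "+")
        delta = int(rng.integers(20, min(120, ex[m + 1][0] - ex[m][1] - 1) if shift_end
                                 else min(120, ex[m][0] - ex[m - 1][1] - 1)))
        if shift_end:
            new = (ex[m][0], ex[m][1] + delta)
            coords = (min(ex[m][1], new[1]), max(ex[m][1], new[1]), ex[m + 1][0])
        else:
            new = (ex[m][0] - delta, ex[m][1])
            coords = (ex[m - 1][1], min(ex[m][0], new[0]), max(ex[m][0], new[0]))
        variant = [iv(*new) if k == m else iv(s, e) for k, (s, e) in enumerate(ex)]
        return variant, coords
    if event_type == "MX":
        if n < 5:
            raise ValueError("MX needs >= 5 exons (two middles plus flanks)")
        m = int(rng.integers(1, n - 3))
        base_keep = [k for k in range(n) if k != m + 1]
        var_keep = [k for k in range(n) if k != m]
        base = [iv(*ex[k]) for k in base_keep]
        variant = [iv(*ex[k]) for k in var_keep]
        coords = (ex[m - 1][1], ex[m][0], ex[m][1], ex[m + 1][0], ex[m + 1][1], ex[m + 2][0])
        # caller treats returned pair as (base, variant) via special handling
        return base + variant, coords  # sentinel; unpacked by caller for MX
    if event_type in ("AF", "AL"):
        genomic_left = (event_type == "AF") == (strand == "+")
        if genomic_left:
            intron = ex[1][0] - ex[0][1]
            if intron < 80:
                raise ValueError("first intron too short for AF/AL implant")
            length = int(rng.integers(40, min(140, intron // 2)))
            gap = int(rng.integers(10, 40))
            new_start = ex[0][1] + gap
            new = (new_start, new_start + length)
            if new[1] >= ex[1][0]:
                new = (ex[1][0] - 1 - length, ex[1][0] - 1)
            variant = [iv(*new)] + [iv(s, e) for s, e in ex[1:]]
            a, b = sorted([ex[0], new])
            coords = (a[0], a[1], b[0], b[1], ex[1][0])
        else:
            intron = ex[-1][0] - ex[-2][1]
            if intron < 80:
                raise ValueError("last intron too short for AF/AL implant")
            length = int(rng.integers(40, min(140, intron // 2)))
            gap = int(rng.integers(10, 40))
            new_end = ex[-1][0] - gap
            new = (new_end - length, new_end)
            if new[0] <= ex[-2][1]:
                new = (ex[-2][1] + 1, ex[-2][1] + 1 + length)
            variant = [iv(s, e) for s, e in ex[:-1]] + [iv(*new)]
            a, b = sorted([ex[-1], new])
            coords = (ex[-2][1], a[0], a[1], b[0], b[1])
        return variant, coords
    raise ValueError(f"unknown event type {event_type!r}")


def generate_genes(spec: FixtureSpec) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Build gene models with implanted events plus the truth table.

    Returns (transcripts, truth) where truth has one row per implanted event:
    gene_id, event_type, chrom, strand, coordinates (dash-joined) and
    event_id in the classifier's canonical form.
    """
    rng = np.random.default_rng(spec.seed)
    plan: dict[int, str] = {}
    for gi, etype in spec.resolved_event_plan():
        if gi in plan:
            raise ValueError(f"gene index {gi}: multiple events planned (one per gene)")
        if etype not in EVENT_TYPES:
            raise ValueError(f"gene index {gi}: unknown event type {etype!r}")
        plan[gi] = etype
    transcripts: list[TranscriptModel] = []
    truth_rows = []
    cursors = {c: BASE_OFFSET for c in spec.chroms}
    for gi in range(spec.n_genes):
        chrom = spec.chroms[gi % len(spec.chroms)]
        strand = "+" if int(rng.integers(0, 2)) == 0 else "-"
        gene_id = f"G{gi:04d}"
        start = cursors[chrom]
        exons = _build_exon_chain(rng, spec, chrom, start, strand)
        etype = plan.get(gi)
        if etype is None:
            # event-free gene: one isoform, or two sharing the intron chain
            # but with a shifted outer end (ragged long-read 5'/3' ends)
            base = TranscriptModel(f"{gene_id}.1", gene_id, chrom, strand, list(exons),
                                   _read_support(rng))
            transcripts.append(base)
            if int(rng.integers(0, 2)) == 1 and len(exons) >= 2:
                shift = int(rng.integers(10, 60))
                ragged = [GenomicInterval(chrom, exons[0].start + shift, exons[0].end, strand)] + \
                    list(exons[1:])
                transcripts.append(
                    TranscriptModel(f"{gene_id}.2", gene_id, chrom, strand, ragged,
                                    _read_support(rng))
                )
        elif etype == "MX":
            both, coords = _variant_for_event(rng, exons, strand, etype)
            half = len(both) // 2
            base_ex, var_ex = both[:half], both[half:]
            transcripts.append(TranscriptModel(f"{gene_id}.1", gene_id, chrom, strand,
                                               base_ex, _read_support(rng)))
            transcripts.append(TranscriptModel(f"{gene_id}.2", gene_id, chrom, strand,
                                               var_ex, _read_support(rng)))
            truth_rows.append((gene_id, etype, chrom, strand, coords))
        else:
            var_ex, coords = _variant_for_event(rng, exons, strand, etype)
            transcripts.append(TranscriptModel(f"{gene_id}.1", gene_id, chrom, strand,
                                               list(exons), _read_support(rng)))
            transcripts.append(TranscriptModel(f"{gene_id}.2", gene_id, chrom, strand,
                                               var_ex, _read_support(rng)))
            truth_rows.append((gene_id, etype, chrom, strand, coords))
        span = exons[-1].end - start
        cursors[chrom] = start + span + GENE_SPACING
    truth = pd.DataFrame(
        [
            {
                "gene_id": g,
                "event_type": t,
                "chrom": c,
                "strand": s,
                "coordinates": "-".join(map(str, coords)),
                "event_id": f"{g};{t}:{c}:{'-'.join(map(str, coords))}:{s}",
            }
            for g, t, c, s, coords in truth_rows
        ],
        columns=["gene_id", "event_type", "chrom", "strand", "coordinates", "event_id"],
    )
    return transcripts, truth


def generate_tracks(
    transcripts: Sequence[TranscriptModel],
    spec: FixtureSpec,
) -> tuple[dict[str, FeatureTrack], pd.DataFrame]:
    """Place one feature per (transcript, track) at a planned signed TSS distance.

    Sign convention follows the distance module: negative = upstream in
    transcription direction.  Decoy features are added per chromosome far
    beyond any planned distance.  If two transcripts' TSSs are close enough
    that one's feature could be the other's nearest, generation fails rather
    than silently corrupting the truth table.
    """
    from .feature_distance import tss_of  # local import to avoid cycle at import time

    rng = np.random.default_rng(spec.seed + 1)
    max_planned = max(abs(d) for d in spec.distance_palette)
    tss_by_chrom: dict[str, list[int]] = {}
    for t in transcripts:
        tss_by_chrom.setdefault(t.chrom, []).append(tss_of(t))
    rows = []
    tracks: dict[str, FeatureTrack] = {}
    for name in spec.track_names:
        intervals = []
        for t in transcripts:
            pos = tss_of(t)
            planned = int(spec.distance_palette[int(rng.integers(0, len(spec.distance_palette)))])
            if planned == 0:
                start = pos - FEATURE_WIDTH // 2
                end = start + FEATURE_WIDTH
            else:
                genomic_downstream = (planned > 0) == (t.strand == "+")
                if genomic_downstream:
                    start = pos + abs(planned)
                    end = start + FEATURE_WIDTH
                else:
                    end = pos - abs(planned) + 1
                    start = end - FEATURE_WIDTH
            if start < 0:
                raise ValueError(
                    f"planned distance {planned} for {t.transcript_id} falls off the chromosome"
                )
            for other in tss_by_chrom[t.chrom]:
                if other == pos:
                    continue
                gap = min(abs(other - start), abs(other - (end - 1)))
                if start <= other < end or gap <= max_planned:
                    raise ValueError(
                        f"feature planned for {t.transcript_id} collides with another TSS; "
                        "use wider gene spacing or single-isoform genes"
                    )
            intervals.append(GenomicInterval(t.chrom, start, end, "."))
            rows.append({"transcript_id": t.transcript_id, "track": name,
                         "planned_distance": planned})
        # decoys, far beyond every planned distance
        for chrom, positions in sorted(tss_by_chrom.items()):
            far = max(positions) + 1_000_000
            intervals.append(GenomicInterval(chrom, far, far + FEATURE_WIDTH, "."))
        tracks[name] = FeatureTrack(name=name, intervals=intervals)
    truth = pd.DataFrame(rows, columns=["transcript_id", "track", "planned_distance"])
    return tracks, truth


@dataclass
class LncFixture:
    candidates: list[TranscriptModel]
    catalog: list[CatalogEntry]
    predictions: tuple[PredictionSet, PredictionSet]
    truth: pd.DataFrame


def generate_lnc_inputs(spec: FixtureSpec, n_candidates: int = 30) -> LncFixture:
    """Candidates, catalog, two prediction tables and their joint truth table.

    Half the candidates are clones of catalog entries with shifted terminal
    exon extents (known in intron-chain matching); the rest carry a shifted
    internal junction (novel).  Catalog tissue labels cycle single tissue /
    two tissues / unlabelled, so tissue-specific extraction has all cases.
    Classifier calls cycle both-noncoding / A-only / B-only / both-coding.
    """
    rng = np.random.default_rng(spec.seed + 2)
    gene_spec = FixtureSpec(
        seed=spec.seed + 3,
        n_genes=n_candidates,
        exons_per_gene=spec.exons_per_gene,
        exon_length=spec.exon_length,
        intron_length=spec.intron_length,
        event_plan=[],  # no splicing variants: one model per gene
        chroms=spec.chroms,
        tissues=spec.tissues,
    )
    base_models, _ = generate_genes(gene_spec)
    # one model per gene (event-free genes may emit a ragged second isoform;
    # keep only the .1 models)
    base_models = [m for m in base_models if m.transcript_id.endswith(".1")][:n_candidates]
    if len(base_models) < n_candidates:
        raise ValueError("not enough base models generated")
    catalog: list[CatalogEntry] = []
    candidates: list[TranscriptModel] = []
    truth_rows = []
    tissue_cycle = ["single", "multi", "none"]
    call_cycle = ["both", "a_only", "b_only", "neither"]
    calls_a: dict[str, str] = {}
    calls_b: dict[str, str] = {}
    for i, model in enumerate(base_models):
        known = i % 2 == 0
        cand_id = f"CAND{i:04d}"
        if known:
            entry_id = f"LNC{i:04d}"
            entry = CatalogEntry(
                TranscriptModel(entry_id, f"LG{i:04d}", model.chrom, model.strand,
                                list(model.exons), 1),
                tissues=_tissue_labels(tissue_cycle[(i // 2) % 3], spec.tissues, rng),
            )
            catalog.append(entry)
            # clone with ragged terminal extents: same intron chain
            ex = list(model.exons)
            d1 = int(rng.integers(5, 50))
            d2 = int(rng.integers(5, 50))
            ex[0] = GenomicInterval(model.chrom, ex[0].start + d1, ex[0].end, model.strand)
            ex[-1] = GenomicInterval(model.chrom, ex[-1].start, ex[-1].end + d2, model.strand)
            cand = TranscriptModel(cand_id, model.gene_id, model.chrom, model.strand, ex,
                                   _read_support(rng))
            ts = sorted(entry.tissues)
            tissue_specific = ts[0] if len(ts) == 1 else ("unassigned" if not ts else "")
            truth_rows.append({"transcript_id": cand_id, "verdict": "known",
                               "matched_entry": entry_id,
                               "tissues": ",".join(ts),
                               "tissue_specific": tissue_specific})
        else:
            # novel: shift one internal junction so the intron chain is unique
            ex = list(model.exons)
            m = len(ex) // 2
            delta = int(rng.integers(7, 17))
            ex[m] = GenomicInterval(model.chrom, ex[m].start + delta, ex[m].end, model.strand)
            cand = TranscriptModel(cand_id, model.gene_id, model.chrom, model.strand, ex,
                                   _read_support(rng))
            truth_rows.append({"transcript_id": cand_id, "verdict": "novel",
                               "matched_entry": "", "tissues": "", "tissue_specific": ""})
        candidates.append(cand)
        mode = call_cycle[i % 4]
        calls_a[cand_id] = "noncoding" if mode in ("both", "a_only") else "coding"
        calls_b[cand_id] = "noncoding" if mode in ("both", "b_only") else "coding"
        truth_rows[-1]["call_a"] = calls_a[cand_id]
        truth_rows[-1]["call_b"] = calls_b[cand_id]
    preds = (
        PredictionSet("PLEK", calls_a,
                      {tid: round(float(rng.normal(0, 1)), 4) for tid in calls_a}),
        PredictionSet("CNCI", calls_b,
                      {tid: round(float(rng.normal(0, 1)), 4) for tid in calls_b}),
    )
    truth = pd.DataFrame(truth_rows, columns=[
        "transcript_id", "verdict", "matched_entry", "tissues", "tissue_specific",
        "call_a", "call_b",
    ])
    return LncFixture(candidates=candidates, catalog=catalog, predictions=preds, truth=truth)


def _tissue_labels(kind: str, tissues: tuple[str, ...], rng: np.random.Generator) -> frozenset[str]:
    if kind == "none":
        return frozenset()
    if kind == "single":
        return frozenset({tissues[int(rng.integers(0, len(tissues)))]})
    k = min(2, len(tissues))
    idx = rng.choice(len(tissues), size=k, replace=False)
    return frozenset(tissues[int(i)] for i in idx)


def generate_annotation(
    seed: int, n_genes: int = 60, n_terms: int = 12, term_size: tuple[int, int] = (4, 12)
) -> tuple[dict[str, set[str]], list[str]]:
    """Random gene->GO-term annotation: (term -> gene set, gene universe)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    terms: dict[str, set[str]] = {}
    for ti in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        idx = rng.choice(n_genes, size=size, replace=False)
        terms[f"GO:{ti:07d}"] = {genes[int(i)] for i in idx}
    return terms, genes


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fixture_set(spec: FixtureSpec, outdir: str | Path, n_candidates: int = 30) -> dict[str, Path]:
    """Generate and write the full fixture family under ``outdir``.

    Emits transcripts.gtf, one BED per feature track, PLEK/CNCI-dialect
    prediction tables, catalog.gtf, tissues.tsv, gene2go.tsv and
    truth/*.tsv; returns the path of every file written.
    """
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    transcripts, event_truth = generate_genes(spec)
    paths["transcripts"] = outdir / "transcripts.gtf"
    write_gtf(transcripts, paths["transcripts"])
    paths["event_truth"] = outdir / "truth" / "events.tsv"
    event_truth.to_csv(paths["event_truth"], sep="\t", index=False)

    track_spec = FixtureSpec(seed=spec.seed, n_genes=spec.n_genes, event_plan=[],
                             chroms=spec.chroms, track_names=spec.track_names,
                             distance_palette=spec.distance_palette)
    track_models, _ = generate_genes(track_spec)
    track_models = [m for m in track_models if m.transcript_id.endswith(".1")]
    tracks, dist_truth = generate_tracks(track_models, track_spec)
    paths["track_transcripts"] = outdir / "track_transcripts.gtf"
    write_gtf(track_models, paths["track_transcripts"])
    for name, track in tracks.items():
        p = outdir / f"{name}.bed"
        write_bed(track, p)
        paths[f"track:{name}"] = p
    paths["distance_truth"] = outdir / "truth" / "distances.tsv"
    dist_truth.to_csv(paths["distance_truth"], sep="\t", index=False)

    lnc = generate_lnc_inputs(spec, n_candidates=n_candidates)
    paths["candidates"] = outdir / "candidates.gtf"
    write_gtf(lnc.candidates, paths["candidates"])
    paths["catalog"] = outdir / "catalog.gtf"
    write_gtf([e.model for e in lnc.catalog], paths["catalog"])
    paths["tissues"] = outdir / "tissues.tsv"
    from .lncrna import write_tissue_table

    write_tissue_table({e.transcript_id: e.tissues for e in lnc.catalog}, paths["tissues"])
    paths["plek"] = outdir / "plek.txt"
    with paths["plek"].open("w") as fh:
        for tid in sorted(lnc.predictions[0].calls):
            lab = "Non-coding" if lnc.predictions[0].calls[tid] == "noncoding" else "Coding"
            fh.write(f"{lab}\t{lnc.predictions[0].scores[tid]}\t>{tid}\n")
    paths["cnci"] = outdir / "cnci.txt"
    with paths["cnci"].open("w") as fh:
        fh.write("Transcript ID\tindex\tscore\n")
        for tid in sorted(lnc.predictions[1].calls):
            fh.write(f"{tid}\t{lnc.predictions[1].calls[tid]}\t{lnc.predictions[1].scores[tid]}\n")
    paths["lnc_truth"] = outdir / "truth" / "lncrna.tsv"
    lnc.truth.to_csv(paths["lnc_truth"], sep="\t", index=False)

    terms, genes = generate_annotation(spec.seed + 4)
    paths["gene2go"] = outdir / "gene2go.tsv"
    with paths["gene2go"].open("w") as fh:
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{gene}\t{term}\n")
    return paths
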