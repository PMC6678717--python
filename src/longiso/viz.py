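"""Figures with machine-readable layout manifests.

Each plotting function renders a PNG/SVG via matplotlib and writes a JSON
manifest alongside it listing every drawn element with its genomic or
numeric coordinates.  Tests assert on the manifest — pixel comparison is
brittle across fonts and backends — and only smoke-test the image file.

Style roles (not hard-coded colors) follow genome-browser convention:
novel long-read isoforms red, known long-read isoforms black, reference
annotation blue, and per-mark arrow colors for CAGE/histone tracks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .feature_distance import DEFAULT_BIN_EDGES
from .io_formats import FeatureTrack, TranscriptModel
from .splicing import ASCountTable, EVENT_TYPE_ORDER

DEFAULT_STYLE = {
    "novel_transcripts": "#d62728",
    "known_tgs_transcripts": "#000000",
    "annotation_transcripts": "#1f77b4",
    "CAGE": "#d62728",
    "H3K4me1": "#d62728",
    "H3K4me3": "#1f77b4",
    "H3K27ac": "#2ca02c",
}

DEFAULT_FLANK = 2000


def _write_manifest(manifest: dict, out_path: Path) -> Path:
    mpath = out_path.with_suffix(out_path.suffix + ".manifest.json")
    with mpath.open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mpath


def plot_transcript_overview(
    gene_id: str,
    novel: Sequence[TranscriptModel],
    known_tgs: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    tracks: Sequence[FeatureTrack],
    out_path: str | Path,
    flank: int = DEFAULT_FLANK,
    style: Optional[Mapping[str, str]] = None,
) -> dict:
    """Gene-level track plot: isoforms over reference annotation and feature marks.

    Transcript labels carry the long-read support in brackets.  Features
    outside the gene span +- flank are clipped from both image and manifest.
    Track stacking (top to bottom): novel, known long-read, annotation,
    feature marks.
    """
    style = {**DEFAULT_STYLE, **(style or {})}
    groups = [
        ("novel_transcripts", [t for t in novel if t.gene_id == gene_id]),
        ("known_tgs_transcripts", [t for t in known_tgs if t.gene_id == gene_id]),
        ("annotation_transcripts", [t for t in annotation if t.gene_id == gene_id]),
    ]
    all_ts = [t for _, ts in groups for t in ts]
    if not all_ts:
        available = sorted({t.gene_id for src in (novel, known_tgs, annotation) for t in src})
        raise ValueError(f"gene {gene_id!r} not found; available genes: {available}")
    chrom = all_ts[0].chrom
    region_start = max(0, min(t.start for t in all_ts) - flank)
    region_end = max(t.end for t in all_ts) + flank

    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(10, 0.6 * (len(all_ts) + len(tracks)) + 2))
    manifest: dict = {
        "gene_id": gene_id,
        "region": {"chrom": chrom, "start": region_start, "end": region_end},
        "elements": [],
    }
    y = 0
    for role, ts in groups:
        for t in ts:
            color = style[role]
            label = f"{t.transcript_id} ({t.read_support})"
            ax.plot([t.start, t.end], [y, y], color=color, lw=1)
            for ex in t.exons:
                ax.add_patch(plt.Rectangle((ex.start, y - 0.3), len(ex), 0.6, color=color))
                manifest["elements"].append(
                    {"kind": "exon", "track": role, "transcript_id": t.transcript_id,
                     "start": ex.start, "end": ex.end}
                )
            for i_start, i_end in t.introns:
                manifest["elements"].append(
                    {"kind": "intron", "track": role, "transcript_id": t.transcript_id,
                     "start": i_start, "end": i_end}
                )
            marker = ">" if t.strand == "+" else "<"
            ax.plot([t.end if t.strand == "+" else t.start], [y], marker=marker, color=color)
            ax.text(region_end, y, label, fontsize=7, va="center")
            manifest["elements"].append(
                {"kind": "label", "track": role, "transcript_id": t.transcript_id,
                 "text": label}
            )
            y -= 1
    for track in tracks:
        for iv in track.on_chrom(chrom):
            if iv.end <= region_start or iv.start >= region_end:
                continue  # clipped
            mid = (iv.start + iv.end) // 2
            ax.plot([mid], [y], marker="v", color=style.get(track.name, "#888888"))
            manifest["elements"].append(
                {"kind": "feature", "track": track.name, "start": iv.start, "end": iv.end}
            )
        y -= 1
    ax.set_xlim(region_start, region_end)
    ax.set_ylim(y - 1, 1)
    ax.set_yticks([])
    ax.set_xlabel(f"{chrom} position (bp)")
    ax.set_title(gene_id)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    _write_manifest(manifest, out_path)
    return manifest


def plot_as_proportions(
    table: ASCountTable,
    test_result: Optional[tuple[float, int, float]],
    out_path: str | Path,
) -> dict:
    """Stacked 100% bars of splicing-type proportions per sample.

    Segment order is fixed (A3, A5, AF, AL, MX, RI, SE) for cross-run
    comparability; the chi-square homogeneity result is annotated when given.
    """
    counts = table.counts
    totals = counts.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("all-zero count table")
    out_path = Path(out_path)
    pct = counts.div(totals.replace(0, float("nan")), axis=0).fillna(0.0) * 100.0
    fig, ax = plt.subplots(figsize=(1.2 * len(table.samples) + 3, 5))
    bottom = [0.0] * len(table.samples)
    cmap = plt.get_cmap("tab10")
    for ci, etype in enumerate(EVENT_TYPE_ORDER):
        vals = pct[etype].tolist()
        ax.bar(table.samples, vals, bottom=bottom, label=etype, color=cmap(ci))
        bottom = [b + v for b, v in zip(bottom, vals)]
    ax.set_ylabel("% of splicing events")
    ax.legend(loc="center left", bbox_to_anchor=(1.02, 0.5), fontsize=8)
    title = "Alternative splicing profile"
    manifest: dict = {
        "samples": list(table.samples),
        "percentages": {s: {t: float(pct.loc[s, t]) for t in EVENT_TYPE_ORDER}
                        for s in table.samples},
        "counts": {s: {t: int(counts.loc[s, t]) for t in EVENT_TYPE_ORDER}
                   for s in table.samples},
    }
    if test_result is not None:
        chi2, dof, p = test_result
        title += f"  (chi2={chi2:.3g}, dof={dof}, p={p:.3g})"
        manifest["chi2"] = {"statistic": float(chi2), "dof": int(dof), "p": float(p)}
    ax.set_title(title, fontsize=10)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    _write_manifest(manifest, out_path)
    return manifest


def plot_distance_distribution(
    histograms: Mapping[str, Sequence[int]],
    out_path: str | Path,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> dict:
    """Per-track histogram of |TSS distance| on the configured bins."""
    if not any(any(v) for v in histograms.values()):
        raise ValueError("no finite distances to plot")
    out_path = Path(out_path)
    edges = list(bin_edges)
    labels = [f"[{a},{b})" for a, b in zip(edges, edges[1:])] + [f">={edges[-1]}"]
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.8 / max(1, len(histograms))
    for i, (name, counts) in enumerate(sorted(histograms.items())):
        xs = [j + i * width for j in range(len(labels))]
        ax.bar(xs, list(counts), width=width, label=name)
    ax.set_xticks([j + 0.4 for j in range(len(labels))])
    ax.set_xticklabels(labels, rotation=30, fontsize=8)
    ax.set_xlabel("|TSS to nearest feature| (bp)")
    ax.set_ylabel("transcripts")
    ax.legend(fontsize=8)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    manifest = {"bin_edges": edges, "bins": labels,
                "counts": {k: [int(c) for c in v] for k, v in histograms.items()}}
    _write_manifest(manifest, out_path)
    return manifest


def plot_lnc_venn(
    set_a: set[str],
    set_b: set[str],
    out_path: str | Path,
    label_a: str = "tool A",
    label_b: str = "tool B",
) -> dict:
    """Two-set Venn of noncoding calls; manifest carries the region counts."""
    only_a = len(set_a - set_b)
    both = len(set_a & set_b)
    only_b = len(set_b - set_a)
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(5, 4))
    c1 = plt.Circle((-0.35, 0), 0.75, alpha=0.4, color="#1f77b4")
    c2 = plt.Circle((0.35, 0), 0.75, alpha=0.4, color="#d62728")
    ax.add_patch(c1)
    ax.add_patch(c2)
    ax.text(-0.75, 0, str(only_a), ha="center", va="center", fontsize=12)
    ax.text(0, 0, str(both), ha="center", va="center", fontsize=12)
    ax.text(0.75, 0, str(only_b), ha="center", va="center", fontsize=12)
    ax.text(-0.6, 0.9, label_a, ha="center", fontsize=10)
    ax.text(0.6, 0.9, label_b, ha="center", fontsize=10)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.1, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    manifest = {"labels": [label_a, label_b],
                "only_a": only_a, "intersection": both, "only_b": only_b}
    _write_manifest(manifest, out_path)
    return manifest
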