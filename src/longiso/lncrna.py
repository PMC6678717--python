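"""Combine coding-potential predictions and match candidates to a lncRNA catalog.

Two external classifiers (e.g. PLEK and CNCI) label each transcript coding or
noncoding from sequence alone.  Their call sets are combined as separate,
intersection and union outputs so users can trade precision (intersection)
against recall (union).  Candidate noncoding transcripts are then compared
with a reference lncRNA catalog carrying tissue labels: a candidate whose
intron chain matches a catalog entry is "known", and if all its matched
entries are annotated to exactly one tissue it is reported as
tissue-specific.

Intron-chain identity is the matching criterion because long-read models
have ragged 5'/3' ends: terminal-exon extents differ between a read-derived
model and the catalog entry it re-identifies, but internal splice junctions
do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .io_formats import FormatError, TranscriptModel

CODING = "coding"
NONCODING = "noncoding"

# dialect-specific label vocabularies, lower-cased
_LABEL_MAP = {
    "coding": CODING,
    "non-coding": NONCODING,
    "noncoding": NONCODING,
    "noncode": NONCODING,
    "nc": NONCODING,
}


@dataclass
class PredictionSet:
    """Normalized calls of one coding-potential classifier."""

    tool_name: str
    calls: dict[str, str]  # transcript_id -> coding | noncoding
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def noncoding_ids(self) -> set[str]:
        return {tid for tid, lab in self.calls.items() if lab == NONCODING}


@dataclass
class LncRNACallSet:
    source: str  # tool name, "intersection" or "union"
    transcript_ids: set[str]


@dataclass
class CatalogEntry:
    """A reference lncRNA with the tissues it is annotated to (possibly none)."""

    model: TranscriptModel
    tissues: frozenset[str] = frozenset()

    @property
    def transcript_id(self) -> str:
        return self.model.transcript_id


@dataclass
class MatchVerdict:
    transcript_id: str
    known: bool
    matched_entries: list[CatalogEntry] = field(default_factory=list)

    @property
    def tissues(self) -> set[str]:
        out: set[str] = set()
        for e in self.matched_entries:
            out |= e.tissues
        return out


def _normalize_label(token: str, path: Path, lineno: int) -> str:
    lab = _LABEL_MAP.get(token.strip().lower())
    if lab is None:
        raise FormatError(f"{path}:{lineno}: unknown coding-potential label {token!r}")
    return lab


def read_predictions(path: str | Path, dialect: str = "generic", tool_name: str | None = None) -> PredictionSet:
    """Read a classifier output table.

    Dialects:
      * ``plek``: label TAB score TAB id (id may carry a FASTA '>' prefix)
      * ``cnci``: id TAB index-label TAB score [...]; a header line starting
        with "Transcript" is skipped
      * ``generic``: id TAB label
    """
    path = Path(path)
    calls: dict[str, str] = {}
    scores: dict[str, float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "plek":
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 PLEK columns")
                label, score, tid = fields[0], fields[1], fields[2]
            elif dialect == "cnci":
                if lineno == 1 and fields[0].lower().startswith("transcript"):
                    continue
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: expected >=3 CNCI columns")
                tid, label, score = fields[0], fields[1], fields[2]
            elif dialect == "generic":
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: expected id TAB label")
                tid, label = fields[0], fields[1]
                score = None
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            tid = tid.lstrip(">").strip()
            if tid in calls:
                raise FormatError(f"{path}:{lineno}: duplicate transcript id {tid}")
            calls[tid] = _normalize_label(label, path, lineno)
            if score is not None:
                try:
                    scores[tid] = float(score)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score {score!r}") from exc
    return PredictionSet(tool_name=tool_name or dialect, calls=calls, scores=scores)


def write_predictions(pred: PredictionSet, path: str | Path) -> None:
    """Write calls in the generic two-column dialect, sorted by id."""
    with Path(path).open("w") as fh:
        for tid in sorted(pred.calls):
            fh.write(f"{tid}\t{pred.calls[tid]}\n")


def combine_predictions(a: PredictionSet, b: PredictionSet) -> dict[str, LncRNACallSet]:
    """Separate, intersection and union noncoding-call sets of two classifiers.

    Ids labelled by only one tool are excluded from the intersection and
    enter the union via the calling tool alone.
    """
    na, nb = a.noncoding_ids, b.noncoding_ids
    return {
        a.tool_name: LncRNACallSet(a.tool_name, set(na)),
        b.tool_name: LncRNACallSet(b.tool_name, set(nb)),
        "intersection": LncRNACallSet("intersection", na & nb),
        "union": LncRNACallSet("union", na | nb),
    }


def _reciprocal_overlap(a: TranscriptModel, b: TranscriptModel) -> float:
    """min(shared exonic bases / exonic bases of each model)."""
    def blocks(t: TranscriptModel) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in t.exons]

    shared = 0
    for s1, e1 in blocks(a):
        for s2, e2 in blocks(b):
            shared += max(0, min(e1, e2) - max(s1, s2))
    la = sum(e - s for s, e in blocks(a))
    lb = sum(e - s for s, e in blocks(b))
    return min(shared / la, shared / lb)


def match_to_catalog(
    candidates: Sequence[TranscriptModel],
    catalog: Sequence[CatalogEntry],
    mode: str = "intron_chain",
    overlap_threshold: float = 0.5,
) -> list[MatchVerdict]:
    """Classify each candidate as known (matched) or novel against the catalog.

    ``intron_chain`` mode (default): known iff some entry on the same chrom
    and strand has the identical ordered intron set; single-exon candidates
    fall back to reciprocal exon overlap.  ``exon_overlap`` mode: known iff
    reciprocal exonic overlap >= ``overlap_threshold`` with some same-strand
    entry.
    """
    if mode not in ("intron_chain", "exon_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (0 < overlap_threshold <= 1):
        raise ValueError("overlap_threshold must be in (0, 1]")
    by_chain: dict[tuple, list[CatalogEntry]] = {}
    by_chrom: dict[tuple[str, str], list[CatalogEntry]] = {}
    for e in catalog:
        key = (e.model.chrom, e.model.strand, e.model.intron_chain)
        by_chain.setdefault(key, []).append(e)
        by_chrom.setdefault((e.model.chrom, e.model.strand), []).append(e)
    verdicts = []
    for cand in candidates:
        matches: list[CatalogEntry] = []
        use_overlap = mode == "exon_overlap" or len(cand.exons) == 1
        if use_overlap:
            for e in by_chrom.get((cand.chrom, cand.strand), []):
                if (
                    cand.start < e.model.end
                    and e.model.start < cand.end
                    and _reciprocal_overlap(cand, e.model) >= overlap_threshold
                ):
                    matches.append(e)
        else:
            matches = list(by_chain.get((cand.chrom, cand.strand, cand.intron_chain), []))
        verdicts.append(MatchVerdict(cand.transcript_id, known=bool(matches), matched_entries=matches))
    return verdicts


UNASSIGNED = "unassigned"


def tissue_specific(verdicts: Iterable[MatchVerdict]) -> dict[str, list[str]]:
    """Group matched candidates whose tissue evidence points to exactly one tissue.

    A candidate is tissue-specific iff the union of tissue labels over all
    its matched catalog entries has size 1.  Candidates matching only
    unlabelled entries are reported under ``unassigned``; multi-tissue and
    novel candidates are omitted.
    """
    out: dict[str, list[str]] = {}
    for v in verdicts:
        if not v.known:
            continue
        tissues = v.tissues
        if len(tissues) == 1:
            out.setdefault(next(iter(tissues)), []).append(v.transcript_id)
        elif len(tissues) == 0:
            out.setdefault(UNASSIGNED, []).append(v.transcript_id)
    for ids in out.values():
        ids.sort()
    return out


def read_tissue_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read transcript_id TAB comma-joined tissue labels (empty second column ok)."""
    path = Path(path)
    out: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tid = fields[0]
            labels = fields[1] if len(fields) > 1 else ""
            out[tid] = frozenset(x for x in labels.split(",") if x)
    return out


def write_tissue_table(tissues: dict[str, frozenset[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for tid in sorted(tissues):
            fh.write(f"{tid}\t{','.join(sorted(tissues[tid]))}\n")


def build_catalog(
    models: Sequence[TranscriptModel], tissues: dict[str, frozenset[str]] | None = None
) -> list[CatalogEntry]:
    tissues = tissues or {}
    return [CatalogEntry(m, frozenset(tissues.get(m.transcript_id, ()))) for m in models]
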