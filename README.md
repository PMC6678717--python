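# longiso

A toolkit for transcriptome analysis of long-read (third-generation
sequencing) data: PacBio and Nanopore reads capture full-length isoforms,
but their higher error rate and ragged ends produce spurious transcript
models. `longiso` helps separate genuine isoforms from artifacts and
characterize what remains:

* **Full-length transcript validation** — a real transcription start site
  (TSS) should sit near independent regulatory evidence.  For every
  transcript, `longiso` computes the signed distance from its TSS (the
  first transcribed nucleotide, strand-aware) to the nearest feature of
  each evidence track (CAGE peaks, H3K4me1/H3K4me3/H3K27ac marks) and can
  discard transcripts with no feature within a cutoff (default 1 kb up- or
  downstream).
* **Alternative-splicing classification** — local splicing events between
  the isoforms of a gene are classified into the seven standard types
  (SE skipped exon, RI retained intron, A5/A3 alternative 5′/3′ splice
  site, MX mutually exclusive exons, AF/AL alternative first/last exon),
  counted per sample, and sample profiles are compared with a Pearson χ²
  homogeneity test.
* **Isoform diversity** — per gene and sample, the Shannon entropy of the
  isoform read-support proportions, H = −Σ pᵢ log₂ pᵢ with
  pᵢ = readsᵢ / Σ reads; the per-gene difference D = |H_a − H_b| between
  two samples ranks the most differentially spliced genes, which feed a
  hypergeometric GO over-representation test with Benjamini–Hochberg
  correction.
* **lncRNA candidates** — noncoding calls from two external
  coding-potential classifiers (PLEK- and CNCI-style tables) are combined
  into separate / intersection / union sets, matched against a reference
  lncRNA catalog by intron-chain identity (robust to ragged read ends),
  and known candidates whose catalog evidence points to exactly one tissue
  are reported as tissue-specific.

Every figure (gene-level transcript overview, stacked AS proportions, TSS
distance histograms, two-set Venn) is emitted together with a JSON layout
manifest holding the exact numbers drawn, so results are scriptable and
testable.

A synthetic-data module generates every input format with known ground
truth (implanted events, planned TSS distances, constructed known/novel
and tissue assignments), so the whole pipeline runs and is tested without
any downloads.

## Worked example

```python
from longiso import fixtures, splicing, feature_distance
from longiso.io_formats import SampleTranscriptome

spec = fixtures.FixtureSpec(seed=42, n_genes=14)
transcripts, truth = fixtures.generate_genes(spec)
sample = SampleTranscriptome("demo", transcripts)

events = splicing.detect_all_events(transcripts)
print(f"{len(events)} splicing events detected in {truth.shape[0]} implanted:")
print(splicing.count_events([sample]).counts.to_string())

track_spec = fixtures.FixtureSpec(seed=42, n_genes=14, event_plan=[])
models, _ = fixtures.generate_genes(track_spec)
models = [m for m in models if m.transcript_id.endswith(".1")]
tracks, _ = fixtures.generate_tracks(models, track_spec)
report = feature_distance.filter_by_distance(
    SampleTranscriptome("demo", models), list(tracks.values()), cutoff_bp=1000)
print(f"TSS filter at 1 kb: kept {len(report.kept)} / {len(models)} transcripts")

scores = splicing.diversity_scores(sample)
top = sorted(scores.values(), key=lambda r: -r.score)[0]
print(f"most diverse gene: {top.gene_id} (H = {top.score:.3f} bits, "
      f"{top.n_isoforms} isoforms)")
```

prints

```
14 splicing events detected in 14 implanted:
      A3  A5  AF  AL  MX  RI  SE
demo   2   2   2   2   2   2   2
TSS filter at 1 kb: kept 13 / 14 transcripts
most diverse gene: G0004 (H = 1.000 bits, 2 isoforms)
```

The 14 synthetic genes carry one implanted event each (two of each type);
the classifier recovers all of them.  One transcript's nearest planned
evidence feature lies beyond 1 kb, so the filter discards it.  The top
diversity score of 1.0 bit means that gene's two isoforms carry equal read
support.

## Command line

Each analysis is also a subcommand of the `longiso` entry point:

```sh
longiso simulate --seed 42 --outdir fx/                 # synthetic inputs + truth tables
longiso stadist  --transcripts fx/track_transcripts.gtf \
                 --track CAGE=fx/CAGE.bed --out dist.tsv
longiso transfilt --transcripts fx/track_transcripts.gtf \
                  --track CAGE=fx/CAGE.bed --cutoff 1000 \
                  --out-kept kept.gtf --out-discarded spurious.gtf
longiso staas    --sample A=a.gtf --sample B=b.gtf --out counts.tsv --plot as.png
longiso calscored --sample-a a.gtf --sample-b b.gtf --top 50 --out scored.tsv
longiso goenrich --genes top.txt --annot gene2go.tsv --out enrich.tsv
longiso lncpred  --plek plek.txt --cnci cnci.txt --out-prefix lnc --venn venn.png
longiso lncext   --candidates cand.gtf --catalog catalog.gtf --out verdict.tsv
longiso lncexttiss --candidates cand.gtf --catalog catalog.gtf \
                   --tissues tissues.tsv --out tiss.tsv
longiso transdisp --gene G0000 --novel fx/transcripts.gtf \
                  --track CAGE=fx/CAGE.bed --out G0000.png
```

Transcript inputs are GTF (1-based; converted internally to 0-based
half-open) or BED12; feature tracks are BED; per-transcript long-read
counts come from a configurable GTF attribute (default `read_count`).

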