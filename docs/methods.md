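# Methods

## Model

The engine treats the regulome as a family of interval tracks: for each
source dataset (e.g., CAGE-derived enhancers, candidate regulatory
elements from peak-called open chromatin, TF ChIP footprints), one track
per tissue or primary cell type, each track a sorted disjoint set of
genomic intervals in one genome build (`hg19` or `hg38`). The core
assumption is that a regulator relevant to a gene and a phenotype is
(a) genomically proximal to one of the gene's transcription start sites
and (b) active — present in the corresponding tissue track. Proximity is
purely linear (a TSS window); no chromatin-contact or eQTL linking is
attempted, so some returned regions will in truth regulate neighbouring
genes.

### Coordinates

Everything internal is 0-based half-open. The 1-based boundaries appear in
exactly two places: VCF positions (`POS` → occupied span
`[POS−1, POS−1+len(REF))`) and genome-browser position strings
(`chr8:11001-20000` for `[11000, 20000)`). Chromosome names are compared
verbatim, with an optional (default-on) load-time normalization of bare
names (`1` → `chr1`, `MT` → `chrM`) to absorb BED dialect differences.

### TSS windows

A transcript's TSS is its first transcribed base: `txStart` on `+`,
`txEnd − 1` on `−`. The window `[TSS − up, TSS + down]` is strand-aware —
"upstream" means against transcription — because that is what upstream of
a TSS means biologically; a `strand_aware=False` flag gives the
genomic-left interpretation for comparison with strand-agnostic pipelines.
The TSS base is always included, so `up = down = 0` still yields a 1-bp
searchable window. Windows clamp at position 0. All transcripts of a gene
contribute windows; no canonical-transcript selection.

### Activity modes

"Present in a tissue track" is ≥ 1 bp overlap between the candidate region
and that track, *not* exact coordinate identity: different tissues' peak
calls delimit the same element with slightly different boundaries, and
identity matching would spuriously fail them. *active-in-any* requires
presence in ≥ 1 queried tissue track of the dataset; *active-in-all*
requires presence in every queried tissue track **that exists** in the
dataset — a tissue without data is reported as missing rather than
counted as a failure, otherwise sparse datasets could never satisfy the
strict mode. The candidate universe is restricted to TSS-window-overlapping
regions before the per-tissue checks; this is equivalent to the literal
order of the two conditions (both are per-region filters) and is verified
against a literal brute-force re-check in the tests.

### miRNA branch

Interaction tables are not tissue-specific, so tissue restriction is
imposed through chromatin: a miRNA locus is returned iff it targets a
query gene (predicted interactions only count with 3′-UTR support;
duplicate (miRNA, gene) records are deduplicated keeping the
highest-priority evidence tag, ties broken lexicographically) and its
transcript span overlaps ≥ 1 bp of an accessible-chromatin track of a
target tissue. Any accessible-chromatin-class track qualifies by default;
`chromatin_datasets` restricts to specific sources. Whole transcript
spans are used, not seed sites.

### Merging

Results are merged with a bedtools-compatible sweep: at `gap=0`
overlapping *and bookended* intervals fuse (matching `bedtools merge`
defaults, cross-checked against the bedtools CLI in the test suite), and
provenance sets union. Merging across datasets uses `gap=0`; there is no
evidence that bridging near-adjacent regions from different assays is
meaningful, and a gap parameter is exposed for users who disagree.

## Data preparation

* **Replicate collapsing** — tracks with identical
  (dataset, tissue, class, build) keys are unioned per-base; pre-lifted
  BEDs are ordinary replicates here (coordinate liftover itself is an
  external preprocessing step).
* **CAGE promoters** — peaks with TPM < 10 are dropped (strictly-less:
  a peak at exactly 10 survives); survivors are extended 200 bp upstream
  in transcription direction, clamped at 0, then collapsed. The API takes
  a per-tissue peak list, so the split-by-ontology step precedes the
  filter by construction.
* **ccRE splitting** — class-annotated BED records are routed to tracks
  by a case-insensitive token vocabulary (`promoter-like`/`PLS`,
  `enhancer-like`/`ELS`, `CTCF`/insulator, `DNase`/accessible);
  unrecognized tokens are skipped and counted, and a file with no
  recognizable token is an error.

## Variant filtering

A record is kept iff its REF-allele span overlaps ≥ 1 region — so a
deletion or MNV straddling a region edge is kept even when POS is outside,
which is the right call for regulatory deletions whose effect is their
span. Symbolic alleles (`<DEL>`, breakends) match on the POS base only,
with a warning; END-tag expansion is out of scope. The header and kept
records pass through byte-identical, in original order; the genome build
is always declared by the caller and validated against the regions' build,
never inferred.

## Evaluation

Cases are (variant, gene, best tissue, related tissues). Categories:
**promoter** if the variant is 1–100 bp upstream (transcription direction)
of *any* transcript start of the gene; else **intragenic** if inside any
transcript span; else **distal**. Promoter precedence resolves
multi-transcript conflicts; distance boundaries (1, 100, 101 bp) are
pinned by tests on both strands. Tiers are nested by construction —
{best} ⊆ {best} ∪ related ⊆ all tissues — which makes recall monotonically
non-decreasing and span specificity monotonically non-increasing across
tiers; the suite asserts exactly this ordering. Specificity is primarily
span-based, `1 − span(selected ∩ unselected) / span(unselected)`
(undefined and an error when the unselected result is empty), with a
region-count variant reported alongside. Cases whose best tissue has no
track anywhere are flagged and excluded from denominators.

## Synthetic data generator

The generator emulates the input shapes, not chromatin biology. On 1 Mb
synthetic chromosomes (`chrS1`, `chrS2`) it places 9 genes (1–3
transcripts, both strands), builds 3 datasets × 4 tissues of tracks, and
plants one regulator per gene at a transcription-direction offset from the
TSS chosen so the variant at the regulator midpoint falls into each of the
three categories in turn: (−150, width 200) → promoter, (+2000, 400) →
intragenic, (−20000, 400) → distal. Plants go into 1–2 phenotype-matched
tissue tracks, except every fourth plant, which is *tissue-mismatched*:
active only in an unrelated tissue, so the single- and related-tissue
searches must miss it while the tissue-unselected control finds it — the
structural analogue of pathogenic regulators that appear only in tracks
unrelated to the phenotype. Decoy regions are uniform random intervals
avoiding all planted spans (±500 bp), with per-dataset width/density
contrasts (sparse narrow CAGE-like vs dense wide peak-like) so summary
statistics exercise realistic spread; negative VCF variants avoid every
track interval. A truth table records, for each planted variant, the
minimal recovering query and an excluding tissue; the suite checks it
exhaustively. All randomness flows from one integer seed through one
generator; identical seeds give byte-identical files.

What passing these tests shows: the search logic, coordinate conventions,
activity-mode quantification, and evaluation arithmetic are correct on
inputs of the right shape. What they do not show: performance or recall on
real genome-scale tracks, robustness to real BED dialect quirks beyond
those modelled, or any statement about real-tissue biology.

## Problem sizes and numerics

Test and acceptance workloads use stores of ≤ a few thousand regions,
chromosomes of 0.1–1 Mb, and per-base oracle masks — sizes at which
literal brute-force re-checks are exact and fast; the library itself
indexes tracks with interval trees and is linear-logarithmic in store
size. There is no floating-point tolerance anywhere in the core: all
interval arithmetic is integral, and specificity/recall are exact
rational arithmetic on integers. Ties and degenerate inputs: empty
searches produce valid empty outputs (an empty BED is a header-only
file, not an error); bookended intervals merge; zero-span unselected
results make specificity an error rather than a NaN.

## Limitations

Linear TSS proximity only (no TADs, eQTLs, co-expression); tissue labels
are free-form strings without ontology reasoning; no alias resolution for
gene symbols; tabix-indexed streaming is not implemented (stores are
loaded into memory, adequate for desk-scale track sets); liftover between
builds is out of scope — mixed-build inputs are rejected, never coerced.
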