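# Methods

This note documents the models, parameters, numerical choices, and known
limitations of the `eukfinder` package. It is the design record a
maintainer should read before changing a default.

## The routing model

Each sequence is assigned one of five categories (Archaea, Bacteria, Virus,
Eukaryote, Unknown) from two evidence layers evaluated in order:

1. **k-mer classifier evidence.** Per query, the best reference is the one
   whose shared canonical k-mers cover the most query bases (`hit_length` =
   union of matched k-mer intervals, in bp — Centrifuge semantics). The hit
   is accepted when `hit_length ≥ min_hit_length`: **40 bp** for short
   reads, **100 bp** for contigs and long reads. When several references
   tie at the best coverage, the query is routed only if all tied taxids
   map to the same category; mixed ties stay Unknown. This is deliberately
   conservative — ambiguity keeps a sequence in the retained pool.
2. **Alignment fallback.** Queries still Unknown are re-routed by their
   best surviving m8 alignment, with **e-value ≤ 0.01, identity ≥ 70 %,
   query coverage ≥ 30 %** (all boundaries inclusive, since the thresholds
   are stated as equalities; coverage = aligned length / query length).
   Best = highest bitscore, ties by lower e-value then lexicographic
   subject id (a deterministic tie-break chosen for reproducibility).

A **lenient** preset (e ≤ 0.1, identity ≥ 50 %, coverage ≥ 10 %) is
provided for divergent communities. Its values are package stand-ins with
no external calibration; treat them as a starting point.

**Mate reconciliation.** Rules are only self-evident for concordant pairs.
The package resolves *any* mate disagreement to Unknown: a pair with one
Eukaryote or Unknown mate is thereby retained for assembly, while
concordantly prokaryotic/viral pairs stay excluded. A (Bacteria, Archaea)
pair also becomes Unknown — retention is the safe direction for a tool
whose purpose is not to lose eukaryotic signal.

**Two-round short workflow.** Round 1 routes reads (min hit length 40);
the Eukaryote ∪ Unknown pool is assembled; contigs **≥ 1,000 bp** are
re-routed in round 2 (min hit length 100); the EUnk contigs go to binning.
Round 2's alignment fallback runs only on classifier-Unknown contigs, which
bounds alignment cost; a flag-level re-run of the fallback on everything is
deliberately not offered because it changes no category that matters (only
already-routed contigs could flip, and those never reach binning).

**Read preparation** trims sliding windows (4 bp) whose mean quality is
below Q25 from both ends, cleans remaining sub-Q25 edge bases, and drops
reads < 40 bp; a read whose mate is dropped moves to the unpaired output.
Quality encoding is fixed to Phred+33; anything else is rejected rather
than guessed. Adapter and host-read removal belong to external tools and
are out of scope for the built-in trimmer.

## The mini classifier

A sorted-array index of canonical 31-mers (k odd so no k-mer is its own
reverse complement; configurable 11–31, packed 2 bits/base into uint64).
It exists so the pipeline is testable end-to-end without reference
databases; it performs exact k-mer matching only — no FM-index, no
mismatch tolerance — so on real, diverged data it under-calls relative to
Centrifuge. All workflow entry points accept precomputed classifier TSVs
so real Centrifuge output can replace it file-for-file.

## Binning

Candidate nuclear/mitochondrial contigs must pass, in order:

* **Consensus (2-of-3).** Three composition clusterings — canonical k-mer
  frequency vectors for k = 4, k = 5, and concatenated k = 5 and k = 6
  blocks (each block L1-normalized) — are computed; "5-6-mer" is read as
  the concatenated two-block vector, the only reading that yields a single
  clustering per k-set. A cluster is *eukaryote-flagged* if a strict
  majority of its routed members (Unknown uninformative) are Eukaryote, or
  it contains any eukaryotic marker call (SSU, LSU or MITO). The marker
  clause covers rDNA and organellar contigs, which form their own
  composition clusters with no routed members; restricting it to SSU alone
  strands those clusters. A contig must sit in a flagged cluster in ≥ 2 of
  the 3 clusterings.
* **Depth cap.** Depth may not *exceed* (strictly) that of the SSU rRNA
  contig; the cap is the maximum mean depth among SSU-marker contigs in the
  candidate set. Biologically the SSU sits in multi-copy rDNA arrays that
  collapse into one high-depth contig, so the cap rejects only contigs
  deeper than the deepest legitimate eukaryotic repeat — high-depth
  bacterial intruders. With no SSU contig the criterion is skipped with a
  warning rather than silently rejecting everything.
* **Prokaryote hit veto.** Best nt hit must not be a prokaryote or virus
  with identity > 90 % *and* aligned length ≥ 1,000 bp (a conjunction:
  91 % over 800 bp passes).
* **Taxonomic coherence.** A contig is kept if any evidence source
  (routing, marker, best hit) calls it eukaryotic, or if it carries no
  taxonomic evidence at all; contigs whose only evidence is non-eukaryotic
  are rejected (`CONFLICTING_TAXONOMY`). Keeping evidence-free contigs is
  essential: it is how genomes absent from every database are recovered.
* **Mitochondrial split.** Contigs with a MITO marker call *and* a
  mitochondrial best hit form the mitochondrial bin, exempt from the depth
  cap (organellar copy number legitimately exceeds rDNA depth). Marker
  alone is not enough — such contigs remain nuclear candidates.

Marker calls are pre-filtered at aligned length > 300 and identity > 90
(both strict). Every rejected contig carries exactly one reason code
(`DEPTH_GT_SSU`, `PROK_HIT`, `CONSENSUS_LT2`, `CONFLICTING_TAXONOMY`);
bins plus rejections always partition the input.

**Clustering stand-in.** The reference implementation of the three
clusterings in the wider ecosystem (MyCC) is a heavy external tool; the
binning criteria, not the clusterer, are the substance here. The built-in
clusterer standardizes features, projects to ≤ 10 principal components, and
runs PAM k-medoids with greedy BUILD initialization and SWAP refinement,
selecting k ∈ [2, min(10, n−1)] by mean silhouette. BUILD is deterministic,
so identical inputs give identical labels regardless of seed (the seed
parameter is kept for interface stability). Degenerate inputs: n = 1 or
all-identical vectors → one cluster (with a warning); n = 2 → two
singletons. External cluster assignments (e.g. real MyCC output) can be
supplied as a TSV and bypass the stand-in.

**Depth stand-in.** In place of read mapping + `jgi_summarize_bam_contig_depths`,
each read is assigned to the contig sharing the most k-mers with it (ties
dropped); mean depth = assigned read bases / contig length, matching the
jgi definition. External jgi depth tables are accepted verbatim.

**Open parameter choices.** The depth cap is computed once over the whole
candidate set, not per bin — with one target eukaryote per community the
two readings coincide, and the global cap avoids instability in small bins.
When criterion-4 evidence sources disagree, any eukaryotic vote wins; no
weighting scheme is attempted because no principled weights exist for
three evidence layers of such different character.

## The simulator

The mock community emulates a staggered benchmark design: `n` background
bacterial genomes with log-spaced molar abundances (3 decades by default),
plus one eukaryote whose reads are titrated in fixed levels sampled without
replacement from a pool, several replicates per level.

Desk-scale defaults (chosen so the full bench runs in minutes on one CPU;
the same code scales to a 51-genome, 16.6 M-read, 8-level × 4-replicate
design via `MockCommunitySpec.paper_scale()`):

| parameter | default | rationale |
|---|---|---|
| background genomes | 10 × 300 kb | enough GC spread (0.30–0.65 ladder) for composition structure |
| background reads | 200,000 (2 × 100 bp, insert 300 ± 30) | ~6.7× max-abundance coverage, realistic depth staggering |
| eukaryote nuclear genome | 200 kb, GC 0.45 | large enough to fragment realistically at low titration |
| rDNA replicon | ~5 kb (SSU+LSU+spacers), 10× copies | multi-copy rDNA arrays collapse into one high-depth contig — this is what anchors the SSU depth cap; a single-copy SSU would sit at median depth and make the cap meaningless |
| mitochondrial replicon | 10 kb, 4× copies | the separate high-depth organellar bin |
| titration levels | 2k, 5k, 10k, 20k reads × 2 replicates | spans ~0.7×–7× nuclear coverage: from almost-no-assembly to near-complete recovery |
| error rate | 0.005 substitutions/base, constant Q30 | Illumina-like scale; high enough that a small fraction of reads lose all exact 31-mers and exercise the Unknown pathway |

Genomes are drawn from genome-specific second-order Markov models with
random dinucleotide bias; the transition matrix is iteratively rebalanced
so its stationary marginal matches the target GC (within ~0.01). Eukaryote
genomes carry planted SSU/LSU/MITO marker templates and 5 × 600 bp
single-copy-gene templates. **All templates are synthetic tagged random
sequences, not biological rRNA or genes** — the built-in marker scanner and
SCG scorer match them by exact k-mer identity (21-mers), so passing tests
demonstrate the *criteria logic*, not HMM-grade marker sensitivity. What
the simulator does not model: indels, quality decay along the read,
chimeric inserts, strain mixtures, repeat families shared across genomes,
and real assembly error — so end-to-end results here bound the pipeline's
bookkeeping correctness, not its field performance.

The **perfect-assembly fixture** replaces the assembler for desk-scale
runs: it emits each replicon's read-covered intervals (merged, ≥ 1,000 bp)
as error-free contigs with truth rows. Determinism is absolute: every
generator consumes `numpy` Generators seeded from the run seed, and reruns
are byte-identical.

## Evaluation metrics

* Precision = TP/(TP+FP), recall = TP/(TP+FN) over contig sets, computed at
  both contig-count and base-pair weight (contig-level primary; empty
  predictions report precision as NA rather than 0).
* NG50/LG50: descending cumulative contig lengths against half the
  *reference* length; undefined (NA) when the assembly never reaches it.
* Genome fraction: percent of reference bases covered by recovered-contig
  source intervals, overlaps counted once (truth-interval union; no
  aligner involved).
* Weighted SCG: Σ over genes of the best per-contig fraction of template
  bases covered by shared 21-mers — per-gene fractional completeness, not
  presence/absence. Exact-k-mer anchoring tolerates roughly one mismatch
  per 100 bp before coverage visibly erodes.

## Reproduction bench and problem sizes

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) recompute, per run seed: the routing oracle on
300 randomized items against an independently coded rule evaluation; the
12-contig binning fixture that hits every rejection reason at its boundary
(cap ± 1; 90/91 % × 800/1,200 bp; 1-of-3 vs 2-of-3; mito conjunction);
1,000-set NG50/LG50 and bitmap genome-fraction oracles; the full
desk-scale titration bench (4 levels × 2 replicates, shared background
classified once — exact, since communities share those reads) plus the
database-ablation re-run of the top community; and a byte-level
determinism check on a small full pipeline. The desk bench sizes above are
the package's standard study conditions; the whole script completes in a
few minutes on one CPU.

## Known limitations

* Exact-k-mer classification has no sensitivity to divergence; real data
  should bring real Centrifuge/PLAST outputs through the file adapters.
* The clusterer is O(n²·k) per silhouette candidate — fine for the
  ≤ a-few-thousand-contig EUnk sets it is meant for, wrong for whole
  assemblies.
* The SSU depth cap assumes at least one SSU-bearing candidate contig;
  communities assembled too shallowly to cover the rDNA skip the criterion.
* `prepare_reads` does quality/length only; adapters and host reads are an
  external-tool concern.
* Binning treats one eukaryote per community as the common case; multiple
  eukaryotes separate only as far as composition clustering separates them.
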