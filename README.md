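# eukfinder

Recovery of eukaryotic nuclear and mitochondrial genomes from metagenomes by
dual-evidence taxonomic routing and supervised consensus binning.

Most metagenome binners are tuned for prokaryotes; microbial eukaryotes
(protists, fungi) are rare, large-genomed, and poorly represented in
reference databases, so their reads are routinely discarded or mis-binned.
`eukfinder` implements a recovery strategy for exactly this situation, aimed
at microbiome researchers who suspect a eukaryote is hiding in their shotgun
data:

1. **Five-way routing.** Every read (or contig) is classified into one of
   five categories — Archaea, Bacteria, Virus, Eukaryote, Unknown — by a
   k-mer classifier (Centrifuge-style evidence: a hit is accepted when its
   matched length ≥ *L*<sub>min</sub>, with *L*<sub>min</sub> = 40 bp for
   short reads and 100 bp for contigs/long reads); sequences still Unknown
   fall through to a tabular-alignment check (PLAST/BLAST m8 evidence,
   accepted at e ≤ 0.01, identity ≥ 70 %, query coverage ≥ 30 %).
2. **Classify → assemble → reclassify.** The Eukaryote ∪ Unknown pool
   ("EUnk") is assembled; contigs ≥ 1,000 bp are re-routed with the longer
   minimum hit length. Carrying *Unknown* forward is the point: a eukaryote
   absent from every database survives to the next stage.
3. **Supervised consensus binning.** Three composition clusterings (4-mer,
   5-mer, 5+6-mer canonical frequencies), read depth, rRNA/mitochondrial
   marker calls, and best nt hits are combined. A contig enters the final
   eukaryotic bin(s) only if it sits in a eukaryote-flagged cluster in ≥ 2 of
   the 3 clusterings, its depth does not exceed that of the SSU rRNA contig,
   and its best nt hit is not a prokaryote/virus at > 90 % identity over
   ≥ 1,000 bp. Contigs with a mitochondrial marker *and* a mitochondrial
   best hit form a separate (high-depth, cap-exempt) mitochondrial bin.

The package is exercisable end-to-end with **no external databases or
binaries**: it ships a mini k-mer reference classifier, a mock-community
simulator with full ground truth (staggered prokaryote background +
titrated eukaryote reads), a perfect-assembly fixture standing in for the
assembler, and the evaluation metrics (precision/recall, NG50/LG50, genome
fraction, weighted single-copy-gene completeness). Real tool outputs
(Centrifuge TSV, PLAST/BLAST m8, MetaBAT2 jgi depth tables, Metaxa2-style
marker tables, MyCC-style cluster assignments) plug in through the same
file adapters.

## Worked example

```python
from eukfinder.simulate import (MockCommunitySpec, generate_genomes,
                                simulate_background, simulate_euk_pool,
                                build_titration_series)
from eukfinder.taxonomy import build_kmer_index
from eukfinder.pipeline import run_community_short

spec = MockCommunitySpec()            # 10 bacteria + 1 eukaryote, 200k background reads
refs = generate_genomes(spec)
db   = build_kmer_index(refs.ref_entries())          # k = 31
bg, bg_truth     = simulate_background(refs, spec)
pool, pool_truth = simulate_euk_pool(refs, spec)
comms = build_titration_series(bg, bg_truth, pool, pool_truth,
                               spec.euk_read_levels, spec.replicates,
                               seed=1234, refs=refs)
run = run_community_short(comms[-1], refs, db, seed=1234)   # top level: 20k euk reads
print(run.workflow.counts)
print({k: round(v, 2) for k, v in run.metrics.items()})
```

Output (seed 1234, community at the 20,000-eukaryote-read level):

```
{'round1': {'Archaea': 0, 'Bacteria': 199168, 'Virus': 0, 'Eukaryote': 19888, 'Unknown': 944},
 'round2': {'Archaea': 0, 'Bacteria': 0, 'Virus': 0, 'Eukaryote': 21, 'Unknown': 0}}
{'n_contigs': 21.0, 'euk_contig_bases': 213533.0, 'prok_contig_bases': 0.0,
 'euk_bases_binned_pct': 100.0, 'prok_bases_binned_pct': 0.0,
 'contamination_of_bins_pct': 0.0, 'genome_fraction_nuclear_pct': 99.12,
 'ng50': 16363.0, 'lg50': 5.0, 'weighted_scg': 5.0,
 'n_nuclear_bins': 1.0, 'n_mito_contigs': 1.0}
```

Reading this: round 1 routed 199k background reads away as Bacteria and kept
~20k Eukaryote + 944 Unknown reads; assembly + round 2 produced 21 EUnk
contigs, all genuinely eukaryotic; binning kept 100 % of their bases with
zero prokaryote contamination, recovering 99.1 % of the nuclear genome, all
5 planted single-copy genes, and the mitochondrial genome as its own
high-depth bin.

## Command line

```bash
eukfinder simulate --spec spec.yaml --out sim/        # mock community + truth
eukfinder db-build --fasta sim/refs.fasta --ref2tax sim/ref2tax.tsv \
                   --taxmap sim/taxmap.tsv --out db.npz
eukfinder read_prep --r1 R1.fastq --r2 R2.fastq --out prep/
eukfinder short --r1 R1.fastq --r2 R2.fastq --db db.npz --taxmap sim/taxmap.tsv \
                --truth sim/truth.tsv --refs-fasta sim/refs.fasta --out short/
eukfinder long  --contigs contigs.fasta --db db.npz --taxmap sim/taxmap.tsv --out long/
eukfinder bin   --contigs short/eunk_contigs.fasta --reads R1.fastq --reads R2.fastq \
                --taxmap sim/taxmap.tsv --routing short/round2_classification.tsv --out bins/
eukfinder evaluate --bins bins/ --truth truth.tsv --genome euk01
```

Every subcommand writes a `manifest.json` (arguments, seed, version, config
hash). Thresholds are exposed as flags (`--min-hit-length`, `--evalue`,
`--pident`, `--qcov`, `--min-contig-len`, `--profile strict|lenient`).

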