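# rediplo

Analysis toolkit for the **early re-diploidization** of a recently
duplicated (young tetraploid) genome — the stage just after a whole-genome
duplication (WGD) when the two genome copies are still nearly identical in
sequence but are beginning to diverge through transposon insertions, local
mutagenesis and expression changes.

The package is written for genome-evolution researchers working with young
polyploid assemblies (e.g. tetraploid cyprinid fish). It provides, as a
library plus a `rediplo` command line:

- **Homeolog pairing** (`rediplo.homeopair`): exact k-mer seeding, ungapped
  HSP formation with exact column identities, sparse-DP colinear chaining
  and reciprocal-best pairing of duplicated contigs; ohnolog gene pairs are
  called by projecting genes through the chain and keeping reciprocal-best
  CDS matches.
- **Ks / 4DTv dating** (`rediplo.kscalc`): Nei–Gojobori (1986) Ka/Ks with
  Jukes–Cantor correction, fourfold-degenerate transversion (4DTv)
  fractions, the Ks-distribution peak by Gaussian KDE, the WGD date
  `T = Ks_peak / 2r`, and a Fisher-exact positive-selection scan on the
  (Sd, Nd) count table.
- **Indel / transposon dissection** (`rediplo.indeltx`): insertion events
  read off inter-HSP chain gaps with x-drop breakpoint refinement,
  transposon-overlap classification, TA target-site dinucleotide
  enrichment, insertion-age landscapes from divergence-to-consensus, and
  the window-level correlation of HSP identity with TE density.
- **SNP flank enrichment** (`rediplo.snpflank`): population SNP density in
  ±500 bp flanks of transposons versus remote and random controls (Welch t
  plus label-permutation tests, distance-decay profile).
- **Expression divergence** (`rediplo.exprton`): T/O/N grouping of ohnolog
  pairs (two / one / neither gene overlapping a transposon), off-gene
  ratios per tissue and |log2 fold-change| comparisons between groups.
- **A forward simulator** (`rediplo.syngen`): generates a post-WGD genome
  (FASTA/GFF3/BED/VCF/TSV) whose two copies diverged a configurable time
  ago at a configurable synonymous rate, with transposon bursts,
  TA-preferring insertions, hypermutated insertion flanks and
  transposon-linked expression effects — together with a machine-readable
  ground truth, so every stage of the pipeline can be scored.

## The model in brief

Two subgenomes separated `T` years ago accumulate synonymous substitutions
at rate `r` per synonymous site per year on each lineage, so the expected
pairwise synonymous divergence is `Ks = 2 r T`. With the default
`r = 3.51e-9` and `T = 1.23 My`, `Ks ≈ 0.0086`; inverting the same formula
dates an observed Ks peak. NG86 counts synonymous (S) and nonsynonymous
(N) sites per codon by enumerating all nine single-base changes, averages
observed differences over all minimal stop-free mutational pathways, and
corrects the proportions with `k = −(3/4) ln(1 − 4p/3)`.

Post-WGD structural divergence is modelled as lineage-specific insertions —
mostly transposon copies with a TA target-site preference — that leave
asymmetric alignment gaps between homeologs, elevate point-mutation density
within ~500 bp, and shift the expression of overlapped genes.

## Worked example

```python
from rediplo.syngen import SimulationConfig, TEFamily, simulate
from rediplo.homeopair import seed_and_chain, pair_contigs, call_ohnologs
from rediplo.kscalc import ks_from_cds_pairs, ks_mode, counting_se, date_divergence
from rediplo import indeltx

cfg = SimulationConfig(
    seed=1, n_contigs=2, contig_len=400_000, n_genes_per_contig=60,
    te_families=(TEFamily("TcMar-Tc1", "DNA", 1600, 60, 3.0e6),
                 TEFamily("L2", "LINE", 2400, 40, 3.0e6)),
)
ds = simulate(cfg)
pairings = pair_contigs(seed_and_chain(ds.sequences), ds.contig_lengths)
pairs, _ = call_ohnologs(pairings, ds.genes, ds.sequences)
genes = {g.gene_id: g for g in ds.genes}
ks = ks_from_cds_pairs([(p.gene_a, p.gene_b,
                         genes[p.gene_a].cds(ds.sequences),
                         genes[p.gene_b].cds(ds.sequences)) for p in pairs])
mode = ks_mode(ks.loc[ks.defined, "ks"], min_bandwidth=counting_se(ks))
date = date_divergence(mode, 3.51e-9)
events, _ = indeltx.extract_indels(pairings, sequences=ds.sequences)
events, pct = indeltx.classify_te_overlap(events, ds.te_table)
```

Output (printed by the snippet in about six seconds):

```
contig pairings : 2
ohnolog pairs   : 117 (truth 120)
Ks mode         : 0.0086 (generator expectation 0.0086)
divergence date : 1.22 Mya
indel events    : 98, TE-overlapping 82.7%
```

The two ancestral contigs are recovered as homeolog pairs, 117 of the 120
true ohnolog pairs are called with no false pairs, the Ks peak matches the
simulated `2rT` and dates the duplication to ~1.2 My, and ~83% of the
detected insertion events overlap the transposon annotation (85% of the
simulated indels were transposon copies).

The same analysis end-to-end, with a Markdown report and a
parameter-recovery table:

```
rediplo run-all --seed 1 -o runs/demo
```

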