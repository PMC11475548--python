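# equitrb

A toolkit for the T-cell receptor beta (TRB) locus of the horse
(*Equus caballus*): germline gene modeling and IMGT-style classification,
a V(D)J rearrangement simulator with ground truth, clonotype extraction
from junction-spanning transcriptome reads, and repertoire summary
statistics.

## The problem

The horse TRB locus is the largest described in a mammal: 136 TRBV genes
(29 subgroups, only ~35% functional) upstream of two tandem TRBD-J-C
clusters (TRBD1 + 6 TRBJ + TRBC1; TRBD2 + 7 TRBJ + TRBC2) and one
inverted 3' TRBV gene. Because no dedicated repertoire-sequencing data
exist for the horse, the expressed beta-chain repertoire is mined from
bulk splenic RNA-seq: every germline TRBJ gene is used as a probe over
the reads at 98–100% nucleotide identity, unique in-frame 120-bp windows
with recognizable TRBJ and TRBC genes become clonotypes, and each
clonotype's CDR3-IMGT (amino acids 105–117, between the V gene's 2nd-CYS
104 and the J-PHE 118 of the conserved FGXG motif) is decomposed into V
remnant, N1, TRBD, N2 and J segments. A TRBD is assigned when at least
six consecutive junction nucleotides (half of germline TRBD1) match one
D gene. D–J cluster pairings then class each rearrangement as
intra-cluster, inter-cluster (TRBD1 joined to a cluster-2 J) or
trans-rearrangement (TRBD2 joined to a cluster-1 J).

`equitrb` implements this procedure end to end, plus a synthetic-data
generator that builds a configurable locus with the same topology and
simulates rearranged, C-spliced 120-bp reads (geometric trimming, random
N-addition, substitution errors) with a lossless truth table, so every
pipeline stage can be verified against known ground truth.

## Worked example

```python
from equitrb import SimConfig, simulate_repertoire, run_pipeline
from equitrb.stats import recovery_report

sim = simulate_repertoire(SimConfig(seed=23), n_records=800)
table, report = run_pipeline(sim.reads, sim.germline)
print(report["clonotypes"])                # 285
rep = recovery_report(table, sim.truth)
print(rep.segments)
```

which prints (seed 23):

```
   segment  precision  recall
0   V_gene      0.987   0.996
1 V_subgroup    0.975   0.996
2        D      1.000   0.978
3        J      1.000   0.996
```

Precision is measured over the calls the pipeline makes (gene-tier calls
for V, non-ND calls for D); recall over all productive simulated
rearrangements. D recall below 1 is expected: rearrangements that trim
the D below six identifiable nucleotides are conservatively reported as
ND, exactly as in the real survey, where 78 of 212 clonotypes had no
recognizable D.

The `examples/` directory holds one narrative script per capability:
germline classification and subgroup clustering, repertoire simulation,
clonotype extraction, and the published-survey summary tables.
A thin CLI wraps the same functions:

```bash
equitrb simulate --seed 1 --n-reads 1000 --out run/
equitrb extract --reads run/reads.fa --germline run/germline --out clonotypes.tsv
equitrb summarize --clonotypes clonotypes.tsv --truth run/truth.tsv --out summary/
```

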