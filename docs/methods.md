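# Methods

## Germline gene model

A germline gene carries its coding nucleotides, optional recombination
signals (RS), a D-J-C cluster id (D/J/C genes), a subgroup label (V
genes) and an orientation flag. V coding sequence is the L-PART1 + V-EXON
concatenation with the V-REGION offset marked; the V-EXON is modeled as
the V-REGION directly (the short L-PART2 between the leader intron and
the V-REGION is not represented — it plays no role in any computation the
package performs). C genes are represented by the first exon, which is
all the 120-bp read window can touch.

### Nucleotide identity

Subgroup membership uses percent nucleotide identity from a global
alignment with free end gaps: match +1, mismatch −1, gap −2, end-gap
runs unpenalised, identity = 100 × matches / aligned columns with the
end-gap overhangs excluded. 'N' matches nothing. Because several optimal
alignments can exist, the reported value is made deterministic by a
two-level tie-break: among optimal-score alignments, the one with most
matches wins, then the one with fewest core columns. The implementation
is a packed-integer wavefront DP (one int64 encodes score, matches and
columns with separated place values), batched over same-length pairs for
the all-vs-all matrix; the test suite checks it cell-for-cell against an
independent plain-Python tuple DP.

One property of this measure matters for interpretation: for unrelated
equal-length sequences the full-length alignment score is negative, so
the optimum degenerates to a short suffix-prefix overlap and the
"identity" of unrelated sequences floats around 57–75%. Real V genes are
homologs with in-register similarity well above 50%, where the
full-length alignment stays optimal and the measure behaves as intended.
The synthetic germline therefore derives all subgroup families from one
ancestor (see below) rather than from independent random sequences.

### Subgroups

Subgroups are the single-linkage connected components of the graph with
an edge wherever identity exceeds the threshold (default 75%), computed
by union-find over the exact identity matrix. Single linkage is the
semantics the survey data imply: a member can fall below 75% against
some of its own subgroup as long as a chain of above-threshold links
connects it. Labels are assigned in order of each component's first gene
in genomic order.

### Anchors and functionality

The three conserved V-REGION anchors are located by codon scan: 1st-CYS
as the first TGT/TGC in codons 15–30 (0-based), the conserved TRP as the
first TGG in codons 33–48, and the 2nd-CYS as the last TGT/TGC within
the final 12 codons. Windows are configurable; anchors that cannot be
located are reported as not found, never guessed. Full IMGT unique
numbering (gap insertion) is not implemented; the windows approximate it
for ungapped V-REGIONs.

Functionality follows the IMGT three-way classification with a
switchable rule set. Pseudogene (P): broken V-REGION frame, an in-frame
stop strictly before the last V-REGION codon, a missing start codon in
L-PART1, a defective splice flag, or a missing conserved anchor. ORF:
open frame but the 3' recombination signal scores below the conservation
threshold. Functional (F) otherwise — including the special case of a
stop codon confined to the last V-REGION codon, which is recorded as
`terminal_stop_only` but does not disqualify the gene, because junctional
trimming and N-diversity usually delete that codon during rearrangement.
J functionality is defined by the presence of the FGXG motif. The
classification is monotone: adding a defect never moves a gene toward F.

Recombination signals are scored as matched positions against the
canonical heptamer CACAGTG and nonamer ACAAAAACC over 16 positions;
spacer content is never scored, but the signal only passes with a
12- or 23-nt spacer (the 12/23 rule) and a score of at least 0.75.
Non-12/23 spacer lengths are representable (defective signals exist in
real loci) and simply fail validation.

## Synthetic repertoire generator

The generator defines the study conditions for all pipeline validation.
Defaults are chosen once, as follows, and are configurable.

**Locus (scaled down).** Six V subgroups with 24 functional and 6
pseudogene members, one inverted pseudogene V at the 3' end, two D
genes of 12 and 17 nt, two D-J-C clusters with 6 and 7 J genes (47–53 nt
band) and one C gene each; all RSs are consensus. The full-size horse
locus (136 V genes) would only scale the quadratic identity
verification without exercising any additional code path.

**V construction.** All families derive from one ancestral codon
sequence, as real subgroups derive from duplications. A fixed set of
~57% of the unprotected codon positions is diverged: at each such
position every family receives a distinct codon, the codons chosen
mutually ≥2 apart in Hamming distance. This pins inter-family identity
near 62% with small variance (safely under the 70% construction bound),
while family members — the prototype plus ~6% codon resampling — stay
above 85%. Anchors (TGT at codon 22, TGG at 40, TGC at 104 of a
108-codon V-REGION), an ATG-led 16-codon L-PART1 and the 9-nt CDR3 tail
are never mutated; scan windows exclude codons that could shadow an
anchor. Identity bands are verified post hoc with the same measure the
classifier uses, with bounded retries.

Two synthetic-design devices deserve explicit mention because real loci
do not guarantee them:

* every V gene carries a unique third-position barcode (pairwise
  Hamming distance ≥ 4) over the 8 codons before the 2nd-CYS, so that a
  120-bp window always contains enough signal for a gene-tier V call;
  real paralogs can be identical over that span, which is exactly why
  the real survey could resolve only 93 of 212 clonotypes to a member
  gene;
* every V gene has a distinct G-free 9-nt germline tail after the
  2nd-CYS, so junction-keyed clonotypes never merge across V genes, and
  a germline-masked junction prefix can never extend into the G-leading
  D genes.

**D genes.** TRBD1 = `GGGACAGGGGGC` (12 nt), TRBD2 =
`GGTGGCGGAGGTGGCAC` (17 nt): G-rich, stop-free in all three frames
(glycine runs), and sharing no substring of length ≥ 4. Distinct 6-mers
make the six-consecutive-nt D rule decisive; excluding shared 4-mers
keeps the probability that a trimmed D remnant plus random N bases
completes a 6-mer of the *other* D negligible (with shared 4-mers this
occurred in ~0.2% of junctions and, through the conservative ND-on-tie
rule, broke exact D recall).

**J and C genes.** Each J is a G-free CDR3 contribution (so it can never
harbour a D-like stretch), the FGXG motif, and a codon tail ending in C
(so the J/C boundary can never straddle a stop codon). Default J lengths
are all ≥ 50 nt within the 47–53 band: at the 98% probe threshold a
50-nt probe tolerates exactly one substitution, a 47-nt probe none. The
two C genes differ at three positions, one inside the first nine bases
so the read-level C check can tell them apart.

**Rearrangement.** Class is drawn from the mix (intra 0.813, inter
0.157, trans 0.030 — the fractions observed among D-identified
clonotypes in the survey); intra-cluster joins choose the cluster with
the observed D-usage bias (TRBD1 0.395 / TRBD2 0.605). V is uniform over
functional genes. Trimming is Geometric(p)−1 per end, capped (V-3' cap
9 = the germline tail; D ends 6): p = 0.45 for V and both D ends, and
p = 1.0 (no trimming) for the J 5' end — the probe threshold means only
near-intact Js are observable, and the real survey indeed found every
clonotype J matching its germline perfectly, so trimmed-J reads would
only be generated to be discarded. N regions are uniform 0–6 nt with
uniform base composition. A record is productive when its junction
(2nd-CYS to J-PHE) is a whole number of codons and translates without a
stop.

**Reads.** The rearranged transcript (V + N1 + D + N2 + J + C exon) is
windowed to 120 bp: centred on the junction midpoint, then shifted
minimally so the window keeps the 2nd-CYS codon, the whole CDR3 and at
least 9 nt of C. Substitution errors at 5 × 10⁻⁴ per base (a post-QC
short-read scale), strand drawn uniformly, truth table written
losslessly. What the generator does *not* model: indel errors, quality
scores, PCR amplification bias, paired ends, allele-level variation and
somatic hypermutation (TR genes do not hypermutate). Passing tests
therefore demonstrate the correctness of the extraction logic under
substitution noise and junctional diversity, not robustness to
platform-specific artifacts.

## Clonotype extraction

1. **Probe scan.** Every J gene slides ungapped over both strands of
   every read; a hit needs ≥ 98% identity over the full probe length.
   The scan is exact (vectorized over reads and offsets), and the best
   placement per probe is kept with a deterministic preference (+ strand,
   lower offset on ties). If several probes tie at the top identity, all
   are kept and flagged ambiguous. Gapped matches are deliberately not
   considered: a gap in a 50-nt J match would be a sequencing indel,
   which the model excludes.
2. **Deduplication.** The 120-nt window around each hit (the whole read
   here, since reads are emitted at window length) is strand-normalized;
   byte-identical windows collapse, accumulating read support. Output
   order is lexicographic by window, which makes the whole pipeline
   deterministic.
3. **Frame / C filter.** The J-PHE codon of the called J fixes the
   reading frame; the window must translate without stops in that frame,
   and at least 9 nt matching a C-gene 5' end (≤ 1 mismatch) must follow
   the J. The C gene of the J's own cluster wins exact ties. A small
   placement search (shifts 0–2) absorbs probe-placement offsets from
   trimmed J ends.
4. **CDR3 delineation.** The 2nd-CYS codon is located by anchoring the
   window's V portion against every germline V 3' end: each germline
   CYS maps to a candidate window position in the J frame; the
   best-matching placement (scored over up to 48 nt ending at the CYS)
   wins and must show TGT/TGC in the window. If no placement validates,
   the last in-frame TGT/TGC upstream of the J-PHE is used. CDR3 =
   codons strictly between 2nd-CYS and J-PHE; windows without a valid
   CYS, with a broken frame or with an in-frame stop are dropped and
   counted per reason.
5. **TRBD assignment.** The germline-attributable junction ends are
   masked first: the longest CDR3 prefix matching the anchor V's
   germline tail and the longest suffix matching the called J's CDR3
   contribution. Each D gene's longest common substring with the
   junction is then found, required to overlap the unmasked core; a
   match anchored in the core may extend into the masked flanks while it
   continues to match the D germline, and the ≥ 6 nt threshold applies
   to the extended stretch. (Without the extension, a masked prefix that
   coincidentally over-extends one base into the D region could push a
   true 6-nt D stretch below threshold.) The D with the longer match
   wins; equal maximal lengths give ND flagged ambiguous — conservative,
   like the survey's 78 "not determined" clonotypes. N1/N2 are the core
   remainders on each side of the match.
6. **TRBV assignment.** Mismatch counts of the window's V portion
   (anchored at the CYS) against every germline V give a tiered call:
   *gene* when a unique best germline beats every other by more than the
   margin (default 2 mismatches), *subgroup* when the genes within the
   margin share one subgroup, *unassigned* otherwise or when fewer than
   15 V nt are available. Pseudogene V calls are allowed — the real
   survey found clonotypes using four genes annotated non-functional.
7. **Classing.** Same D/J cluster → intra; TRBD1 with a cluster-2 J →
   inter; TRBD2 with a cluster-1 J → trans; ND → unknown.

Clonotype rows are finally collapsed by the configured identity key
(junction nucleotides by default; CDR3-AA + V + J available). The run
report counts every candidate dropped at each stage, and candidates =
passed + dropped always holds.

An out-of-frame rearrangement can survive the filters when a chance
reading frame happens to look open across the whole window; the
procedure has no way to know, and the real survey would have kept such
reads too. On default simulations these are a small minority and almost
never receive a gene-tier V call.

## Summary statistics

Per-TRBJ usage tables carry clonotype counts, D composition (TRBD1 /
TRBD2 / ND), mean CDR3 length at two decimals and its range, with
cluster and overall totals recomputed from the rows (count-weighted
means, min/max of ranges). Rearrangement accounting derives intra /
inter / trans counts from the cluster × D composition margins, with the
intra percentage over D-identified clonotypes. Per-subgroup V usage
counts gene- and subgroup-tier calls, with gene-tier calls broken out as
"resolved"; subgroups with a single germline member count their
clonotypes as resolved (flagged implied), reconciling the published 93
resolved against the 89 visibly itemised. The germline census tabulates
genes × functionality per subgroup. All reported percentages round half
away from zero (the survey's own rounding is not fully consistent; the
two figures that disagree with any standard rule are not reproduced
anywhere in this package).

The bundled reference tables are transcriptions of the published
survey's printed summary tables, stored as plain TSV under
`equitrb/data/`; the loaders parse them into the same frame layout the
aggregation functions emit, so the identical code path serves both
simulated and published data.

## Numerical and scale choices

Test and acceptance problem sizes: identity oracle suites at 200 random
pairs (length ≤ 50); D-assignment oracle at 1,000 simulated junctions;
exact-recovery runs at 1,000 simulated rearrangements; D-recall runs at
1,200; J-recall at 5,000 reads; class-mix recovery at 10,000 draws
against three binomial standard errors. The default germline builds in
~3 s including the post-hoc identity verification; a session-scoped
build is shared across tests. Sequence length for the alignment DP is
capped at 2,000 nt (the packed-integer encoding reserves place values
for score, matches and columns; the cap keeps them disjoint).

## Known limitations

* No indel handling anywhere: a sequencing indel inside a J probe or a
  junction silently fails the probe threshold or shifts the frame.
* IMGT unique numbering is approximated by codon windows; genes with
  unusual CDR1/CDR2 lengths would need adjusted windows.
* The ORF rule set implements only the documented subset (RS
  conservation); real IMGT annotation uses additional evidence, so
  per-gene ORF calls on real data may differ.
* The V-call margin operates on raw mismatch counts over the shared
  anchored span; with very unequal germline V lengths a
  length-normalised score would be preferable.
* Trans-rearrangements are simulated as a class frequency, not as a
  mechanistic inversion model.
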