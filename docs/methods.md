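# Methods

This note documents the models, parameter choices and numerical conventions
behind `lncevo`, and what the synthetic-data experiments do and do not
demonstrate.

## Triplex alignment model

LncRNA DNA binding is modelled as gapless triplex-rule alignment. A triad
rule is a triple (RNA base, duplex purine base, motif); the DNA string is
scanned as the putative purine-rich strand, and a rule applies at a
position only when the scanned base is itself a purine. The parallel motif
aligns the RNA 5′→3′ with the DNA; the antiparallel motif aligns the
reversed RNA. Promoters are scanned on both strands, since either strand
of the duplex can carry the purine tract.

Rule tables (editable via `TriplexRuleset.to_table`/`from_table`):

* parallel, canonical: T·A-T, C·G-C
* antiparallel, canonical: A·A-T, G·G-C, T·A-T
* "all" preset extension: parallel G·A-T and antiparallel C·A-T
  (weak, non-canonical triads; the published rule tables of triplex
  prediction tools differ in their non-canonical extensions, so the table
  is configuration-visible rather than asserted as identical to any tool).

A reported segment (TFO/TTS pair) must satisfy, with defaults in
parentheses: length ≥ `min_nt` (50), identity = paired/length ≥
`min_identity_percent` (60%), and positive total score, where paired
positions score +1 and the T×T and C×C juxtapositions score `tt_penalty`
(−1000) and `cc_penalty` (0). Penalties ≤ −900 are treated as hard
barriers: one occurrence disqualifies any segment containing it (for
segments shorter than ~900 bp this is equivalent to the score rule; real
TFOs are far shorter). Segments contained in a longer qualifying segment
of the same motif are suppressed. The implementation screens diagonals
with a vectorized max-subarray test and is verified, on small inputs,
to equal exhaustive enumeration of all substring pairs.

Chaining: TTSs whose DNA intervals overlap or lie within `offset` (15) bp
are chained into a DBS (span = union hull); TFOs are chained into DBDs the
same way. DBS identity is the unweighted mean of member identities;
affinity = length × identity/100; strong ⇔ affinity ≥ 60, weak ⇔
36 < affinity < 60, otherwise subthreshold (affinity exactly 36 is
subthreshold, exactly 60 is strong). DBD1 is the DBD with the most DBSs
genome-wide (ties: larger summed affinity, then 5′-most span). Coordinates
are 0-based half-open internally; BED exports are 0-based, VCF/FASTA
1-based.

## Orthology and HS calling

A genome carries an ortholog of a lncRNA gene iff its exon hits strictly
exceed half the gene's exon count (ties are non-orthologous); a gene is
human-specific iff no ortholog is called in any surveyed genome. A genome
missing from a gene's table rows is an error, never "no ortholog". Hits
are counted without synteny or ordering constraints.

## Distances and age labels

Counterpart sequences are compared site-wise after exclusion of gaps and
ambiguity codes (the denominator is the number of compared sites, not the
DBS length). K2P: K = −½ ln((1−2P−Q)√(1−2Q)) with transition proportion P
and transversion proportion Q; non-positive logarithm arguments raise a
saturation error — the 10.0 sentinel is reserved for missing counterparts
and never produced by the distance itself. A Tamura–Nei (1993)
implementation serves as an independent cross-check (the two agree to
< 0.005 at the divergences involved).

Age labels: old ⇔ K(chimp) > 0.034 and K(Altai) = 0; young ⇔
K(Altai) > 0.034 or K(Denisovan) > 0.034. The conditions can overlap
(K(Altai) = 0 with K(Denisovan) > 0.034); "old" takes precedence, since
identity to the Altai genome anchors the change before the archaic split.
Epoch flags: C ⇔ K(chimp) ≥ 0.037; A/D/V require both the top-20% rank by
human–chimp distance and K > 0.037 to that archaic genome.

Ancestor-mode concordance compares d(ancestor→modern) with the mean of the
three ancestor→archaic distances; exact ties count ½ (the usual tie
convention for concordance statistics; a star topology then gives exactly
0.5 in expectation). On ~140-bp DBSs at archaic-scale divergence most
comparisons are ties, so the pipeline-scale concordance (~0.47) mostly
reflects that noise floor, not topology.

## Selection statistics

Tajima's D uses the standard 1989 constants; windows with S = 0 (or n < 4)
are flagged undefined and excluded from background percentiles. Fay–Wu's
θ_H = Σ 2 S_i i²/(n(n−1)) over derived counts; sites with unknown
ancestral state are excluded from H (both π and θ_H) but retained for D.
Weighted Fst is the Weir–Cockerham (1984) estimator with ratio-of-sums
combination across SNPs; haplotypes are paired in panel order into diploid
individuals. The integrated Fst for a focal population is, by default, the
mean of the two pairwise values involving it ("max" is selectable) — the
exact combiner used upstream is not published, so it is pluggable.

Backgrounds are empirical quantiles over non-overlapping tiles (1500 bp
for genes, 147 bp — the mean strong-DBS length — for DBSs; partial
terminal tiles kept if ≥ 50% of a window). The joint positive-selection
call in a focal population requires D(focal) below the lower-10% genome
threshold, D > 0 in both other populations, and integrated Fst above the
upper-10% threshold. The reference thresholds (−0.97/−0.96/−0.97 and
0.22) are config defaults; the pipeline regenerates them from the
synthetic genome background.

## Expression impact

Robust expression: median TPM strictly > 0.1 in a tissue. Representative
transcript: among DBD-containing transcripts, highest overall median TPM
(ties: lexicographically smallest id). Pair significance: |Spearman ρ| >
0.3 and BH-FDR < 0.05, corrected jointly over the whole pair × tissue
family (the FDR family is a design choice; joint correction is the
conservative reading and is recorded in output metadata). Tissues with
fewer than 10 samples are skipped. The tissue shift test is a one-sided
two-sample KS test per tissue × archaic genome — alternative: tissue
distances stochastically larger than the pooled all-tissue background —
with BH-FDR < 0.001; epoch labels follow the nested progressions
{D} → D, {A,D} → AD, {A,D,V} → ADV, and any other significant combination
maps to "none". eQTLs qualify at MAF ≥ 0.1 in ≥ 1 population and
|ES| ≥ 0.5 in ≥ 1 tissue inside a DBS; conserved = the containing DBS has
counterparts in all three archaic genomes, novel = in none, other =
partial. Effect sizes are consumed from input, GTEx-style; the synthetic
generator re-estimates them from its own data by OLS.

## eGRAM

Co-regulator sets are maximal cliques of the regulator graph with edges at
|r| ≥ `pearson_min` (0.5); the clique reading matches the pairwise wording
of the procedure, and a connected-component mode would only coarsen it.
Targets require binding affinity ≥ 60 AND |r| ≥ 0.5 with the regulator
(absolute correlation by default; sign-sensitive mode available). A
module is the union of a set's member targets, kept at ≥ `module_size`
(50) genes — a minimum, not an exact size. Enrichment is the hypergeometric
upper tail against the expression matrix's gene universe, BH-FDR ≤ 0.01.
Cross-species comparison maps a module through an ortholog map and counts
a mapped gene as "in a species-B module" iff it passes the same
correlation criterion with a mapped member regulator on the B matrix; the
self-comparison therefore returns fraction 1 by construction, which is the
built-in sanity check.

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with planted ground truth:

* **Genome/promoters**: random sequence, evenly spaced genes on
  alternating strands, 5000-bp strand-oriented promoter windows
  (−3500/+1500 around the TSS). Planted triplex tracts are the
  parallel-motif partners of a pyrimidine-rich DBD RNA, with evenly spaced
  non-pairing mismatches tuned to the requested identity.
* **Haplotype panels**: sites are independent (free recombination); each
  site's frequency is drawn from the neutral 1/i spectrum on a hidden
  grid and sampled binomially per population. Sweeps resample window
  sites from a mixture of singletons (60%) and near-fixed derived alleles
  (40%) in the focal population; in the other populations the planted
  window keeps intermediate-frequency variation (the D > 0 contrast the
  joint rule requires). Differentiation uses Balding–Nichols draws.
  θ defaults to 0.008/site — above the human genome-wide ~0.001 — so
  147-bp windows carry enough segregating sites for the window statistics
  to be defined at synthetic scale. No linkage, demography or
  linked-selection realism is claimed: passing tests show the statistics
  and decision rules behave correctly on their inputs, not that the
  pipeline would have the same power on real LD-structured data.
* **Counterparts**: independent per-site substitutions (2:1
  transition:transversion; no indels, matching the substitution-only
  distance model), chained modern → common archaic node (2/3 of the
  archaic divergence) → three archaic branches (1/3) → ancestor → chimp,
  so archaic genomes are intermediate and human–chimp divergence totals
  `divergence_chimp` (default 0.012; archaic 0.002). Deleted DBSs get no
  chimp counterpart.
* **Expression**: latent-factor modules (gene = base + loading·factor +
  noise, TPM clipped at 0.01), additive per-alt-allele eQTL shifts with
  OLS-re-estimated effect sizes, independent background genes/lncRNAs for
  the random-pair null, and one pathway planted inside a module.

Defaults for the end-to-end pipeline: 72 genes (60 target genes planted at
identity 0.85 for the first lncRNA, 8 at 0.9 for the second), 2 scanned
lncRNAs of 120 nt, 200 lncRNA gene records with 66 planted human-specific,
200 haplotypes per population, 4 tissues × 60 samples. These sizes keep a
full run under a minute on one CPU; the acceptance script's calibration
uses 60-haplotype panels over 30-kb regions (100 background windows) and
20–50 sweep seeds.

## Numerical conventions and degenerate inputs

* Identity comparisons use an absolute 1e-9 slack so 60.0% passes the
  ≥ 60 threshold under float arithmetic; the diagonal screen uses float32
  with a slack chosen so rounding can only add candidate diagonals.
* Undefined statistics (D with S = 0, H with no known ancestral states,
  Fst with no shared polymorphism, ρ on constant vectors) are flagged
  NaN/skipped, logged, and excluded from percentile backgrounds.
* Multi-call VCF loci resolve to the highest-QUAL record (ties: first in
  file order); indels are skipped, distances being substitution-based.
* All randomness flows from a single seed through spawned generator
  streams; reruns are byte-identical, and output files embed the config
  hash instead of timestamps.

## Known limitations

* The triplex rule tables and the TT/CC-penalty semantics are one
  defensible reading of sparsely documented tool parameters; they are
  config-exposed, not claimed identical to the original predictor.
* DBS-scale windows carry few substitutions, so ancestor-mode concordance
  and age labels are noisy at realistic divergences (quantified above).
* The synthetic populations cannot exhibit hitchhiking, background
  selection, or LD decay; r² results on them only validate the estimator.
* The expression model is Gaussian on a shifted scale, not count-based;
  TPM clipping at 0.01 slightly truncates the left tail.
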