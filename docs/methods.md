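# Methods

`phosphonet` implements the downstream inference chain of a label-free
phosphoproteomic case–control study: from a site × sample intensity matrix to
normalized site ratios, differential phosphosites, expression-pattern
clusters, sequence motifs, kinase activities and kinase-regulated networks.
This note records the models, the defaults that matter, the numerical
conventions, and what the synthetic-cohort tests do and do not establish.

## Quantification model

Raw intensities `I_ij` (site j, sample i) are assumed log-normal.  The
processing chain is:

1. **Centering.** `R_ij = I_ij / mean_i(I_ij)`, the mean taken over *present*
   values of the site's row.  Every centered row has mean 1; missing stays
   missing, and a 0 in the input is treated as missing (LFQ convention:
   "not observed", never "absent").  No imputation is done anywhere.
2. **Protein correction.** Each site ratio is divided by its parent protein's
   centered ratio, removing protein-abundance changes from the modification
   signal.  Sites without a quantified protein pass through and are flagged.
3. **log2 transform**, after which values are treated as approximately normal.

Because centering divides by each row's own realized mean, protein correction
cancels a shared per-sample protein profile *exactly* only for sites whose
site-level regulation is constant across samples (they come out at exactly 1);
for general regulation the cancellation is exact up to one multiplicative
constant per row.  All cross-sample contrasts — which is everything the
differential tests and downstream stages consume — are exactly invariant to
the protein profile either way, and the test suite asserts both forms.

## Differential testing

Per site, a classic pooled-variance (Student) two-sample t test on log2
values, two-tailed by default; `tails="one"` tests mean(A) > mean(B) (the
convention used for directed validation comparisons).  Welch's form is
available behind a flag.  Defaults follow the study conventions for this kind
of data: raw p < 0.05 together with linear fold change ≥ 1.5 (or ≤ 1/1.5)
defines significance; Benjamini–Hochberg q-values are always reported
alongside but do not gate.  Degenerate rows: zero pooled variance with equal
means gives p = 1; with unequal means p = 0 and a `degenerate` flag.  Sites
with fewer than `min_per_group` (default 2) present values per group are
reported as untested rather than dropped.

## Expression-pattern clustering

Sites are screened by sample SD (ddof = 1, present values) with the strict
threshold SD > 0.5, collapsed to per-group mean profiles in a fixed group
order (HC, SLE_S, SLE_A, RA by default), standardized per row to mean 0 /
SD 1, and clustered with fuzzy c-means (Euclidean, default c = 5).  The
fuzzifier defaults to the Schwämmle–Jensen estimate
`m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)`
(N profiles, D columns), the convention of the Mfuzz soft-clustering package;
a fixed m can be passed instead.  10 random restarts, best objective wins;
argmax ties in hard assignment go to the lowest cluster index; a point
coincident with a center takes membership exactly 1 by the limit convention.
Row standardization is deliberate — raw log2 magnitudes would dominate shape —
but it turns genuinely flat profiles into amplified noise; in the pipeline
flat sites never reach the clusterer because the SD screen removes them.

## Motif discovery

motif-x-style greedy iteration over fixed-width windows (default ±6 → 13-mer;
window width is configurable, not dictated by the data model).  Each step
scores every (offset, residue) pair by the one-sided binomial tail
P[X ≥ k] with k foreground matches, n the foreground size, and p the
background frequency of the residue at that offset; the most significant pair
passing min_count = 20 and p < 1e-6 is fixed and both sets are restricted.
Ties break toward larger k, then smaller |offset|, then alphabetical residue,
making discovery deterministic.  Emitted motifs have disjoint foreground
support because matching windows are removed before the search restarts.
Pad characters (X beyond protein termini) never count as matches and are
excluded from background denominators at their offset.  The default
background is all identified windows of the same center residue, mirroring
the enrichment-against-identified philosophy of the Fisher tests; an external
FASTA background is accepted.

## Kinase-substrate prediction and activity

Published kinase-specificity tools built on curated substrate corpora are not
reproducible from their descriptions, so substrate prediction here is a
transparent PSSM: a window's score is the sum of log-odds weights per offset,
X contributes 0, and a site is a substrate when the score reaches the
kinase's threshold (a site may serve several kinases).  For simulated
cohorts, PSSMs are derived from the planted consensus motifs (consensus
positions weighted 4.0, call threshold 75 % of the maximum); for real data
the user supplies the matrices.

Kinase activity is preranked GSEA over sites ranked by log2 fold change
(descending, ties by site id).  ES is the maximal deviation of the weighted
running sum (hit step `|metric|^p` normalized over hits, default p = 1; miss
step `1/(N − N_hits)`); when the maximal positive and negative deviations tie
in magnitude (within 1e-12), the earlier rank wins — an explicit convention
so independent recomputation agrees bit-for-bit.  The null permutes site
labels: 1000 random same-size site sets by default, one independently seeded
stream per kinase so results do not depend on iteration order.
NES = ES / mean(|null ES| of the same sign) is the activity score; the
permutation p is add-one corrected; substrate sets are intersected with the
ranking and sets below 3 members are skipped.  Permutation count, weighting
exponent and minimum set size are package choices (the upstream convention
leaves them unstated) and are all configurable.

## Enrichment and networks

Term enrichment is the two-tailed Fisher exact test (probability-mass
two-sided convention) of a foreground set against the identified universe,
with BH q alongside and raw p < 0.05 as the gate.  Site-level foregrounds are
collapsed to protein level for protein-keyed annotations (a protein counts
once).

The kinase–substrate network joins kinases passing the activity gate
(NES ≠ 0, permutation p < 0.05) to their significantly differential
substrates; a kinase with no significant substrate is omitted.  The
quadripartite network takes the top-10 activated and top-10 inhibited
kinases, skips any that catalyze no significant site, then adds those sites,
their parent proteins, and enriched terms (p < 0.05) containing at least one
included protein.  Edges run kinase → site → protein → pathway (catalyzes /
site_of / member_of); direction is an attribute in the exports (GraphML, SIF,
node/edge TSVs), all Cytoscape-importable.  Construction is pure set algebra
and reproduces bit-identically.

## Synthetic cohorts

The generator states a world matching the analysis assumptions: log2 site
intensity = protein baseline (per protein per sample, SD 0.5) + site
stoichiometry offset + kinase-driven group effect + N(0, 0.3) residual noise,
exponentiated to log-normal raw intensities; the protein matrix shares the
same baselines plus N(0, 0.1) measurement noise, which is what makes protein
correction identifiable.  Default cohort: four groups of 15/14/7/16 sample
pools (HC/SLE_S/SLE_A/RA — a pooled autoimmune design), 300 proteins with
Poisson(3), min 1, sites each; 6 kinases × 20 substrates with ±1.0 log2
effects arranged to produce five expression patterns (up in all disease, up
in active lupus only, down in disease, down in active lupus only, flat).
Substrate windows carry canonical consensus motifs (basophilic RRxS,
proline-directed S-P, acidophilic, and mixed variants) at prevalence 0.8;
background sequence is uniform over the 20 residues — the simplest defensible
null for motif statistics.  Missingness is 10 % MCAR by default, or logistic
in latent log2 intensity (centred on the median so the overall rate stays
near nominal) for missing-not-at-random behaviour.  All randomness flows
through one seeded NumPy PCG64 generator: identical seeds give bit-identical
cohorts, and `run-all` therefore reproduces every output file byte for byte.

What green tests establish: the algebraic contracts hold exactly, the
statistics match independent oracles, and planted structure (effects, motifs,
active kinases, patterns) is recovered under the stated noise.  What they do
not establish: behaviour under real LFQ pathologies — correlated peptide
sampling, batch effects, non-log-normal tails, localization ambiguity — and
the generator makes no attempt to emulate identification or spectral
properties.

## Known limitations

- The PSSM substrate predictor is a stand-in for curated kinase–substrate
  resources; its calls are only as good as the supplied matrices.
- Fuzzy c-means has no automatic cluster-number selection; c is a parameter.
- Raw p-values gate significance (by design, matching the analysis
  convention); users wanting FDR control should gate on the reported q.
- Pooling semantics are not modelled: pools are ordinary samples in the
  design table.
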