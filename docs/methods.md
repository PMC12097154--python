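# Methods

This note documents the models, parameter choices and known limitations of
`pupitome`. Parameters named here are the defaults of
`pupitome.pipeline.PipelineConfig`; all are overridable.

## Quantification model and preprocessing

Input is a peptide × sample intensity matrix in arbitrary MaxLFQ units with
decoy/contaminant flags and a per-peptide distinct-ion count. Filtering
removes decoys and contaminants, blanks peptides observed in at most one
sample *within a run* (dropping the peptide only when no run retains two
observations — the most conservative reading that keeps cross-run
information), and removes protein groups whose total distinct ion count
across runs is 1. Intensities are log2-transformed and median-centered per
sample, which removes sample-level loading differences; centering is exactly
invariant to rescaling any one sample.

**Missingness.** Within each biological triplicate a peptide with exactly
one missing value is treated as missing-at-random (a technical dropout —
two detections make a real absence unlikely); two or three missing values
are missing-not-at-random (below-detection-limit abundance). MAR cells are
imputed as `mar_factor` = 0.95 of the lowest observed value of that peptide
within its triplicate, accounting for the residual correlation between
missingness and abundance. MNAR cells get a MinProb draw from a Gaussian
centered on the run's 0.5 % quantile of centered observed values
(`low_quantile` = 0.005, linear-interpolation quantile) with
`sd_mnar` = 0.05. Two deliberate choices here:

* the 0.95 factor is applied literally on the transformed (log2, centered)
  scale, matching the pipeline order; on that scale it *raises* negative
  minima toward zero, so a `mar_scale="raw"` switch applies the factor to
  the raw intensity instead (a −log2(1/0.95) shift);
* the triplicate-local minimum is used, not the peptide's global minimum.

## Differential enrichment

Peptides are aggregated per protein by Tukey median polish; the protein
profile is the overall effect plus the per-sample column effects, so a
constant offset between peptides is absorbed and a single outlying peptide
cell perturbs only its own sample. Contrasts are all within-run triplicate
pairs differing in exactly one of bait construct, treatment or timepoint
(no cross-run comparisons); bait contrasts are oriented bait-minus-control,
treatment contrasts treatment-minus-control (sucrose−mannitol,
rapamycin−untreated), timepoint contrasts later-minus-earlier.

Per-protein statistics use an empirical-Bayes moderated t: pooled
two-sample variances s²_g (d = n₁+n₂−2 df) are shrunk toward a scaled
inverse-chi-square prior fitted by moment matching on log s²_g (the prior
df d₀ via a Newton inverse of the trigamma function); the posterior
variance (d₀s₀² + d·s²_g)/(d₀+d) feeds a t statistic on d+d₀ df. This is
the standard variance-moderation model for triplicate-scale proteomics and
is cross-checked against the Bioconductor reference implementation in the
test suite; the robust ridge estimator used by some proteomics packages is
deliberately not replicated — the surrounding procedure, not the point
estimator, is what this package specifies, and the substitution's
calibration (type-I rate ≈ 0.05, observed FDP ≤ the nominal 0.05–0.10) is
part of the acceptance checks. BH-FDR is applied within each contrast
(one family per volcano plot); *enriched* means q < `alpha` = 0.05 **and**
log2fc > 0 — only bait-side enrichment counts.

## Interactome tiers

A *biological replication* is an independent (run, bait-construct) pair in
which a protein is enriched over its control — the GFP bait where present,
otherwise the control treatment. Enrichment with two baits in one run plus
one bait in a second run counts as thrice replicated. Flags record whether
a protein was *ever* enriched on the GFP side of any comparison and whether
it was ever enriched under control conditions (mannitol / no rapamycin).

Tiers, from a protein's replication count: widest ≥ 2 (no further filter);
wider ≥ 3 and never GFP-enriched; core ≥ 5 and never GFP-enriched, or
flagged as a putative kinase substrate. The treatment filter (removal of
control-condition-enriched proteins) applies to wider and core but not
widest. Two ambiguities were resolved as follows and left switchable:
"minimum significant experiments" counts (run × construct) replications
rather than distinct constructs, matching the worked replication example;
and the treatment filter removes proteins *ever* enriched in control
conditions (the stricter reading), not only those exclusively so.

Benchmarking: previously reported interactors (evidence-filtered at
score > 0.25, plus an independent literature set) are high-confidence;
thylakoid-predicted proteins are low-confidence; their ratio proxies
signal-to-noise and is reported per tier with an explicit infinite flag when
the low count is zero. Overlaps are tested by the upper-tail hypergeometric
with the detected-protein universe as population. Response modules come from
2D hierarchical clustering (Ward linkage, Euclidean distance, undetected
log2fc imputed as 0, rows cut at k = 6). The interaction robustness score is
the cumulative enriched log2 fold change over control comparisons.
Coexpression strengths are standardized to unit variance network-wide,
filtered to the 99th percentile, and communities found by greedy modularity
maximization (algorithm choice is configuration, not contract).

## Lysine accessibility and disorder

ASA is computed by Shrake–Rupley sphere sampling (960 points per atom,
probe 1.4 Å, per-element van der Waals radii) with the sampling sphere
oriented in a molecule-fixed principal-axes frame, which makes ASA, RSA and
depth exactly invariant under rigid motions rather than only up to
quadrature noise. RSA divides residue ASA by the Tien et al. *theoretical*
maximum for that amino acid and is not capped at 1. Residue depth is
approximated as the mean over atoms of the distance to the nearest
accessible sphere point minus the probe radius: surface atoms score about
one van der Waals radius, deeply buried atoms their distance from solvent.
The solvation-simulation DEPTH protocol is not reproduced; the analysis only
thresholds depth at 3.6 Å (shallow/deep), which this approximation
preserves. Accessible lysines are Lys with RSA strictly > 0.7; surface
lysines have depth strictly < 3.6 Å.

Disorder at a residue is the mean RSA over a 25-residue window centered on
it (truncated windows at chain ends average over the available residues;
no padding), clamped to [0, 1] — the surface-accessibility form of a
structure-based disorder score. The per-protein summary is the median over
accessible lysines only (not all lysines); per-residue model confidence
(pLDDT, read from the B-factor column) is parsed and reported but not mixed
into the score. Group comparisons use two-sided Welch t-tests. Predicted
bait–prey complexes are classified from their local interaction score and
area: strong positive at LIS ≥ 0.203 and LIA ≥ 3432, positive at
LIS ≥ 0.073 and LIA ≥ 1610, inclusive bounds; LIS > 0 is the weak
direct-interaction evidence flag.

To recompute reference values for real kinases (e.g. S6K1 or KIN10), place
their predicted models under `data/alphafold/AF-<accession>-F1-model_v4.pdb`
(downloadable from the AlphaFold database); the corresponding test picks
them up from there. No third-party model files ship with the package.

## Phosphosite motifs

Sites are filtered at localization probability ≥ 0.75 (the cutoff behind
"unambiguous localization" is a convention, exposed in config). Windows are
11-mers centered on the phospho-acceptor, padded with `_` at chain ends.
Motif fold enrichment is the foreground/background frequency ratio with a
Jeffreys-style pseudocount of 0.5 per cell, finite for all inputs and
converging to the raw ratio. The proline-directed "SP" motif is center
S/T with P at +1; "RxxS" places R at −3; "SxxP" (P at +3) ships as well
because both spellings of the second motif appear in the TOR-substrate
literature for the same sites — the fold of each is reported rather than
adjudicating the naming. The background is all quantified, localized sites
not enriched in the bait contrasts. De-novo motif discovery is out of
scope; declared-pattern counting replaces it. Substrate flagging requires
log2fc > log2(30) with q < 0.05 in every required bait; flagged proteins
feed the core-tier substrate clause.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: five bait constructs
(LST8/RAPTOR × constitutive/inducible PUP(E), ScFKBP) plus a GFP control,
organized into three runs (constitutive at 24 h; inducible at 4 and 24 h,
both sucrose vs mannitol; ScFKBP rapamycin vs untreated at 4 and 24 h),
three replicates per cell. Intensities are additive on the log2 scale —
protein baselines N(25, 2) matching MaxLFQ dynamic range, peptide offsets
N(0, 1), noise sd 0.5, planted bait effects uniform in [2, 4] log2 units —
then exponentiated. MNAR dropout follows a decreasing logistic in true
log2 intensity (midpoint 21.5, slope 0.8; slope 0 disables it); MAR dropout
is uniform at 2 %. Tier roles are planted at 5 % core / 5 % wider /
5 % widest, with 3 % GFP-binders, 3 % control-condition binders, 2 %
substrates, 5 % decoys, 5 % contaminants — modest, realistic fractions for
an interactome screen. Planted tier labels are *derived* by applying the
tier rules to the planted enrichment pattern, so the truth encoding cannot
drift from the pipeline's rules.

Toy structures are accessibility phantoms, not folds: backbone + CB
pseudo-atoms on a compact lattice (globule; residues placed center-outward,
so low indices are buried), an ideal helix geometry (1.5 Å rise,
100°/residue), or a deliberately spread extended chain whose residues all
clear RSA 0.7 despite lacking side chains; a globule may carry an extended
tail for buried-vs-exposed contrasts. Chain connectivity in the globule is
not physical.

Consequently, passing tests show that the *procedure* — filtering,
imputation, moderation, tallying, tiering, profiling — behaves as specified
under a controlled generative model. They do not show robustness to
real-data pathologies the generator omits: correlated peptide noise,
shared peptides between protein groups, retention-time batch effects,
match-between-runs artifacts, or genuine structural ensembles.

## Numerical choices and limitations

Median polish iterates to a 1e-8 relative residual tolerance (50 iteration
cap). The trigamma inverse uses Newton iteration from the standard
starting point 0.5 + 1/y. Degenerate inputs are defined: zero-variance
Welch comparisons with equal means give p = 1; an all-zero-variance
enrichment contrast gives t = 0; a zero low-confidence count gives an
infinite benchmark ratio with a flag rather than an exception; imputation
never alters observed cells, and MAR imputation requires an observed
triplicate minimum by construction. Problem sizes in the acceptance script
(2000-protein calibration matrices over 20 seeds, 300-protein synthetic
studies, 10 000 MinProb draws, 500-site motif tables) were chosen so each
estimate's sampling error is far inside its tolerance band. The pipeline is
single-threaded and deterministic for a given seed; all randomness flows
from `numpy.random.default_rng`.
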