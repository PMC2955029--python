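# Methods

This note records the models, algorithms, numerical choices and design
decisions behind `cophylointron`, and what the synthetic-data experiments do
and do not establish.

## The scientific setting

Group I introns are self-splicing mobile elements that occasionally appear
inside the mitochondrial cox1 gene of sponges and corals. Whether such an
intron was inherited vertically with its host lineage or moved horizontally
(driven by the homing endonuclease it encodes) can be framed as a
co-phylogeny question: treat the cox1 gene as the "host", the intron as a
"parasite", and ask whether their trees are congruent. The package covers
the full analysis chain: locating introns in cox1 sequences relative to an
intronless reference CDS, estimating maximum-likelihood trees for each
partition, and running three complementary congruence tests whose null
hypotheses point in opposite directions (the AU and likelihood-ratio tests
assume congruence under H0; ParaFit assumes random association).

## Intron detection (`intron_scan`)

A query is globally aligned to an intronless reference CDS with affine gap
costs (match +2, mismatch −3, gap open −8, gap extension −0.05, free end
gaps; all overridable). Gap extension is nearly free by design: a kilobase
intron then costs little more than a single gap opening, which keeps
insertions near a sequence end from being absorbed into the unpenalised
terminal overhang. Runs of reference gaps of at least `min_len` (default
30 bp, well below the smallest reported group I intron) are reported as
insertions.

Coordinates follow the "inserted after position N" convention: N is the
last reference CDS position (1-based from the A of the start codon) before
the inserted sequence. When an insertion shares flanking bases with the
exon its placement is ambiguous; both the detector and the generators
canonicalise to the **leftmost** equivalent placement, so round trips are
bit-exact. Reference suitability is judged by exon identity, computed over
aligned columns plus short (<30 bp) internal gap runs scored as
mismatches — long insertion-scale runs and terminal overhangs are excluded
so a genuine intron does not depress identity, while a patchwork alignment
of unrelated sequences does. Queries under 40% exon identity are rejected.

ORFs are scanned on both strands as maximal start(ATG)-to-stop stretches of
at least `min_aa` (default 50) residues under a configurable genetic code
(default NCBI table 4, the mold/protozoan/coelenterate mitochondrial code in
which TGA is tryptophan). Each ORF is checked for the LAGLIDADG motif
(exact or one mismatch) and its internal TGA codons — stops under the
standard code — are counted.

`column_stats` classifies alignment columns using unambiguous residues
only: constant (≤1 state), variable, parsimony-informative (≥2 states each
in ≥2 sequences); a column is "with missing" if it contains `-`, `?` or
`N`. A column that is constant among unambiguous residues counts as
constant regardless of missing data.

## Likelihood engine (`phylo_core`)

Substitution models are the reversible nucleotide families JC, K80, HKY,
TrN and GTR with optional discrete-gamma rate variation and an
invariant-site class. The rate matrix is scaled so that the expected rate
is one substitution per site per unit branch length *including* the
invariant class (gamma rates are divided by 1 − p_inv), so branch lengths
are always in expected substitutions per site. Gamma classes are
equal-probability; class rates default to the category medians
(`gamma_method="mean"` is available for cross-checks against engines that
use category means). Transition probabilities come from the
eigendecomposition of the symmetrised rate matrix.

Site likelihoods use Felsenstein pruning over unique column patterns;
ambiguity codes and gaps contribute partial likelihood one over their
compatible states. Branch lengths are optimised one at a time by bounded
Brent search on [1e−8, 20], evaluating the likelihood cheaply from cached
conditionals on both sides of the branch; model parameters by L-BFGS-B on
log/logit-transformed vectors; the two are alternated until the
log-likelihood improves by less than 1e−4 (a looser "quick" preset —
tolerance 0.05, fewer Brent iterations — is used inside bootstrap null
replicates).

Tree search is a deterministic hill climb: neighbor-joining start from
Jukes-Cantor distances, exhaustive NNI rounds (optional SPR), candidate
moves screened with a single branch-length pass, full re-optimisation on
acceptance, ties keeping the incumbent — so data without signal return the
NJ starting tree. At the ≤25-taxon scale of mitochondrial intron datasets
this reaches the same optima as exhaustive enumeration (verified at 5
taxa, where all 15 topologies can be scored), which is why heavier
branch-swapping (TBR) was not implemented.

## Congruence tests (`cophylo_tests`)

**Reciprocal AU tests.** For each partition the ML topologies of both
partitions are re-optimised (branch lengths and model) on that partition's
data; the per-site log-likelihood vectors are resampled by the multiscale
RELL bootstrap (ten scales 0.5–1.4, 10,000 replicates each, seeded) and
the AU p-value comes from the weighted-least-squares fit of
z(r) = d√r + c/√r over scales with interior win frequencies. A topology
that never (always) wins at every scale is beyond the bootstrap's
resolution and is assigned p = 0 (p = 1).

**Huelsenbeck–Bull LRT.** lnL0 assumes one topology for both partitions
(estimated on the concatenation; each partition keeps its own model and
branch lengths); lnL1 lets each partition have its own tree;
d = 2(lnL0 − lnL1) ≤ 0. The null distribution bootstraps the columns of
each partition independently, concatenates, and randomises which columns
belong to which partition before re-running the three tree searches. Under
this homogeneity null both pseudo-partitions draw from one signal mixture,
so the one-tree hypothesis holds by construction; p is the plain proportion
of null d values below the observed d, with no continuity correction. An
alternative null that permutes which partition-B row carries each taxon
label (`null_mode="pair-shuffle"`) is exposed for comparison, but note that
it generates the null under partition independence and therefore inverts
the direction of the test; it is not the default. Null-replicate searches
use the reduced NJ-only search for tractability; the observed statistic
uses the full configured search. This makes the null slightly conservative
(reduced searches find slightly worse shared topologies), which is visible
as a mild deficit of small p-values under H0.

## ParaFit (`parafit`)

Patristic distance matrices for hosts and parasites are embedded by
principal coordinates: Gower double-centering of −d²/2, eigendecomposition,
axes scaled by √λ, axes with eigenvalue ≤ 1e−8·λ_max dropped and
negative-eigenvalue axes never retained. When a meaningful negative
eigenvalue appears the Lingoes correction adds 2c (c = |λ_min|) to all
squared off-diagonal distances and re-decomposes (Cailliez is available but
untuned). Patristic distances are used raw by default; `sqrt_distances=True`
embeds their square roots, which are exactly Euclidean for any tree metric.

ParaFitGlobal is the sum of squared entries of the fourth-corner matrix
D = B′AC (B hosts × axes, C parasites × axes, A the binary hosts ×
parasites association). ParaFitLink1 for a link is the drop in the global
statistic when that link is removed. Significance comes from permuting,
independently for each parasite, which host it is attached to; within one
replicate the full and reduced association matrices share the same
permutations; p-values use (1 + exceedances)/(1 + permutations). These
conventions reproduce the reference R implementation (`ape::parafit`)
digit-for-digit on shared instances, which the test suite checks via
Rscript. Because a small set of deeply divergent taxa can dominate the
global statistic, `parafit_test(..., drop_taxa=...)` re-runs the analysis
without named hosts as a one-flag sensitivity check.

Note that the per-link statistics do **not** sum to the global statistic
even for disjoint one-to-one links: link1_k = 2⟨D, D_k⟩ − |D_k|² with D_k
the rank-one per-link fourth corner, and the cross products ⟨D_j, D_k⟩ do
not vanish in general. The single-link case, where equality does hold, is
tested.

## Synthetic data (`synthetic_data`)

The generator emulates the structure the analysis assumes: a Yule host tree
(`birth_rate` 1/time unit; leaves labelled by a random permutation so names
are exchangeable); a parasite that tracks host lineages and duplicates at
host speciations; Poisson host switches (per lineage-time) that *move* the
parasite to a contemporaneous random other host lineage, displacing any
resident intron (the homing analogue); Poisson losses; and alignments
evolved along each tree under a chosen model with a per-partition clock
factor converting time to substitutions per site. `n_switches` replaces the
Poisson switch process with an exact event count at uniform random times,
and `forced_switches` pins individual events to (time, donor, recipient)
lineages for by-construction tests. Coding sequences are random codons free
of stops under table 4; synthetic introns can carry a single
homing-endonuclease-style ORF containing the LAGLIDADG motif and at least
one TGA codon.

Default study conditions mirror the real datasets where the analysis fixes
them: partitions of 630 (cox1) and 1078 (intron) columns, 12 host taxa,
one-to-one host–intron links. Where the analysis is silent the defaults are
a Yule birth rate of 1, clock factors of 0.15 substitutions/site per time
unit per partition (tree height ≈ 2–3 time units, i.e. realistic
mitochondrial divergences of a few tens of percent), and JC evolution for
calibration studies (model misspecification is not the quantity under
test).

What the generator does *not* emulate: within-host coalescence, codon
structure and selection on cox1, indels other than whole-intron insertion,
rate heterogeneity between clades, and intron secondary structure. Passing
calibration on these data therefore shows that the tests are correctly
implemented and calibrated under their own assumptions, not that they are
robust to the full complexity of real mitochondrial data.

## Calibration experiments (problem sizes)

The acceptance suite runs the statistical studies at desk scale, chosen up
front for single-CPU runtime:

* LRT type-I error: 100 co-diverging datasets (5 hosts, 250 bp per
  partition, JC), 99 null replicates each, nominal α = 0.05, acceptance
  band [0.01, 0.10]. The reduced null search makes the test mildly
  conservative.
* LRT power: 20 datasets with two *effective* host switches on 12 hosts
  (2 kb per partition), 99 replicates, requirement ≥ 0.8. "Effective"
  means the realised switches leave topological discordance among the
  surviving taxa (`require_discordance=True`): a transfer whose trace is
  erased by subsequent losses or displacement produces data in which the
  one-tree hypothesis holds exactly, and is therefore not an alternative
  any congruence test could detect.
* ParaFit type-I: 500 random host–parasite associations between independent
  12-taxon trees, 199 permutations, band [0.01, 0.10]; power: 100
  identical-tree identity-association datasets, requirement ≥ 0.8.

`scripts/acceptance.py` recomputes the same quantities (at 60/15 and 300/60
datasets for the LRT and ParaFit studies respectively) plus the oracle
gaps, the canonical 714/723/870 insertion round trips and the AU behaviour
under shared and conflicting histories, all from data generated under the
given `--seed`.

## Degenerate inputs and tie-breaks

Alignments of identical sequences make every topology tie; the search
returns the NJ start. Identical site-likelihood vectors in the AU test
yield p = 1 for all candidates with a warning. All-gap columns contribute
likelihood one. Negative NJ branch estimates are clamped to zero. Saturated
JC distances are capped at 5 substitutions/site. Every stochastic routine
takes an explicit seed, and fixed seeds give bit-identical outputs.

## Known limitations

The engine is desk-scale: pattern-compressed pruning in numpy is ample for
tens of taxa but not for genome-scale matrices. TrN/GTR model fitting uses
numerical optimisation without analytic gradients. TBR search, Bayesian
inference, codon models, partitioned models beyond the two-partition LRT,
intron secondary-structure prediction and database homology searches are
out of scope. Bootstrap node supports are available by resampling but are
not part of the tested surface (they are search-dependent).
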