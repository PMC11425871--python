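# Methods

This note documents the models and procedures implemented in `neo3d`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmarks do and do not demonstrate.

## 1. Curation of T-cell assay records

Raw records carry (peptide, allele, n_positive, n_total, species,
mhc_class).  The pipeline keeps Homo sapiens / MHC class II records with
peptides of length 11–30 (the HLA-II-presented range) over the 20-letter
amino-acid alphabet (peptides are uppercased first; exports vary in case),
standardises allele names, merges identical (peptide, allele) records, and
labels by positive assay rate with *strict* thresholds: rate > 0.70 →
positive, rate < 0.30 → negative, anything in [0.30, 0.70] discarded as
ambiguous (counted in the curation report so dataset sizes are auditable).

Two decisions were genuinely open:

* **Positive-rate aggregation.**  The rate of a merged peptide is computed
  from pooled counts, Σ n_positive / Σ n_total, which weights experiments by
  size; an unweighted mean of per-record rates is available behind
  `CurationConfig(rate_method="averaged")`.
* **Allele grammar.**  `modify_hla_type` accepts an optional `HLA-` prefix,
  any of the separators `* _ : -` (or none, for compact 4-digit forms), and
  zero-pads group/protein fields: `DRB1_0101 → DRB1*01:01`.  Only class II
  loci (`D...`) parse; everything else maps to the unknown marker.  Unknown
  alleles receive the default `DRB1*01:01` in the full dataset and are
  excluded from the known-allele dataset.

## 2. Peptide-to-genome mapping

Curated epitopes are literal substrings of their source proteins, so an
exact substring search over a user-supplied protein FASTA (cross-referenced
with a gene BED) replaces an online alignment chain; it is deterministic and
download-free.  Peptides hitting several genes resolve to the
lexicographically smallest gene id (stable and auditable; configurable via a
precomputed hit table for users who ran an external aligner).  Coordinates
are 0-based half-open; a locus is assigned to the 500 kb bin containing the
floor of its interval midpoint.  Unmapped peptides are dropped from feature
assembly with a logged count.

## 3. Compartment degree and radial targets

Per chromosome, the Hi-C count matrix is distance-normalised (each entry
divided by the mean count at its genomic separation; separations with fewer
than 3 observations borrow the nearest populated separation's expectation),
the Pearson correlation matrix of the O/E rows is formed, and the per-bin
activity is the leading eigenvector.  Numerical choices:

* The O/E **main diagonal is set to the neutral value 1** before the
  correlation.  With a zero diagonal, each row's largest entries sit at
  mutually exclusive positions, which injects spurious anti-correlation
  between neighbouring same-compartment bins and, on small matrices, makes
  the leading mode a within-block contrast rather than the compartment
  split.
* Bins whose off-diagonal O/E row has zero variance (empty/unmappable bins)
  are excluded from the correlation and assigned activity 0.
* The eigenvector's global sign is arbitrary.  It is oriented so activity
  correlates positively with a gene-density marker track when one is given
  (gene-dense chromatin is active chromatin); otherwise so the mean activity
  of the top-decile row-sum bins is positive; remaining exact ties make
  the first nonzero component positive.

Activity ranks map linearly to target radii:
`r*(i) = R · (1 − q_i (1 − m))` with `q_i` the fractional activity rank
(ties share mean rank) and `m = 0.1` the minimum-radius fraction, so the
most active bin is targeted at 0.1 R and the least active at R.

## 4. Structure reconstruction

One bead per 500 kb bin, one chain per chromosome, all chains confined to a
nucleus of radius R (default 10 bond lengths; lengths are in normalised
nuclear units where 1 = one bin step).  The potential is

* harmonic bonds between consecutive beads (`k_bond = 100`, `b = 1`),
* harmonic radial bias toward the activity-derived target radius
  (`k_radial = 10`),
* soft-core repulsion `k_rep (c − d)²` for non-bonded pairs closer than
  `c = 0.8` (`k_rep = 1`),
* optionally, harmonic pairwise restraints with targets
  `d_ij = c · f_ij^(−1/α)` (off by default; the constant c is calibrated so
  the median bonded-pair target equals the bond length).

Optimisation is annealed gradient descent from a random confined
initialisation: per-bead displacements are clipped at 0.1 b for stability,
Gaussian noise with geometrically decaying scale (initial 0.05 b) is
injected for the first 80% of the `n_steps = 5000` steps, and the
best-energy snapshot at 50 checkpoints is returned (best-so-far energy is
non-increasing by construction).  A convergence flag records whether the
final relative energy change exceeded `tol = 1e-4`.  Chains interact only
through repulsion and shared confinement; no trans-chromosomal restraints.
Force constants express the modelling hierarchy — connectivity is a hard
property of the molecule (k_bond ≫ k_radial), the radial preference is a
statistical tendency, and repulsion merely prevents collapse.  All values
are configurable; none is claimed optimal.

Pairwise restraints are kept optional because connectivity and radial
activity are the two constraints the modelling rationale names explicitly;
whether population Hi-C distances should additionally restrain the model is
a methodological choice, so both modes are implemented and tested (the
structure-recovery benchmark uses them; the pipeline default does not).

## 5. Features and classifiers

Per peptide: 1 baseline score + ⟨x, y, z⟩ from each of two cell-line
structures + both radial positions = 9 features in a fixed column order.
Peptides missing a locus, a bead, or a score are dropped with recorded
reasons.  BA and EL scores are alternative single features, never used
together.  Features are z-scored inside training folds only (distance-based
learners need comparable scales; the flag is configurable).

Learners: KNN with K = 8 (score = positive-neighbour fraction; equidistant
neighbours resolve by sklearn's stable index order), SVC with RBF kernel at
library defaults (decision values mapped to [0, 1] by a logistic link fitted
on the training fold's own decision values), and plain logistic regression.
Evaluation: stratified 5-fold cross-validation repeated (default 100×, each
repeat a different fold split) and LOO.  Per repeat, out-of-fold scores are
pooled into one ROC/PR; AUC/AUPR headline numbers are means across repeats,
threshold metrics (precision/recall/F1 at the best-F1 cutoff, ties → lowest
cutoff) come from the first repeat's pooled scores, and curves are exported
from the first repeat.  AUC uses the rank (Mann–Whitney) formulation with
ties counting ½; AUPR is the step-wise precision-weighted recall increment
sum.  Both are verified against independent implementations in the test
suite.

## 6. The synthetic study world

The generator produces the statistical structure the analysis assumes, so
every stage is testable against known ground truth:

* **Structures.**  The first cell line's truth structure is *radially
  organised*: each chromosome gets a smooth activity profile (white noise
  convolved with a Gaussian kernel, correlation length 5 bins — the
  multi-bin scale of A/B blocks), and a confined self-avoiding-style walk is
  biased toward the activity-ranked target radii by picking the best of 24
  admissible directions per step (bond lengths stay exact).  The second cell
  line perturbs the first (rigid per-chain rotations + 0.5 b bead jitter):
  genome organisation is largely shared between cell types, and the
  analysis's averaging of radii over cell lines presumes that sharing.
  A plain unbiased confined walk (`gen_structure`) is kept for benchmarks
  that need exact bond/confinement invariants without radial organisation.
* **Contact maps.**  λ_ij ∝ d_ij^(−α) (α = 1) with Poisson counts, total
  expected depth 2×10⁶ per cell line, zero diagonal, symmetrised.  In the
  default world the kernel additionally carries exp(κ a_i a_j) with κ = 1:
  the same-compartment contact enrichment that population Hi-C shows and
  that the compartment-degree eigenvector detects.
* **Genes.**  150 genes with 350-residue i.i.d. random proteins, placed in
  bins with probability ∝ exp(0.5 a): gene density tracks activity, which is
  what makes the gene-density orientation rule meaningful.  Gene intervals
  lie inside single bins so the locus→bin mapping is unambiguous.
* **Assay labels.**  Peptides (length uniform on [11, 30]) are cut from
  random genes; each peptide's positive-assay probability is
  `p = logistic(b0 + b_base·s + b_rad·r̄ + u)` with `s` the surrogate
  baseline score, `r̄` the mean normalised locus radius over cell lines, and
  `u ~ N(0, σ_u²)` a per-peptide latent offset; outcomes are 10 Bernoulli
  assays.  σ_u captures the large unexplained variance of real
  immunogenicity (T-cell repertoire and assay heterogeneity); without it,
  thresholded-rate labels would be a near-deterministic function of the
  score.  Defaults (b0 = 0.1, b_base = 0.8, b_rad = −2, σ_u = 1.5) put the
  surrogate baseline in the published operating regime of sequence-only
  MHC-II immunogenicity predictors — pooled AUC ≈ 0.6 with ≈ 40% positives
  after curation.
* **Surrogate baseline scorer.**  A fixed 9×20 position-weight matrix over
  the peptide's central 9-mer (the MHC-II binding core), mapped to [0, 1]
  through the Gaussian CDF of the PWM-sum null distribution, so random
  peptides score ≈ uniformly, like a percentile-style predictor output.  A
  theoretical min–max scaling was rejected: a 9-term sum never approaches
  the sum of per-position extrema, so it collapses all real peptides to
  ≈ 0.5.  The "EL" table in synthetic bundles is a noisy monotone
  distortion of the "BA" scorer.

**What passing benchmarks show — and don't.**  The world has no unmappable
bins, translocations, TADs or loops; proteins are random (no homology, so
multi-gene peptides are vanishingly rare); assay counts are clean binomials.
Success on it demonstrates that each stage recovers what it is designed to
recover and that an injected radial effect of realistic size is detectable
through the feature-assembly and evaluation machinery — not that real
IEDB/Hi-C data carry such an effect.

## 7. Known limitations

* Recovering per-bin activity from a single contact map is a noisy inverse
  problem: at 60 bins per chromosome the leading eigenvector sometimes
  mixes compartment signal with other modes, so pipeline runs that rebuild
  structures from Hi-C attenuate the radial signal (the linear model still
  gains; the locality-based learners may not).  Deeper maps and longer
  chromosomes sharpen recovery.
* Under a null world (no radial effect), adding the eight structural
  features *costs* KNN and the RBF SVM roughly 0.03–0.10 AUC: peptides
  sharing a bin have identical structural features, so KNN's neighbourhoods
  collapse onto same-locus peptides whose labels are unrelated to the
  query's.  This is expected behaviour of locality-based learners under
  irrelevant, group-duplicated features — logistic regression, which can
  zero them out, stays near the baseline — but it means AUC gains of those
  learners on real data should always be read against such a null.
* The reconstruction returns one population-averaged structure per cell
  line; single-cell variability is out of scope, as are `.hic`/`.cool`
  binary readers (text COO/dense only) and any re-implementation of
  NetMHCIIpan (adapter + surrogate only).
* Benchmarks are sized for a single CPU: 5-fold × 20 repeats on ~550
  peptides, 100-bead recovery runs, 4000-step relaxations.  These sizes are
  stated choices of the package, and all scale up via configuration.
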