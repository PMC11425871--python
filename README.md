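# neo3d

**MHC-II neoantigen immunogenicity prediction augmented with 3D-genome
features.**

Sequence-based predictors of whether an HLA-II-presented peptide will
activate CD4⁺ T cells (NetMHCIIpan-style binding-affinity or eluted-ligand
scores) leave much of measured immunogenicity unexplained.  `neo3d`
implements, as a tested and reusable pipeline, an analysis built on a
complementary hypothesis: *where a peptide's encoding DNA sits inside the
nucleus carries information about its immunogenicity*.  Transcriptionally
active (A-compartment) chromatin preferentially occupies the nuclear
interior; the pipeline reconstructs a whole-genome polymer model from Hi-C
data, reads off each peptide locus's 3D position, and asks whether adding
those coordinates to the baseline score improves classification of
T-cell-assay outcomes.

The pipeline is aimed at computational immunologists and regulatory-genomics
researchers who want to (a) reproduce the analysis end to end on synthetic
data with known ground truth, or (b) run it on their own curated assay
tables, Hi-C maps and baseline scores.

## The model

For peptide *p* with baseline score *s* ∈ [0, 1], the classifier input is the
9-vector

    x(p) = ( s,  ⟨x,y,z⟩₁,  ⟨x,y,z⟩₂,  r₁,  r₂ )

where ⟨x,y,z⟩ₖ is the position of the peptide's 500 kb genomic bin in the
reconstructed structure of cell line *k* (hESC-like and IMR90-like) and
rₖ = ‖⟨x,y,z⟩ₖ‖ is its radial distance from the nuclear centre.  Structures
minimise

    U = Σ_bonds k_b (‖d‖ − b)²  +  Σ_beads k_r (r_i − r*_i)²
      + Σ_close k_rep (c − d_ij)²  [+ Σ_ij k_p (d_ij − c·f_ij^(−1/α))²]

by annealed gradient descent: harmonic bonds enforce chain connectivity,
a radial bias pulls each bead toward a target radius r\*_i derived from its
*compartment degree* (the leading eigenvector of the Pearson-correlation
matrix of the O/E-normalised Hi-C map; higher activity → smaller target
radius), soft-core repulsion provides excluded volume, and optional pairwise
restraints tie distances to contact frequencies.

Assay records are curated IEDB-style: Homo sapiens, MHC class II, peptide
length 11–30, canonical residues only, alleles standardised to
`locus*GG:PP` (default `DRB1*01:01` when unknown), identical (peptide,
allele) records merged, and labels assigned by positive assay rate
(> 0.70 positive, < 0.30 negative, otherwise discarded).  KNN (K = 8), a
Gaussian-kernel SVM and logistic regression are compared against the
baseline score alone under repeated stratified 5-fold and leave-one-out
cross-validation, reporting precision/recall/F1 at the best-F1 cutoff, AUPR
and ROC AUC.

## Worked example

Generate a fully synthetic study world (ground-truth structures, Hi-C maps,
gene annotation, assay table with a built-in radial immunogenicity effect)
and run the whole pipeline:

```bash
neo3d simulate --outdir demo/bundle --seed 42 --n-peptides 800
neo3d run --config demo/config.yaml --outdir demo/out
```

with `demo/config.yaml` pointing at the bundle files (see
`tests/test_pipeline.py` for the exact schema).  The run executes
curate → map → compartments → reconstruct (×2 cell lines) → featurize →
evaluate and prints:

```
completed stages: curate, map, compartments, reconstruct, featurize, evaluate
```

`demo/out/metrics.tsv` (20 repeats of stratified 5-fold CV, 446 curated
peptides, 224 positive / 222 negative):

```
Setting   Method       Precision  Recall    F1-measure  AUPR      AUC       cutoff
BA,kfold  baseline-BA  0.619672   0.84375   0.714556    0.685124  0.714165  0.338151
BA,kfold  Plus3D-KNN   0.530864   0.959821  0.683625    0.626774  0.662095  0.25
BA,kfold  Plus3D-SVM   0.576369   0.892857  0.700525    0.668643  0.710506  0.237455
BA,kfold  Plus3D-LR    0.65371    0.825893  0.729783    0.708775  0.73794   0.400909
```

Reading the table: the baseline score alone reaches AUC 0.714 on this
dataset.  Adding the eight reconstructed 3D-genome features lifts logistic
regression to AUC 0.738 (ΔAUC +0.024 ± 0.006 across repeats, see
`deltas.tsv`), because the reconstructed radial positions partially recover
the injected effect (peptide loci nearer the nuclear centre are more often
immunogenic).  The locality-based learners are more sensitive to
reconstruction noise in the added coordinates: the SVM stays at the baseline
and KNN falls below it here.  When features are read from the ground-truth
structures instead (no reconstruction error; this is what the acceptance
checks do), all three learners beat the baseline and logistic regression
gains ≈ 0.07–0.14 AUC.

Each stage is also exposed separately (`neo3d curate`, `neo3d map`,
`neo3d compartments`, `neo3d reconstruct`, `neo3d featurize`,
`neo3d evaluate --plots ...`), re-runnable from intermediates, and usable as
a library (`import neo3d`).

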