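"""Synthetic study-world generator.

Builds everything the pipeline consumes, with the statistical structure the
analysis assumes, so every downstream stage is testable without external
downloads:

* ground-truth 3D genome structures (confined self-avoiding-style random
  walks, one chain per chromosome, one bead per 500 kb bin);
* population Hi-C contact maps derived from those structures by a power-law
  distance-to-contact model with Poisson counting noise;
* a gene table (BED-style intervals + random protein sequences);
* a peptide assay table: peptides cut from gene proteins, with per-peptide
  positive-assay probability following a declared logistic model

      p = logistic(b0 + b_base * s + b_rad * rbar)

  where ``s`` is the surrogate baseline score of the peptide and ``rbar`` the
  mean normalised radial position of its gene's bin across cell lines.  A
  negative ``b_rad`` encodes the hypothesis under study: peptides whose DNA
  loci sit nearer the nuclear centre are more likely immunogenic.

Every generator is bit-reproducible given its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .baseline import AMINO_ACIDS, DEFAULT_SCORER, SurrogateScorer
from .chromatin import (
    ContactMatrix,
    GenomeStructure,
    write_contact_maps,
    write_structure,
)
from .curation import UNKNOWN_ALLELE, modify_hla_type

__all__ = [
    "EffectParams",
    "SyntheticWorld",
    "gen_structure",
    "gen_organized_structure",
    "smooth_activity",
    "perturb_structure",
    "gen_contact_map",
    "gen_gene_table",
    "gen_peptide_dataset",
    "gene_density",
    "build_world",
    "write_bundle",
]

_HLA_ALLELES = [
    "DRB1*01:01",
    "DRB1*03:01",
    "DRB1*04:01",
    "DRB1*07:01",
    "DRB1*15:01",
    "DQB1*03:02",
    "DPB1*04:01",
]
# raw formatting variants, to exercise allele standardisation downstream
_ALLELE_FORMATS = (
    lambda a: a,
    lambda a: "HLA-" + a,
    lambda a: a.replace("*", "_").replace(":", ""),
)


@dataclass
class EffectParams:
    """Coefficients of the logistic assay-outcome model.

    ``sigma_u`` is the standard deviation of a per-peptide latent logit
    offset: immunogenicity has substantial variance that neither the
    sequence score nor the locus position explains (T-cell repertoire and
    assay heterogeneity), and without it a thresholded-rate label would be
    a near-deterministic function of the score.  Defaults are calibrated so
    the surrogate baseline operates in the published regime of sequence-only
    MHC-II immunogenicity predictors (pooled AUC around 0.6) with a
    positive-class fraction near 0.4.
    """

    b0: float = 0.1
    b_base: float = 0.8
    b_rad: float = -2.0
    sigma_u: float = 1.5


@dataclass
class SyntheticWorld:
    structures: dict  # cell_line -> GenomeStructure (ground truth)
    contact_maps: dict  # cell_line -> list of ContactMatrix
    gene_table: pd.DataFrame
    peptide_table: pd.DataFrame  # raw assay records
    truth: pd.DataFrame  # per-peptide latent quantities
    effect_params: EffectParams
    seed: int
    bin_size_bp: int = 500_000


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _chromosome_names(n_chains: int) -> list:
    names = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    if n_chains <= len(names):
        return names[:n_chains]
    return names + [f"chr{i}" for i in range(23, n_chains)]


def gen_structure(
    n_chains: int,
    beads_per_chain: int,
    bond_length: float,
    nucleus_radius: float,
    seed: int,
    cell_line: str = "truth",
    bin_size_bp: int = 500_000,
    min_separation_frac: float = 0.5,
    max_resamples: int = 1000,
    max_restarts: int = 100,
) -> GenomeStructure:
    """Confined self-avoiding-style random walk, one chain per chromosome.

    Consecutive beads are exactly ``bond_length`` apart, every bead lies
    within ``nucleus_radius`` of the origin, and beads of the same chain keep
    at least ``min_separation_frac * bond_length`` from each other.  Steps
    violating the constraints are resampled (up to ``max_resamples``); if a
    step cannot be placed the chain restarts.
    """
    if n_chains < 1 or beads_per_chain < 2:
        raise ValueError("need n_chains >= 1 and beads_per_chain >= 2")
    if bond_length <= 0 or nucleus_radius <= 0:
        raise ValueError("dimensions must be positive")
    if bond_length >= 2.0 * nucleus_radius:
        raise ValueError("bond_length >= 2 * nucleus_radius: walk cannot stay confined")
    if bond_length >= nucleus_radius:
        raise ValueError("bond_length must be smaller than nucleus_radius")

    rng = np.random.default_rng(seed)
    min_sep = min_separation_frac * bond_length
    chains = {}
    for chrom in _chromosome_names(n_chains):
        for _restart in range(max_restarts):
            coords = _walk_chain(
                rng, beads_per_chain, bond_length, nucleus_radius, min_sep, max_resamples
            )
            if coords is not None:
                chains[chrom] = coords
                break
        else:
            raise RuntimeError(f"could not place chain {chrom} after {max_restarts} restarts")
    return GenomeStructure(
        cell_line=cell_line,
        chains=chains,
        nucleus_radius=nucleus_radius,
        bin_size_bp=bin_size_bp,
    )


def smooth_activity(n_bins: int, rng, correlation_length: int = 10) -> np.ndarray:
    """A smooth, compartment-like per-bin activity profile (mean 0, sd 1).

    White noise convolved with a Gaussian kernel of width
    ``correlation_length`` bins: activity varies along the chain on the
    multi-bin scale characteristic of A/B compartment blocks.
    """
    raw = rng.normal(size=n_bins + 6 * correlation_length)
    x = np.arange(-3 * correlation_length, 3 * correlation_length + 1)
    kernel = np.exp(-0.5 * (x / correlation_length) ** 2)
    sm = np.convolve(raw, kernel, mode="same")[
        3 * correlation_length : 3 * correlation_length + n_bins
    ]
    sm = sm - sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def gen_organized_structure(
    n_chains: int,
    beads_per_chain: int,
    bond_length: float,
    nucleus_radius: float,
    seed: int,
    cell_line: str = "truth",
    bin_size_bp: int = 500_000,
    min_radius_frac: float = 0.1,
    activity_correlation_length: int = 5,
    n_candidates: int = 24,
    min_separation_frac: float = 0.5,
    max_resamples: int = 200,
    max_restarts: int = 100,
) -> GenomeStructure:
    """Radially organised truth structure: active chromatin near the centre.

    Each chromosome receives a smooth activity profile; activity ranks map to
    target radii (high activity -> small radius), and the confined walk is
    biased toward those targets by choosing, among ``n_candidates`` admissible
    random directions per step, the one whose endpoint radius is closest to
    the next bead's target.  Bond lengths stay exact and confinement and
    minimum-separation constraints are preserved; the resulting structure is
    the ground truth whose contact maps carry a recoverable compartment
    signal.
    """
    from .chromatin import ActivityProfile, assign_radial_targets

    if n_chains < 1 or beads_per_chain < 2:
        raise ValueError("need n_chains >= 1 and beads_per_chain >= 2")
    if bond_length <= 0 or nucleus_radius <= 0:
        raise ValueError("dimensions must be positive")
    if bond_length >= nucleus_radius:
        raise ValueError("bond_length must be smaller than nucleus_radius")

    rng = np.random.default_rng(seed)
    min_sep = min_separation_frac * bond_length
    chains, activities = {}, {}
    for chrom in _chromosome_names(n_chains):
        act = smooth_activity(beads_per_chain, rng, activity_correlation_length)
        targets = assign_radial_targets(
            ActivityProfile(chrom, act), nucleus_radius, min_radius_frac
        ).radial_target
        for _restart in range(max_restarts):
            coords = _biased_walk(
                rng, targets, bond_length, nucleus_radius, min_sep,
                n_candidates, max_resamples,
            )
            if coords is not None:
                chains[chrom] = coords
                activities[chrom] = act
                break
        else:
            raise RuntimeError(f"could not place chain {chrom} after {max_restarts} restarts")
    return GenomeStructure(
        cell_line=cell_line,
        chains=chains,
        nucleus_radius=nucleus_radius,
        bin_size_bp=bin_size_bp,
        activities=activities,
    )


def _biased_walk(rng, targets, bond, radius, min_sep, n_candidates, max_resamples):
    n_beads = targets.size
    d0 = rng.normal(size=3)
    d0 /= np.linalg.norm(d0)
    coords = [d0 * min(targets[0], radius - 1e-9)]
    for i in range(1, n_beads):
        best = None
        for _try in range(max_resamples):
            dirs = rng.normal(size=(n_candidates, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            cands = coords[-1] + bond * dirs
            r = np.linalg.norm(cands, axis=1)
            ok = r <= radius
            if len(coords) > 1:
                prev = np.asarray(coords[:-1])
                dmin = np.min(
                    np.linalg.norm(prev[None, :, :] - cands[:, None, :], axis=-1), axis=1
                )
                ok &= dmin >= min_sep
            if ok.any():
                idx = np.flatnonzero(ok)
                best = cands[idx[np.argmin(np.abs(r[idx] - targets[i]))]]
                break
        if best is None:
            return None
        coords.append(best)
    return np.asarray(coords)


def perturb_structure(
    structure: GenomeStructure,
    seed: int,
    cell_line: str,
    jitter: float = 0.5,
) -> GenomeStructure:
    """A correlated variant of a structure, emulating a second cell line.

    Genome organisation is largely shared between cell types, so the second
    cell line is generated from the first rather than independently: each
    chain receives a random rigid rotation about the nuclear centre (radii
    preserved) plus isotropic per-bead jitter with standard deviation
    ``jitter`` (in the structure's length units), then beads straying outside
    the nucleus are pulled back to its surface.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = structure.nucleus_radius
    chains = {}
    for chrom, X in structure.chains.items():
        rot = Rotation.random(rng=rng).as_matrix()
        Y = X @ rot.T + rng.normal(0.0, jitter, size=X.shape)
        norms = np.linalg.norm(Y, axis=1, keepdims=True)
        over = norms[:, 0] > R
        if over.any():
            Y[over] *= R / norms[over]
        chains[chrom] = Y
    return GenomeStructure(
        cell_line=cell_line,
        chains=chains,
        nucleus_radius=R,
        bin_size_bp=structure.bin_size_bp,
        activities=dict(structure.activities) if structure.activities else None,
    )


def _walk_chain(rng, n_beads, bond, radius, min_sep, max_resamples):
    start_dir = rng.normal(size=3)
    start_dir /= np.linalg.norm(start_dir)
    coords = [start_dir * (0.5 * radius) * rng.random() ** (1.0 / 3.0)]
    for _ in range(n_beads - 1):
        placed = False
        for _try in range(max_resamples):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = coords[-1] + bond * d
            if np.linalg.norm(cand) > radius:
                continue
            if len(coords) > 1:
                prev = np.asarray(coords[:-1])
                if np.min(np.linalg.norm(prev - cand, axis=1)) < min_sep:
                    continue
            coords.append(cand)
            placed = True
            break
        if not placed:
            return None
    return np.asarray(coords)


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def expected_contacts(structure: GenomeStructure, alpha: float, depth: float) -> dict:
    """Noise-free expected contact intensities lambda_ij per chromosome.

    Same kernel and normalisation as :func:`gen_contact_map` before Poisson
    sampling; useful for checking the distance-to-contact monotonicity.
    """
    if alpha <= 0 or depth <= 0:
        raise ValueError("alpha and depth must be positive")
    dist = {}
    total_w = 0.0
    for chrom in structure.chromosomes:
        X = structure.chains[chrom]
        D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        iu = np.triu_indices(D.shape[0], k=1)
        total_w += np.sum(D[iu] ** (-alpha))
        dist[chrom] = D
    out = {}
    for chrom, D in dist.items():
        n = D.shape[0]
        lam = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        lam[iu] = (depth / 2.0) * (D[iu] ** (-alpha)) / total_w
        out[chrom] = lam + lam.T
    return out


def gen_contact_map(
    structure: GenomeStructure,
    alpha: float,
    depth: float,
    seed: int,
    compartment_strength: float = 0.0,
) -> list:
    """Poisson-sampled contact maps with a power-law distance kernel.

    Expected counts follow lambda_ij proportional to d_ij^(-alpha) for i != j
    within each chromosome, globally scaled so the expected total count over
    all matrices is ``depth``.  Counts are drawn Poisson on the upper triangle
    and mirrored; diagonals are zero.

    With ``compartment_strength`` kappa > 0 (and a structure carrying per-bin
    activities), the kernel gains the factor exp(kappa * a_i * a_j): the
    preferential same-compartment contact of population Hi-C, in which A-A
    and B-B bin pairs touch more often than A-B pairs at equal distance.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if compartment_strength > 0 and not structure.activities:
        raise ValueError("compartment_strength > 0 requires per-bin activities")
    rng = np.random.default_rng(seed)
    weights = []
    for chrom in structure.chromosomes:
        X = structure.chains[chrom]
        diff = X[:, None, :] - X[None, :, :]
        D = np.linalg.norm(diff, axis=-1)
        iu = np.triu_indices(D.shape[0], k=1)
        if np.any(D[iu] == 0):
            raise ValueError(f"coincident beads on {chrom}: zero off-diagonal distance")
        w = np.zeros_like(D)
        w[iu] = D[iu] ** (-alpha)
        if compartment_strength > 0:
            a = np.asarray(structure.activities[chrom], dtype=float)
            w[iu] *= np.exp(compartment_strength * (a[:, None] * a[None, :])[iu])
        weights.append((chrom, w))
    total_w = sum(w.sum() for _, w in weights)
    out = []
    for chrom, w in weights:
        n = w.shape[0]
        iu = np.triu_indices(n, k=1)
        lam = (depth / 2.0) * w[iu] / total_w
        counts = rng.poisson(lam).astype(float)
        m = np.zeros((n, n))
        m[iu] = counts
        m = m + m.T
        out.append(
            ContactMatrix(chromosome=chrom, bin_size_bp=structure.bin_size_bp, counts=m)
        )
    return out


# ---------------------------------------------------------------------------
# genes and peptides
# ---------------------------------------------------------------------------

def gen_gene_table(
    structure: GenomeStructure,
    n_genes: int,
    seed: int,
    protein_length: int = 350,
    gene_span_bp: int = 30_000,
    activity_bias: float = 0.5,
) -> pd.DataFrame:
    """Random gene annotation compatible with a genome structure.

    Each gene is dropped into a bin (its interval fully inside that bin, so
    the bin of its midpoint is unambiguous) and receives an i.i.d. random
    protein sequence.  When the structure carries per-bin activities, bins
    are sampled with probability proportional to exp(activity_bias * a):
    gene-dense chromatin is active chromatin, which is what lets gene
    density orient the compartment eigenvector downstream.  Without
    activities (or with activity_bias = 0) placement is uniform.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if gene_span_bp >= structure.bin_size_bp:
        raise ValueError("gene_span_bp must be smaller than the bin size")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    chroms = structure.chromosomes
    bins = [(c, b) for c in chroms for b in range(structure.n_beads(c))]
    if structure.activities and activity_bias != 0.0:
        act = np.concatenate([structure.activities[c] for c in chroms])
        probs = np.exp(activity_bias * act)
        probs /= probs.sum()
    else:
        probs = np.full(len(bins), 1.0 / len(bins))
    rows = []
    width = len(str(n_genes))
    for g in range(n_genes):
        chrom, b = bins[int(rng.choice(len(bins), p=probs))]
        offset = int(rng.integers(structure.bin_size_bp - gene_span_bp))
        start = b * structure.bin_size_bp + offset
        protein = "".join(rng.choice(aa, size=protein_length))
        rows.append(
            {
                "gene_id": f"G{g:0{width}d}",
                "chromosome": chrom,
                "start_bp": start,
                "end_bp": start + gene_span_bp,
                "protein_sequence": protein,
            }
        )
    return pd.DataFrame(rows)


def gene_density(gene_table: pd.DataFrame, chromosome: str, n_bins: int, bin_size_bp: int):
    """Genes-per-bin marker track used to orient compartment activity."""
    track = np.zeros(n_bins)
    sub = gene_table[gene_table["chromosome"] == chromosome]
    mids = (sub["start_bp"] + sub["end_bp"]) // 2
    for m in mids:
        b = int(m) // bin_size_bp
        if 0 <= b < n_bins:
            track[b] += 1
    return track


def gen_peptide_dataset(
    world_structures: dict,
    gene_table: pd.DataFrame,
    n_peptides: int,
    effect_params: EffectParams,
    assays_per_peptide: int = 10,
    seed: int = 0,
    scorer: SurrogateScorer = DEFAULT_SCORER,
    known_allele_frac: float = 0.3,
    split_prob: float = 0.3,
):
    """Generate raw assay records under the declared logistic label model.

    Returns ``(records, truth)``: records are curation-ready rows (peptide,
    allele, n_positive, n_total, species, mhc_class) — some peptides split
    into two records and some allele strings left raw/absent to exercise the
    curation rules — and truth holds the latent per-peptide quantities
    (surrogate score, mean normalised radius, true assay probability).
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    if assays_per_peptide < 1:
        raise ValueError("assays_per_peptide must be >= 1")
    usable = gene_table[gene_table["protein_sequence"].str.len() >= 11]
    if usable.empty:
        raise ValueError("all proteins shorter than 11 residues: cannot cut peptides")
    rng = np.random.default_rng(seed)
    genes = usable.reset_index(drop=True)
    cells = list(world_structures)
    bin_size = world_structures[cells[0]].bin_size_bp

    seen = set()
    pep_rows = []
    truth_rows = []
    for _ in range(n_peptides):
        for _try in range(50):
            g = genes.iloc[int(rng.integers(len(genes)))]
            prot = g["protein_sequence"]
            L = int(rng.integers(11, min(30, len(prot)) + 1))
            start = int(rng.integers(len(prot) - L + 1))
            pep = prot[start : start + L]
            if pep not in seen:
                seen.add(pep)
                break
        else:
            raise RuntimeError("could not generate a unique peptide; enlarge gene table")

        mid = (int(g["start_bp"]) + int(g["end_bp"])) // 2
        bin_index = mid // bin_size
        radii = []
        for cell in cells:
            st = world_structures[cell]
            _, _, _, r = _bead(st, g["chromosome"], bin_index)
            radii.append(r / st.nucleus_radius)
        rbar = float(np.mean(radii))
        s = scorer.score(pep)
        u = float(rng.normal(0.0, effect_params.sigma_u)) if effect_params.sigma_u > 0 else 0.0
        p = float(
            expit(effect_params.b0 + effect_params.b_base * s + effect_params.b_rad * rbar + u)
        )
        n_pos = int(rng.binomial(assays_per_peptide, p))

        if rng.random() < known_allele_frac:
            allele = _HLA_ALLELES[int(rng.integers(len(_HLA_ALLELES)))]
            raw_allele = _ALLELE_FORMATS[int(rng.integers(len(_ALLELE_FORMATS)))](allele)
        else:
            raw_allele = ""

        n_tot = assays_per_peptide
        if n_tot >= 2 and rng.random() < split_prob:
            k = int(rng.integers(1, n_tot))
            k_pos = int(rng.hypergeometric(n_pos, n_tot - n_pos, k))
            pieces = [(k_pos, k), (n_pos - k_pos, n_tot - k)]
        else:
            pieces = [(n_pos, n_tot)]
        for np_i, nt_i in pieces:
            pep_rows.append(
                {
                    "peptide": pep,
                    "allele": raw_allele,
                    "n_positive": np_i,
                    "n_total": nt_i,
                    "species": "Homo sapiens",
                    "mhc_class": "II",
                }
            )
        truth_rows.append(
            {
                "peptide": pep,
                "gene_id": g["gene_id"],
                "chromosome": g["chromosome"],
                "bin_index": bin_index,
                "score": s,
                "radius_mean": rbar,
                "p_true": p,
                "n_positive": n_pos,
                "n_total": n_tot,
            }
        )
    return pd.DataFrame(pep_rows), pd.DataFrame(truth_rows)


def _bead(structure: GenomeStructure, chromosome, bin_index):
    xyz = structure.chains[chromosome]
    if not (0 <= bin_index < xyz.shape[0]):
        raise IndexError(f"gene bin {bin_index} outside {chromosome}")
    x, y, z = xyz[bin_index]
    return x, y, z, float(np.linalg.norm(xyz[bin_index]))


# ---------------------------------------------------------------------------
# whole worlds and bundles
# ---------------------------------------------------------------------------

def build_world(
    n_chains: int = 3,
    beads_per_chain: int = 60,
    n_genes: int = 150,
    n_peptides: int = 300,
    effect_params: EffectParams | None = None,
    assays_per_peptide: int = 10,
    bond_length: float = 1.0,
    nucleus_radius: float = 6.0,
    bin_size_bp: int = 500_000,
    alpha: float = 1.0,
    depth: float = 2e6,
    seed: int = 0,
    cell_lines=("hESC", "IMR90"),
    known_allele_frac: float = 0.3,
    compartment_strength: float = 1.0,
) -> SyntheticWorld:
    """Generate a complete, self-consistent synthetic study world.

    The first cell line's structure is radially organised by a smooth
    compartment-like activity profile (active regions near the nuclear
    centre), so its distance-derived contact maps carry a recoverable
    compartment signal; further cell lines perturb the first (genome
    organisation is largely shared between cell types).  One gene table and
    one assay table are shared.
    """
    if effect_params is None:
        effect_params = EffectParams()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + len(cell_lines))]
    structures = {}
    contact_maps = {}
    for i, cell in enumerate(cell_lines):
        if i == 0:
            st = gen_organized_structure(
                n_chains,
                beads_per_chain,
                bond_length,
                nucleus_radius,
                seed=seeds[i],
                cell_line=cell,
                bin_size_bp=bin_size_bp,
            )
        else:  # later cell lines share the first one's organisation
            st = perturb_structure(
                structures[cell_lines[0]],
                seed=seeds[i],
                cell_line=cell,
                jitter=0.5 * bond_length,
            )
        structures[cell] = st
        contact_maps[cell] = gen_contact_map(
            st, alpha=alpha, depth=depth, seed=seeds[i] + 1,
            compartment_strength=compartment_strength,
        )
    ref = structures[cell_lines[0]]
    gene_table = gen_gene_table(ref, n_genes=n_genes, seed=seeds[-3])
    records, truth = gen_peptide_dataset(
        structures,
        gene_table,
        n_peptides=n_peptides,
        effect_params=effect_params,
        assays_per_peptide=assays_per_peptide,
        seed=seeds[-2],
        known_allele_frac=known_allele_frac,
    )
    return SyntheticWorld(
        structures=structures,
        contact_maps=contact_maps,
        gene_table=gene_table,
        peptide_table=records,
        truth=truth,
        effect_params=effect_params,
        seed=seed,
        bin_size_bp=bin_size_bp,
    )


def write_bundle(world: SyntheticWorld, outdir, default_allele: str = "DRB1*01:01") -> dict:
    """Write every downstream input file; returns {name: path}.

    Baseline score tables are written in two surrogate "training modes":
    ``BA`` is the scorer that drives the label model; ``EL`` is a noisy
    monotone distortion of it (an independent-looking second baseline).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "assays.tsv"
    world.peptide_table.to_csv(p, sep="\t", index=False)
    paths["assays"] = p

    p = outdir / "genes.bed"
    bed = world.gene_table[["chromosome", "start_bp", "end_bp", "gene_id"]]
    bed.to_csv(p, sep="\t", index=False, header=False)
    paths["genes_bed"] = p

    p = outdir / "proteins.fasta"
    with open(p, "w") as fh:
        for row in world.gene_table.itertuples(index=False):
            fh.write(f">{row.gene_id}\n{row.protein_sequence}\n")
    paths["proteins_fasta"] = p

    for cell, maps in world.contact_maps.items():
        p = outdir / f"contacts_{cell}.tsv"
        write_contact_maps(maps, p)
        paths[f"contacts_{cell}"] = p
    for cell, st in world.structures.items():
        p = outdir / f"structure_{cell}.tsv"
        write_structure(st, p)
        paths[f"structure_{cell}"] = p

    # baseline tables keyed by (peptide, standardised-or-default allele)
    keys = {}
    for row in world.peptide_table.itertuples(index=False):
        std = modify_hla_type(row.allele)
        allele = default_allele if std == UNKNOWN_ALLELE else std
        keys[(row.peptide.upper(), allele)] = None
    peps = sorted(keys)
    ba = np.array([DEFAULT_SCORER.score(pep) for pep, _ in peps])
    rng = np.random.default_rng(world.seed + 17)
    el_raw = ba + rng.normal(0.0, 0.1, size=ba.size)
    el = (el_raw - el_raw.min()) / max(el_raw.max() - el_raw.min(), 1e-12)
    for mode, scores in (("BA", ba), ("EL", el)):
        p = outdir / f"baseline_{mode}.tsv"
        pd.DataFrame(
            {
                "peptide": [k[0] for k in peps],
                "allele": [k[1] for k in peps],
                "score": scores,
            }
        ).to_csv(p, sep="\t", index=False, float_format="%.8g")
        paths[f"baseline_{mode}"] = p

    p = outdir / "world_params.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "seed": world.seed,
                "bin_size_bp": world.bin_size_bp,
                "effect_params": vars(world.effect_params),
                "n_peptides": int(world.truth.shape[0]),
                "cell_lines": list(world.structures),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    paths["params"] = p
    return paths
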