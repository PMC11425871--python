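"""Offline peptide-to-genome mapping.

Each curated peptide is located on the genome by exact substring search over
a user-supplied protein FASTA (one record per gene) cross-referenced with a
BED file of gene loci.  This replaces an online BLAST/annotation chain with a
deterministic, download-free equivalent: curated epitopes are literal
substrings of their source proteins, so an exact search recovers the gene.
Peptides hitting several genes resolve to the lexicographically smallest
gene id (a stable, auditable tie-break); a precomputed peptide->gene hit
table from an external search can be supplied instead.

Coordinates are 0-based half-open (BED convention).  A locus is assigned to
a fixed-size genomic bin by the floor of its midpoint over the bin size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicLocus",
    "ProteinAnnotation",
    "load_annotation",
    "map_peptide",
    "locus_to_bin",
    "map_peptides",
]


@dataclass(frozen=True)
class GenomicLocus:
    chromosome: str
    start_bp: int
    end_bp: int
    gene_id: str
    match_quality: str = "exact"

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise ValueError(
                f"{self.gene_id}: invalid interval {self.start_bp}-{self.end_bp}"
            )


@dataclass
class ProteinAnnotation:
    """Gene-indexed protein sequences and genomic intervals."""

    proteins: dict  # gene_id -> protein sequence
    loci: dict  # gene_id -> GenomicLocus
    unmatched_fasta: list = field(default_factory=list)  # in FASTA, no BED entry
    unmatched_bed: list = field(default_factory=list)  # in BED, no FASTA record

    def __post_init__(self):
        self._order = sorted(set(self.proteins) & set(self.loci))

    @property
    def gene_ids(self) -> list:
        """Cross-referenced gene ids, lexicographically sorted."""
        return self._order


def load_annotation(fasta_path, bed_path) -> ProteinAnnotation:
    """Load and cross-reference a protein FASTA and a gene BED.

    The BED may have up to 6 columns; columns 1-3 (chrom, start, end) and 4
    (name = gene id) are used.  Duplicate gene ids in the BED and invalid
    intervals are errors; ids present in only one file are reported, not
    fatal.
    """
    proteins = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        proteins[rec.id] = str(rec.seq).upper()

    loci = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{bed_path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_bp, end_bp = int(start), int(end)
            except ValueError:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates")
            if end_bp <= start_bp:
                raise ValueError(f"{bed_path}:{lineno}: end <= start for {name}")
            if name in loci:
                raise ValueError(f"{bed_path}:{lineno}: duplicate gene id {name!r}")
            loci[name] = GenomicLocus(
                chromosome=chrom, start_bp=start_bp, end_bp=end_bp, gene_id=name
            )

    unmatched_fasta = sorted(set(proteins) - set(loci))
    unmatched_bed = sorted(set(loci) - set(proteins))
    return ProteinAnnotation(
        proteins=proteins,
        loci=loci,
        unmatched_fasta=unmatched_fasta,
        unmatched_bed=unmatched_bed,
    )


def map_peptide(
    peptide: str, annotation: ProteinAnnotation, hit_table: dict | None = None
) -> GenomicLocus | None:
    """Locate one peptide by exact substring search over all proteins.

    Returns the locus of the lexicographically smallest matching gene id, or
    None when no protein contains the peptide.  ``hit_table`` (peptide ->
    gene_id) bypasses the search for users who ran an external aligner.
    """
    pep = peptide.upper()
    if hit_table is not None and pep in hit_table:
        gid = hit_table[pep]
        return annotation.loci.get(gid)
    for gid in annotation.gene_ids:  # sorted: first hit is the tie-break winner
        if pep in annotation.proteins[gid]:
            return annotation.loci[gid]
    return None


def locus_to_bin(locus: GenomicLocus, bin_size_bp: int, valid_chromosomes=None):
    """Fixed-size bin containing the locus midpoint.

    bin_index = floor(midpoint / bin_size); midpoints exactly on a boundary
    fall into the upper (half-open) bin.
    """
    if bin_size_bp <= 0:
        raise ValueError("bin_size_bp must be positive")
    if valid_chromosomes is not None and locus.chromosome not in valid_chromosomes:
        raise KeyError(f"chromosome {locus.chromosome!r} not in structure")
    midpoint = (locus.start_bp + locus.end_bp) // 2
    return locus.chromosome, midpoint // bin_size_bp


def map_peptides(
    curated: pd.DataFrame,
    annotation: ProteinAnnotation,
    bin_size_bp: int,
    hit_table: dict | None = None,
):
    """Map a curated peptide table; returns (mapped frame, n_unmapped).

    Output columns: peptide, allele, label, chromosome, start, end, gene_id,
    bin_index.  Peptides with no hit are dropped (counted, not fatal): the
    downstream feature assembly requires a genomic locus.
    """
    rows = []
    n_unmapped = 0
    cache: dict = {}
    for rec in curated.itertuples(index=False):
        pep = rec.peptide
        if pep not in cache:
            cache[pep] = map_peptide(pep, annotation, hit_table=hit_table)
        locus = cache[pep]
        if locus is None:
            n_unmapped += 1
            continue
        chrom, bin_index = locus_to_bin(locus, bin_size_bp)
        rows.append(
            {
                "peptide": pep,
                "allele": rec.allele,
                "label": rec.label,
                "chromosome": chrom,
                "start": locus.start_bp,
                "end": locus.end_bp,
                "gene_id": locus.gene_id,
                "bin_index": bin_index,
            }
        )
    cols = ["peptide", "allele", "label", "chromosome", "start", "end", "gene_id", "bin_index"]
    return pd.DataFrame(rows, columns=cols), n_unmapped
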