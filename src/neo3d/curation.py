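"""Curation of raw T-cell-assay records into labelled peptide datasets.

Raw records in the style of an IEDB T-Cell Assay export (peptide, HLA allele,
positive/total assay counts, species, MHC class) are filtered and labelled:

1. keep Homo sapiens, MHC class II records;
2. keep peptides of length 11-30 (the MHC-II-presented length range);
3. uppercase peptides and reject any containing a non-canonical residue;
4. standardise HLA allele names to ``locus*GG:PP`` form (``modify_hla_type``);
5. merge identical (peptide, allele) records by pooling assay counts;
6. label by positive rate: > 0.70 -> positive, < 0.30 -> negative, anything
   in between is discarded as ambiguous.

Two datasets come out: the *full* dataset, where peptides with unknown MHC
subtype are assigned the default allele DRB1*01:01, and the *known-allele*
dataset restricted to records whose allele parsed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .baseline import AMINO_ACIDS

__all__ = [
    "CurationConfig",
    "CurationResult",
    "UNKNOWN_ALLELE",
    "check_illegal_peptides",
    "modify_hla_type",
    "curate",
    "read_assay_records",
    "write_curated",
    "curated_to_records",
]

UNKNOWN_ALLELE = "unknown"
_CANONICAL = set(AMINO_ACIDS)

RAW_COLUMNS = ["peptide", "allele", "n_positive", "n_total", "species", "mhc_class"]
CURATED_COLUMNS = ["peptide", "allele", "label", "positive_rate", "n_assays"]


@dataclass
class CurationConfig:
    min_len: int = 11
    max_len: int = 30
    pos_threshold: float = 0.70
    neg_threshold: float = 0.30
    default_allele: str = "DRB1*01:01"
    species_filter: str = "Homo sapiens"
    mhc_class_filter: str = "II"
    #: "pooled": positive_rate = sum(n_positive)/sum(n_total) over merged
    #: records; "averaged": unweighted mean of per-record rates.
    rate_method: str = "pooled"

    def __post_init__(self):
        if not (0 <= self.neg_threshold < self.pos_threshold <= 1):
            raise ValueError("need 0 <= neg_threshold < pos_threshold <= 1")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.rate_method not in ("pooled", "averaged"):
            raise ValueError("rate_method must be 'pooled' or 'averaged'")


@dataclass
class CurationResult:
    """Outputs of `curate`: two datasets plus an auditable exclusion report."""

    full: pd.DataFrame
    known_allele: pd.DataFrame
    report: dict = field(default_factory=dict)

    def report_text(self) -> str:
        lines = ["curation report", "---------------"]
        for k, v in self.report.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def check_illegal_peptides(records: pd.DataFrame):
    """Split records on amino-acid alphabet legitimacy.

    Peptides are uppercased first (exports vary in case); any record whose
    peptide contains a character outside the 20 canonical letters is rejected,
    with the offending character recorded in an ``illegal_char`` column.
    """
    df = records.copy()
    df["peptide"] = df["peptide"].astype(str).str.upper()
    bad_char = df["peptide"].map(_first_illegal)
    rejected = df[bad_char.notna()].copy()
    rejected["illegal_char"] = bad_char[bad_char.notna()]
    kept = df[bad_char.isna()].copy()
    return kept, rejected


def _first_illegal(peptide: str):
    for ch in peptide:
        if ch not in _CANONICAL:
            return ch
    return None


# HLA-II allele grammar: optional "HLA-" prefix, a class-II locus (DRB1,
# DQA1, DQB1, DPB1, DRA, ...), then group and protein fields separated by
# any of * _ : - or (for 2+2 digit forms) nothing.  Output: locus*GG:PP.
_SEP = r"[\*_:\- ]"
_LOCUS = r"(D[A-Z]{1,2}\d?)"
_TWO_SEP = re.compile(rf"^{_LOCUS}{_SEP}+(\d{{1,2}}){_SEP}+(\d{{1,2}})$")
_COMPACT = re.compile(rf"^{_LOCUS}{_SEP}*(\d{{2}}){_SEP}*(\d{{2}})$")


def modify_hla_type(allele) -> str:
    """Standardise an HLA-II allele name, or return the unknown marker.

    Accepts an optional ``HLA-`` prefix and separators ``* _ : -`` (or none,
    for compact 4-digit forms); group/protein fields are zero-padded to two
    digits.  Anything that does not parse maps to :data:`UNKNOWN_ALLELE`.
    """
    if allele is None or (isinstance(allele, float) and pd.isna(allele)):
        return UNKNOWN_ALLELE
    a = str(allele).strip().upper()
    if not a or a in ("NAN", "NA", "NONE", UNKNOWN_ALLELE.upper()):
        return UNKNOWN_ALLELE
    a = re.sub(r"^HLA-", "", a)
    m = _TWO_SEP.match(a) or _COMPACT.match(a)
    if not m:
        return UNKNOWN_ALLELE
    locus, group, protein = m.groups()
    return f"{locus}*{group.zfill(2)}:{protein.zfill(2)}"


def curate(records: pd.DataFrame, config: CurationConfig | None = None) -> CurationResult:
    """Run the full curation pipeline on raw assay records.

    Returns a :class:`CurationResult` whose ``full`` dataset substitutes the
    default allele for unknown-subtype peptides and whose ``known_allele``
    dataset drops them.  Output is sorted by (peptide, allele) so it does not
    depend on input record order.
    """
    if config is None:
        config = CurationConfig()
    report: dict = {"input_records": int(len(records))}
    if records.empty:
        empty = pd.DataFrame(columns=CURATED_COLUMNS)
        report["kept_peptides_full"] = 0
        return CurationResult(full=empty, known_allele=empty.copy(), report=report)

    df = records.copy()
    df["n_positive"] = df["n_positive"].astype(int)
    df["n_total"] = df["n_total"].astype(int)
    if (df["n_positive"] > df["n_total"]).any() or (df["n_total"] < 1).any():
        raise ValueError("invalid assay counts: need 0 <= n_positive <= n_total, n_total >= 1")

    keep = df["species"].astype(str).str.strip().str.casefold() == config.species_filter.casefold()
    report["excluded_species"] = int((~keep).sum())
    df = df[keep]
    keep = df["mhc_class"].astype(str).str.strip().str.upper() == config.mhc_class_filter.upper()
    report["excluded_mhc_class"] = int((~keep).sum())
    df = df[keep]

    df["peptide"] = df["peptide"].astype(str).str.upper()
    lengths = df["peptide"].str.len()
    keep = (lengths >= config.min_len) & (lengths <= config.max_len)
    report["excluded_length"] = int((~keep).sum())
    df = df[keep]

    df, rejected = check_illegal_peptides(df)
    report["excluded_illegal_residue"] = int(len(rejected))

    df["allele"] = df["allele"].map(modify_hla_type)

    grouped = df.groupby(["peptide", "allele"], sort=True)
    merged = grouped.agg(
        n_positive=("n_positive", "sum"), n_assays=("n_total", "sum")
    ).reset_index()
    if config.rate_method == "pooled":
        merged["positive_rate"] = merged["n_positive"] / merged["n_assays"]
    else:
        rate = grouped.apply(
            lambda g: (g["n_positive"] / g["n_total"]).mean(), include_groups=False
        )
        merged["positive_rate"] = rate.values

    pos = merged["positive_rate"] > config.pos_threshold
    neg = merged["positive_rate"] < config.neg_threshold
    report["discarded_ambiguous_rate"] = int((~pos & ~neg).sum())
    merged = merged[pos | neg].copy()
    merged["label"] = pd.Series("negative", index=merged.index).where(
        ~(merged["positive_rate"] > config.pos_threshold), "positive"
    )

    known = merged[merged["allele"] != UNKNOWN_ALLELE].copy()
    full = merged.copy()
    full.loc[full["allele"] == UNKNOWN_ALLELE, "allele"] = config.default_allele
    # re-merge in case a default-allele record already existed for a peptide
    full = _remerge_default(full, config)

    full = full[CURATED_COLUMNS].sort_values(["peptide", "allele"]).reset_index(drop=True)
    known = known[CURATED_COLUMNS].sort_values(["peptide", "allele"]).reset_index(drop=True)
    report["kept_peptides_full"] = int(len(full))
    report["kept_peptides_known_allele"] = int(len(known))
    report["label_positive_full"] = int((full["label"] == "positive").sum())
    report["label_negative_full"] = int((full["label"] == "negative").sum())
    return CurationResult(full=full, known_allele=known, report=report)


def _remerge_default(full: pd.DataFrame, config: CurationConfig) -> pd.DataFrame:
    dup = full.duplicated(["peptide", "allele"], keep=False)
    if not dup.any():
        return full
    merged = (
        full.groupby(["peptide", "allele"], sort=True)
        .agg(n_positive=("n_positive", "sum"), n_assays=("n_assays", "sum"))
        .reset_index()
    )
    merged["positive_rate"] = merged["n_positive"] / merged["n_assays"]
    pos = merged["positive_rate"] > config.pos_threshold
    neg = merged["positive_rate"] < config.neg_threshold
    merged = merged[pos | neg].copy()
    merged["label"] = pd.Series("negative", index=merged.index).where(
        ~(merged["positive_rate"] > config.pos_threshold), "positive"
    )
    return merged


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_assay_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str}, keep_default_na=False)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay file {path} missing columns {sorted(missing)}")
    return df[RAW_COLUMNS]


def write_curated(df: pd.DataFrame, path):
    df[CURATED_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def curated_to_records(curated: pd.DataFrame, config: CurationConfig | None = None) -> pd.DataFrame:
    """Re-express a curated dataset as raw assay records (for audits).

    The pooled positive rate and assay count determine the positive count
    exactly, so curating the result again reproduces the curated dataset.
    """
    if config is None:
        config = CurationConfig()
    out = curated.copy()
    out["n_total"] = out["n_assays"].astype(int)
    out["n_positive"] = (out["positive_rate"] * out["n_total"]).round().astype(int)
    out["species"] = config.species_filter
    out["mhc_class"] = config.mhc_class_filter
    return out[RAW_COLUMNS]
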