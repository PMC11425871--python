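"""Assembly of the 9-feature vector per peptide.

For each curated peptide the classifier input is: one baseline score
(BA-, EL- or surrogate-mode), the <x, y, z> coordinates of its DNA locus
bead in each of two cell-line genome structures, and the bead's radial
position (distance from the nuclear centre) in each structure — 9 features
in a fixed column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import bead_lookup

__all__ = [
    "BaselineScoreTable",
    "FeatureTable",
    "load_baseline_scores",
    "scores_from_function",
    "assemble",
    "read_feature_table",
]

#: header names a NetMHCIIpan-style export may use for its score column,
#: in priority order
_ADAPTER_SCORE_COLUMNS = ["score", "Score", "Score_BA", "Score_EL", "Prediction", "Rank"]


@dataclass
class BaselineScoreTable:
    """Per-(peptide, allele) baseline scores in [0, 1]."""

    entries: dict  # (peptide, allele) -> float
    mode: str  # BA | EL | surrogate
    n_duplicates_dropped: int = 0
    source_column: str | None = None

    def get(self, peptide: str, allele: str):
        return self.entries.get((peptide, allele))


@dataclass
class FeatureTable:
    """Per-peptide features + labels with a frozen 9-column feature order."""

    frame: pd.DataFrame
    feature_names: list
    cell_lines: tuple
    mode: str
    dropped: dict = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return (self.frame["label"] == "positive").to_numpy(dtype=int)

    def to_tsv(self, path):
        cols = ["peptide", "allele", "label"] + self.feature_names
        self.frame[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def feature_names(cell_lines) -> list:
    a, b = cell_lines
    return [
        "score",
        f"{a}_x",
        f"{a}_y",
        f"{a}_z",
        f"{b}_x",
        f"{b}_y",
        f"{b}_z",
        f"{a}_r",
        f"{b}_r",
    ]


def load_baseline_scores(path, mode: str) -> BaselineScoreTable:
    """Load a baseline score table.

    Primary format: TSV with columns (peptide, allele, score).  An adapter
    also accepts NetMHCIIpan-style multi-column output, extracting the first
    recognised score column by header name (recorded in ``source_column``).
    Duplicate (peptide, allele) keys keep the best (highest) score.
    """
    df = pd.read_csv(path, sep="\t")
    if "peptide" not in df.columns or "allele" not in df.columns:
        raise ValueError(f"{path}: baseline table needs 'peptide' and 'allele' columns")
    col = next((c for c in _ADAPTER_SCORE_COLUMNS if c in df.columns), None)
    if col is None:
        raise ValueError(f"{path}: no recognised score column (tried {_ADAPTER_SCORE_COLUMNS})")
    scores = pd.to_numeric(df[col], errors="coerce")
    if scores.isna().any():
        row = int(np.flatnonzero(scores.isna())[0])
        raise ValueError(f"{path}: non-numeric score at data row {row + 1}")
    entries: dict = {}
    n_dup = 0
    for pep, allele, s in zip(df["peptide"], df["allele"], scores):
        key = (str(pep).upper(), str(allele))
        if key in entries:
            n_dup += 1
            entries[key] = max(entries[key], float(s))
        else:
            entries[key] = float(s)
    return BaselineScoreTable(
        entries=entries, mode=mode, n_duplicates_dropped=n_dup, source_column=col
    )


def scores_from_function(pairs, score_fn, mode: str = "surrogate") -> BaselineScoreTable:
    """Build a score table by applying ``score_fn(peptide)`` to each key."""
    entries = {(p.upper(), a): float(score_fn(p)) for p, a in pairs}
    return BaselineScoreTable(entries=entries, mode=mode)


def assemble(
    mapped: pd.DataFrame,
    structures,
    scores: BaselineScoreTable,
) -> FeatureTable:
    """Join mapped peptides, two genome structures and baseline scores.

    ``mapped`` is the genome-mapping output (peptide, allele, label,
    chromosome, bin_index, ...).  Peptides lacking a bead in either structure
    or a baseline score are dropped with a recorded reason; emitted rows have
    no missing values.
    """
    structures = list(structures)
    if len(structures) != 2:
        raise ValueError("exactly two cell-line structures are required")
    a, b = structures
    if a.bin_size_bp != b.bin_size_bp:
        raise ValueError(
            f"structures disagree on bin size: {a.bin_size_bp} vs {b.bin_size_bp}"
        )
    cells = (a.cell_line, b.cell_line)
    names = feature_names(cells)
    dropped = {"no_bead": 0, "no_score": 0}
    rows = []
    for rec in mapped.itertuples(index=False):
        try:
            xa, ya, za, ra = bead_lookup(a, rec.chromosome, rec.bin_index)
            xb, yb, zb, rb = bead_lookup(b, rec.chromosome, rec.bin_index)
        except (KeyError, IndexError):
            dropped["no_bead"] += 1
            continue
        s = scores.get(rec.peptide, rec.allele)
        if s is None:
            dropped["no_score"] += 1
            continue
        rows.append(
            {
                "peptide": rec.peptide,
                "allele": rec.allele,
                "label": rec.label,
                "score": s,
                f"{cells[0]}_x": xa,
                f"{cells[0]}_y": ya,
                f"{cells[0]}_z": za,
                f"{cells[1]}_x": xb,
                f"{cells[1]}_y": yb,
                f"{cells[1]}_z": zb,
                f"{cells[0]}_r": ra,
                f"{cells[1]}_r": rb,
            }
        )
    frame = pd.DataFrame(rows, columns=["peptide", "allele", "label"] + names)
    return FeatureTable(
        frame=frame,
        feature_names=names,
        cell_lines=cells,
        mode=scores.mode,
        dropped=dropped,
    )


def read_feature_table(path, cell_lines) -> FeatureTable:
    names = feature_names(cell_lines)
    frame = pd.read_csv(path, sep="\t")
    missing = set(["peptide", "allele", "label"] + names) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    return FeatureTable(frame=frame, feature_names=names, cell_lines=tuple(cell_lines), mode="loaded")
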