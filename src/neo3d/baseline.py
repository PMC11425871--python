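"""Surrogate peptide–MHC baseline scorer.

Immunogenicity pipelines built on NetMHCIIpan treat the binding-affinity (BA)
or eluted-ligand (EL) score as an opaque per-peptide input in [0, 1].  This
module provides a deterministic stand-in with the same contract: a fixed
position-weight-matrix (PWM) score over the peptide's central 9-mer
(the canonical MHC-II binding core length), mapped to [0, 1] through the
Gaussian CDF of the PWM-sum null distribution (uniform residue usage), so
random peptides score approximately uniformly — the behaviour of a
percentile-style predictor output.  The scorer carries no learned biology;
it exists so the pipeline and its benchmarks run without an external
predictor.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

CORE_LENGTH = 9


class SurrogateScorer:
    """Fixed-PWM peptide scorer emulating a BA/EL-style baseline.

    Parameters
    ----------
    pwm_seed : int
        Seed for the one-off draw of the 9x20 weight matrix.  Two scorers
        built with the same seed are identical; different seeds give
        independent surrogate "training modes".
    """

    def __init__(self, pwm_seed: int = 2021):
        rng = np.random.default_rng(pwm_seed)
        self.weights = rng.normal(0.0, 1.0, size=(CORE_LENGTH, len(AMINO_ACIDS)))
        # null moments of the PWM sum under uniform residue usage
        self._null_mean = self.weights.mean(axis=1).sum()
        self._null_sd = float(np.sqrt(self.weights.var(axis=1).sum()))

    def core(self, peptide: str) -> str:
        """Central 9-mer of a peptide (length >= 9)."""
        if len(peptide) < CORE_LENGTH:
            raise ValueError(f"peptide shorter than binding core: {peptide!r}")
        start = (len(peptide) - CORE_LENGTH) // 2
        return peptide[start : start + CORE_LENGTH]

    def score(self, peptide: str) -> float:
        """PWM sum over the central 9-mer, null-CDF-mapped into [0, 1]."""
        core = self.core(peptide.upper())
        try:
            raw = sum(self.weights[i, _AA_INDEX[aa]] for i, aa in enumerate(core))
        except KeyError as exc:
            raise ValueError(f"non-canonical residue {exc} in peptide {peptide!r}")
        return float(ndtr((raw - self._null_mean) / self._null_sd))

    def score_many(self, peptides) -> np.ndarray:
        return np.array([self.score(p) for p in peptides])


#: Default scorer used for the "surrogate" baseline mode and for the
#: synthetic label model.
DEFAULT_SCORER = SurrogateScorer()
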