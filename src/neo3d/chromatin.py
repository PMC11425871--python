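"""Hi-C compartment analysis and polymer-model 3D genome reconstruction.

The genome is modelled as one bead-on-a-string polymer chain per chromosome,
one bead per fixed-size Hi-C bin (500 kb by default).  Two observations drive
bead placement:

* **connectivity** — sequential bins are spatial neighbours, enforced by a
  harmonic bond between consecutive beads;
* **activity** — transcriptionally active (A-compartment-like) chromatin sits
  closer to the nuclear centre.  Per-bin activity is estimated as the
  *compartment degree*: the leading eigenvector of the Pearson-correlation
  matrix of the distance-normalised (observed/expected) Hi-C map.  Activity
  ranks are mapped to target radii, and a harmonic radial bias pulls each bead
  toward its target.

A soft-core repulsion gives the chains excluded volume, and (optionally)
pairwise harmonic restraints with targets d_ij = c * f_ij^(-1/alpha) tie the
structure to the contact frequencies f_ij directly.  The potential is relaxed
from a random confined initialisation by annealed, noise-injected gradient
descent ("overdamped Langevin" style); the best-energy snapshot is returned.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ContactMatrix",
    "ActivityProfile",
    "GenomeStructure",
    "ReconstructionConfig",
    "compartment_degree",
    "assign_radial_targets",
    "reconstruct",
    "bead_lookup",
    "read_contact_maps",
    "write_contact_maps",
    "read_dense_matrix",
    "read_structure",
    "write_structure",
]

DEFAULT_BIN_SIZE = 500_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C contact counts for one chromosome."""

    chromosome: str
    bin_size_bp: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.counts.shape[0] < 2:
            raise ValueError("contact matrix needs at least 2 bins")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError(f"contact matrix for {self.chromosome} is not symmetric")
        if (self.counts < 0).any():
            raise ValueError("contact counts must be non-negative")
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class ActivityProfile:
    """Per-bin compartment-degree activity and derived radial targets."""

    chromosome: str
    activity: np.ndarray
    radial_target: np.ndarray | None = None

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.radial_target is not None:
            self.radial_target = np.asarray(self.radial_target, dtype=float)
            if self.radial_target.shape != self.activity.shape:
                raise ValueError("radial_target length must match activity")


@dataclass
class GenomeStructure:
    """Per-bead 3D coordinates: one chain per chromosome, one bead per bin."""

    cell_line: str
    chains: dict  # chromosome -> (n, 3) float array, genomic order
    nucleus_radius: float
    bin_size_bp: int
    activities: dict | None = None  # chromosome -> (n,) activity, optional
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chains = {c: np.asarray(x, dtype=float) for c, x in self.chains.items()}
        for c, x in self.chains.items():
            if x.ndim != 2 or x.shape[1] != 3:
                raise ValueError(f"chain {c}: coordinates must be (n, 3)")

    @property
    def chromosomes(self) -> list:
        return list(self.chains)

    def n_beads(self, chromosome: str | None = None) -> int:
        if chromosome is not None:
            return self.chains[chromosome].shape[0]
        return sum(x.shape[0] for x in self.chains.values())

    def radii(self, chromosome: str) -> np.ndarray:
        return np.linalg.norm(self.chains[chromosome], axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, xyz in self.chains.items():
            r = np.linalg.norm(xyz, axis=1)
            act = None
            if self.activities and chrom in self.activities:
                act = np.asarray(self.activities[chrom], dtype=float)
            for i in range(xyz.shape[0]):
                rows.append(
                    {
                        "cell_line": self.cell_line,
                        "chromosome": chrom,
                        "bin_index": i,
                        "x": xyz[i, 0],
                        "y": xyz[i, 1],
                        "z": xyz[i, 2],
                        "radius": r[i],
                        "activity": act[i] if act is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def bead_lookup(structure: GenomeStructure, chromosome: str, bin_index: int):
    """Coordinates and radial position of one bead.

    Returns ``(x, y, z, radius)`` with ``radius = sqrt(x^2 + y^2 + z^2)``.
    """
    if chromosome not in structure.chains:
        raise KeyError(f"chromosome {chromosome!r} not in structure")
    xyz = structure.chains[chromosome]
    if not (0 <= bin_index < xyz.shape[0]):
        raise IndexError(
            f"bin {bin_index} out of range for {chromosome} (n={xyz.shape[0]})"
        )
    x, y, z = (float(v) for v in xyz[bin_index])
    return x, y, z, float(np.sqrt(x * x + y * y + z * z))


# ---------------------------------------------------------------------------
# compartment degree
# ---------------------------------------------------------------------------

def _observed_expected(counts: np.ndarray, min_obs: int = 3) -> np.ndarray:
    """Distance-decay normalisation: counts / mean(count at that separation).

    Diagonals with fewer than `min_obs` entries borrow the expectation of the
    nearest separation that has enough; the main diagonal is set to the
    neutral value 1 so it does not dominate the row correlations.
    """
    n = counts.shape[0]
    expected = np.empty(n)
    expected[0] = np.nan
    per_offset = []
    for k in range(1, n):
        diag = np.diagonal(counts, offset=k)
        per_offset.append((k, diag))
    populated = {k: diag.mean() for k, diag in per_offset if diag.size >= min_obs}
    for k, diag in per_offset:
        if k in populated:
            expected[k] = populated[k]
        elif populated:
            nearest = min(populated, key=lambda kk: (abs(kk - k), kk))
            expected[k] = populated[nearest]
        else:  # tiny matrix: no offset has min_obs entries, use own mean
            expected[k] = diag.mean()
    oe = np.ones_like(counts)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    off = sep > 0
    exp_mat = np.ones_like(counts)
    exp_mat[off] = expected[sep[off]]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp_mat > 0, counts / exp_mat, 0.0)
    oe[off] = ratio[off]
    return oe


def compartment_degree(matrix: ContactMatrix, marker: np.ndarray | None = None) -> ActivityProfile:
    """Per-bin chromatin activity from a Hi-C matrix.

    Pipeline: O/E normalisation by genomic-distance decay, Pearson correlation
    of the O/E rows, leading eigenvector of the correlation matrix.  The
    eigenvector's global sign is arbitrary; it is oriented so activity
    correlates positively with `marker` (e.g. gene density per bin) when
    given, otherwise so the mean activity of the top-decile row-sum bins is
    positive.

    Bins whose O/E rows have zero variance (typically unmappable/empty bins)
    are excluded from the correlation and assigned activity 0.
    """
    counts = matrix.counts
    if not np.any(counts):
        raise ValueError(f"all-zero contact matrix for {matrix.chromosome}")
    oe = _observed_expected(counts)
    off = ~np.eye(counts.shape[0], dtype=bool)  # variance judged off-diagonal
    keep = np.array([oe[i][off[i]].std() > 0 for i in range(counts.shape[0])])
    n = counts.shape[0]
    activity = np.zeros(n)
    if keep.sum() >= 2:
        sub = oe[np.ix_(keep, keep)]
        corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=0.0)
        w, v = np.linalg.eigh(corr)
        lead = v[:, np.argmax(w)]
        activity[keep] = lead
    # orient the arbitrary eigenvector sign
    if marker is not None:
        marker = np.asarray(marker, dtype=float)
        if marker.shape[0] != n:
            raise ValueError("marker track length must match bin count")
        dev = (activity - activity.mean()) @ (marker - marker.mean())
        if dev < 0:
            activity = -activity
        elif dev == 0:
            activity = _orient_by_rowsum(activity, counts)
    else:
        activity = _orient_by_rowsum(activity, counts)
    return ActivityProfile(chromosome=matrix.chromosome, activity=activity)


def _orient_by_rowsum(activity: np.ndarray, counts: np.ndarray) -> np.ndarray:
    rowsum = counts.sum(axis=1)
    top = rowsum >= np.quantile(rowsum, 0.9)
    m = activity[top].mean() if top.any() else 0.0
    if m < 0:
        return -activity
    if m == 0:
        nz = np.nonzero(activity)[0]
        if nz.size and activity[nz[0]] < 0:
            return -activity
    return activity


def assign_radial_targets(
    profile: ActivityProfile, nucleus_radius: float, min_radius_frac: float = 0.1
) -> ActivityProfile:
    """Map activity ranks to target radial positions.

    The most active bin is sent to ``R * min_radius_frac`` (near the centre),
    the least active to ``R``; in between the target decreases linearly with
    the fractional activity rank q in [0, 1] (ties share their mean rank):

        r_target(i) = R * (1 - q_i * (1 - min_radius_frac))
    """
    a = profile.activity
    n = a.size
    if n == 1:
        q = np.array([0.5])
    else:
        q = (rankdata(a, method="average") - 1.0) / (n - 1.0)
    target = nucleus_radius * (1.0 - q * (1.0 - min_radius_frac))
    return ActivityProfile(
        chromosome=profile.chromosome, activity=a.copy(), radial_target=target
    )


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionConfig:
    """Force-field and optimiser settings for structure reconstruction.

    Lengths are in normalised nuclear units (bond_length = 1 corresponds to
    one 500 kb bin step).  Defaults target a whole-genome run with nucleus
    radius ~10 bond lengths; all are configurable.
    """

    bond_length: float = 1.0
    k_bond: float = 100.0
    k_radial: float = 10.0
    k_repulsion: float = 1.0
    k_pair: float = 1.0
    repulsion_cutoff: float = 0.8
    n_steps: int = 5000
    step_size: float = 1e-3
    noise_scale: float = 0.05  # initial Langevin noise, in bond lengths
    n_checkpoints: int = 50
    tol: float = 1e-4
    seed: int = 0
    use_pairwise_restraints: bool = False
    alpha: float = 1.0

    def __post_init__(self):
        for name in ("k_bond", "k_radial", "k_repulsion", "k_pair"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def _pairwise_targets(matrices, offsets, n_total, config):
    """Target distance matrix c * f^(-1/alpha) (NaN where no restraint)."""
    T = np.full((n_total, n_total), np.nan)
    adj_scale = []
    for cm, off in zip(matrices, offsets):
        f = cm.counts
        nz = f > 0
        np.fill_diagonal(nz, False)
        with np.errstate(divide="ignore"):
            d = np.where(nz, f, np.nan) ** (-1.0 / config.alpha)
        n = cm.n_bins
        T[off : off + n, off : off + n] = d
        adj = np.diagonal(f, offset=1)
        adj_scale.extend(adj[adj > 0] ** (-1.0 / config.alpha))
    if not adj_scale:
        raise ValueError("pairwise restraints requested but no bonded contacts observed")
    c = config.bond_length / np.median(adj_scale)
    return c * T


def reconstruct(
    matrices: list,
    profiles: list,
    config: ReconstructionConfig | None = None,
    nucleus_radius: float = 10.0,
    cell_line: str = "model",
) -> GenomeStructure:
    """Reconstruct a whole-genome bead-on-a-string structure.

    Minimises

        U = sum_bonds k_bond (|d| - b)^2
          + sum_beads k_radial (r_i - r_target_i)^2
          + sum_{d_ij < cutoff} k_repulsion (cutoff - d_ij)^2
          + [optional] sum_ij k_pair (d_ij - c f_ij^(-1/alpha))^2

    by annealed gradient descent from a random confined initialisation.
    Deterministic given ``config.seed``.  The returned structure carries
    ``diagnostics`` with final energy terms, the best-energy history at
    checkpoints, and a ``converged`` flag (False if the energy was still
    changing by more than ``tol`` relative at the end).
    """
    if config is None:
        config = ReconstructionConfig()
    if len(matrices) != len(profiles):
        raise ValueError("need exactly one activity profile per contact matrix")
    for cm, pr in zip(matrices, profiles):
        if cm.chromosome != pr.chromosome:
            raise ValueError("matrix/profile chromosome order mismatch")
        if cm.n_bins != pr.activity.size:
            raise ValueError(f"bin count mismatch on {cm.chromosome}")

    chroms = [cm.chromosome for cm in matrices]
    sizes = [cm.n_bins for cm in matrices]
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    n = int(np.sum(sizes))

    # radial targets (fill from activity if the caller did not)
    targets = []
    for pr in profiles:
        if pr.radial_target is None:
            pr = assign_radial_targets(pr, nucleus_radius)
        targets.append(pr.radial_target)
    t_rad = np.concatenate(targets)

    # bonded pairs: consecutive beads within each chain
    bond_i = np.concatenate(
        [off + np.arange(sz - 1) for off, sz in zip(offsets, sizes)]
    ).astype(int)
    bond_j = bond_i + 1
    bonded = np.zeros((n, n), dtype=bool)
    bonded[bond_i, bond_j] = bonded[bond_j, bond_i] = True

    pair_T = None
    if config.use_pairwise_restraints:
        pair_T = _pairwise_targets(matrices, offsets, n, config)
        has_pair = np.isfinite(pair_T)
    rep_allowed = ~bonded
    np.fill_diagonal(rep_allowed, False)

    rng = np.random.default_rng(config.seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    X = u * (0.8 * nucleus_radius) * rng.random(n)[:, None] ** (1.0 / 3.0)

    b = config.bond_length
    cut = config.repulsion_cutoff
    max_disp = 0.1 * b
    cp_every = max(1, config.n_steps // config.n_checkpoints)
    noise_floor_step = int(0.8 * config.n_steps)  # final 20%: pure descent

    def energy(X):
        diff = X[:, None, :] - X[None, :, :]
        D = np.linalg.norm(diff, axis=-1)
        db = D[bond_i, bond_j]
        e_bond = config.k_bond * np.sum((db - b) ** 2)
        r = np.linalg.norm(X, axis=1)
        e_rad = config.k_radial * np.sum((r - t_rad) ** 2)
        close = (D < cut) & rep_allowed
        e_rep = 0.5 * config.k_repulsion * np.sum((cut - D[close]) ** 2)
        e_pair = 0.0
        if pair_T is not None:
            m = has_pair
            e_pair = 0.5 * config.k_pair * np.sum((D[m] - pair_T[m]) ** 2)
        return {
            "bond": float(e_bond),
            "radial": float(e_rad),
            "repulsion": float(e_rep),
            "pairwise": float(e_pair),
            "total": float(e_bond + e_rad + e_rep + e_pair),
        }

    best_E = np.inf
    best_X = X.copy()
    best_history = []
    energy_history = []
    eps = 1e-12

    for step in range(config.n_steps):
        diff = X[:, None, :] - X[None, :, :]
        D = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(D, np.inf)
        C = np.zeros((n, n))
        # bonds
        db = D[bond_i, bond_j]
        cb = 2.0 * config.k_bond * (db - b) / np.maximum(db, eps)
        C[bond_i, bond_j] = cb
        C[bond_j, bond_i] = cb
        # soft-core repulsion (each unordered pair counted once in U)
        close = (D < cut) & rep_allowed
        C[close] += -2.0 * config.k_repulsion * (cut - D[close]) / np.maximum(D[close], eps)
        # optional pairwise Hi-C restraints
        if pair_T is not None:
            m = has_pair
            C[m] += 2.0 * config.k_pair * (D[m] - pair_T[m]) / np.maximum(D[m], eps)
        grad = np.einsum("ij,ijk->ik", C, diff)
        # radial bias
        r = np.linalg.norm(X, axis=1)
        grad += 2.0 * config.k_radial * ((r - t_rad) / np.maximum(r, eps))[:, None] * X

        disp = -config.step_size * grad
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        scale = np.minimum(1.0, max_disp / np.maximum(norms, eps))
        X = X + disp * scale
        if step < noise_floor_step and config.noise_scale > 0:
            sigma = config.noise_scale * b * np.exp(-5.0 * step / max(1, noise_floor_step))
            X = X + rng.normal(0.0, sigma, size=X.shape)

        if (step + 1) % cp_every == 0 or step == config.n_steps - 1:
            terms = energy(X)
            energy_history.append(terms["total"])
            if terms["total"] < best_E:
                best_E = terms["total"]
                best_X = X.copy()
            best_history.append(best_E)

    final_terms = energy(best_X)
    converged = True
    if len(energy_history) >= 2:
        e1, e0 = energy_history[-1], energy_history[-2]
        converged = abs(e1 - e0) <= config.tol * max(abs(e1), 1.0)

    chains = {
        c: best_X[off : off + sz] for c, off, sz in zip(chroms, offsets, sizes)
    }
    activities = {pr.chromosome: pr.activity for pr in profiles}
    return GenomeStructure(
        cell_line=cell_line,
        chains=chains,
        nucleus_radius=nucleus_radius,
        bin_size_bp=matrices[0].bin_size_bp,
        activities=activities,
        diagnostics={
            "energy": final_terms,
            "best_history": best_history,
            "energy_history": energy_history,
            "converged": converged,
            "config": dataclasses.asdict(config),
        },
    )


# ---------------------------------------------------------------------------
# I/O: COO contact maps, dense matrices, structure tables
# ---------------------------------------------------------------------------

def write_contact_maps(matrices, path):
    """Write contact maps as COO TSV (chromosome, bin_i, bin_j, count), i <= j."""
    rows = []
    for cm in matrices:
        iu, ju = np.triu_indices(cm.n_bins, k=0)
        cnt = cm.counts[iu, ju]
        nz = cnt > 0
        for i, j, c in zip(iu[nz], ju[nz], cnt[nz]):
            rows.append((cm.chromosome, int(i), int(j), c))
    df = pd.DataFrame(rows, columns=["chromosome", "bin_i", "bin_j", "count"])
    df.to_csv(path, sep="\t", index=False)


def read_contact_maps(path, bin_size_bp: int = DEFAULT_BIN_SIZE) -> list:
    """Read COO TSV contact maps; symmetrises and zero-fills missing bins."""
    df = pd.read_csv(path, sep="\t")
    required = {"chromosome", "bin_i", "bin_j", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"contact map file {path} missing columns {required - set(df.columns)}")
    out = []
    for chrom, sub in df.groupby("chromosome", sort=False):
        n = int(max(sub.bin_i.max(), sub.bin_j.max())) + 1
        m = np.zeros((n, n))
        m[sub.bin_i, sub.bin_j] = sub["count"]
        m = np.maximum(m, m.T)
        out.append(ContactMatrix(chromosome=str(chrom), bin_size_bp=bin_size_bp, counts=m))
    return out


def read_dense_matrix(path, chromosome: str, bin_size_bp: int = DEFAULT_BIN_SIZE) -> ContactMatrix:
    """Read one whitespace-separated dense matrix as a ContactMatrix."""
    m = np.loadtxt(path)
    return ContactMatrix(chromosome=chromosome, bin_size_bp=bin_size_bp, counts=m)


def write_structure(structure: GenomeStructure, path):
    df = structure.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_structure(
    path, nucleus_radius: float, bin_size_bp: int = DEFAULT_BIN_SIZE
) -> GenomeStructure:
    df = pd.read_csv(path, sep="\t")
    cell = str(df.cell_line.iloc[0])
    chains, acts = {}, {}
    for chrom, sub in df.groupby("chromosome", sort=False):
        sub = sub.sort_values("bin_index")
        chains[str(chrom)] = sub[["x", "y", "z"]].to_numpy()
        acts[str(chrom)] = sub["activity"].to_numpy()
    return GenomeStructure(
        cell_line=cell,
        chains=chains,
        nucleus_radius=nucleus_radius,
        bin_size_bp=bin_size_bp,
        activities=acts,
    )
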