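"""End-to-end pipeline orchestration.

Stages: curate -> map -> compartments -> reconstruct (per cell line) ->
featurize (per baseline mode) -> evaluate.  A master seed deterministically
derives per-stage seeds; a manifest records per-stage row counts, seeds and
content hashes of every output file, so two runs with the same configuration
and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, curation, evaluation, features, mapping, synthetic
from .baseline import DEFAULT_SCORER
from .chromatin import ReconstructionConfig

log = logging.getLogger("neo3d")

__all__ = ["RunConfig", "run", "simulate", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    assays: str
    fasta: str
    bed: str
    contact_maps: dict  # cell_line -> COO TSV path (exactly two)
    baseline_scores: dict = field(default_factory=dict)  # mode -> path
    baseline_modes: tuple = ("surrogate",)
    bin_size_bp: int = 500_000
    nucleus_radius: float = 10.0
    curation: curation.CurationConfig = field(default_factory=curation.CurationConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    cv_kinds: tuple = ("kfold",)
    n_folds: int = 5
    n_repeats: int = 100
    knn_k: int = 8
    dataset: str = "full"  # full | known_allele
    master_seed: int = 0

    def validate(self):
        for name in ("assays", "fasta", "bed"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"config field '{name}': missing file {getattr(self, name)}")
        if len(self.contact_maps) != 2:
            raise ValueError("config field 'contact_maps': exactly two cell lines required")
        for cell, path in self.contact_maps.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"config field 'contact_maps.{cell}': missing file {path}")
        for mode in self.baseline_modes:
            if mode != "surrogate" and mode not in self.baseline_scores:
                raise ValueError(f"baseline mode {mode!r} has no score table in 'baseline_scores'")
        for mode, path in self.baseline_scores.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"config field 'baseline_scores.{mode}': missing file {path}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cur = curation.CurationConfig(**raw.pop("curation", {}))
    rec = ReconstructionConfig(**raw.pop("reconstruction", {}))
    for key in ("baseline_modes", "cv_kinds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(curation=cur, reconstruction=rec, **raw)


def _stage_seeds(master_seed: int, n: int) -> list:
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed, 8)
    manifest = {
        "config": _config_dict(config),
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "stages": {},
        "outputs": {},
    }

    def record(stage, t0, **counts):
        manifest["stages"][stage] = {
            "status": "completed",
            "seconds": round(time.time() - t0, 3),
            **counts,
        }
        log.info("stage %s done: %s", stage, counts)

    try:
        # --- curate ---------------------------------------------------
        t0 = time.time()
        records = curation.read_assay_records(config.assays)
        cur = curation.curate(records, config.curation)
        curated = cur.full if config.dataset == "full" else cur.known_allele
        curation.write_curated(cur.full, outdir / "curated_full.tsv")
        curation.write_curated(cur.known_allele, outdir / "curated_known_allele.tsv")
        (outdir / "curation_report.txt").write_text(cur.report_text() + "\n")
        record("curate", t0, n_curated=len(curated), **{k: v for k, v in cur.report.items()})

        # --- map ------------------------------------------------------
        t0 = time.time()
        annotation = mapping.load_annotation(config.fasta, config.bed)
        mapped, n_unmapped = mapping.map_peptides(curated, annotation, config.bin_size_bp)
        mapped.to_csv(outdir / "mapped.tsv", sep="\t", index=False)
        record("map", t0, n_mapped=len(mapped), n_unmapped=n_unmapped)

        # --- compartments --------------------------------------------
        t0 = time.time()
        maps = {
            cell: chromatin.read_contact_maps(path, config.bin_size_bp)
            for cell, path in config.contact_maps.items()
        }
        profiles = {}
        gene_bed = pd.read_csv(
            config.bed, sep="\t", header=None,
            names=["chromosome", "start_bp", "end_bp", "gene_id"], usecols=range(4),
        )
        for cell, cms in maps.items():
            profs = []
            for cm in cms:
                marker = synthetic.gene_density(
                    gene_bed, cm.chromosome, cm.n_bins, config.bin_size_bp
                )
                prof = chromatin.compartment_degree(cm, marker=marker)
                profs.append(
                    chromatin.assign_radial_targets(prof, config.nucleus_radius)
                )
            profiles[cell] = profs
        n_bins = sum(cm.n_bins for cms in maps.values() for cm in cms)
        record("compartments", t0, n_bins=n_bins)

        # --- reconstruct ---------------------------------------------
        t0 = time.time()
        structures = []
        for i, (cell, cms) in enumerate(maps.items()):
            rc = dataclasses.replace(config.reconstruction, seed=seeds[2 + i])
            st = chromatin.reconstruct(
                cms,
                profiles[cell],
                rc,
                nucleus_radius=config.nucleus_radius,
                cell_line=cell,
            )
            chromatin.write_structure(st, outdir / f"structure_{cell}.tsv")
            structures.append(st)
        record(
            "reconstruct",
            t0,
            n_structures=len(structures),
            converged=[bool(s.diagnostics["converged"]) for s in structures],
        )

        # --- featurize ------------------------------------------------
        t0 = time.time()
        tables = {}
        for mode in config.baseline_modes:
            if mode == "surrogate":
                pairs = list(zip(mapped["peptide"], mapped["allele"]))
                score_table = features.scores_from_function(pairs, DEFAULT_SCORER.score)
            else:
                score_table = features.load_baseline_scores(config.baseline_scores[mode], mode)
            ft = features.assemble(mapped, structures, score_table)
            ft.to_tsv(outdir / f"features_{mode}.tsv")
            tables[mode] = ft
        record(
            "featurize",
            t0,
            n_rows={m: len(t.frame) for m, t in tables.items()},
            dropped={m: t.dropped for m, t in tables.items()},
        )

        # --- evaluate -------------------------------------------------
        t0 = time.time()
        all_metrics = []
        all_deltas = []
        for mode, ft in tables.items():
            for kind in config.cv_kinds:
                scheme = evaluation.CVScheme(
                    kind=kind,
                    n_folds=config.n_folds,
                    n_repeats=config.n_repeats,
                    seed=seeds[5],
                )
                rep = evaluation.evaluate_methods(
                    ft,
                    scheme,
                    baseline_name=f"baseline-{mode}",
                    setting=f"{mode},{kind}",
                    clf_seed=seeds[6],
                    knn_k=config.knn_k,
                )
                all_metrics.append(rep.metrics)
                all_deltas.append(evaluation.compare(ft.X[:, 0], ft.y, [rep]))
        metrics = pd.concat(all_metrics, ignore_index=True)
        metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format="%.6g")
        deltas = pd.concat(all_deltas, ignore_index=True)
        deltas.to_csv(outdir / "deltas.tsv", sep="\t", index=False, float_format="%.6g")
        record("evaluate", t0, n_settings=len(all_metrics))
    except Exception as exc:
        stage = len(manifest["stages"])
        names = ["curate", "map", "compartments", "reconstruct", "featurize", "evaluate"]
        failed = names[stage] if stage < len(names) else "unknown"
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.txt")):
        manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["contact_maps"] = {k: str(v) for k, v in config.contact_maps.items()}
    d["baseline_scores"] = {k: str(v) for k, v in config.baseline_scores.items()}
    return d


def simulate(
    outdir,
    n_chains: int = 3,
    beads_per_chain: int = 30,
    n_genes: int = 120,
    n_peptides: int = 300,
    b0: float = 0.0,
    b_base: float = 2.0,
    b_rad: float = -2.0,
    assays_per_peptide: int = 10,
    nucleus_radius: float = 6.0,
    seed: int = 0,
) -> RunConfig:
    """Generate a synthetic input bundle and a ready-to-run configuration."""
    world = synthetic.build_world(
        n_chains=n_chains,
        beads_per_chain=beads_per_chain,
        n_genes=n_genes,
        n_peptides=n_peptides,
        effect_params=synthetic.EffectParams(b0=b0, b_base=b_base, b_rad=b_rad),
        assays_per_peptide=assays_per_peptide,
        nucleus_radius=nucleus_radius,
        seed=seed,
    )
    paths = synthetic.write_bundle(world, outdir)
    cells = list(world.structures)
    return RunConfig(
        assays=str(paths["assays"]),
        fasta=str(paths["proteins_fasta"]),
        bed=str(paths["genes_bed"]),
        contact_maps={c: str(paths[f"contacts_{c}"]) for c in cells},
        baseline_scores={
            "BA": str(paths["baseline_BA"]),
            "EL": str(paths["baseline_EL"]),
        },
        bin_size_bp=world.bin_size_bp,
        nucleus_radius=nucleus_radius,
        master_seed=seed,
    )
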