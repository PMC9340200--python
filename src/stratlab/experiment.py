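"""End-to-end orchestration of the discovery/target/panel study design.

One run simulates a structured multi-population cohort, applies variant QC,
builds the four external PC spaces (cohort-specific for each target cohort,
all-reference, European-like, non-European-like), projects the discovery and
target cohorts onto them, runs the five GWAS versions (no-PC control plus
four PC adjustments) on the discovery cohort, constructs the five clumped and
thresholded polygenic scores per target cohort, fits both 25-cell validation
grids per trait, and produces the six-model variance decompositions — writing
every table plus a provenance manifest to the run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix
from .decomposition import run_decomposition
from .gwas import run_gwas
from .pc_space import make_pc_sets
from .prs import (
    ClumpSpec,
    THRESHOLD_GRID,
    clump,
    select_best_threshold,
    unit_norm_dosages,
)
from .synthetic_cohorts import (
    TraitModel,
    emulation_pop_sizes,
    paper_emulation_preset,
    simulate_covariates,
    simulate_genotypes,
    simulate_trait,
    split_cohorts,
)
from .validation import run_grid
from .variant_qc import filter_variants

logger = logging.getLogger(__name__)


def _package_version() -> str:
    from stratlab import __version__

    return __version__

#: grid row/column naming: internal panel key -> public label suffix
_PANEL_LABEL = {
    "cohort": "cohort",
    "all_reference": "allref",
    "panel_european": "EURlike",
    "panel_non_european": "NEURlike",
}


@dataclass
class ExperimentConfig:
    """Complete, serializable description of one experiment run."""

    seed: int = 1
    scale: float = 0.5
    discovery_n: int = 8000
    n_variants: int = 20000
    n_causal: int = 2000
    k_pcs: int = 20
    height_heritability: float = 0.4
    height_structure: float = 0.08
    bmi_heritability: float = 0.3
    bmi_structure: float = 0.005
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.5, "batch": 0.1}
    )
    clump_r2: float = 0.05
    clump_kb: float = 1000.0
    threshold_grid: tuple = THRESHOLD_GRID
    out_dir: str = "runs/run"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["threshold_grid"] = list(d["threshold_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["threshold_grid"] = tuple(d["threshold_grid"])
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["threshold_grid"] = list(d["threshold_grid"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ExperimentResult:
    """In-memory handles to everything one run computed."""

    config: ExperimentConfig
    out_dir: Path
    lambdas: pd.DataFrame
    grids: dict            # (cohort, trait) -> GridResult
    decompositions: dict   # (cohort, trait, prs_label) -> DecompositionResult
    qc_report: object
    thresholds: dict       # (cohort, trait, prs_label) -> chosen threshold


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"experiment stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full study design; returns in-memory results.

    Fully deterministic under the config's seed: per-stage seeds are small
    fixed offsets from it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    # ---- simulate ----------------------------------------------------- #
    model, sizes, populations = paper_emulation_preset(
        scale=config.scale,
        discovery_n=config.discovery_n,
        n_variants=config.n_variants,
    )
    pop_sizes = emulation_pop_sizes(sizes, populations)
    n_per_pop = [pop_sizes.get(lbl, 30) for lbl in model.pop_labels]
    geno = _stage("simulate_genotypes")(simulate_genotypes)(model, n_per_pop, seed)
    samples = _stage("simulate_covariates")(simulate_covariates)(
        geno, model, seed + 1
    )

    trait_models = {
        "height_like": TraitModel(
            heritability=config.height_heritability,
            n_causal=config.n_causal,
            structure_effect=config.height_structure,
            covariate_effects=config.covariate_effects,
            name="height_like",
        ),
        "bmi_like": TraitModel(
            heritability=config.bmi_heritability,
            n_causal=config.n_causal,
            structure_effect=config.bmi_structure,
            covariate_effects=config.covariate_effects,
            name="bmi_like",
        ),
    }
    traits, truths = {}, {}
    for i, (tname, tmodel) in enumerate(trait_models.items()):
        traits[tname], truths[tname] = _stage(f"simulate_trait:{tname}")(
            simulate_trait
        )(geno, samples, tmodel, seed + 10 + i)

    pheno = samples.copy()
    for tname in traits:
        pheno[f"trait_{tname}"] = traits[tname]
    _write_tsv(pheno, out / "pheno.tsv")
    for tname, truth in truths.items():
        _write_tsv(
            pd.DataFrame(
                {"variant_id": truth["causal_variant_ids"], "beta": truth["betas"]}
            ),
            out / f"truth_{tname}.tsv",
        )

    # ---- split -------------------------------------------------------- #
    split = _stage("split_cohorts")(split_cohorts)(
        samples, sizes, seed + 20, populations
    )
    split.external_panels["all_reference"] = np.sort(
        np.concatenate(
            [
                split.external_panels["panel_european"],
                split.external_panels["panel_non_european"],
            ]
        )
    )
    split.validate_disjoint()

    # ---- QC ----------------------------------------------------------- #
    geno, qc_report = _stage("variant_qc")(filter_variants)(geno)
    _write_tsv(qc_report.to_frame(), out / "qc_report.tsv")

    pos = {s: i for i, s in enumerate(geno.sample_ids)}

    def take(ids):
        idx = [pos[s] for s in ids]
        sub = geno.take_samples(ids)
        return sub, samples.iloc[idx].reset_index(drop=True)

    discovery, disc_samples = take(split.discovery_ids)
    cohorts_geno = {"discovery": discovery}
    cohort_samples = {"discovery": disc_samples}
    for cname, ids in (
        ("target_same", split.target_same_ids),
        ("target_other", split.target_other_ids),
    ):
        cohorts_geno[cname], cohort_samples[cname] = take(ids)

    panels = {
        key: geno.take_samples(split.external_panels[key])
        for key in (
            "panel_cohort_same",
            "panel_cohort_other",
            "all_reference",
            "panel_european",
            "panel_non_european",
        )
    }

    # ---- PC spaces + projections -------------------------------------- #
    spaces, coords = _stage("pc_spaces")(make_pc_sets)(
        cohorts_geno, panels, k=config.k_pcs
    )
    for cname in coords:
        for pname, cc in coords[cname].items():
            _write_tsv(cc.to_frame(), out / f"pcs_{cname}_{pname}.tsv")

    # ---- GWAS (5 versions per trait) ----------------------------------- #
    # cohort-specific space for the discovery cohort = its own cohort's panel
    gwas_pc_options = {
        "PRS_0": None,
        "PRS_cohort": coords["discovery"]["panel_cohort_same"],
        "PRS_allref": coords["discovery"]["all_reference"],
        "PRS_EURlike": coords["discovery"]["panel_european"],
        "PRS_NEURlike": coords["discovery"]["panel_non_european"],
    }
    disc_idx = [pos[s] for s in split.discovery_ids]
    all_stats: dict[tuple[str, str], object] = {}
    lam_rows = []
    for tname, trait_vec in traits.items():
        tv = np.asarray(trait_vec)[disc_idx]
        for label, pcset in gwas_pc_options.items():
            ss = _stage(f"gwas:{tname}:{label}")(run_gwas)(
                discovery, tv, disc_samples, pcset,
                n_pcs=config.k_pcs, pc_set_label=label,
            )
            all_stats[(tname, label)] = ss
            ss.to_tsv(out / f"gwas_{tname}_{label}.tsv")
            lam_rows.append(
                {"trait": tname, "gwas": label, "lambda_gc": ss.lambda_gc}
            )
    lambdas = pd.DataFrame(lam_rows)
    _write_tsv(lambdas, out / "lambda.tsv")

    # ---- PRS + validation grids + decomposition ------------------------ #
    clump_spec = ClumpSpec(r2_max=config.clump_r2, window_kb=config.clump_kb)
    grids, decomps, thresholds = {}, {}, {}
    for cname in ("target_same", "target_other"):
        tgt_geno = cohorts_geno[cname]
        tgt_samples = cohort_samples[cname]
        cohort_panel = (
            "panel_cohort_same" if cname == "target_same" else "panel_cohort_other"
        )
        pc_sets = {
            "PC_cohort": coords[cname][cohort_panel],
            "PC_allref": coords[cname]["all_reference"],
            "PC_EURlike": coords[cname]["panel_european"],
            "PC_NEURlike": coords[cname]["panel_non_european"],
        }
        tgt_idx = [pos[s] for s in tgt_geno.sample_ids]
        z_ref = unit_norm_dosages(tgt_geno)  # shared across the 10 clump runs
        for tname in traits:
            tv = np.asarray(traits[tname])[tgt_idx]
            profiles = {}
            for label in gwas_pc_options:
                ss = all_stats[(tname, label)]
                clumped = _stage(f"clump:{cname}:{tname}:{label}")(clump)(
                    ss, tgt_geno, clump_spec, z_ref
                )
                profile = _stage(f"prs:{cname}:{tname}:{label}")(
                    select_best_threshold
                )(
                    tgt_geno, tv, tgt_samples, ss, clumped,
                    pc_covariates=None, grid=tuple(config.threshold_grid),
                    source_label=label,
                )
                profiles[label] = profile
                thresholds[(cname, tname, label)] = profile.chosen_threshold
                profile.to_files(out / f"prs_{cname}_{tname}_{label}")

            grid = _stage(f"grid:{cname}:{tname}")(run_grid)(
                tv, profiles, tgt_samples, pc_sets, n_pcs=config.k_pcs
            )
            grids[(cname, tname)] = grid
            _write_tsv(grid.delta_bic, out / f"grid_deltabic_{cname}_{tname}.tsv",
                       index=True)
            _write_tsv(grid.added_r2, out / f"grid_addedr2_{cname}_{tname}.tsv",
                       index=True)

            dec_rows = []
            for label, profile in profiles.items():
                dec = _stage(f"decomposition:{cname}:{tname}:{label}")(
                    run_decomposition
                )(tv, profile, pc_sets["PC_cohort"], tgt_samples,
                  n_pcs=config.k_pcs)
                decomps[(cname, tname, label)] = dec
                t = dec.table.copy()
                t.insert(0, "prs", label)
                dec_rows.append(t)
            _write_tsv(pd.concat(dec_rows, ignore_index=True),
                       out / f"decomposition_{cname}_{tname}.tsv")

    # ---- manifest ------------------------------------------------------ #
    manifest = {
        "config": {**dataclasses.asdict(config),
                   "threshold_grid": list(config.threshold_grid)},
        "config_digest": config.digest(),
        "seed": seed,
        "stratlab_version": _package_version(),
        "best_cells": {
            f"{c}:{t}": list(g.best_cell) for (c, t), g in grids.items()
        },
        "chosen_thresholds": {
            f"{c}:{t}:{p}": thr for (c, t, p), thr in thresholds.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")

    return ExperimentResult(
        config=config,
        out_dir=out,
        lambdas=lambdas,
        grids=grids,
        decompositions=decomps,
        qc_report=qc_report,
        thresholds=thresholds,
    )
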