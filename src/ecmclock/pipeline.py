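"""End-to-end pipeline: simulate → signature → trajectories → matreotype →
clocks → parabiosis, from a single seeded configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import write_annotation
from .clocks import (
    correct_age_gap,
    fit_stable_clock,
    predict_age,
    run_clock_ensemble,
    run_random_clocks,
    stability_selection,
)
from .cohort import write_cohort
from .cross_species import parabiosis_rejuvenation_analysis, shared_age_associations
from .matreotype import (
    chapter_ecm_enrichment,
    composition_test,
    derive_disease_matreotype,
)
from .signature import fit_age_associations, replicated_aging_matreotype
from .simulate import (
    default_mouse_config,
    generate_annotation,
    generate_human_cohort,
    generate_mouse_parabiosis_cohort,
    generate_phenotype_associations,
    scaled_human_config,
)
from .tables import write_phenotype_associations
from .trajectories import (
    cluster_matrisome_enrichment,
    cluster_trajectories,
    smooth_trajectories,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds with their standard defaults."""

    seed: int = 0
    alpha: float = 0.05
    association_alpha: float = 1e-5
    min_phenotypes: int = 10
    percentile: float = 0.5
    selection_threshold: float = 0.5
    cut_height: float = 5.0
    n_permutations: int = 10_000
    train_size: int = 100
    n_samples: int = 150
    n_proteins: int = 2000
    shift_young: float = 5.0
    shift_old: float = -5.0
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        defaults = cls()
        for key, value in raw.items():
            if getattr(defaults, key) != value:
                logger.info("config override: %s = %r", key, value)
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (independent of stage order)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": dataclasses.asdict(config), "stages": {}}

    def record(stage: str, **info):
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage), **info}

    try:
        # -- simulate --------------------------------------------------
        sim_seed = stage_seed(config.seed, "simulate")
        cfg_a = scaled_human_config(sim_seed, n_samples=config.n_samples,
                                    n_proteins=config.n_proteins,
                                    **config.simulation)
        annotation = generate_annotation(cfg_a)
        cohort_a, truth = generate_human_cohort(cfg_a, annotation, name="cohort_a")
        cfg_b = dataclasses.replace(cfg_a, seed=sim_seed + 1, age_range=(16.0, 66.0),
                                    n_samples=max(config.n_samples, 2 * config.train_size))
        cohort_b, _ = generate_human_cohort(cfg_b, annotation, truth=truth, name="cohort_b")
        mouse_cfg = default_mouse_config(sim_seed + 2)
        mouse, _ = generate_mouse_parabiosis_cohort(
            mouse_cfg, shift_young=config.shift_young, shift_old=config.shift_old)
        assoc = generate_phenotype_associations(
            annotation, seed=sim_seed + 3, association_alpha=config.association_alpha)

        write_annotation(annotation, out / "annotation.tsv")
        write_cohort(cohort_a, out / "cohort_a_abundance.tsv", out / "cohort_a_meta.tsv")
        write_cohort(cohort_b, out / "cohort_b_abundance.tsv", out / "cohort_b_meta.tsv")
        write_cohort(mouse, out / "mouse_abundance.tsv", out / "mouse_meta.tsv")
        write_phenotype_associations(assoc, out / "phenotype_associations.tsv")
        truth.to_csv(out / "ground_truth.tsv", sep="\t")
        record("simulate", n_samples_a=cohort_a.n_samples, n_samples_b=cohort_b.n_samples,
               n_proteins=cohort_a.n_proteins)

        # -- signature -------------------------------------------------
        tab_a = fit_age_associations(cohort_a, covariates=("sex", "bmi"), log2=True)
        tab_b = fit_age_associations(cohort_b, covariates=("sex", "bmi"), log2=True)
        tab_a.to_csv(out / "age_associations_a.tsv", sep="\t")
        tab_b.to_csv(out / "age_associations_b.tsv", sep="\t")
        aging = replicated_aging_matreotype(
            tab_a.loc[tab_a.index.isin(annotation.index[annotation["division"] != "non_matrisome"])],
            tab_b.loc[tab_b.index.isin(annotation.index[annotation["division"] != "non_matrisome"])],
            alpha=config.alpha)
        (out / "aging_matreotype.txt").write_text("\n".join(aging.sorted_proteins()) + "\n")
        record("signature", n_aging_matreotype=len(aging))

        # -- trajectories ----------------------------------------------
        traj = smooth_trajectories(cohort_a)
        assignment = cluster_trajectories(traj, cut_height=config.cut_height)
        enrich = cluster_matrisome_enrichment(assignment, annotation)
        traj.curves.to_csv(out / "trajectory_curves.tsv", sep="\t")
        assignment.to_csv(out / "trajectory_clusters.tsv", sep="\t")
        enrich.to_csv(out / "cluster_matrisome_enrichment.tsv", sep="\t")
        record("trajectories", n_clusters=int(assignment.nunique()),
               n_enriched=int((enrich["q_value"] < config.alpha).sum()))

        # -- matreotype ------------------------------------------------
        disease = derive_disease_matreotype(
            assoc, annotation, min_phenotypes=config.min_phenotypes,
            percentile=config.percentile)
        chapters = chapter_ecm_enrichment(assoc, annotation)
        (out / "disease_matreotype.txt").write_text(
            "\n".join(disease.sorted_proteins()) + "\n")
        chapters.to_csv(out / "chapter_ecm_enrichment.tsv", sep="\t")
        comp_seed = stage_seed(config.seed, "matreotype")
        for sig, label in ((aging, "aging"), (disease, "disease")):
            if len(sig):
                comp = composition_test(sig, annotation, grouping="division",
                                        seed=comp_seed)
                comp.table.to_csv(out / f"composition_{label}.tsv", sep="\t")
        record("matreotype", n_disease_matreotype=len(disease),
               n_shared=len(set(aging.proteins) & set(disease.proteins)))

        # -- clocks ----------------------------------------------------
        clock_seed = stage_seed(config.seed, "clocks")
        ecm = run_clock_ensemble(cohort_a, annotation, mode="ecm",
                                 n_permutations=config.n_permutations,
                                 train_size=config.train_size, seed=clock_seed)
        unsup = run_clock_ensemble(cohort_a, annotation, mode="unsupervised",
                                   n_permutations=config.n_permutations,
                                   train_size=config.train_size, seed=clock_seed + 1)
        random_ens = run_random_clocks(cohort_a, ecm, seed=clock_seed + 2)
        stable_set = stability_selection(ecm, threshold=config.selection_threshold)
        ecm.selection_frequency_.to_csv(out / "ecm_selection_frequency.tsv", sep="\t")
        summary = pd.DataFrame({
            "mode": ["ecm", "unsupervised", "random"],
            "mean_test_r": [ecm.mean_test_r(), unsup.mean_test_r(),
                            random_ens.mean_test_r()],
        })
        summary.to_csv(out / "clock_summary.tsv", sep="\t", index=False)
        gaps = None
        if len(stable_set):
            stable = fit_stable_clock(cohort_a, stable_set.proteins, seed=clock_seed + 3)
            stable.save(out / "stable_clock.json")
            pred = predict_age(stable, cohort_b)
            gaps = correct_age_gap(pred, cohort_b.ages)
            gaps.samples.to_csv(out / "age_gaps_b.tsv", sep="\t")
        record("clocks", mean_r_ecm=ecm.mean_test_r(),
               mean_r_unsupervised=unsup.mean_test_r(),
               mean_r_random=random_ens.mean_test_r(),
               n_stable=len(stable_set))

        # -- parabiosis / cross-species --------------------------------
        para_seed = stage_seed(config.seed, "parabiosis")
        controls = mouse.subset(
            sample_ids=mouse.meta.index[mouse.meta["parabiosis_group"] == "control"],
            name="mouse_controls")
        mouse_annotation = generate_annotation(mouse_cfg)
        mouse_ens = run_clock_ensemble(
            controls, mouse_annotation, mode="ecm",
            n_permutations=min(config.n_permutations, 200),
            train_size=max(10, controls.n_samples // 2), seed=para_seed)
        para = parabiosis_rejuvenation_analysis(mouse, mouse_ens)
        para.contrasts.to_csv(out / "parabiosis_contrasts.tsv", sep="\t")
        para.delta_age.to_csv(out / "parabiosis_delta_age.tsv", sep="\t")
        mouse_tab = fit_age_associations(controls, covariates=("sex",), log2=True)
        shared_tab, r_xspecies, p_xspecies = shared_age_associations(tab_a, mouse_tab)
        shared_tab.to_csv(out / "cross_species_associations.tsv", sep="\t")
        record("parabiosis", n_shared_associations=int(shared_tab["shared"].sum()),
               effect_correlation=r_xspecies,
               **{f"delta_age_{g}": float(v) for g, v in para.group_means.items()})
    except Exception as exc:  # annotate which stage failed
        done = list(manifest["stages"])
        raise RuntimeError(
            f"pipeline aborted after stages {done}: {exc}"
        ) from exc

    manifest["inputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def verify_manifest(outdir) -> list[str]:
    """Return names of recorded files whose hashes no longer match."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    tampered = []
    for name, digest in manifest.get("inputs", {}).items():
        path = out / name
        if not path.exists() or _sha256(path) != digest:
            tampered.append(name)
            logger.warning("manifest hash mismatch: %s", name)
    return tampered
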