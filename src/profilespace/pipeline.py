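"""End-to-end orchestration: config, stage execution, and the run report.

A single master seed drives every stochastic stage; each stage derives an
independent child seed from (seed, stage name), so toggling one stage never
perturbs another's random stream.  The report records parameter echoes,
SHA-256 hashes and a manifest of every written file, plus headline statistics
(FDR-significant parcel counts per contrast, ANOVA F/p over subgroup effect
maps, reliability summaries), and is itself written as JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrasts as ct
from . import io as psio
from . import mpc as mpcmod
from . import spatial as sp
from . import synth
from .geometry import make_sphere_parcellation
from .profiles import MeasureTable, profile_measures

log = logging.getLogger("profilespace")

_STAGES = ("simulate", "profile", "gradient", "contrast", "reliability", "spatial")


@dataclass
class RunConfig:
    """Serializable pipeline configuration (unknown keys are rejected)."""

    seed: int = 0
    out_dir: str = "profilespace_out"
    # geometry
    n_vertices: int = 2000
    n_parcels: int = 100
    # cohort
    n_female: int = 297
    n_male: int = 250
    oc_fraction: float = 170 / 594
    missing_cycle_fraction: float = 140 / 424
    # planted effects
    n_depths: int = 12
    effect_parcels_fraction: float = 0.10
    effect_d_range: tuple[float, float] = (0.2, 0.5)
    skew_d: float = 0.0
    hormone_m: float = 0.0
    hormone_h_bins: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    hormone_h_oc: float = 0.0
    # reference maps
    n_genes: int = 25
    n_coupled: int = 5
    gene_coupling: float = 0.6
    # inference settings
    n_perm: int = 200
    n_splits: int = 100
    fdr_q: float = 0.05
    # stage toggles
    stages: tuple[str, ...] = _STAGES

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        cfg.stages = tuple(cfg.stages)
        cfg.effect_d_range = tuple(cfg.effect_d_range)
        cfg.hormone_h_bins = tuple(cfg.hormone_h_bins)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        d["effect_d_range"] = list(d["effect_d_range"])
        d["hormone_h_bins"] = list(d["hormone_h_bins"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def stage_seed(seed: int, stage: str) -> int:
    """Independent child seed for a named stage, below 2**31."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence((seed, idx)).generate_state(1)[0] % 2**31)


@dataclass
class RunReport:
    config: dict
    stages_run: list[str] = field(default_factory=list)
    files: dict = field(default_factory=dict)  # path -> sha256
    headline: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the toggled stages of simulate -> profiles -> mpc ->
    contrasts -> reliability -> spatial, writing all tables and the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))

    def record(path: Path):
        report.files[str(path)] = _sha256(path)

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s: start", stage)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                report.timings[stage] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", stage, exc)
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
                report.stages_run.append(stage)
                log.info("stage %s: done in %.2fs", stage, report.timings[stage])

        return _T()

    rng_truth = np.random.default_rng(stage_seed(config.seed, "simulate"))

    # --- simulate ----------------------------------------------------------
    with timed("simulate"):
        geom = make_sphere_parcellation(
            config.n_vertices, config.n_parcels,
            seed=stage_seed(config.seed, "simulate"),
        )
        cohort = synth.simulate_cohort(
            config.n_female, config.n_male,
            oc_fraction=config.oc_fraction,
            missing_cycle_fraction=config.missing_cycle_fraction,
            seed=stage_seed(config.seed, "simulate") + 1,
        )
        p = geom.n_parcels
        d_map = np.zeros(p)
        n_eff = int(round(config.effect_parcels_fraction * p))
        eff_idx = rng_truth.choice(p, size=n_eff, replace=False)
        lo, hi = config.effect_d_range
        d_map[eff_idx] = rng_truth.uniform(lo, hi, size=n_eff)
        effects = synth.GroundTruthEffects(
            mean_effect_map=d_map,
            skew_effect_map=np.where(d_map != 0, config.skew_d, 0.0),
            hormone_modulation=np.where(d_map != 0, config.hormone_m, 0.0),
            h_bins={"oc": config.hormone_h_oc, "bins": config.hormone_h_bins},
        )
        profiles = synth.simulate_profiles(
            geom, cohort, effects, n_depths=config.n_depths,
            seed=stage_seed(config.seed, "simulate") + 2,
        )
        refmaps = synth.simulate_reference_maps(
            geom, d_map, n_genes=config.n_genes, n_coupled=config.n_coupled,
            coupling=config.gene_coupling,
            seed=stage_seed(config.seed, "simulate") + 3,
        )
        psio.write_geometry(geom, out / "geometry.json")
        psio.write_cohort(cohort, out / "cohort.csv")
        psio.write_profiles(profiles, out / "profiles.npz")
        refmaps.gene_panel.to_csv(out / "gene_panel.tsv", sep="\t",
                                  index_label="parcel")
        np.savetxt(out / "true_effect_map.tsv", d_map, fmt="%.8g")
        for f in ("geometry.json", "cohort.csv", "profiles.npz",
                  "profiles.npz.json", "gene_panel.tsv", "true_effect_map.tsv"):
            record(out / f)

    measures: dict[str, MeasureTable] = {}

    # --- profile measures --------------------------------------------------
    if "profile" in config.stages:
        with timed("profile"):
            mean_t, skew_raw, skew_scaled = profile_measures(profiles)
            measures["mean"] = mean_t
            measures["skewness_scaled"] = skew_scaled
            psio.write_measure(mean_t, out / "measure_mean.tsv")
            psio.write_measure(skew_raw, out / "measure_skewness_raw.tsv")
            psio.write_measure(skew_scaled, out / "measure_skewness_scaled.tsv")
            for f in ("measure_mean.tsv", "measure_skewness_raw.tsv",
                      "measure_skewness_scaled.tsv"):
                record(out / f)

    # --- gradients ----------------------------------------------------------
    if "gradient" in config.stages and "mean" in measures:
        with timed("gradient"):
            grp_grad, g1, group_matrix = mpcmod.gradient_pipeline(profiles)
            measures["gradient1"] = MeasureTable(
                "gradient1",
                pd.DataFrame(g1, index=measures["mean"].values.index,
                             columns=measures["mean"].values.columns),
                scaling="per_subject_minmax",
            )
            psio.write_matrix(group_matrix.values, out / "mpc_group.tsv")
            pd.DataFrame(
                grp_grad.components,
                index=measures["mean"].values.columns,
                columns=[f"g{j + 1}" for j in
                         range(grp_grad.components.shape[1])],
            ).to_csv(out / "gradients_group.tsv", sep="\t",
                     index_label="parcel")
            psio.write_measure(measures["gradient1"], out / "measure_gradient1.tsv")
            for f in ("mpc_group.tsv", "gradients_group.tsv",
                      "measure_gradient1.tsv"):
                record(out / f)

    # --- contrasts ----------------------------------------------------------
    results_by_measure: dict[str, dict[str, ct.ContrastResult]] = {}
    if "contrast" in config.stages and measures:
        with timed("contrast"):
            groups = ct.assign_hormone_groups(cohort)
            sig_counts = {}
            for name, table in measures.items():
                res = ct.run_group_comparisons(
                    table.values, cohort, groups, q=config.fdr_q
                )
                results_by_measure[name] = res
                for cname, r in res.items():
                    fn = out / f"contrast_{name}_{cname}.tsv"
                    psio.write_contrast(r, fn)
                    record(fn)
                    record(Path(str(fn) + ".json"))
                    sig_counts[f"{name}:{cname}"] = int(r.fdr_mask.sum())
            report.headline["fdr_significant_parcels"] = sig_counts
            subgroup_d = {
                f"{g}_vs_males": results_by_measure["mean"][f"{g}_vs_males"].cohen_d
                for g in ct.SUBGROUPS
                if f"{g}_vs_males" in results_by_measure["mean"]
            }
            if len(subgroup_d) >= 2:
                f_stat, p_val, tukey = ct.effectsize_anova_tukey(subgroup_d)
                tukey.to_csv(out / "anova_tukey.tsv", sep="\t", index=False)
                record(out / "anova_tukey.tsv")
                report.headline["anova"] = {"F": f_stat, "p": p_val}

    # --- reliability --------------------------------------------------------
    if "reliability" in config.stages and measures:
        with timed("reliability"):
            rel = {}
            for name, table in measures.items():
                r = ct.split_half_reliability(
                    table.values, cohort, n_perm=config.n_splits,
                    seed=stage_seed(config.seed, "reliability"),
                )
                rel[name] = {"mean_r": r.mean, "ci": list(r.ci)}
            report.headline["split_half_reliability"] = rel

    # --- spatial ------------------------------------------------------------
    if "spatial" in config.stages and results_by_measure:
        with timed("spatial"):
            spins = sp.generate_spins(
                geom, config.n_perm, seed=stage_seed(config.seed, "spatial")
            )
            pheno = {
                name: res["all_females_vs_males"].t
                for name, res in results_by_measure.items()
            }
            gene_res = sp.per_gene_association(
                pheno, refmaps.gene_panel, spins, fdr_q=config.fdr_q
            )
            f_stat, f_p = sp.gene_set_ftest(
                pheno["mean"], refmaps.gene_panel, spins
            )
            decode = sp.contextual_decoding(
                pheno, refmaps.cortical_types, refmaps.artery_map,
                refmaps.vein_map, spins, fdr_q=config.fdr_q,
            )
            gene_res.per_gene.to_csv(out / "gene_associations.tsv", sep="\t",
                                     index=False)
            decode.to_csv(out / "contextual_decoding.tsv", sep="\t", index=False)
            record(out / "gene_associations.tsv")
            record(out / "contextual_decoding.tsv")
            report.headline["gene_set_F"] = {"F": f_stat, "p": f_p}
            report.headline["n_genes_flagged"] = int(
                gene_res.per_gene["q_sig"].sum()
            )

    report.to_json(out / "report.json")
    return report
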