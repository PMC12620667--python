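"""End-to-end orchestration: filter -> ploidy -> clones -> diversity/F_ST/
PCA -> GEA -> offset, with a manifest of per-stage counts.

The pipeline is a thin composition of the stage modules: running it equals
running each stage by hand with the same parameters. Sites with fewer than
``min_site_n`` samples are excluded from per-site diversity reporting but
retained everywhere else.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonality, gea, offset as offset_mod, ploidy, popgen
from .filtering import FilterConfig, run_filter_chain
from .vcfio import read_env_table, read_sample_table, read_vcf, write_genotype_table


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run (YAML-mappable)."""

    vcf: str
    sample_table: str
    env_table: str | None = None
    geo_distances: str | None = None  # TSV square matrix of site distances
    out_dir: str = "run_out"
    filter: FilterConfig = field(default_factory=FilterConfig)
    clone_threshold: float | None = None  # None = predict
    clone_fraction: float = 0.5
    linkage: str = "average"
    ploidy_min_allele_depth: int = 10
    ploidy_min_median_depth: float = 30.0
    ploidy_min_sites: int = 50
    ploidy_margin: float = 10.0
    gea_axes: int = 3
    gea_alpha: float = 0.01
    gea_r_threshold: float = 0.9
    offset_k: int = 4
    min_site_n: int = 5
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filter" in raw and isinstance(raw["filter"], dict):
            f = raw["filter"]
            if "site_mean_depth_range" in f:
                f["site_mean_depth_range"] = tuple(f["site_mean_depth_range"])
            raw["filter"] = FilterConfig(**f)
        return cls(**raw)

    def validate(self) -> None:
        for label, p in (("vcf", self.vcf), ("sample_table", self.sample_table)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} not found: {p}")
        if self.env_table is not None and not Path(self.env_table).exists():
            raise FileNotFoundError(f"env_table not found: {self.env_table}")
        if self.env_table is not None and self.geo_distances is None:
            raise ValueError(
                "GEA requires geo_distances (a site distance table) when an "
                "env_table is given"
            )
        if (
            self.geo_distances is not None
            and not Path(self.geo_distances).exists()
        ):
            raise FileNotFoundError(
                f"geo_distances not found: {self.geo_distances}"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest dict (also written as JSON).

    Aborts with the failing stage named; all randomness (rarefaction
    bootstrap) derives from ``config.seed``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {"seed": config.seed}}
    stage = "read_inputs"
    try:
        data = read_vcf(config.vcf)
        samples = read_sample_table(config.sample_table)
        manifest["input"] = {
            "n_samples": data.genotypes.n_samples,
            "n_raw_snps": data.genotypes.n_loci,
        }

        stage = "filter"
        gm, depths, log = run_filter_chain(data, config.filter)
        manifest["filter"] = log.stages
        manifest["filtered"] = {
            "n_samples": gm.n_samples,
            "n_snps": gm.n_loci,
        }
        write_genotype_table(gm, out / "genotypes_filtered.tsv")
        site_of = dict(
            zip(samples["sample_id"].astype(str), samples["site_code"].astype(str))
        )
        sites = np.asarray([site_of[s] for s in gm.sample_ids])

        stage = "ploidy"
        calls = ploidy.classify_all(
            gm, depths,
            min_allele_depth=config.ploidy_min_allele_depth,
            min_median_depth=config.ploidy_min_median_depth,
            min_sites=config.ploidy_min_sites,
            margin=config.ploidy_margin,
        )
        ploidy_df = pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id, "call": c.call,
                    "logL_dip": c.loglik_diploid, "logL_trip": c.loglik_triploid,
                    "n_sites": c.n_sites, "median_depth": c.median_depth,
                }
                for c in calls
            ]
        )
        ploidy_df.to_csv(out / "ploidy.tsv", sep="\t", index=False)
        manifest["ploidy"] = ploidy_df["call"].value_counts().to_dict()

        stage = "clonality"
        dm = clonality.hamming_distances(gm)
        candidates = clonality.candidate_thresholds(dm, config.linkage)
        threshold = (
            config.clone_threshold
            if config.clone_threshold is not None
            else clonality.predict_clone_threshold(candidates, config.clone_fraction)
        )
        assignment = clonality.assign_mll(dm, threshold, config.linkage)
        pd.DataFrame(
            {
                "sample_id": assignment.sample_ids,
                "site": sites,
                "mlg": assignment.mlg_ids,
                "mll": assignment.mll_ids,
            }
        ).to_csv(out / "clones.tsv", sep="\t", index=False)
        manifest["clonality"] = {
            "threshold": float(threshold),
            "n_mlg": assignment.n_mlg,
            "n_mll": assignment.n_mll,
        }

        stage = "diversity"
        div = clonality.diversity_table(assignment, sites)
        reportable = div["n_samples"] >= config.min_site_n
        div[reportable].to_csv(out / "clonal_diversity.tsv", sep="\t", index=False)
        gen_div = []
        for unit in ("ramets", "genets"):
            d = popgen.diversity_stats(
                gm, sites, unit=unit, assignment=assignment, min_n=config.min_site_n
            )
            gen_div.append(d)
        pd.concat(gen_div).to_csv(out / "genetic_diversity.tsv", sep="\t", index=False)
        manifest["diversity"] = {
            "n_sites_reported": int(reportable.sum()),
            "n_sites_low_n": int((~reportable).sum()),
        }

        stage = "fst_pca"
        fst = popgen.pairwise_fst(gm, sites)
        fst.to_csv(out / "fst.tsv", sep="\t")
        pc = popgen.pca(gm, n_axes=3)
        pd.DataFrame(
            pc.scores, index=pc.sample_ids,
            columns=[f"PC{i+1}" for i in range(pc.n_axes)],
        ).to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
        offdiag = fst.to_numpy()[~np.eye(len(fst), dtype=bool)]
        manifest["fst"] = {
            "max_pairwise": float(np.nanmax(offdiag)),
            "mean_pairwise": float(np.nanmean(offdiag)),
        }

        if config.env_table is not None:
            stage = "gea"
            env = read_env_table(config.env_table)
            env_wide = env.pivot(
                index="site", columns="variable", values="baseline_value"
            )
            geo = pd.read_csv(config.geo_distances, sep="\t", index_col=0)
            geo = geo.loc[env_wide.index, env_wide.index]
            geo_dm = clonality.DistanceMatrix(
                sample_ids=list(geo.index), values=geo.to_numpy(dtype=float)
            )
            gres = gea.run_gea(
                gm, sites, env_wide, geo_dm,
                n_axes=config.gea_axes, alpha=config.gea_alpha,
                r_threshold=config.gea_r_threshold,
            )
            gres.outliers.table.to_csv(out / "gea_outliers.tsv", sep="\t", index=False)
            manifest["gea"] = {
                "n_outliers": int(gres.outliers.table["outlier"].sum()),
                "r2": gres.model.r2,
                "adj_r2": gres.model.adj_r2,
                "inflation_factor": gres.outliers.inflation_factor,
                "variables": gres.env_variables,
            }

            stage = "offset"
            out_idx = gres.outliers.outlier_idx
            if len(out_idx) >= 2:
                env_fut = env.pivot(
                    index="site", columns="variable", values="future_value"
                )[gres.env_variables]
                xb = env_wide[gres.env_variables].loc[sites].to_numpy(float)
                xf = env_fut.loc[sites].to_numpy(float)
                k = min(config.offset_k, gm.n_samples - 1)
                model = offset_mod.fit_effects(
                    gm.take_loci(out_idx), xb, n_factors=k,
                    variables=gres.env_variables,
                )
                ores = offset_mod.genetic_offset(
                    model, xb, xf, sample_ids=gm.sample_ids, sites=sites
                )
                ores.per_sample.to_csv(out / "offset_samples.tsv", sep="\t", index=False)
                ores.per_site.to_csv(out / "offset_sites.tsv", sep="\t", index=False)
                manifest["offset"] = {
                    "n_outlier_loci": int(len(out_idx)),
                    "site_offsets": dict(
                        zip(ores.per_site["site"], ores.per_site["offset"])
                    ),
                }
            else:
                manifest["offset"] = {
                    "n_outlier_loci": int(len(out_idx)),
                    "note": "too few outlier loci; offset skipped",
                }
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
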