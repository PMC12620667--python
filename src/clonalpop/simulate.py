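"""Synthetic clonal metapopulations with known ground truth.

The generator emulates the data structure of a maerl-bed style study:
several sites along an environmental gradient, each holding a handful of
genets (clonal lineages) represented by one or more ramets (physical
individuals), genotyped at thousands of biallelic SNPs with read depths.

Neutral site allele frequencies follow the Balding-Nichols island model:
``p_site ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` so that F is the expected
differentiation among sites. Adaptive loci are additionally shifted along a
standardized environmental driver on the logit scale before the
Balding-Nichols draw, planting a genotype-environment association with
realistic sampling noise. Ramets copy their genet founder and accumulate
rare somatic dosage shifts (+/-1, clipped), so clonemates differ by small
Hamming distances — the reason a nonzero clone threshold is needed
downstream. Read depths are negative-binomial with binomial allele split
around dosage/ploidy, the signal used for allele-balance ploidy inference.

Triploid genets are emitted in the VCF as diploid-style calls (any
intermediate dosage codes as heterozygous), mirroring ploidy-2 variant
calling of mixed-ploidy samples, so read depths carry the only triploidy
signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DepthMatrix, GenotypeMatrix
from .vcfio import write_vcf

ENV_VARIABLES = ("temperature", "salinity", "velocity")


@dataclass
class SimConfig:
    """Ground-truth parameters of one simulated dataset.

    Defaults describe a small clonal metapopulation: 7 sites of 12 samples
    nested in 3 genetic clusters (between-cluster F = 0.2, within-cluster
    site F = 0.01, spanning the differentiation range of strongly
    structured coastal populations), 5000 SNPs, geometric genet sizes
    (mean ~1.7 ramets per genet), somatic mutation rate 1e-3 per locus per
    ramet, sequencing depth 60x with moderate overdispersion, 1% allele
    miscall error, and 50 adaptive loci strongly tied to a temperature
    gradient (effect size 3 on the logit scale, i.e. detectable
    outlier-class loci).
    """

    n_sites: int = 7
    samples_per_site: int = 12
    n_loci: int = 5000
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    fst_f: float = 0.01
    genet_geometric_p: float = 0.6
    genet_sizes: list[list[int]] | None = None
    somatic_rate: float = 1e-3
    triploid_fraction: float = 0.0
    depth_mean: float = 60.0
    depth_dispersion: float = 8.0
    error_rate: float = 0.01
    n_adaptive_loci: int = 50
    effect_size: float = 3.0
    n_clusters: int = 3
    cluster_f: float = 0.2
    env_future_shift: tuple[float, ...] = (1.5, -0.3, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.fst_f,
            self.genet_geometric_p,
            self.somatic_rate,
            self.triploid_fraction,
            self.error_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_adaptive_loci > self.n_loci:
            raise ValueError("n_adaptive_loci exceeds n_loci")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_maf_range must be within (0, 1) and ordered")


@dataclass
class SimTruth:
    """Generating values of a simulated dataset.

    ``samples``: sample_id, site, genet_id, ploidy per sample.
    ``loci``: contig, pos, adaptive flag and effect size per locus.
    ``site_freqs``: sites x loci allele-frequency matrix.
    ``env``: per-site environment, baseline and future.
    """

    samples: pd.DataFrame
    loci: pd.DataFrame
    site_freqs: np.ndarray
    env: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def n_genets(self) -> int:
        return self.samples["genet_id"].nunique()


def simulate_site_frequencies(
    p_ancestral: np.ndarray,
    F: float,
    n_sites: int,
    rng: np.random.Generator,
    env_z: np.ndarray | None = None,
    adaptive_idx: np.ndarray | None = None,
    effect_size: float = 0.0,
) -> np.ndarray:
    """Balding-Nichols site frequencies, with optional planted adaptation.

    Neutral loci draw ``p_site ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` independently
    per site and locus; the Beta mean is the ancestral ``p`` and F controls
    the variance (expected differentiation). Adaptive loci shift the Beta
    mean on the logit scale, ``logit(p) + b * z_site``, before drawing, where
    ``z`` is a standardized environmental value per site. ``F = 0`` is the
    degenerate no-differentiation limit: every site gets the ancestral
    frequency exactly.
    """
    p = np.asarray(p_ancestral, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    # p may be per-locus (shared ancestral pool) or per-site x locus
    # (e.g. cluster means in a hierarchical island model)
    means = np.tile(p, (n_sites, 1)) if p.ndim == 1 else p.copy()
    if means.shape[0] != n_sites:
        raise ValueError("2D ancestral frequencies must be sites x loci")
    if adaptive_idx is not None and effect_size != 0.0:
        if env_z is None:
            raise ValueError("adaptive loci require env_z")
        base = means[:, adaptive_idx]
        logit = np.log(base / (1 - base))
        shifted = logit + effect_size * np.asarray(env_z)[:, None]
        means[:, adaptive_idx] = 1.0 / (1.0 + np.exp(-shifted))
    if F == 0.0:
        return means
    scale = (1.0 - F) / F
    freqs = rng.beta(means * scale, (1.0 - means) * scale)
    # guard against numerically degenerate draws
    return np.clip(freqs, 1e-6, 1.0 - 1e-6)


def _genet_sizes_for_site(
    n_samples: int, geometric_p: float, rng: np.random.Generator
) -> list[int]:
    """Geometric clone sizes drawn until they cover the site's sample count;
    the last genet is truncated so sizes sum exactly to n_samples."""
    sizes: list[int] = []
    remaining = n_samples
    while remaining > 0:
        s = min(int(rng.geometric(geometric_p)), remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def simulate_clonal_samples(
    freqs: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw genets per site, replicate ramets, apply somatic mutations.

    Each genet founder is drawn binomially from its site's allele
    frequencies (``Binomial(ploidy, p)`` per locus, so triploids take
    dosages 0..3). Every ramet copies its founder; with probability
    ``somatic_rate`` per locus the dosage then shifts by +/-1 (direction
    equiprobable, clipped to [0, ploidy]). With ``somatic_rate = 0`` all
    ramets of a genet are identical.
    """
    n_sites, n_loci = freqs.shape
    sample_ids: list[str] = []
    sites: list[str] = []
    genet_ids: list[int] = []
    ploidies: list[int] = []
    rows: list[np.ndarray] = []
    genet_counter = 0
    for s in range(n_sites):
        site_code = f"S{s:02d}"
        if config.genet_sizes is not None:
            sizes = list(config.genet_sizes[s])
            if sum(sizes) != config.samples_per_site:
                raise ValueError(
                    f"genet sizes for site {site_code} sum to {sum(sizes)}, "
                    f"expected {config.samples_per_site}"
                )
        else:
            sizes = _genet_sizes_for_site(
                config.samples_per_site, config.genet_geometric_p, rng
            )
        for size in sizes:
            ploidy = 3 if rng.random() < config.triploid_fraction else 2
            founder = rng.binomial(ploidy, freqs[s])
            for _ in range(size):
                dosage = founder.copy()
                if config.somatic_rate > 0:
                    hit = rng.random(n_loci) < config.somatic_rate
                    if hit.any():
                        step = rng.choice((-1, 1), size=int(hit.sum()))
                        dosage[hit] = np.clip(dosage[hit] + step, 0, ploidy)
                rows.append(dosage.astype(np.int16))
                sample_ids.append(f"{site_code}_R{len(sample_ids):03d}")
                sites.append(site_code)
                genet_ids.append(genet_counter)
                ploidies.append(ploidy)
            genet_counter += 1

    loci = pd.DataFrame(
        {
            "contig": [f"contig{j // 40}" for j in range(n_loci)],
            "pos": [1 + 1500 * (j % 40) for j in range(n_loci)],
            "ref": ["A"] * n_loci,
            "alt": ["T"] * n_loci,
            "multiallelic": [False] * n_loci,
        }
    )
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        loci=loci,
        dosages=np.vstack(rows),
        ploidy=np.asarray(ploidies),
    )
    truth_samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "site": sites,
            "genet_id": genet_ids,
            "ploidy": ploidies,
        }
    )
    truth = SimTruth(samples=truth_samples, loci=loci.copy(), site_freqs=freqs)
    return gm, truth


def simulate_depths(
    gm: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> DepthMatrix:
    """Negative-binomial total depth, binomial allele split.

    Total depth per call ~ NB with the configured mean and dispersion
    (gamma-Poisson mixture); alt reads ~ Binomial(depth, theta') with
    theta = dosage/ploidy and the miscall adjustment
    theta' = theta(1-e) + (1-theta)e.
    """
    shape = gm.dosages.shape
    r = config.depth_dispersion
    p_nb = r / (r + config.depth_mean)
    total = rng.negative_binomial(r, p_nb, size=shape)
    theta = gm.dosages / gm.ploidy[:, None]
    theta = theta * (1 - config.error_rate) + (1 - theta) * config.error_rate
    alt = rng.binomial(total, theta)
    return DepthMatrix(ref_depth=total - alt, alt_depth=alt)


def diploidize(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Recode dosages as diploid-style calls: 0 -> 0, ploidy -> 2, any
    intermediate dosage -> 1 (het). Ploidy metadata becomes 2 everywhere."""
    dos = gm.dosages.copy()
    full = dos == gm.ploidy[:, None]
    het = (dos > 0) & ~full
    dos[full] = 2
    dos[het] = 1
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        loci=gm.loci.copy(),
        dosages=dos,
        ploidy=np.full(gm.n_samples, 2),
    )


def _site_environment(
    config: SimConfig,
    rng: np.random.Generator,
    cluster_of_site: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-site environment: temperature spans ~10-16 C across sites as a
    modest smooth trend along the coast plus dominant site-specific
    deviations (as for real coastal sites, where depth, estuarine
    influence and local hydrography perturb the regional gradient);
    salinity and seawater velocity vary with weaker trends. The local
    component is what keeps environment only partially collinear with
    geography, so spatial detrending is meaningful without absorbing the
    whole environmental signal. Future values add the configured scenario
    shift plus site jitter. Returns the long-format table and the local
    (anomaly) temperature component, the selective driver of the planted
    adaptive loci.

    The anomaly is constructed orthogonal, at site level, to the smooth
    coastal trend (polynomials up to degree 4, spanning the smooth
    spatial modes a Moran's-eigenvector basis would model) and to the
    genetic-cluster contrasts. A genotype-environment association that is collinear with
    spatial trend or neutral structure is unidentifiable to any method
    that conditions on them — by planting the signal in the identifiable
    subspace, recovery experiments measure the method's power rather than
    the (provable) confounding loss."""
    n = config.n_sites
    grad = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    temp_local = rng.normal(0, 1.0, n)
    if n > 4 and cluster_of_site is not None:
        basis = [np.ones(n), grad, grad**2, grad**3, grad**4]
        for c in range(1, config.n_clusters):
            basis.append((cluster_of_site == c).astype(float))
        Q = np.linalg.qr(np.column_stack(basis))[0]
        temp_local = temp_local - Q @ (Q.T @ temp_local)
    if temp_local.std() > 0:
        temp_local = 1.8 * temp_local / temp_local.std()
    temperature = 13.0 + 1.0 * grad + temp_local
    salinity = 34.8 + 0.3 * grad[::-1] + rng.normal(0, 0.3, n)
    velocity = np.abs(0.15 + 0.08 * rng.normal(0, 1, n))
    baseline = np.column_stack([temperature, salinity, velocity])
    shift = np.asarray(config.env_future_shift)
    future = baseline + shift[None, :] + rng.normal(0, 0.05, baseline.shape)
    records = []
    for s in range(n):
        for k, var in enumerate(ENV_VARIABLES):
            records.append(
                {
                    "site": f"S{s:02d}",
                    "variable": var,
                    "baseline_value": baseline[s, k],
                    "future_value": future[s, k],
                }
            )
    return pd.DataFrame(records), temp_local


@dataclass
class SimulatedDataset:
    """In-memory bundle produced by :func:`simulate_dataset`."""

    genotypes: GenotypeMatrix  # true dosages (0..ploidy)
    genotypes_diploid: GenotypeMatrix  # diploid-coded, as a caller would emit
    depths: DepthMatrix
    truth: SimTruth
    env: pd.DataFrame
    site_qual: np.ndarray
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator under one seed: frequencies -> genets/ramets ->
    depths -> environment. Fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    cluster_of_site = (
        np.arange(config.n_sites) % config.n_clusters
        if config.n_clusters > 0
        else None
    )
    env, temp_local = _site_environment(config, rng, cluster_of_site)
    # selection acts on the local temperature anomaly (micro-habitat
    # adaptation among nearby sites), not the broad coastal trend: range
    # shifts, not selection differentials, track the regional gradient —
    # and the anomaly is the component that survives spatial detrending
    env_z = (
        (temp_local - temp_local.mean()) / temp_local.std()
        if config.n_sites > 1 and temp_local.std() > 0
        else np.zeros(config.n_sites)
    )

    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, config.n_loci)
    adaptive_idx = (
        rng.choice(config.n_loci, size=config.n_adaptive_loci, replace=False)
        if config.n_adaptive_loci
        else np.asarray([], dtype=int)
    )
    if config.n_clusters > 0 and config.cluster_f > 0.0:
        # hierarchical island model: sites nest in genetic clusters whose
        # frequencies diverge more strongly than sites within them — the
        # dominant structure axes are then neutral cluster contrasts, as in
        # strongly structured empirical data, not the adaptive gradient
        cluster_means = simulate_site_frequencies(
            p_anc, config.cluster_f, config.n_clusters, rng
        )
        p_base = np.clip(cluster_means[cluster_of_site], 1e-4, 1 - 1e-4)
    else:
        p_base = p_anc
    freqs = simulate_site_frequencies(
        p_base,
        config.fst_f,
        config.n_sites,
        rng,
        env_z=env_z,
        adaptive_idx=adaptive_idx,
        effect_size=config.effect_size,
    )
    gm, truth = simulate_clonal_samples(freqs, config, rng)
    depths = simulate_depths(gm, config, rng)
    truth.env = env
    truth.loci["adaptive"] = False
    truth.loci.loc[adaptive_idx, "adaptive"] = True
    truth.loci["effect"] = 0.0
    truth.loci.loc[adaptive_idx, "effect"] = config.effect_size
    site_qual = rng.uniform(100.0, 1000.0, config.n_loci)
    return SimulatedDataset(
        genotypes=gm,
        genotypes_diploid=diploidize(gm),
        depths=depths,
        truth=truth,
        env=env,
        site_qual=site_qual,
        config=config,
    )


def emit_dataset(config: SimConfig, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write the dataset to ``outdir``: VCF, sample table, environment table
    and ground-truth tables. Byte-identical across runs with the same seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)

    gq = np.minimum(99, 3 * ds.depths.total_depth).astype(float)
    paths = {
        "vcf": out / "variants.vcf",
        "samples": out / "samples.tsv",
        "env": out / "environment.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "truth_loci": out / "truth_loci.tsv",
        "geo_distances": out / "geo_distances.tsv",
    }
    write_vcf(
        ds.genotypes_diploid,
        paths["vcf"],
        depths=ds.depths,
        site_qual=ds.site_qual,
        genotype_qual=gq,
    )
    samples = ds.truth.samples.copy()
    # simple coastline-like coordinates so spatial steps have something to use
    site_order = sorted(samples["site"].unique())
    coords = {
        s: (50.0 + 0.15 * i, -5.0 + 0.35 * i) for i, s in enumerate(site_order)
    }
    samples["lat"] = samples["site"].map(lambda s: coords[s][0])
    samples["lon"] = samples["site"].map(lambda s: coords[s][1])
    samples.rename(columns={"site": "site_code"})[
        ["sample_id", "site_code", "lat", "lon"]
    ].to_csv(paths["samples"], sep="\t", index=False, float_format="%.6f")
    ds.env.to_csv(paths["env"], sep="\t", index=False, float_format="%.8f")
    ds.truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    ds.truth.loci.to_csv(
        paths["truth_loci"], sep="\t", index=False, float_format="%.8f"
    )
    # straight-line site distances in km (~111 km/degree), a stand-in for
    # least-cost marine distances when no raster is in play
    xy = np.asarray([coords[s] for s in site_order]) * 111.0
    D = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    pd.DataFrame(D, index=site_order, columns=site_order).to_csv(
        paths["geo_distances"], sep="\t", float_format="%.4f"
    )
    return paths
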