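"""Synthetic study generator with known ground truth.

Emulates the design of a wild quantitative-genetics study of floral traits:
six sites along an elevation gradient, 40 tagged plants per site, five flower
replicates per plant, a few thousand genome-wide SNPs with family structure
inside sites (hence variance in pairwise relatedness but very low between-site
differentiation), two correlated floral traits — one heritable (h2 = 0.14,
"flower weight") and one with essentially no additive variance under
stabilizing selection ("standard petal area") — binomial fruit-set fitness on
a Gaussian surface, and 3-minute pollinator censuses.

Every stochastic draw is routed through the config seed; identical configs
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .genotypes import GenotypeMatrix

#: default per-site elevations (m a.s.l.); the study area spans ~0-900 m
DEFAULT_ELEVATIONS = (60.0, 150.0, 320.0, 480.0, 660.0, 850.0)


@dataclass
class TraitParams:
    """Generating parameters for one floral trait.

    Variances are at the flower level, in squared trait units:
    ``v_a`` additive genetic, ``v_s`` site (random component, excluding the
    elevation trend), ``v_i`` permanent environment (plant), ``v_error``
    flower-to-flower residual.  ``elevation_slope`` is the linear trend in
    trait units per metre, applied to site-mean-centred elevation.
    """

    mean: float
    v_a: float
    v_s: float
    v_i: float
    v_error: float
    elevation_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_a", "v_s", "v_i", "v_error"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.mean) or not np.isfinite(self.elevation_slope):
            raise ValueError("non-finite trait parameter")

    @property
    def total_variance(self) -> float:
        return self.v_a + self.v_s + self.v_i + self.v_error

    @property
    def h2(self) -> float:
        """Generating narrow-sense heritability V_a / (V_a+V_s+V_i+V_e)."""
        return self.v_a / self.total_variance


@dataclass
class FamilyStructure:
    """Sibship clusters from founder gene-dropping.

    Each site has a founder pool; plants are grouped into full-sib families
    whose two parents are drawn from the pool (reuse creates half-sib links).
    With probability ``migration`` one parent of a family comes from another
    site's pool, creating cross-site relatives without between-site allele
    frequency differentiation.
    """

    mean_sibship: float = 4.0
    migration: float = 0.05
    founders_per_site: int = 25


@dataclass
class FitnessParams:
    """Gaussian fruit-set surface on the plant-mean focal trait.

    Fruit probability ``p(z) = max_prob * exp(-(z - optimum)^2 / (2 width^2))``,
    fruits ~ Binomial(flower scars, p).  ``optimum=None`` places the optimum at
    the realized trait mean; ``width=None`` solves the width so the analytic
    variance-standardized quadratic gradient equals ``gamma_target``.
    """

    trait: str = "standard_area_mm2"
    flowers_rate: float = 40.0
    optimum: float | None = None
    width: float | None = None
    gamma_target: float = -0.086
    max_prob: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.max_prob <= 1.0:
            raise ValueError("max_prob must be in (0, 1]")
        if self.width is not None and self.width <= 0:
            raise ValueError("fitness surface width must be > 0")


@dataclass
class CensusParams:
    """Pollinator census design: visits ~ Poisson(rate * flowers surveyed)."""

    n_censuses: int = 569
    mean_flowers: float = 40.0
    duration_min: float = 3.0
    rate_per_flower: float = 0.0155
    taxon_shares: dict = field(
        default_factory=lambda: {
            "Apis mellifera": 0.91,
            "Bombus sp.": 0.069,
            "other": 0.021,
        }
    )


def _default_traits() -> dict:
    # Calibrated so the emulated population shows: flower weight
    # h2 = 0.140, plant-mean CV ~ 21%, variance partition ~ 53/33/14 (site /
    # plant / flower); standard area h2 ~ 0.001, partition ~ 40/42/18.
    return {
        "flower_weight_mg": TraitParams(
            mean=26.0, v_a=4.74, v_s=17.94, v_i=6.44, v_error=4.74,
            elevation_slope=-0.002,
        ),
        "standard_area_mm2": TraitParams(
            mean=50.0, v_a=0.131, v_s=52.4, v_i=55.0, v_error=23.6,
            elevation_slope=-0.005,
        ),
    }


@dataclass
class SimulationConfig:
    """Full design of a synthetic study; the seed is mandatory state."""

    n_sites: int = 6
    plants_per_site: int = 40
    flowers_per_plant: int = 5
    n_loci: int = 2000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    family_structure: FamilyStructure = field(default_factory=FamilyStructure)
    elevation_per_site: tuple[float, ...] = DEFAULT_ELEVATIONS
    traits: dict = field(default_factory=_default_traits)
    genetic_corr: float = 0.06
    env_corr: float | None = None  # None -> solved for phenotypic_corr_target
    phenotypic_corr_target: float = 0.43
    fitness: FitnessParams = field(default_factory=FitnessParams)
    census: CensusParams = field(default_factory=CensusParams)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 100:
            raise ValueError("n_loci must be >= 100 (GRM too noisy below)")
        if self.flowers_per_plant < 2:
            raise ValueError(
                "flowers_per_plant must be >= 2 to separate V_i from V_error"
            )
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        if len(self.elevation_per_site) < self.n_sites:
            raise ValueError("need an elevation for every site")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not -1.0 <= self.genetic_corr <= 1.0:
            raise ValueError("genetic_corr must be in [-1, 1]")

    @property
    def n_plants(self) -> int:
        return self.n_sites * self.plants_per_site

    def rngs(self, *labels: str) -> list[np.random.Generator]:
        """Deterministic child generators, one per stage label."""
        order = ("genotypes", "phenotypes", "fitness", "census", "missing")
        base = np.random.SeedSequence(self.seed)
        children = base.spawn(len(order))
        lut = dict(zip(order, children))
        return [np.random.default_rng(lut[l]) for l in labels]


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus the truth used to generate it."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # plant_id, site, elevation_m, flower_idx, traits
    fitness: pd.DataFrame | None  # plant_id, fruits, flower_scars
    censuses: pd.DataFrame | None
    breeding_values: pd.DataFrame  # plant_id x trait
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genotypes.write_tsv(outdir / "genotypes.tsv")
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        if self.fitness is not None:
            self.fitness.to_csv(outdir / "fitness.csv", index=False)
        if self.censuses is not None:
            self.censuses.to_csv(outdir / "census.csv", index=False)
        write_vcf(self.genotypes, outdir / "genotypes.vcf")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Gene-drop founder families to produce a dosage matrix with sibships.

    Founder haplotypes are Bernoulli(p_k) draws at each locus (loci unlinked,
    frequencies uniform over ``founder_maf_range`` and shared across sites, so
    between-site differentiation stays minimal).  Families inherit one random
    allele per parent per locus, producing full sibs (r = 0.5), half sibs
    through founder reuse (r = 0.25) and a background of unrelated pairs.
    """
    (rng,) = config.rngs("genotypes")
    fam = config.family_structure
    p = rng.uniform(*config.founder_maf_range, size=config.n_loci)

    # founder haplotype pools: (site, founder, 2, loci) as uint8 bits
    founders = (
        rng.random((config.n_sites, fam.founders_per_site, 2, config.n_loci))
        < p
    ).astype(np.uint8)

    ids, sites_lab = [], []
    rows = np.empty((config.n_plants, config.n_loci), dtype=float)
    family_ids = []
    r = 0
    for s in range(config.n_sites):
        remaining = config.plants_per_site
        fam_no = 0
        while remaining > 0:
            size = 1 + rng.poisson(max(fam.mean_sibship - 1.0, 0.0))
            size = int(min(size, remaining))
            # parents: two distinct founders; one may migrate from another site
            site_a = s
            if config.n_sites > 1 and rng.random() < fam.migration:
                site_a = int(rng.choice([j for j in range(config.n_sites) if j != s]))
            ia = int(rng.integers(fam.founders_per_site))
            ib = int(rng.integers(fam.founders_per_site))
            if site_a == s:
                while ib == ia:
                    ib = int(rng.integers(fam.founders_per_site))
            pa, pb = founders[site_a, ia], founders[s, ib]
            for _ in range(size):
                ha = pa[rng.integers(0, 2, size=config.n_loci), np.arange(config.n_loci)]
                hb = pb[rng.integers(0, 2, size=config.n_loci), np.arange(config.n_loci)]
                rows[r] = ha + hb
                ids.append(f"S{s + 1}P{r + 1:03d}")
                sites_lab.append(f"site{s + 1}")
                family_ids.append(f"S{s + 1}F{fam_no:02d}")
                r += 1
            remaining -= size
            fam_no += 1
    loci = [f"snp{k + 1:05d}" for k in range(config.n_loci)]
    g = GenotypeMatrix(ids, loci, rows, np.asarray(sites_lab))
    if config.missing_rate > 0:
        (mrng,) = config.rngs("missing")
        mask = mrng.random(rows.shape) < config.missing_rate
        d = g.dosages.copy()
        d[mask] = np.nan
        g = GenotypeMatrix(ids, loci, d, np.asarray(sites_lab))
    g.family_ids = family_ids  # ancillary truth, not part of the container API
    return g


# ---------------------------------------------------------------------------
# phenotypes


def solve_env_corr(config: SimulationConfig) -> float:
    """Environmental correlation giving the target plant-mean phenotypic r.

    The plant-mean covariance between two traits is linear in the shared
    environmental correlation rho (applied to site, permanent-environment and
    residual effects), with a fixed genetic and elevation-trend contribution;
    the solver inverts that linear map.
    """
    names = list(config.traits)
    if len(names) != 2:
        raise ValueError("env_corr solver requires exactly two traits")
    t1, t2 = (config.traits[n] for n in names)
    k = config.flowers_per_plant
    elev = np.asarray(config.elevation_per_site[: config.n_sites])
    v_elev = elev.var()  # population variance across sites
    var1 = t1.v_a + t1.v_s + t1.v_i + t1.v_error / k + t1.elevation_slope**2 * v_elev
    var2 = t2.v_a + t2.v_s + t2.v_i + t2.v_error / k + t2.elevation_slope**2 * v_elev
    fixed_cov = (
        config.genetic_corr * np.sqrt(t1.v_a * t2.v_a)
        + t1.elevation_slope * t2.elevation_slope * v_elev
    )
    slope = (
        np.sqrt(t1.v_s * t2.v_s)
        + np.sqrt(t1.v_i * t2.v_i)
        + np.sqrt(t1.v_error * t2.v_error) / k
    )
    rho = (config.phenotypic_corr_target * np.sqrt(var1 * var2) - fixed_cov) / slope
    if not -1.0 <= rho <= 1.0:
        raise ValueError(
            f"phenotypic correlation target {config.phenotypic_corr_target} "
            f"unreachable (requires env_corr = {rho:.3f})"
        )
    return float(rho)


def _corr2(rho: float) -> np.ndarray:
    return np.array([[1.0, rho], [rho, 1.0]])


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Replicated flower phenotypes on top of simulated genotypes.

    Breeding values are genotype-based: per-locus allelic effects (correlated
    across traits with ``genetic_corr``) are summed over centred dosages and
    rescaled so the realized sample variance equals ``v_a`` exactly — the
    VanRaden GRM then captures the simulated additive variance.  Phenotype =
    mean + slope * centred elevation + site effect + permanent environment +
    breeding value + flower residual; site/plant/flower environmental effects
    share correlation ``env_corr`` across traits.

    Returns ``(phenotypes, breeding_values, truth)``.
    """
    if not config.traits:
        raise ValueError("at least one trait required")
    (rng,) = config.rngs("phenotypes")
    names = list(config.traits)
    tp = [config.traits[n] for n in names]
    T = len(names)
    n = genotypes.n_individuals
    if n != config.n_plants:
        raise ValueError("genotype matrix does not match config design")

    d = genotypes.dosages
    if np.isnan(d).any():
        # gene-dropped matrices are complete; injected missingness is for QC
        # testing, breeding values use the underlying calls' mean fill
        col = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col[None, :], d)
    p = d.mean(axis=0) / 2.0
    zc = d - 2.0 * p

    rho_g = config.genetic_corr if T == 2 else 0.0
    eff = rng.multivariate_normal(np.zeros(T), _corr2(rho_g) if T == 2 else np.eye(T),
                                  size=config.n_loci)
    a = zc @ eff  # (n, T) raw breeding values
    realized_rg = None
    for t in range(T):
        sd = a[:, t].std(ddof=1)
        if tp[t].v_a == 0.0 or sd == 0.0:
            a[:, t] = 0.0
        else:
            a[:, t] *= np.sqrt(tp[t].v_a) / sd
    if T == 2 and a[:, 0].std() > 0 and a[:, 1].std() > 0:
        realized_rg = float(np.corrcoef(a[:, 0], a[:, 1])[0, 1])

    rho_e = config.env_corr if config.env_corr is not None else (
        solve_env_corr(config) if T == 2 else 0.0
    )
    corr_e = _corr2(rho_e) if T == 2 else np.eye(T)

    elev = np.asarray(config.elevation_per_site[: config.n_sites], dtype=float)
    elev_c = elev - elev.mean()
    site_eff = rng.multivariate_normal(np.zeros(T), corr_e, size=config.n_sites)
    site_eff = site_eff * np.array([np.sqrt(t.v_s) for t in tp])[None, :]
    perm_eff = rng.multivariate_normal(np.zeros(T), corr_e, size=n)
    perm_eff = perm_eff * np.array([np.sqrt(t.v_i) for t in tp])[None, :]

    k = config.flowers_per_plant
    resid = rng.multivariate_normal(np.zeros(T), corr_e, size=n * k)
    resid = resid * np.array([np.sqrt(t.v_error) for t in tp])[None, :]

    site_index = np.repeat(np.arange(config.n_sites), config.plants_per_site)
    recs = {
        "plant_id": np.repeat(genotypes.individual_ids, k),
        "site": np.repeat([f"site{s + 1}" for s in site_index], k),
        "elevation_m": np.repeat(elev[site_index], k),
        "flower_idx": np.tile(np.arange(1, k + 1), n),
    }
    for t, name in enumerate(names):
        plant_level = (
            tp[t].mean
            + tp[t].elevation_slope * elev_c[site_index]
            + site_eff[site_index, t]
            + perm_eff[:, t]
            + a[:, t]
        )
        recs[name] = np.repeat(plant_level, k) + resid[:, t]
    phenotypes = pd.DataFrame(recs)
    breeding = pd.DataFrame(a, index=genotypes.individual_ids, columns=names)
    breeding.index.name = "plant_id"

    truth = {
        "traits": {
            name: {
                **dataclasses.asdict(t),
                "h2": t.h2,
                "evolvability_pct": 100.0 * t.v_a / t.mean**2,
                "realized_h2": float(
                    a[:, i].var(ddof=1) / t.total_variance
                ),
                "realized_components": {
                    "v_a": float(a[:, i].var(ddof=1)),
                    "v_s": float(site_eff[:, i].var(ddof=1))
                    if site_eff.shape[0] > 1 else 0.0,
                    "v_i": float(perm_eff[:, i].var(ddof=1)),
                    "v_error": float(resid[:, i].var(ddof=1)),
                },
            }
            for i, (name, t) in enumerate(zip(names, tp))
        },
        "genetic_corr": config.genetic_corr,
        "realized_genetic_corr": realized_rg,
        "env_corr": rho_e,
        "phenotypic_corr_target": config.phenotypic_corr_target,
        "seed": config.seed,
    }
    return phenotypes, breeding, truth


# ---------------------------------------------------------------------------
# fitness


def gaussian_surface_gamma(
    optimum: float, width: float, z_mean: float, z_sd: float
) -> float:
    """Analytic variance-standardized quadratic gradient of a Gaussian surface.

    For plant-mean trait z ~ N(z_mean, z_sd^2) and expected fitness
    ``W(z) = m exp(-(z-optimum)^2 / (2 width^2))``, returns the mean over the
    phenotype distribution of the second derivative of relative fitness with
    respect to the standardized trait.  With the optimum at the mean this is
    ``-1 / (1 + (width/z_sd)^2)`` in closed form; elsewhere it is evaluated by
    Gauss-Hermite quadrature.
    """
    om = width / z_sd
    th = (optimum - z_mean) / z_sd
    nodes, weights = np.polynomial.hermite_e.hermegauss(101)
    wts = weights / weights.sum()
    f = np.exp(-((nodes - th) ** 2) / (2.0 * om**2))
    wbar = float(np.sum(wts * f))
    # d2/du2 of f: f * ((u-th)^2/om^4 - 1/om^2)
    d2 = f * (((nodes - th) ** 2) / om**4 - 1.0 / om**2)
    return float(np.sum(wts * d2) / wbar)


def solve_surface_width(
    gamma_target: float, optimum: float, z_mean: float, z_sd: float
) -> float:
    """Width giving the requested (negative) standardized quadratic gradient."""
    if gamma_target >= 0:
        raise ValueError("gamma_target must be negative for a stabilizing surface")
    lo, hi = 0.05, 200.0
    fn = lambda w: gaussian_surface_gamma(optimum, w * z_sd, z_mean, z_sd) - gamma_target
    return float(optimize.brentq(fn, lo, hi, xtol=1e-10)) * z_sd


def simulate_fitness(
    phenotypes: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, dict]:
    """Binomial fruit counts from the Gaussian surface on plant-mean trait.

    Flower-scar counts are 1 + Poisson(flowers_rate - 1).  Truth records the
    analytic standardized quadratic gradient implied by (optimum, width, trait
    SD) plus its empirical average over the observed plant means.
    """
    fp = config.fitness
    if fp.trait not in phenotypes.columns:
        raise ValueError(f"focal trait {fp.trait!r} not in phenotype table")
    (rng,) = config.rngs("fitness")
    z = phenotypes.groupby("plant_id", sort=False)[fp.trait].mean()
    z_mean, z_sd = float(z.mean()), float(z.std(ddof=1))
    optimum = fp.optimum if fp.optimum is not None else z_mean
    if fp.width is not None:
        width = fp.width
    else:
        width = solve_surface_width(fp.gamma_target, optimum, z_mean, z_sd)
    scars = 1 + rng.poisson(max(fp.flowers_rate - 1.0, 0.0), size=z.size)
    prob = fp.max_prob * np.exp(-((z.to_numpy() - optimum) ** 2) / (2.0 * width**2))
    fruits = rng.binomial(scars, prob)
    fitness = pd.DataFrame(
        {"plant_id": z.index, "fruits": fruits, "flower_scars": scars}
    )
    # empirical averaged second derivative of relative fitness over observed z
    u = (z.to_numpy() - z_mean) / z_sd
    th = (optimum - z_mean) / z_sd
    om = width / z_sd
    f = np.exp(-((u - th) ** 2) / (2.0 * om**2))
    emp_gamma = float(np.mean(f * (((u - th) ** 2) / om**4 - 1.0 / om**2)) / f.mean())
    truth = {
        "trait": fp.trait,
        "optimum": float(optimum),
        "width": float(width),
        "max_prob": fp.max_prob,
        "trait_mean": z_mean,
        "trait_sd": z_sd,
        "gamma_analytic": gaussian_surface_gamma(optimum, width, z_mean, z_sd),
        "gamma_empirical": emp_gamma,
    }
    return fitness, truth


# ---------------------------------------------------------------------------
# censuses


def simulate_censuses(config: SimulationConfig) -> pd.DataFrame:
    """Pollinator censuses: per-census flowers surveyed and visits by taxon."""
    cp = config.census
    (rng,) = config.rngs("census")
    sites = [f"site{1 + i % config.n_sites}" for i in range(cp.n_censuses)]
    flowers = 1 + rng.poisson(cp.mean_flowers - 1.0, size=cp.n_censuses)
    total = rng.poisson(cp.rate_per_flower * flowers)
    taxa = list(cp.taxon_shares)
    shares = np.asarray([cp.taxon_shares[t] for t in taxa], dtype=float)
    shares = shares / shares.sum()
    by_taxon = np.array([rng.multinomial(v, shares) for v in total])
    rows = []
    for i in range(cp.n_censuses):
        for j, taxon in enumerate(taxa):
            rows.append(
                {
                    "site": sites[i],
                    "census_id": i + 1,
                    "duration_min": cp.duration_min,
                    "flowers_surveyed": int(flowers[i]),
                    "taxon": taxon,
                    "visits": int(by_taxon[i, j]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole study


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study (genotypes through censuses)."""
    config = config if config is not None else SimulationConfig()
    genotypes = simulate_genotypes(config)
    phenotypes, breeding, truth = simulate_phenotypes(genotypes, config)
    fitness, fit_truth = simulate_fitness(phenotypes, config)
    censuses = simulate_censuses(config)
    truth["fitness"] = fit_truth
    truth["design"] = {
        "n_sites": config.n_sites,
        "plants_per_site": config.plants_per_site,
        "flowers_per_plant": config.flowers_per_plant,
        "n_loci": config.n_loci,
    }
    r = (
        phenotypes.groupby("plant_id", sort=False)[list(config.traits)]
        .mean()
        .corr()
        .iloc[0, -1]
        if len(config.traits) > 1
        else None
    )
    truth["realized_phenotypic_corr"] = None if r is None else float(r)
    return SimulatedStudy(genotypes, phenotypes, fitness, censuses, breeding, truth)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal diploid VCF 4.2 (unphased GT only)."""
    dose_to_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j, locus in enumerate(g.locus_ids):
            calls = [
                dose_to_gt.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosages[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
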