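"""End-to-end analysis pipeline: QC -> GRM -> descriptive -> animal models ->
selection -> power, from one config with one global seed.

Each stage writes its artifacts under ``outdir/<stage>/`` and contributes a
section to a combined JSON report; a markdown report renders the
genetic-parameter and selection-coefficient tables.  The global seed
is split deterministically into per-stage seeds so stages stay reproducible
even when other stages are skipped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .animal import AnimalModel
from .descriptive import (
    coefficient_of_variation,
    partition_trait_variance,
    phenotypic_correlation,
    repeatability,
    visitation_summary,
)
from .genotypes import apply_qc_filters, impute_missing, read_genotypes
from .power import DEFAULT_VAR_REL, PowerSpec, greml_power_h2, greml_power_rg, var_rel_from_grm
from .relatedness import relatedness_summary, vanraden_grm
from .selection import estimate_selection

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, per-stage parameters and the global seed for a pipeline run."""

    outdir: str = "out"
    genotypes: str | None = None
    genotype_format: str = "auto"
    phenotypes: str | None = None
    fitness: str | None = None
    census: str | None = None
    traits: tuple[str, ...] = ("standard_area_mm2", "flower_weight_mg")
    qc: dict = field(default_factory=dict)  # apply_qc_filters kwargs
    chain: dict = field(
        default_factory=lambda: {"n_iter": 5000, "burnin": 1000, "thin": 2}
    )
    px_traits: tuple[str, ...] = ()  # traits fitted with parameter expansion
    fit_naive: bool = True
    fit_bivariate: bool = True
    n_boot: int = 2000
    power_h2_values: tuple[float, ...] = (0.1, 0.14)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        order = ("animal", "selection", "power")
        ss = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(ss[order.index(stage)].generate_state(1)[0] % (2**31))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the combined report dict (also written to
    ``outdir/report.json`` and ``outdir/report.md``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": dataclasses.asdict(config),
        "versions": {"wildqg": __version__},
        "stages": {},
    }
    t_start = time.time()

    if config.phenotypes is None:
        raise ValueError("a phenotype table is required")
    phenotypes = pd.read_csv(config.phenotypes)
    trait_cols = [t for t in config.traits if t in phenotypes.columns]
    if not trait_cols:
        raise ValueError("no configured trait columns in the phenotype table")

    # --- QC ---------------------------------------------------------------
    stage_dir = out / "qc"
    stage_dir.mkdir(exist_ok=True)
    try:
        sites = (
            phenotypes.groupby("plant_id", sort=False)["site"].first().to_dict()
        )
        g_raw = read_genotypes(
            config.genotypes, config.genotype_format, sites=sites
        )
        g_qc, qc_report = apply_qc_filters(g_raw, **config.qc)
        g_qc.write_tsv(stage_dir / "genotypes_qc.tsv")
        (stage_dir / "qc.json").write_text(json.dumps(qc_report.to_dict(), indent=2))
        report["stages"]["qc"] = qc_report.to_dict()
    except Exception as exc:
        raise StageError("qc", exc) from exc

    # --- GRM --------------------------------------------------------------
    stage_dir = out / "grm"
    stage_dir.mkdir(exist_ok=True)
    try:
        grm = vanraden_grm(impute_missing(g_qc))
        grm.write_tsv(stage_dir / "grm.tsv")
        grm_summary = relatedness_summary(grm, g_qc.sites)
        (stage_dir / "summary.json").write_text(
            json.dumps(grm_summary, indent=2)
        )
        report["stages"]["grm"] = grm_summary
    except Exception as exc:
        raise StageError("grm", exc) from exc

    # --- descriptive ------------------------------------------------------
    stage_dir = out / "describe"
    stage_dir.mkdir(exist_ok=True)
    try:
        desc: dict = {"traits": {}}
        plant_means = phenotypes.groupby("plant_id", sort=False)[trait_cols].mean()
        for t in trait_cols:
            desc["traits"][t] = {
                "partition": partition_trait_variance(phenotypes, t),
                "repeatability_pct": repeatability(phenotypes, t),
                "cv_pct": coefficient_of_variation(plant_means[t].to_numpy()),
                "plant_mean": float(plant_means[t].mean()),
            }
        if len(trait_cols) == 2:
            r, p = phenotypic_correlation(
                plant_means[trait_cols[0]], plant_means[trait_cols[1]]
            )
            desc["phenotypic_correlation"] = {"r": r, "p": p}
        if config.census is not None:
            censuses = pd.read_csv(config.census)
            desc["visitation"] = visitation_summary(censuses)
        (stage_dir / "describe.json").write_text(
            json.dumps(desc, indent=2, default=float)
        )
        report["stages"]["describe"] = desc
    except Exception as exc:
        raise StageError("describe", exc) from exc

    # --- animal models ----------------------------------------------------
    stage_dir = out / "animal"
    stage_dir.mkdir(exist_ok=True)
    try:
        seed = RunConfig.stage_seed(config, "animal")
        animal: dict = {"univariate": {}, "bivariate": None}
        for i, t in enumerate(trait_cols):
            px = t in config.px_traits
            full = AnimalModel(phenotypes, grm, t, px=px).fit(
                seed=seed + 10 * i, **config.chain
            )
            h2 = full.heritability()
            e = full.evolvability()
            entry = {
                "h2": {"mean": h2.mean, "ci95": h2.ci95, "ess": h2.ess},
                "evolvability_pct": {"mean": e.mean, "ci95": e.ci95},
                "trait_mean": full.model.bundle.trait_means[t],
                "dic": full.dic,
                "point": {k: float(v) for k, v in full.point.items()},
                "px": px,
            }
            full.draws.to_csv(stage_dir / f"draws_{t}.csv", index=False)
            if config.fit_naive:
                naive = AnimalModel(phenotypes, grm, t, naive=True, px=px).fit(
                    seed=seed + 10 * i + 1, **config.chain
                )
                nh2 = naive.heritability()
                entry["naive"] = {
                    "h2": {"mean": nh2.mean, "ci95": nh2.ci95},
                    "dic": naive.dic,
                    "delta_dic": naive.dic - full.dic,
                }
            animal["univariate"][t] = entry
        if config.fit_bivariate and len(trait_cols) == 2:
            biv = AnimalModel(phenotypes, grm, tuple(trait_cols)).fit(
                seed=seed + 99, **config.chain
            )
            rg = biv.genetic_correlation()
            animal["bivariate"] = {
                "r_G": {"mean": rg.mean, "ci95": rg.ci95, "ess": rg.ess},
                "dic": biv.dic,
            }
            biv.draws.to_csv(stage_dir / "draws_bivariate.csv", index=False)
        (stage_dir / "animal.json").write_text(
            json.dumps(animal, indent=2, default=float)
        )
        report["stages"]["animal"] = animal
    except Exception as exc:
        raise StageError("animal", exc) from exc

    # --- selection --------------------------------------------------------
    stage_dir = out / "selection"
    stage_dir.mkdir(exist_ok=True)
    if config.fitness is None or not Path(config.fitness).exists():
        logger.warning("no fitness table; selection stage skipped")
        report["stages"]["selection"] = None
    else:
        try:
            fitness = pd.read_csv(config.fitness)
            sel = estimate_selection(
                phenotypes,
                fitness,
                trait_cols,
                n_boot=config.n_boot,
                seed=RunConfig.stage_seed(config, "selection"),
            )
            sel_json: dict = {"differentials": {}, "gradients": None}
            frames = []
            for t, coeffs in sel["differentials"].items():
                df = coeffs.to_frame()
                frames.append(df)
                sel_json["differentials"][t] = df.to_dict(orient="records")
            if sel["gradients"] is not None:
                df = sel["gradients"].to_frame()
                frames.append(df)
                sel_json["gradients"] = df.to_dict(orient="records")
            pd.concat(frames).to_csv(stage_dir / "coefficients.csv", index=False)
            (stage_dir / "selection.json").write_text(
                json.dumps(sel_json, indent=2, default=float)
            )
            report["stages"]["selection"] = sel_json
        except Exception as exc:
            raise StageError("selection", exc) from exc

    # --- power ------------------------------------------------------------
    stage_dir = out / "power"
    stage_dir.mkdir(exist_ok=True)
    try:
        n = grm.n
        var_rel_emp = var_rel_from_grm(grm)
        powers: dict = {
            "n": n,
            "var_rel_default": DEFAULT_VAR_REL,
            "var_rel_empirical": var_rel_emp,
            "h2": {},
        }
        for h2v in config.power_h2_values:
            powers["h2"][str(h2v)] = {
                "default": greml_power_h2(PowerSpec(n=n, h2=h2v)),
                "empirical": greml_power_h2(
                    PowerSpec(n=n, h2=h2v, var_rel=var_rel_emp)
                ),
            }
        uni = report["stages"]["animal"]["univariate"]
        if len(trait_cols) == 2:
            h2a = uni[trait_cols[0]]["h2"]["mean"]
            h2b = uni[trait_cols[1]]["h2"]["mean"]
            rg_est = (
                report["stages"]["animal"]["bivariate"]["r_G"]["mean"]
                if report["stages"]["animal"]["bivariate"]
                else 0.0
            )
            powers["rg"] = greml_power_rg(
                PowerSpec(
                    n=n, h2=max(h2a, 1e-6), h2_second=max(h2b, 1e-6),
                    rg=rg_est, var_rel=var_rel_emp,
                )
            )
        (stage_dir / "power.json").write_text(
            json.dumps(powers, indent=2, default=float)
        )
        report["stages"]["power"] = powers
    except Exception as exc:
        raise StageError("power", exc) from exc

    report["wall_time_s"] = time.time() - t_start
    write_report(report, out)
    return report


def _fmt_ci(d: dict) -> str:
    lo, hi = d["ci95"]
    return f"{d['mean']:.3f} [{lo:.3f}, {hi:.3f}]"


def write_report(report: dict, outdir) -> None:
    """Write ``report.json`` and a markdown rendering of the main tables."""
    outdir = Path(outdir)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=float)
    )
    lines = ["# wildqg pipeline report", ""]
    stages = report["stages"]
    if stages.get("qc"):
        qc = stages["qc"]
        lines += [
            "## Genotype QC",
            f"- loci: {qc['n_loci_in']} -> {qc['n_loci_out']} "
            f"(call rate {qc['loci_removed_call_rate']}, MAF {qc['loci_removed_maf']}, "
            f"oHET {qc['loci_removed_ohet']})",
            f"- individuals: {qc['n_individuals_in']} -> {qc['n_individuals_out']}",
            "",
        ]
    if stages.get("grm"):
        g = stages["grm"]["overall"]
        lines += [
            "## Relatedness",
            f"- off-diagonal mean {g['mean']:.3f}, range [{g['min']:.2f}, "
            f"{g['max']:.2f}], fraction < 0.2: {g['frac_below_0.2']:.2f}",
            "",
        ]
    if stages.get("animal"):
        lines += [
            "## Genetic parameters (posterior mean [95% CI])",
            "",
            "| trait | naive h2 | final h2 | evolvability e |",
            "|---|---|---|---|",
        ]
        for t, entry in stages["animal"]["univariate"].items():
            naive = entry.get("naive")
            lines.append(
                f"| {t} | "
                + (_fmt_ci(naive["h2"]) if naive else "—")
                + f" | {_fmt_ci(entry['h2'])} | "
                + f"{entry['evolvability_pct']['mean']:.2f}% "
                + "[{:.2f}, {:.2f}] |".format(*entry["evolvability_pct"]["ci95"])
            )
        if stages["animal"].get("bivariate"):
            lines.append("")
            lines.append(f"- r_G = {_fmt_ci(stages['animal']['bivariate']['r_G'])}")
        lines.append("")
    if stages.get("selection"):
        lines += [
            "## Selection coefficients (estimate ± SE, bootstrap p)",
            "",
            "| term | estimate | SE | p |",
            "|---|---|---|---|",
        ]
        sel = stages["selection"]
        rows = []
        for t, recs in sel["differentials"].items():
            rows += recs
        if sel.get("gradients"):
            rows += sel["gradients"]
        for r in rows:
            se = "—" if r["se"] is None else f"{r['se']:.3f}"
            p = "—" if r["p"] is None else f"{r['p']:.3f}"
            lines.append(f"| {r['term']} | {r['estimate']:.4f} | {se} | {p} |")
        lines.append("")
    if stages.get("describe"):
        d = stages["describe"]
        lines += ["## Descriptive", ""]
        for t, e in d["traits"].items():
            part = e["partition"]
            lines.append(
                f"- {t}: site {part['site_pct']:.0f}% / individual "
                f"{part['individual_pct']:.0f}% / within {part['within_pct']:.0f}%, "
                f"R = {e['repeatability_pct']:.0f}%, CV = {e['cv_pct']:.1f}%"
            )
        if "phenotypic_correlation" in d:
            pc = d["phenotypic_correlation"]
            lines.append(
                f"- phenotypic correlation r = {pc['r']:.2f} (p = {pc['p']:.2g})"
            )
        if d.get("visitation"):
            v = d["visitation"]
            lines.append(
                f"- visitation: {v['rate_per_flower_per_census']:.3f} visits/"
                f"flower/census; one visit every {v['waiting_time_h']} h; "
                f"shares {v['taxon_share_pct']}"
            )
        lines.append("")
    if stages.get("power"):
        p = stages["power"]
        lines += ["## Power", ""]
        for h2v, entry in p["h2"].items():
            lines.append(
                f"- h2 = {h2v}: power {entry['default']['power']:.2f} "
                f"(var_rel {p['var_rel_default']:.1e}), "
                f"{entry['empirical']['power']:.2f} (empirical "
                f"{p['var_rel_empirical']:.2e})"
            )
        if "rg" in p:
            lines.append(f"- r_G power: {p['rg']['power']:.2f}")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
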