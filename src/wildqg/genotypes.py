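"""Genotype containers, input parsing and SNP/individual quality control.

The analysis substrate is an individuals x loci dosage matrix (counts of the
alternate allele, 0/1/2, with missing calls allowed).  Genotypes arrive either
as a biallelic VCF (GT field) or as a plain TSV dosage table.  QC mirrors the
usual GBS filtering sequence: locus call rate, minor-allele frequency,
individual call rate, and observed-heterozygosity bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: accepted spellings for a missing dosage in TSV input
MISSING_TOKENS = {"NA", "na", "NaN", "nan", ".", "./.", ""}


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class EmptyGenotypeError(ValueError):
    """Raised when parsing or filtering leaves no individuals or loci."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix with optional missing entries.

    Dosages are stored as float with ``np.nan`` marking missing calls; observed
    values are restricted to {0, 1, 2}.  ``sites`` carries the site-of-origin
    label per individual when known (used downstream for relatedness summaries
    and the animal model's site effect).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray  # (n_individuals, n_loci) float, nan = missing
    sites: np.ndarray | None = None  # (n_individuals,) labels
    imputed: bool = False  # fractional mean-dosage entries allowed if True

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.locus_ids) != m:
            raise ValueError("dimension mismatch between ids and dosage matrix")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual IDs")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus IDs")
        obs = self.dosages[~np.isnan(self.dosages)]
        if self.imputed:
            if obs.size and ((obs < 0) | (obs > 2)).any():
                raise ValueError("dosages must lie in [0, 2]")
        elif obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.sites is not None:
            self.sites = np.asarray(self.sites)
            if self.sites.shape[0] != n:
                raise ValueError("sites length does not match individuals")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.individual_ids, columns=self.locus_ids
        )

    def write_tsv(self, path) -> None:
        """Write as TSV: rows = individuals, header = locus IDs, NA = missing.

        A ``site`` column is included right after the index when available.
        """
        df = self.to_dataframe()
        out = df.copy()
        if self.sites is not None:
            out.insert(0, "site", self.sites)
        out.index.name = "individual_id"
        out.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes(path, format: str = "auto", sites: dict | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (biallelic GT records) or a TSV dosage table.

    Multiallelic VCF records are skipped with a logged count.  ``sites`` may
    map individual IDs to site labels (VCFs carry no site metadata).
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "dosage_table"
    if format == "vcf":
        g = _read_vcf(path)
    elif format == "dosage_table":
        g = _read_dosage_table(path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    if sites is not None:
        g.sites = np.asarray([sites.get(i) for i in g.individual_ids])
    return g


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise GenotypeParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise EmptyGenotypeError(f"VCF {path} contains no samples")
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    # cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    code_to_dose = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] in (".", ""):
            n_multiallelic += 1
            continue
        columns.append(code_to_dose[np.asarray(var.gt_types)])
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        locus_ids.append(name)
    if n_multiallelic:
        logger.warning("skipped %d non-biallelic VCF records", n_multiallelic)
    if not locus_ids:
        raise EmptyGenotypeError(f"VCF {path} contains no biallelic records")
    return GenotypeMatrix(samples, locus_ids, np.column_stack(columns))


def _read_dosage_table(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
    except Exception as exc:
        raise GenotypeParseError(f"cannot parse dosage table {path}: {exc}") from exc
    if df.empty:
        raise EmptyGenotypeError(f"dosage table {path} has no individuals")
    sites = None
    if "site" in df.columns:
        sites = df.pop("site").to_numpy()
    mat = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        vals = df[col].to_numpy()
        for i, v in enumerate(vals):
            if v in MISSING_TOKENS:
                mat[i, j] = np.nan
            else:
                try:
                    mat[i, j] = float(v)
                except ValueError as exc:
                    raise GenotypeParseError(
                        f"{path}: bad dosage {v!r} at row {df.index[i]!r}, "
                        f"locus {col!r} (line {i + 2})"
                    ) from exc
    return GenotypeMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], mat, sites
    )


# ---------------------------------------------------------------------------
# per-locus statistics


def compute_locus_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus call rate, folded minor-allele frequency and observed het.

    MAF and oHET are computed from non-missing calls only; loci with zero
    calls get ``call_rate`` 0 and NaN (undefined) for the other two.
    """
    if g.n_individuals < 1:
        raise EmptyGenotypeError("no individuals")
    d = g.dosages
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    call_rate = n_called / g.n_individuals
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / np.where(n_called > 0, 2 * n_called, np.nan)
        maf = np.minimum(p, 1 - p)
        ohet = np.nansum(d == 1, axis=0) / np.where(n_called > 0, n_called, np.nan)
    return pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "ohet": ohet}, index=g.locus_ids
    )


# ---------------------------------------------------------------------------
# QC filtering


@dataclass
class QCReport:
    """Per-step removal counts from :func:`apply_qc_filters`.

    The steps run in the order listed; oHET is recomputed on the individuals
    and loci surviving the first three filters, so reordering would change the
    outcome — the per-step counts make that visible.
    """

    n_individuals_in: int
    n_loci_in: int
    loci_removed_call_rate: int = 0
    loci_removed_maf: int = 0
    individuals_removed_call_rate: int = 0
    loci_removed_ohet: int = 0
    n_individuals_out: int = 0
    n_loci_out: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def loci_removed(self) -> int:
        return (
            self.loci_removed_call_rate
            + self.loci_removed_maf
            + self.loci_removed_ohet
        )

    @property
    def individuals_removed(self) -> int:
        return self.individuals_removed_call_rate

    def to_dict(self) -> dict:
        return {
            "n_individuals_in": self.n_individuals_in,
            "n_loci_in": self.n_loci_in,
            "loci_removed_call_rate": self.loci_removed_call_rate,
            "loci_removed_maf": self.loci_removed_maf,
            "individuals_removed_call_rate": self.individuals_removed_call_rate,
            "loci_removed_ohet": self.loci_removed_ohet,
            "loci_removed": self.loci_removed,
            "individuals_removed": self.individuals_removed,
            "n_individuals_out": self.n_individuals_out,
            "n_loci_out": self.n_loci_out,
            "thresholds": self.thresholds,
        }


def apply_qc_filters(
    g: GenotypeMatrix,
    locus_call_rate_min: float = 0.90,
    maf_min: float = 0.01,
    indiv_call_rate_min: float = 0.85,
    ohet_bounds: tuple[float, float] = (0.02, 0.98),
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the SNP/individual QC filters in their stated order.

    Order: (1) locus call rate >= ``locus_call_rate_min``; (2) MAF >
    ``maf_min``; (3) individual call rate >= ``indiv_call_rate_min``;
    (4) oHET within ``ohet_bounds`` (exclusive), recomputed on the survivors.
    """
    for t in (locus_call_rate_min, maf_min, indiv_call_rate_min, *ohet_bounds):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    report = QCReport(
        g.n_individuals,
        g.n_loci,
        thresholds={
            "locus_call_rate_min": locus_call_rate_min,
            "maf_min": maf_min,
            "indiv_call_rate_min": indiv_call_rate_min,
            "ohet_bounds": list(ohet_bounds),
        },
    )
    stats = compute_locus_stats(g)

    keep_loci = stats["call_rate"].to_numpy() >= locus_call_rate_min
    report.loci_removed_call_rate = int((~keep_loci).sum())

    maf = stats["maf"].to_numpy()
    fails_maf = keep_loci & ~(maf > maf_min)
    report.loci_removed_maf = int(fails_maf.sum())
    keep_loci &= ~fails_maf

    d = g.dosages[:, keep_loci]
    if d.shape[1] == 0:
        raise EmptyGenotypeError("all loci removed by QC")
    ind_call = (~np.isnan(d)).mean(axis=1)
    keep_ind = ind_call >= indiv_call_rate_min
    report.individuals_removed_call_rate = int((~keep_ind).sum())
    if not keep_ind.any():
        raise EmptyGenotypeError("all individuals removed by QC")

    survivors = GenotypeMatrix(
        [i for i, k in zip(g.individual_ids, keep_ind) if k],
        [l for l, k in zip(g.locus_ids, keep_loci) if k],
        g.dosages[np.ix_(keep_ind, keep_loci)],
        g.sites[keep_ind] if g.sites is not None else None,
    )
    # oHET recomputed on the surviving individuals/loci
    ohet = compute_locus_stats(survivors)["ohet"].to_numpy()
    lo, hi = ohet_bounds
    with np.errstate(invalid="ignore"):
        keep_ohet = np.where(np.isnan(ohet), True, (ohet >= lo) & (ohet <= hi))
    report.loci_removed_ohet = int((~keep_ohet).sum())
    if not keep_ohet.any():
        raise EmptyGenotypeError("all loci removed by oHET filter")
    out = GenotypeMatrix(
        survivors.individual_ids,
        [l for l, k in zip(survivors.locus_ids, keep_ohet) if k],
        survivors.dosages[:, keep_ohet],
        survivors.sites,
    )
    report.n_individuals_out = out.n_individuals
    report.n_loci_out = out.n_loci
    logger.info(
        "QC: %d/%d loci and %d/%d individuals retained",
        out.n_loci, g.n_loci, out.n_individuals, g.n_individuals,
    )
    return out, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the locus mean dosage (2 * allele freq).

    This is the allele-frequency expectation used by realized-relatedness
    software; it leaves observed column means unchanged.  Loci with zero
    calls cannot be imputed and raise (they should have been filtered).
    """
    d = g.dosages
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        bad = [l for l, n in zip(g.locus_ids, n_called) if n == 0]
        raise ValueError(f"loci with zero calls cannot be imputed: {bad[:5]}")
    if called.all():
        return replace(g, imputed=True)
    col_mean = np.nansum(d, axis=0) / n_called
    filled = np.where(called, d, col_mean[None, :])
    return replace(g, dosages=filled, imputed=True)
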