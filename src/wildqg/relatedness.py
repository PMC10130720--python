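"""Genome-wide realized relatedness (VanRaden GRM) and its summaries.

The GRM measures excess allele sharing between pairs relative to the sampled
population: each locus is centred by twice its sample allele frequency and the
cross-product matrix is scaled by a single global denominator
``2 * sum_k p_k (1 - p_k)`` (VanRaden "method 1").  Off-diagonal values can be
negative — pairs sharing fewer alleles than expected given the sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RelatednessMatrix:
    """Symmetric realized-relatedness matrix over a set of individuals."""

    individual_ids: list[str]
    values: np.ndarray  # (n, n) symmetric
    n_loci_used: int
    ridge: float = 0.0  # diagonal ridge added by stabilize_for_inversion

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match number of individuals")
        if not np.isfinite(self.values).all():
            raise ValueError("GRM contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal values as a flat array."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, ids: list[str]) -> "RelatednessMatrix":
        """Reorder/subset to the given individual IDs (all must be present)."""
        index = {v: i for i, v in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"individuals absent from GRM: {missing[:10]}")
        idx = np.array([index[i] for i in ids])
        return RelatednessMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.n_loci_used, self.ridge
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def read_grm_tsv(path) -> RelatednessMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    vals = (vals + vals.T) / 2.0  # symmetrize away text round-off
    return RelatednessMatrix([str(i) for i in df.index], vals, n_loci_used=0)


def vanraden_grm(g: GenotypeMatrix) -> RelatednessMatrix:
    """VanRaden method-1 GRM from a complete dosage matrix.

    ``G = Z Z' / (2 * sum_k p_k (1 - p_k))`` with ``Z`` the dosage matrix
    centred by ``2 p_k`` and allele frequencies estimated from the sample
    itself.  Monomorphic loci carry no information and are excluded from both
    numerator and denominator (logged).
    """
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("dosage matrix contains missing values; impute first")
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals for a GRM")
    p = d.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("excluding %d monomorphic loci from GRM", n_mono)
    if not poly.any():
        raise ValueError("all loci monomorphic; GRM undefined")
    z = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    values = (z @ z.T) / denom
    values = (values + values.T) / 2.0
    return RelatednessMatrix(
        list(g.individual_ids), values, n_loci_used=int(poly.sum())
    )


def relatedness_summary(
    grm: RelatednessMatrix, site_labels=None, threshold: float = 0.2
) -> dict:
    """Overall and within-site summaries of pairwise relatedness."""
    off = grm.off_diagonal()

    def _stats(x: np.ndarray) -> dict:
        q = np.quantile(x, [0.025, 0.25, 0.5, 0.75, 0.975])
        return {
            "n_pairs": int(x.size),
            "min": float(x.min()),
            "max": float(x.max()),
            "mean": float(x.mean()),
            "q2.5": float(q[0]),
            "q25": float(q[1]),
            "median": float(q[2]),
            "q75": float(q[3]),
            "q97.5": float(q[4]),
            f"frac_below_{threshold}": float((x < threshold).mean()),
        }

    out = {
        "overall": _stats(off),
        "diagonal_mean": float(np.diag(grm.values).mean()),
        "n_loci_used": grm.n_loci_used,
    }
    if site_labels is not None:
        site_labels = np.asarray(site_labels)
        if site_labels.shape[0] != grm.n:
            raise ValueError("site labels do not align with GRM individuals")
        within = {}
        for s in pd.unique(site_labels):
            idx = np.flatnonzero(site_labels == s)
            if idx.size < 2:
                continue
            sub = grm.values[np.ix_(idx, idx)]
            within[str(s)] = _stats(sub[np.triu_indices(idx.size, k=1)])
        out["within_site"] = within
    return out


def stabilize_for_inversion(
    grm: RelatednessMatrix, ridge: float = 1e-6, min_eigenvalue: float = 1e-8
) -> RelatednessMatrix:
    """Add a diagonal ridge until the smallest eigenvalue exceeds a tolerance.

    The animal model needs ``G`` invertible; duplicated individuals or more
    individuals than markers make the raw GRM rank deficient.  The applied
    ridge is recorded on the returned matrix.
    """
    w = np.linalg.eigvalsh(grm.values)
    lam = float(w[0])
    applied = 0.0
    values = grm.values
    if lam < min_eigenvalue:
        applied = max(ridge, min_eigenvalue - lam)
        values = values + applied * np.eye(grm.n)
        logger.info(
            "GRM stabilized: min eigenvalue %.3g, ridge %.3g applied", lam, applied
        )
    return RelatednessMatrix(
        list(grm.individual_ids), values, grm.n_loci_used, ridge=applied
    )
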