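"""Genotype parsing, per-locus statistics, QC filtering and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wildqg.genotypes import (
    EmptyGenotypeError,
    GenotypeMatrix,
    GenotypeParseError,
    apply_qc_filters,
    compute_locus_stats,
    impute_missing,
    read_genotypes,
)


def brute_force_locus_stats(dosages: np.ndarray) -> pd.DataFrame:
    """Independent per-locus tally with explicit loops."""
    rows = []
    n = dosages.shape[0]
    for j in range(dosages.shape[1]):
        col = [d for d in dosages[:, j] if not np.isnan(d)]
        if not col:
            rows.append({"call_rate": 0.0, "maf": np.nan, "ohet": np.nan})
            continue
        p = sum(col) / (2 * len(col))
        rows.append(
            {
                "call_rate": len(col) / n,
                "maf": min(p, 1 - p),
                "ohet": sum(1 for d in col if d == 1) / len(col),
            }
        )
    return pd.DataFrame(rows)


class TestReading:
    def test_vcf_toy(self, toy_vcf):
        g = read_genotypes(toy_vcf, "vcf")
        assert g.individual_ids == ["indA", "indB", "indC"]
        # triallelic snp2 skipped
        assert g.locus_ids == ["snp1", "snp3"]
        np.testing.assert_array_equal(g.dosages[:, 0], [0, 1, 2])
        assert np.isnan(g.dosages[0, 1]) and g.dosages[2, 1] == 0

    def test_dosage_table_with_na(self, toy_dosage_tsv):
        g = read_genotypes(toy_dosage_tsv, "dosage_table")
        assert g.n_individuals == 3 and g.n_loci == 3
        assert np.isnan(g.dosages[0, 2])
        assert list(g.sites) == ["site1", "site1", "site2"]

    def test_roundtrip_tsv(self, tmp_path, study):
        path = tmp_path / "g.tsv"
        study.genotypes.write_tsv(path)
        g2 = read_genotypes(path, "dosage_table")
        np.testing.assert_array_equal(
            study.genotypes.dosages, g2.dosages
        )
        assert g2.individual_ids == study.genotypes.individual_ids

    def test_bad_dosage_names_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tsnp1\nindA\t0\nindB\tfoo\n")
        with pytest.raises(GenotypeParseError, match="snp1"):
            read_genotypes(path, "dosage_table")

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("id\tsnp1\n")
        with pytest.raises(EmptyGenotypeError):
            read_genotypes(path, "dosage_table")

    def test_invalid_dosage_value_rejected(self):
        with pytest.raises(ValueError, match="dosages"):
            GenotypeMatrix(["a"], ["l1"], np.array([[3.0]]))


class TestLocusStats:
    def test_direct_counts(self):
        g = GenotypeMatrix(["a", "b", "c"], ["l1"], np.array([[0.0], [1.0], [2.0]]))
        s = compute_locus_stats(g)
        assert s.loc["l1", "maf"] == 0.5
        assert s.loc["l1", "ohet"] == pytest.approx(1 / 3)
        assert s.loc["l1", "call_rate"] == 1.0

    def test_missing_calls(self):
        g = GenotypeMatrix(
            ["a", "b", "c"], ["l1"], np.array([[0.0], [0.0], [np.nan]])
        )
        s = compute_locus_stats(g)
        assert s.loc["l1", "call_rate"] == pytest.approx(2 / 3)
        assert s.loc["l1", "maf"] == 0.0

    def test_matches_brute_force(self, rng):
        d = rng.integers(0, 3, size=(25, 10)).astype(float)
        d[rng.random(d.shape) < 0.2] = np.nan
        g = GenotypeMatrix(
            [f"i{k}" for k in range(25)], [f"l{j}" for j in range(10)], d
        )
        fast = compute_locus_stats(g).reset_index(drop=True)
        slow = brute_force_locus_stats(d)
        pd.testing.assert_frame_equal(fast, slow, check_exact=False)


def _qc_toy():
    """6 individuals x 5 loci; one locus fails each rule, one individual
    fails call rate after locus filtering."""
    M = np.nan
    d = np.array(
        [
            # l_ok   l_call  l_maf  l_het  l_ok2
            [0.0,    M,      0.0,   1.0,   0.0],
            [1.0,    M,      0.0,   1.0,   2.0],
            [2.0,    M,      0.0,   1.0,   1.0],
            [0.0,    0.0,    0.0,   1.0,   2.0],
            [1.0,    1.0,    0.0,   1.0,   0.0],
            [0.0,    2.0,    0.0,   1.0,   M],  # low individual call rate
        ]
    )
    return GenotypeMatrix(
        [f"i{k}" for k in range(6)],
        ["l_ok", "l_call", "l_maf", "l_het", "l_ok2"],
        d,
    )


class TestQCFilters:
    def test_constructed_counts(self):
        g = _qc_toy()
        out, rep = apply_qc_filters(
            g,
            locus_call_rate_min=0.8,
            maf_min=0.01,
            indiv_call_rate_min=0.85,
            ohet_bounds=(0.02, 0.98),
        )
        assert rep.loci_removed_call_rate == 1  # l_call (3/6 called)
        assert rep.loci_removed_maf == 1  # l_maf monomorphic
        assert rep.individuals_removed_call_rate == 1  # i5: 2/3 called
        assert rep.loci_removed_ohet == 1  # l_het: all heterozygous
        assert rep.loci_removed == 3
        assert rep.individuals_removed == 1
        assert out.n_loci == 2 and out.n_individuals == 5

    def test_identity_thresholds(self, study):
        g = study.genotypes
        out, rep = apply_qc_filters(
            g, locus_call_rate_min=0.0, maf_min=0.0,
            indiv_call_rate_min=0.0, ohet_bounds=(0.0, 1.0),
        )
        assert out.n_loci == g.n_loci
        assert out.n_individuals == g.n_individuals
        np.testing.assert_array_equal(out.dosages, g.dosages)

    def test_matches_brute_force_on_missing_study(self):
        from wildqg.simulate import SimulationConfig, simulate_genotypes

        g = simulate_genotypes(
            SimulationConfig(seed=77, n_loci=300, missing_rate=0.05)
        )
        out, rep = apply_qc_filters(g)
        # naive loop oracle, same filter order
        d = g.dosages
        keep_l = []
        for j in range(g.n_loci):
            col = d[:, j]
            called = col[~np.isnan(col)]
            cr = called.size / g.n_individuals
            p = called.sum() / (2 * called.size) if called.size else 0.0
            keep_l.append(cr >= 0.90 and min(p, 1 - p) > 0.01)
        d2 = d[:, keep_l]
        keep_i = [
            (~np.isnan(d2[i])).sum() / d2.shape[1] >= 0.85
            for i in range(d2.shape[0])
        ]
        d3 = d2[keep_i]
        keep_l2 = []
        for j in range(d3.shape[1]):
            col = d3[:, j]
            called = col[~np.isnan(col)]
            ohet = (called == 1).sum() / called.size
            keep_l2.append(0.02 <= ohet <= 0.98)
        assert out.n_individuals == sum(keep_i)
        assert out.n_loci == sum(keep_l2)

    def test_idempotent(self):
        from wildqg.simulate import SimulationConfig, simulate_genotypes

        g = simulate_genotypes(
            SimulationConfig(seed=78, n_loci=200, missing_rate=0.08)
        )
        once, _ = apply_qc_filters(g)
        twice, rep2 = apply_qc_filters(once)
        assert twice.n_loci == once.n_loci
        assert twice.n_individuals == once.n_individuals
        assert rep2.loci_removed == 0 and rep2.individuals_removed == 0

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(
        call=st.floats(0.0, 0.95),
        maf=st.floats(0.0, 0.3),
        ind=st.floats(0.0, 0.95),
    )
    def test_monotone_per_step(self, call, maf, ind):
        """Each filter step is monotone in its own threshold.

        (Whole-pipeline survivor counts are *not* jointly monotone: removing
        more loci changes the base on which individual call rates and oHET
        are recomputed — which is why the report carries per-step counts.)
        """
        from wildqg.simulate import SimulationConfig, simulate_genotypes

        g = simulate_genotypes(
            SimulationConfig(seed=79, n_loci=150, missing_rate=0.1,
                             plants_per_site=10)
        )
        base_args = {
            "locus_call_rate_min": call,
            "maf_min": maf,
            "indiv_call_rate_min": ind,
        }
        try:
            _, rep0 = apply_qc_filters(g, **base_args)
        except EmptyGenotypeError:
            return
        for key, step_attr in (
            ("locus_call_rate_min", "loci_removed_call_rate"),
            ("maf_min", "loci_removed_maf"),
            ("indiv_call_rate_min", "individuals_removed_call_rate"),
        ):
            args = dict(base_args)
            args[key] = min(args[key] + 0.05, 1.0)
            try:
                _, rep1 = apply_qc_filters(g, **args)
            except EmptyGenotypeError:
                continue
            assert getattr(rep1, step_attr) >= getattr(rep0, step_attr)

    def test_all_removed_raises(self):
        g = _qc_toy()
        with pytest.raises(EmptyGenotypeError):
            apply_qc_filters(g, maf_min=0.5)


class TestImputation:
    def test_mean_fill(self):
        g = GenotypeMatrix(
            ["a", "b", "c"], ["l1"], np.array([[0.0], [2.0], [np.nan]])
        )
        out = impute_missing(g)
        assert out.dosages[2, 0] == 1.0
        assert not np.isnan(out.dosages).any()

    def test_complete_unchanged(self, study):
        out = impute_missing(study.genotypes)
        np.testing.assert_array_equal(out.dosages, study.genotypes.dosages)

    def test_column_means_preserved(self, rng):
        d = rng.integers(0, 3, (30, 8)).astype(float)
        d[rng.random(d.shape) < 0.25] = np.nan
        g = GenotypeMatrix(
            [f"i{k}" for k in range(30)], [f"l{j}" for j in range(8)], d
        )
        out = impute_missing(g)
        np.testing.assert_allclose(
            out.dosages.mean(axis=0), np.nanmean(d, axis=0)
        )

    def test_zero_call_locus_raises(self):
        g = GenotypeMatrix(["a", "b"], ["l1"], np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValueError, match="zero calls"):
            impute_missing(g)
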