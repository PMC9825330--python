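import numpy as np
import pytest

from comorbnet.assoc import (
    AssociationRecord,
    PhenotypeMeta,
    apply_phenotype_filters,
    apply_significance_filter,
    assemble_matrix,
    greedy_ld_prune,
    read_summary_stats,
)

HEADER = "phecode\tsnp\tchrom\tpos\tbeta\tse\tpval\n"


def rec(pheno="250.2", snp="rs1", chrom="1", pos=1000, beta=0.5, se=0.25, pval=1e-6):
    return AssociationRecord(pheno, snp, chrom, pos, beta, se, pval)


class TestReadSummaryStats:
    def test_header_only_file_yields_empty_list(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(HEADER)
        records, report = read_summary_stats(path)
        assert records == []
        assert report.n_rows == 0

    def test_z_score_is_beta_over_se(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(HEADER + "250.2\trs1\t1\t1000\t0.5\t0.25\t1e-6\n")
        records, _ = read_summary_stats(path)
        assert len(records) == 1
        assert records[0].z == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "row, reason",
        [
            ("250.2\trs1\t1\t1000\t0.5\t0\t1e-6\n", "se<=0"),
            ("250.2\trs1\t1\t1000\tx\t0.25\t1e-6\n", "unparseable"),
            ("250.2\trs1\t1\t1000\t0.5\t0.25\t1.5\n", "pval outside (0,1]"),
        ],
    )
    def test_invalid_rows_skipped_and_counted(self, tmp_path, row, reason):
        path = tmp_path / "s.tsv"
        path.write_text(HEADER + row)
        records, report = read_summary_stats(path)
        assert records == []
        assert report.n_skipped == 1
        assert report.skip_reasons[reason] == 1

    def test_unknown_schema_column_is_fatal(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(HEADER)
        with pytest.raises(ValueError, match="nope"):
            read_summary_stats(path, schema={"beta": "nope"})


class TestPhenotypeFilters:
    META = {
        "a": PhenotypeMeta("a", "A", "circulatory system", 999),
        "b": PhenotypeMeta("b", "B", "circulatory system", 1000),
        "c": PhenotypeMeta("c", "C", "injuries & poisonings", 50000),
    }

    def test_case_count_boundary(self):
        records = [rec(pheno="a"), rec(pheno="b")]
        kept = apply_phenotype_filters(records, self.META)
        assert [r.phenotype_id for r in kept] == ["b"]  # <1000 removed, ==1000 kept

    def test_excluded_category_removed_regardless_of_cases(self):
        assert apply_phenotype_filters([rec(pheno="c")], self.META) == []

    def test_unknown_phenotype_is_fatal_with_id(self):
        with pytest.raises(ValueError, match="zzz"):
            apply_phenotype_filters([rec(pheno="zzz")], self.META)


class TestSignificanceFilter:
    def test_strict_threshold(self):
        records = [rec(snp="rs1", pval=9.9e-5), rec(snp="rs2", pval=1e-4)]
        kept = apply_significance_filter(records)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_all_pass_is_identity(self):
        records = [rec(pval=1e-9), rec(snp="rs2", pval=1e-8)]
        assert apply_significance_filter(records) == records

    def test_bad_alpha_is_fatal(self):
        with pytest.raises(ValueError):
            apply_significance_filter([], alpha=0)


class TestGreedyLdPrune:
    def test_empty_input(self):
        assert greedy_ld_prune([], {}) == set()

    def test_correlated_pair_keeps_more_significant(self):
        variants = [
            ("v1", "1", 1000, 1e-6),
            ("v2", "1", 20000, 1e-5),
            ("v3", "1", 60000, 1e-3),
        ]
        r2 = {frozenset(("v1", "v2")): 0.6}
        assert greedy_ld_prune(variants, r2) == {"v1", "v3"}

    def test_cross_chromosome_pairs_never_compared(self):
        variants = [("v1", "1", 1000, 1e-6), ("v2", "2", 1000, 1e-5)]
        r2 = {frozenset(("v1", "v2")): 0.99}
        assert greedy_ld_prune(variants, r2) == {"v1", "v2"}

    def test_tie_broken_by_larger_position(self):
        variants = [("v1", "1", 1000, 1e-6), ("v2", "1", 2000, 1e-6)]
        r2 = {frozenset(("v1", "v2")): 0.9}
        assert greedy_ld_prune(variants, r2) == {"v1"}

    def test_unknown_r2_treated_as_independent(self):
        variants = [("v1", "1", 1000, 1e-6), ("v2", "1", 2000, 1e-5)]
        assert greedy_ld_prune(variants, {}) == {"v1", "v2"}

    def test_result_invariant_to_input_order(self, rng):
        variants = [(f"v{i}", "1", int(p), float(mp)) for i, (p, mp) in
                    enumerate(zip(rng.integers(1, 200_000, 40),
                                  rng.uniform(1e-8, 1e-3, 40)))]
        pairs = {frozenset((a[0], b[0])): float(r)
                 for a, b, r in zip(variants[::2], variants[1::2], rng.random(20))}
        base = greedy_ld_prune(variants, pairs)
        for _ in range(3):
            shuffled = list(variants)
            rng.shuffle(shuffled)
            assert greedy_ld_prune(shuffled, pairs) == base

    def test_negative_position_fatal(self):
        with pytest.raises(ValueError):
            greedy_ld_prune([("v1", "1", -5, 1e-6)], {})


class TestAssembleMatrix:
    def test_single_record(self):
        M = assemble_matrix([rec(pheno="D1", snp="rs1", beta=0.5, se=0.25)])
        assert M.shape == (1, 1)
        assert M.values[0, 0] == pytest.approx(2.0)

    def test_sparsity_bookkeeping(self):
        records = [
            rec(pheno="D1", snp="rs1"), rec(pheno="D1", snp="rs2"),
            rec(pheno="D2", snp="rs1"),
        ]
        M = assemble_matrix(records)
        assert M.shape == (2, 2)
        assert M.values.nnz == 3

    def test_unretained_snp_excluded(self):
        M = assemble_matrix([rec(snp="rs1"), rec(snp="rs2")], retained_snps={"rs1"})
        assert M.snps == ["rs1"]

    def test_duplicate_key_fatal(self):
        with pytest.raises(ValueError, match="rs1"):
            assemble_matrix([rec(), rec(beta=0.1)])

    def test_filter_composition_order_independent(self):
        meta = {"a": PhenotypeMeta("a", "A", "x", 2000),
                "b": PhenotypeMeta("b", "B", "x", 10)}
        records = [rec(pheno="a", pval=1e-6), rec(pheno="a", snp="rs2", pval=0.5),
                   rec(pheno="b", pval=1e-9)]
        ab = apply_significance_filter(apply_phenotype_filters(records, meta))
        ba = apply_phenotype_filters(apply_significance_filter(records), meta)
        assert ab == ba

    def test_write_read_round_trip_exact(self, tmp_path, rng):
        records = [rec(pheno=f"D{i}", snp=f"rs{k}", beta=float(b), se=float(s))
                   for i, k, b, s in zip(rng.integers(0, 5, 30).tolist(),
                                         rng.integers(0, 20, 30).tolist(),
                                         rng.normal(size=30),
                                         rng.uniform(0.01, 0.2, 30))]
        uniq = {(r.phenotype_id, r.snp_id): r for r in records}
        M = assemble_matrix(uniq.values())
        M.write(tmp_path / "m")
        M2 = M.read(tmp_path / "m")
        assert M2.phenotypes == M.phenotypes
        assert M2.snps == M.snps
        assert (M2.values != M.values).nnz == 0  # bit-exact
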