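"""IO round trips, validation errors, and technical-replicate collapse."""

import numpy as np
import pytest

from rgselect import errors
from rgselect.stability import GeNormResult, StabilityReport
from rgselect.tables_io import (
    CtMatrix,
    ExpressionMatrix,
    RunConfig,
    Sample,
    collapse_technical_replicates,
    read_ct_table,
    read_expression_table,
    read_report_scores,
    write_ct_table,
    write_expression_table,
    write_report,
)


@pytest.fixture
def expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        ["g1", "g2"], ["IM", "MG", "B"],
        np.array([[100.0, 200.0, 300.0], [400.0, 500.0, 600.0]]),
    )


def random_ct(rng, n_genes=4, missing=True) -> CtMatrix:
    samples = [
        Sample(f"{st}.b{b}.t{t}", st, b, t)
        for st in ("IM", "MG")
        for b in (1, 2)
        for t in (1, 2, 3)
    ]
    ct = rng.uniform(18, 30, (n_genes, len(samples)))
    if missing:
        ct[0, 3] = np.nan
        ct[2, 7] = np.nan
    return CtMatrix([f"g{i}" for i in range(n_genes)], samples, ct)


class TestExpressionTables:
    def test_round_trip_is_value_exact(self, expr, tmp_path):
        path = tmp_path / "expr.tsv"
        write_expression_table(expr, path)
        back = read_expression_table(path)
        assert back.gene_ids == expr.gene_ids
        assert back.condition_labels == expr.condition_labels
        np.testing.assert_array_equal(back.values, expr.values)

    def test_csv_dialect_accepted(self, expr, tmp_path):
        path = tmp_path / "expr.csv"
        write_expression_table(expr, path, sep=",")
        back = read_expression_table(path)
        np.testing.assert_array_equal(back.values, expr.values)

    @pytest.mark.parametrize(
        "content, exc",
        [
            ("gene\tIM\tMG\ng1\t100\t-5\n", errors.NegativeExpressionError),
            ("gene\tIM\tMG\ng1\t100\tabc\n", errors.NonNumericCellError),
            ("gene\tIM\tMG\ng1\t1\t2\ng1\t3\t4\n", errors.DuplicateGeneError),
        ],
    )
    def test_invalid_tables_raise_named_errors(self, tmp_path, content, exc):
        path = tmp_path / "bad.tsv"
        path.write_text(content)
        with pytest.raises(exc):
            read_expression_table(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(errors.MissingTableError):
            read_expression_table(tmp_path / "absent.tsv")


class TestCtTables:
    def test_constant_ct_long_read(self, tmp_path):
        lines = ["gene\tsample\tstage\tbio_rep\ttech_rep\tct"]
        for st in ("IM", "MG", "B", "MR"):
            for b in (1, 2, 3):
                lines.append(f"g1\t{st}.b{b}\t{st}\t{b}\t1\t25.0")
        path = tmp_path / "ct.tsv"
        path.write_text("\n".join(lines) + "\n")
        m = read_ct_table(path)
        assert m.n_genes == 1 and m.n_samples == 12
        np.testing.assert_array_equal(m.ct, np.full((1, 12), 25.0))

    def test_long_round_trip_full_precision(self, rng, tmp_path):
        m = random_ct(rng)
        path = tmp_path / "ct.tsv"
        write_ct_table(m, path)
        back = read_ct_table(path)
        assert back.gene_ids == m.gene_ids
        assert [s.triple for s in back.samples] == [s.triple for s in m.samples]
        np.testing.assert_array_equal(back.ct, m.ct)  # NaN positions included

    def test_wide_round_trip(self, rng, tmp_path):
        m = random_ct(rng)
        path = tmp_path / "ct_wide.tsv"
        write_ct_table(m, path, layout="wide")
        back = read_ct_table(path, layout="wide")
        np.testing.assert_allclose(back.ct, m.ct, rtol=0, atol=1e-12)

    def test_duplicate_gene_sample_pair_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "gene\tsample\tstage\tbio_rep\ttech_rep\tct\n"
            "g1\ts1\tIM\t1\t1\t25.0\n"
            "g1\ts1\tIM\t1\t1\t26.0\n"
        )
        with pytest.raises(errors.DuplicateSampleError):
            read_ct_table(path)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("gene\tsample\tstage\tbio_rep\ttech_rep\tct\tbogus\n")
        with pytest.raises(errors.UnknownColumnError):
            read_ct_table(path)

    def test_empty_and_na_cells_become_missing(self, tmp_path):
        path = tmp_path / "miss.tsv"
        path.write_text(
            "gene\tsample\tstage\tbio_rep\ttech_rep\tct\n"
            "g1\ts1\tIM\t1\t1\t\n"
            "g1\ts2\tIM\t2\t1\tNA\n"
            "g1\ts3\tIM\t3\t1\t24.5\n"
        )
        m = read_ct_table(path)
        assert np.isnan(m.ct[0, 0]) and np.isnan(m.ct[0, 1]) and m.ct[0, 2] == 24.5

    def test_implausible_ct_warns_but_loads(self):
        samples = [Sample("s1", "IM", 1, 1), Sample("s2", "IM", 2, 1)]
        with pytest.warns(UserWarning, match="plausible"):
            CtMatrix(["g1"], samples, np.array([[50.0, 25.0]]))


class TestCollapse:
    def test_mean_of_technical_replicates(self):
        samples = [Sample(f"t{t}", "IM", 1, t) for t in (1, 2, 3)]
        m = CtMatrix(["g1"], samples, np.array([[24.9, 25.0, 25.1]]))
        out = collapse_technical_replicates(m)
        assert out.n_samples == 1
        assert out.ct[0, 0] == pytest.approx(25.0)

    def test_single_replicate_unchanged(self):
        m = CtMatrix(["g1"], [Sample("s", "IM", 1, 1)], np.array([[23.7]]))
        out = collapse_technical_replicates(m)
        assert out.ct[0, 0] == 23.7

    def test_missing_replicates_excluded_from_mean(self):
        samples = [Sample(f"t{t}", "IM", 1, t) for t in (1, 2, 3)]
        m = CtMatrix(["g1"], samples, np.array([[24.0, np.nan, 26.0]]))
        assert collapse_technical_replicates(m).ct[0, 0] == pytest.approx(25.0)

    def test_all_missing_triple_stays_missing(self):
        samples = [Sample(f"t{t}", "IM", 1, t) for t in (1, 2)]
        m = CtMatrix(["g1"], samples, np.array([[np.nan, np.nan]]))
        assert np.isnan(collapse_technical_replicates(m).ct[0, 0])

    def test_idempotent(self, rng):
        m = random_ct(rng, missing=False)
        once = collapse_technical_replicates(m)
        twice = collapse_technical_replicates(once)
        np.testing.assert_array_equal(once.ct, twice.ct)
        assert [s.triple for s in once.samples] == [s.triple for s in twice.samples]


class TestRunConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"expr_min": 2000.0, "expr_max": 200.0},
            {"cv_max": 0.0},
            {"eff_min": 1.2},
            {"v_threshold": 1.5},
            {"amp_factor": 1.0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(errors.ConfigError):
            RunConfig(**kw)

    def test_yaml_round_trip_with_override(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("cv_max: 0.2\nk_top: 8\n")
        cfg = RunConfig.from_yaml(path, k_top=5)
        assert cfg.cv_max == 0.2 and cfg.k_top == 5

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("not_a_threshold: 1\n")
        with pytest.raises(errors.ConfigError):
            RunConfig.from_yaml(path)


def _empty_report() -> StabilityReport:
    empty_f = np.array([])
    empty_i = np.array([], dtype=int)
    gen = GeNormResult([], empty_f, [], ("", ""), [], empty_i, empty_f)
    return StabilityReport([], empty_f, empty_f, empty_f, empty_i, empty_i,
                           empty_i, empty_f, gen, None)


class TestReports:
    def test_empty_gene_set_gives_header_only_table(self, tmp_path):
        paths = write_report(_empty_report(), tmp_path)
        lines = paths["scores"].read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("gene")

    def test_report_round_trip_reproduces_scores(self, tmp_path):
        from rgselect import evaluate_stability, generate_ct_matrix

        m, _ = generate_ct_matrix(n_genes=8, seed=3)
        report = evaluate_stability(m)
        paths = write_report(report, tmp_path)
        back = read_report_scores(paths["scores"])
        np.testing.assert_allclose(back["genorm_m"].to_numpy(), report.genorm_m)
        np.testing.assert_allclose(back["whisker_d"].to_numpy(), report.whisker_d)
        np.testing.assert_allclose(
            back["normfinder_stability"].to_numpy(), report.normfinder
        )

    def test_summary_lists_exactly_the_consensus_selection(self, tmp_path):
        import json

        from rgselect import consensus_select, evaluate_stability, generate_ct_matrix

        m, _ = generate_ct_matrix(n_genes=10, seed=4)
        report = evaluate_stability(m)
        selection = consensus_select(report, k_top=5, min_methods=2)
        paths = write_report(report, tmp_path, selection)
        summary = json.loads(paths["summary_json"].read_text())
        assert summary["selected_genes"] == selection.selected
        assert summary["consensus_genes"] == selection.consensus
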