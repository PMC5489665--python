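"""Whisker D-value, boxplot summary, consensus selection, minimal RG count."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rgselect import errors
from rgselect.stability import (
    GeNormResult,
    StabilityReport,
    boxplot_summary,
    consensus_select,
    minimal_rg_count,
    whisker_d_value,
)

ct_vectors = st.lists(
    st.floats(min_value=15.0, max_value=35.0), min_size=2, max_size=20
)


class TestWhiskerD:
    def test_constant_vector_is_zero(self):
        assert whisker_d_value([24.0] * 5) == 0.0

    def test_plain_range(self):
        assert whisker_d_value([20.1, 20.5, 21.0]) == pytest.approx(0.9)

    def test_missing_values_ignored(self):
        assert whisker_d_value([20.0, np.nan, 22.5]) == pytest.approx(2.5)

    def test_all_missing_raises(self):
        with pytest.raises(errors.AllMissingError):
            whisker_d_value([np.nan, np.nan])

    @given(ct_vectors, st.floats(min_value=-10, max_value=10))
    def test_translation_invariant(self, v, c):
        shifted = [x + c for x in v]
        assert whisker_d_value(shifted) == pytest.approx(whisker_d_value(v), abs=1e-9)

    @given(ct_vectors, st.floats(min_value=15.0, max_value=35.0))
    def test_monotone_under_new_observation(self, v, extra):
        assert whisker_d_value(v + [extra]) >= whisker_d_value(v)


class TestBoxplotSummary:
    def test_odd_length_five_numbers(self):
        mn, q1, med, q3, mx = boxplot_summary([1.0, 2.0, 3.0, 4.0, 5.0])
        assert (mn, med, mx) == (1.0, 3.0, 5.0)
        assert (q1, q3) == (2.0, 4.0)

    def test_constant_vector_collapses(self):
        assert boxplot_summary([7.0] * 4) == (7.0,) * 5

    def test_linear_interpolation_convention(self):
        # positions (n-1)p: q1 at 0.75 -> 20.3, median 20.6, q3 at 2.25 -> 20.9
        mn, q1, med, q3, mx = boxplot_summary([20.0, 20.4, 20.8, 21.2])
        assert q1 == pytest.approx(20.3)
        assert med == pytest.approx(20.6)
        assert q3 == pytest.approx(20.9)


# ---------------------------------------------------------------------------
# consensus selection, exercised on the pepper-fruit study's published
# per-method top-12 rankings and primer characteristics
# ---------------------------------------------------------------------------

TOP12_WHISKER = ["CaREV16", "CaREV21", "CaREV27", "CaREV24", "CaREV09", "CaREV28",
                 "CaREV33", "CaREV31", "CaREV05", "CaREV08", "CaREV23", "CaREV32"]
TOP12_GENORM = ["CaREV05", "CaREV08", "CaREV31", "CaREV33", "CaREV09", "CaREV27",
                "CaREV21", "CaREV16", "CaREV28", "CaREV23", "CaREV26", "CaREV32"]
TOP12_NORMFINDER = ["CaREV16", "CaREV21", "CaREV27", "CaREV26", "CaREV14", "CaREV23",
                    "CaREV19", "CaREV28", "CaREV09", "CaREV20", "CaREV25", "CaREV32"]

#: primer amplification efficiencies (standard-curve E) for the panel
EFFICIENCY = {
    "CaREV05": 1.05, "CaREV09": 0.96, "CaREV16": 1.03, "CaREV21": 0.97,
    "CaREV23": 0.99, "CaREV26": 0.98, "CaREV27": 0.99, "CaREV28": 0.86,
    "CaREV31": 0.73, "CaREV32": 0.93, "CaREV33": 0.79,
}

ALL_GENES = [f"CaREV{i:02d}" for i in range(1, 36)]


def study_report() -> StabilityReport:
    """Report whose three rankings reproduce the study's printed lists.

    Scores are rank-valued stand-ins: only the order (and the QC columns)
    matters to consensus selection.
    """

    def ranks_from(top12):
        rest = [g for g in ALL_GENES if g not in top12]
        order = top12 + rest
        return np.array([order.index(g) + 1 for g in ALL_GENES])

    r_w = ranks_from(TOP12_WHISKER)
    r_g = ranks_from(TOP12_GENORM)
    r_n = ranks_from(TOP12_NORMFINDER)
    mean_ct = np.full(35, 24.0)
    mean_ct[ALL_GENES.index("CaREV23")] = 28.4  # near the guideline ceiling
    genorm_order = [ALL_GENES[i] for i in np.argsort(r_g)]
    gen = GeNormResult(
        ALL_GENES, r_g.astype(float), genorm_order[:-2][::-1],
        tuple(genorm_order[:2]), genorm_order,
    )
    return StabilityReport(
        gene_ids=ALL_GENES,
        whisker_d=r_w.astype(float),
        genorm_m=r_g.astype(float),
        normfinder=r_n.astype(float),
        rank_whisker=r_w,
        rank_genorm=r_g,
        rank_normfinder=r_n,
        mean_ct=mean_ct,
        genorm=gen,
        normfinder_result=None,
    )


class TestConsensusSelect:
    def test_two_method_intersection_of_study_rankings(self):
        sel = consensus_select(study_report(), k_top=12, min_methods=2,
                               efficiencies=None)
        assert set(sel.consensus) == {
            "CaREV05", "CaREV08", "CaREV31", "CaREV33", "CaREV09", "CaREV27",
            "CaREV21", "CaREV16", "CaREV28", "CaREV23", "CaREV26", "CaREV32",
        }

    def test_qc_reproduces_the_published_ten_gene_selection(self):
        # QC acts on the weakly expressed gene and the one inefficient
        # primer pair flagged in the study
        sel = consensus_select(
            study_report(), k_top=12, min_methods=2,
            efficiencies={"CaREV28": EFFICIENCY["CaREV28"]},
        )
        assert set(sel.dropped) == {"CaREV23", "CaREV28"}
        assert set(sel.selected) == {
            "CaREV05", "CaREV08", "CaREV31", "CaREV33", "CaREV09",
            "CaREV27", "CaREV21", "CaREV16", "CaREV26", "CaREV32",
        }
        # ordered by geNorm rank
        assert sel.selected[:2] == ["CaREV05", "CaREV08"]

    def test_full_efficiency_table_also_drops_borderline_primers(self):
        # applying the efficiency window to every known E additionally
        # removes the two candidates at 0.73 and 0.79
        sel = consensus_select(study_report(), k_top=12, min_methods=2,
                               efficiencies=EFFICIENCY)
        assert set(sel.dropped) == {"CaREV23", "CaREV28", "CaREV31", "CaREV33"}

    def test_min_methods_one_gives_union(self):
        sel = consensus_select(study_report(), k_top=12, min_methods=1)
        assert set(sel.consensus) == (
            set(TOP12_WHISKER) | set(TOP12_GENORM) | set(TOP12_NORMFINDER)
        )

    def test_identical_rankings_intersect_to_single_topk(self):
        rep = study_report()
        rep.rank_whisker = rep.rank_genorm.copy()
        rep.rank_normfinder = rep.rank_genorm.copy()
        sel = consensus_select(rep, k_top=12, min_methods=3, efficiencies=None)
        assert set(sel.consensus) == set(TOP12_GENORM)

    def test_k_top_exceeding_gene_count_raises(self):
        with pytest.raises(errors.InsufficientGenesError):
            consensus_select(study_report(), k_top=40)


class TestMinimalRgCount:
    def test_low_v2_means_two_genes_suffice(self):
        res = minimal_rg_count((np.array([2]), np.array([0.05])), threshold=0.15)
        assert res.n == 2 and not res.warning

    def test_first_crossing_wins(self):
        res = minimal_rg_count((np.array([2, 3, 4]), np.array([0.3, 0.2, 0.1])))
        assert res.n == 4 and not res.warning

    def test_no_crossing_falls_back_with_warning(self):
        res = minimal_rg_count((np.array([2, 3]), np.array([0.3, 0.2])))
        assert res.n == 3 and res.warning

    def test_empty_curve_raises(self):
        with pytest.raises(errors.InsufficientDataError):
            minimal_rg_count((np.array([]), np.array([])))
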