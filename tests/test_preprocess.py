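import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tci.preprocess import (
    binarize_mutations,
    call_degs,
    combine_sga,
    filter_scna,
    remove_cis_scna_degs,
    remove_tissue_specific_degs,
)
from tci.types import BinaryEventMatrix, FormatError, NormalReference, ScnaCallMatrix


def events(*rows):
    return pd.DataFrame(rows, columns=["tumor_id", "gene", "variant_class"])


class TestBinarizeMutations:
    def test_multiple_missense_events_set_single_bit(self):
        m = binarize_mutations(
            events(("t1", "G", "non_synonymous_snv"), ("t1", "G", "non_synonymous_snv")),
            ["t1"], ["G"],
        )
        assert m.values.tolist() == [[1]]

    def test_synonymous_only_stays_zero(self):
        m = binarize_mutations(events(("t1", "G", "synonymous")), ["t1"], ["G"])
        assert m.values.tolist() == [[0]]

    def test_indels_count_as_alterations(self):
        m = binarize_mutations(events(("t1", "G", "indel")), ["t1"], ["G"])
        assert m.values.tolist() == [[1]]

    def test_no_events_all_zero(self):
        m = binarize_mutations(events(), ["t1", "t2"], ["G1", "G2"])
        assert m.values.sum() == 0

    def test_unknown_tumor_strict_vs_lenient(self):
        evs = events(("tX", "G", "indel"))
        with pytest.raises(FormatError, match="unknown tumor"):
            binarize_mutations(evs, ["t1"], ["G"])
        m = binarize_mutations(evs, ["t1"], ["G"], strict=False)
        assert m.values.sum() == 0


class TestFilterScna:
    def tissue(self, n, label="A"):
        return {f"t{i + 1}": label for i in range(n)}

    def test_both_events_above_quarter_zeroed_in_type(self):
        # 10 type-A tumors: gene del in 3 (30%), amp in 3 (30%)
        col = [-2] * 3 + [2] * 3 + [0] * 4
        calls = ScnaCallMatrix(np.array([col]), ["g"], [f"t{i + 1}" for i in range(10)])
        binary, removals = filter_scna(calls, self.tissue(10))
        assert binary.values.sum() == 0
        assert removals[0].gene == "g" and removals[0].rule == "scna_inconsistent"

    def test_one_sided_extremes_kept(self):
        col = [2] * 3 + [-2] * 1 + [0] * 6
        calls = ScnaCallMatrix(np.array([col]), ["g"], [f"t{i + 1}" for i in range(10)])
        binary, removals = filter_scna(calls, self.tissue(10))
        assert binary.values.sum() == 4 and not removals

    def test_exactly_25_percent_both_kept(self):
        # strict >: 1 of 4 on each side is exactly 25%
        col = [-2, 2, 0, 0]
        calls = ScnaCallMatrix(np.array([col]), ["g"], [f"t{i + 1}" for i in range(4)])
        binary, removals = filter_scna(calls, self.tissue(4))
        assert binary.values.sum() == 2 and not removals

    def test_single_copy_levels_never_binarized(self):
        calls = ScnaCallMatrix(np.array([[1, -1]]), ["g"], ["t1", "t2"])
        binary, _ = filter_scna(calls, self.tissue(2))
        assert binary.values.sum() == 0

    def test_removal_is_per_cancer_type(self):
        # inconsistent in type A only; type B keeps its events
        col = [-2, -2, 2, 2] + [2, 0, 0, 0]
        tissue = {f"t{i + 1}": ("A" if i < 4 else "B") for i in range(8)}
        calls = ScnaCallMatrix(np.array([col]), ["g"], [f"t{i + 1}" for i in range(8)])
        binary, _ = filter_scna(calls, tissue)
        assert binary.values[:4].sum() == 0 and binary.values[4:].sum() == 1

    def test_idempotent(self):
        col = [-2] * 3 + [2] * 3 + [0] * 4
        tumors = [f"t{i + 1}" for i in range(10)]
        calls = ScnaCallMatrix(np.array([col]), ["g"], tumors)
        once, _ = filter_scna(calls, self.tissue(10))
        # re-applying the binarized result through the rule changes nothing
        again, _ = filter_scna(
            ScnaCallMatrix(2 * once.values.T.astype(int), ["g"], tumors), self.tissue(10)
        )
        assert again.equals(once)


class TestCombineSga:
    def test_or_semantics_and_union_axis(self):
        sm = BinaryEventMatrix([[1, 0]], ["t1"], ["g1", "g2"])
        scna = BinaryEventMatrix([[0, 1]], ["t1"], ["g2", "g3"])
        combined = combine_sga(sm, scna)
        assert combined.genes == ["g1", "g2", "g3"]
        assert combined.values.tolist() == [[1, 0, 1]]

    def test_commutative_on_values(self):
        sm = BinaryEventMatrix([[1, 0], [0, 0]], ["t1", "t2"], ["g1", "g2"])
        scna = BinaryEventMatrix([[0, 1], [1, 0]], ["t1", "t2"], ["g2", "g3"])
        ab = combine_sga(sm, scna).to_frame()
        ba = combine_sga(scna, sm).to_frame()
        pd.testing.assert_frame_equal(ab[sorted(ab.columns)], ba[sorted(ba.columns)])

    def test_tumor_axis_mismatch_errors(self):
        sm = BinaryEventMatrix([[1]], ["t1"], ["g"])
        scna = BinaryEventMatrix([[1]], ["t2"], ["g"])
        with pytest.raises(FormatError):
            combine_sga(sm, scna)


def reference(genes, tissues, mean=0.0, sd=1.0):
    return NormalReference(
        pd.DataFrame(
            [
                {"gene": g, "tissue": s, "mean": mean, "sd": sd, "n": 50}
                for g in genes
                for s in tissues
            ]
        )
    )


class TestCallDegs:
    def expr(self, z_by_gene, tumors=("t1",)):
        # gene×tumor orientation
        return pd.DataFrame(z_by_gene, index=list(tumors)).T

    def test_three_sigma_is_deg_up(self):
        deg, direction, _ = call_degs(
            self.expr({"g": [3.0]}), {"t1": "A"}, reference(["g"], ["A"])
        )
        assert deg.values.tolist() == [[1]] and direction.tolist() == [[1]]

    def test_zero_z_not_deg(self):
        deg, direction, _ = call_degs(
            self.expr({"g": [0.0]}), {"t1": "A"}, reference(["g"], ["A"])
        )
        assert deg.values.sum() == 0 and direction.sum() == 0

    def test_boundary_p_exactly_alpha_is_deg(self):
        z = float(stats.norm.isf(0.005))  # p == 0.005, inclusive boundary
        deg, _, _ = call_degs(self.expr({"g": [-z]}), {"t1": "A"}, reference(["g"], ["A"]))
        assert deg.values.tolist() == [[1]]

    def test_missing_reference_excludes_gene_and_logs(self):
        deg, _, removals = call_degs(
            self.expr({"g": [5.0], "h": [5.0]}),
            {"t1": "A"},
            reference(["g"], ["A"]),
        )
        assert deg.column("g").tolist() == [1]
        assert deg.column("h").tolist() == [0]
        assert any(r.gene == "h" and r.rule == "no_normal_reference" for r in removals)

    def test_null_rate_near_twice_alpha(self, rng):
        # tumors drawn from the reference Gaussian: DEG rate → 2·alpha = 1%
        n_g, n_t = 100, 400
        expr = pd.DataFrame(
            rng.normal(0, 1, (n_g, n_t)),
            index=[f"g{i}" for i in range(n_g)],
            columns=[f"t{i}" for i in range(n_t)],
        )
        deg, _, _ = call_degs(
            expr, {f"t{i}": "A" for i in range(n_t)}, reference(expr.index, ["A"])
        )
        rate = deg.values.mean()
        assert abs(rate - 0.01) < 0.003


class TestCisScnaRemoval:
    def setup_method(self):
        self.deg = BinaryEventMatrix([[1]], ["t1"], ["g"])

    def run(self, level, direction, **kw):
        scna = ScnaCallMatrix(np.array([[level]]), ["g"], ["t1"])
        out, _ = remove_cis_scna_degs(self.deg, np.array([[direction]], dtype=np.int8), scna, **kw)
        return int(out.values[0, 0])

    def test_amplified_and_overexpressed_removed(self):
        assert self.run(2, 1) == 0

    def test_amplified_but_underexpressed_kept(self):
        assert self.run(2, -1) == 1

    def test_no_scna_kept(self):
        assert self.run(0, 1) == 1

    def test_deleted_and_underexpressed_removed(self):
        assert self.run(-2, -1) == 0

    def test_any_scna_mode_removes_discordant(self):
        assert self.run(2, -1, concordant_only=False) == 0


class TestTissueSpecificDegs:
    def cohort_deg(self, freq_a, freq_b, n=200):
        rng = np.random.default_rng(0)
        half = n // 2
        col = np.concatenate(
            [rng.random(half) < freq_a, rng.random(half) < freq_b]
        ).astype(int)
        deg = BinaryEventMatrix(col[:, None], [f"t{i}" for i in range(n)], ["g"])
        tissue = {f"t{i}": ("A" if i < half else "B") for i in range(n)}
        return deg, tissue

    def test_presence_rule_removes_marker_gene(self):
        deg, tissue = self.cohort_deg(0.95, 0.005)
        out, removals = remove_tissue_specific_degs(deg, tissue)
        assert out.values.sum() == 0
        assert removals[0].rule == "tissue_presence"

    def test_shared_gene_kept(self):
        deg, tissue = self.cohort_deg(0.5, 0.3)
        out, removals = remove_tissue_specific_degs(deg, tissue)
        assert out.values.sum() == deg.values.sum() and not removals

    def test_correlation_rule_removes_high_r_gene(self):
        n = 100
        col = np.array([1] * 50 + [0] * 50)  # r = 1 with the type-A indicator
        deg = BinaryEventMatrix(col[:, None], [f"t{i}" for i in range(n)], ["g"])
        tissue = {f"t{i}": ("A" if i < 50 else "B") for i in range(n)}
        out, removals = remove_tissue_specific_degs(deg, tissue, rule="correlation")
        assert out.values.sum() == 0
        assert removals[0].rule == "tissue_correlation"

    def test_single_type_cohort_is_noop(self):
        deg = BinaryEventMatrix([[1], [1]], ["t1", "t2"], ["g"])
        out, removals = remove_tissue_specific_degs(deg, {"t1": "A", "t2": "A"})
        assert out.equals(deg) and not removals
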