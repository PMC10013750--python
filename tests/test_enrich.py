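"""Normalization, ortholog mapping, dual-FDR selection, and gene-set scoring."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from necroseq import enrich as enr
from necroseq import simulate as sim
from necroseq.containers import SpeciesCountMatrix, default_program, remove_core_program

from ._oracles import bh_step_up


def _scm(counts: pd.DataFrame, species="graft", compartments=None, condition="control"):
    compartments = compartments or ["core"] * counts.shape[1]
    meta = pd.DataFrame(
        {"compartment": compartments, "condition": condition}, index=counts.columns
    )
    return SpeciesCountMatrix(counts, species, meta)


class TestNormalize:
    def test_closed_form_single_gene(self):
        counts = pd.DataFrame({"s1": [1_000_000]}, index=["g"])
        val = enr.normalize_counts(counts, pseudocount=0)
        assert val.iloc[0, 0] == pytest.approx(math.log2(1e6))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, (20, 3)), columns=list("abc"))
        doubled = counts.copy()
        doubled["b"] *= 2
        a = enr.normalize_counts(counts, pseudocount=0)
        b = enr.normalize_counts(doubled, pseudocount=0)
        pd.testing.assert_frame_equal(a, b)

    def test_pseudocount_keeps_zeros_finite(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        assert np.isfinite(enr.normalize_counts(counts, pseudocount=0.5)).all().all()

    def test_zero_library_names_sample(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            enr.normalize_counts(counts, pseudocount=0)


class TestMapOrthologs:
    def test_identity_map(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["gA", "gB"])
        host = _scm(counts, species="host")
        out = enr.map_orthologs(host, {"gA": "gA", "gB": "gB"})
        pd.testing.assert_frame_equal(out.counts, counts.rename_axis("gene"))

    def test_many_to_one_sums(self):
        counts = pd.DataFrame({"s1": [3, 4]}, index=["h1", "h2"])
        out = enr.map_orthologs(_scm(counts, species="host"), {"h1": "gA", "h2": "gA"})
        assert out.counts.loc["gA", "s1"] == 7

    def test_unmapped_fraction_dropped_and_recorded(self):
        n = 50
        counts = pd.DataFrame({"s1": range(n)}, index=[f"h{i}" for i in range(n)])
        omap = {f"h{i}": f"g{i}" for i in range(45)}  # 90% coverage
        out = enr.map_orthologs(_scm(counts, species="host"), omap)
        assert len(out.counts.attrs["dropped_genes"]) == 5
        assert out.counts.shape[0] == 45

    def test_empty_coverage_is_error(self):
        counts = pd.DataFrame({"s1": [1]}, index=["h1"])
        with pytest.raises(ValueError, match="covers no host gene"):
            enr.map_orthologs(_scm(counts, species="host"), {"x": "g"})


class TestBHOracle:
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=12)
    )
    def test_bh_matches_brute_force_step_up(self, pvals):
        p = np.asarray(pvals)
        np.testing.assert_allclose(enr._bh(p), bh_step_up(p), atol=1e-12)


def _toy_table(q_cr, q_th, lfc_cr=None, lfc_th=None):
    n = len(q_cr)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "q_core_rim_graft": q_cr,
            "q_tumor_host_core": q_th,
            "lfc_core_rim_graft": lfc_cr if lfc_cr is not None else [1.0] * n,
            "lfc_tumor_host_core": lfc_th if lfc_th is not None else [1.0] * n,
        },
        index=pd.Index(genes, name="gene"),
    )


class TestDualSelection:
    def test_all_q_one_gives_empty_set(self):
        gs = enr.select_dual_significant(_toy_table([1.0, 1.0], [1.0, 1.0]))
        assert gs.genes == []

    def test_singleton_fixture(self):
        table = _toy_table([0.001, 0.5, 0.001], [0.002, 0.001, 0.9])
        gs = enr.select_dual_significant(table, 0.01)
        assert gs.genes == ["g0"]

    def test_vacuous_threshold_keeps_all(self):
        table = _toy_table([0.9, 0.4], [0.7, 0.8])
        assert len(enr.select_dual_significant(table, 1.0)) == 2

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        table = _toy_table(rng.random(100), rng.random(100),
                           rng.normal(size=100), rng.normal(size=100))
        tight = set(enr.select_dual_significant(table, 0.05).genes)
        loose = set(enr.select_dual_significant(table, 0.20).genes)
        assert tight <= loose

    def test_direction_filter(self):
        table = _toy_table([0.001, 0.001], [0.001, 0.001], [2.0, -2.0], [1.0, 1.0])
        up = enr.select_dual_significant(table, 0.01, {"core_rim": "up"})
        down = enr.select_dual_significant(table, 0.01, {"core_rim": "down"})
        assert up.genes == ["g0"] and down.genes == ["g1"]

    def test_unknown_direction_keyword_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            enr.select_dual_significant(_toy_table([0.5], [0.5]), 0.01, {"core_rim": "sideways"})


class TestGeneFoldSummary:
    def _full_table(self):
        table = _toy_table([0.01], [0.01], [0.0], [5.0])
        for c in enr.CONTRASTS:
            if f"lfc_{c}" not in table:
                table[f"lfc_{c}"] = 0.0
            if f"q_{c}" not in table:
                table[f"q_{c}"] = 0.5
        return table

    def test_log2fc_five_is_fold_32(self):
        out = enr.gene_fold_summary(self._full_table(), "g0")
        assert out["fold_tumor_host"] == pytest.approx(32.0)
        assert out["fold_core_rim"] == pytest.approx(1.0)

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError):
            enr.gene_fold_summary(self._full_table(), "missing")


class TestGeneSetOps:
    def _contrast_table(self, lfc):
        genes = [f"g{i}" for i in range(len(lfc))]
        return pd.DataFrame({"lfc": lfc}, index=pd.Index(genes, name="gene"))

    def test_fraction_increased_fixture_23_of_100(self):
        lfc = [1.0] * 23 + [-1.0] * 70 + [0.0] * 7
        table = self._contrast_table(lfc)
        gs = enr.GeneSet("all", list(table.index))
        assert enr.fraction_increased(table, gs) == pytest.approx(0.23)

    def test_fraction_increased_antisymmetry(self):
        rng = np.random.default_rng(5)
        lfc = np.round(rng.normal(size=50), 2)
        table = self._contrast_table(lfc)
        gs = enr.GeneSet("all", list(table.index))
        f_pos = enr.fraction_increased(table, gs)
        f_neg = enr.fraction_increased(self._contrast_table(-lfc), gs)
        ties = (lfc == 0).mean()
        assert f_pos + f_neg + ties == pytest.approx(1.0)

    def test_empty_overlap_is_error(self):
        with pytest.raises(ValueError, match="no overlap"):
            enr.fraction_increased(self._contrast_table([1.0]), enr.GeneSet("x", ["zz"]))

    def test_score_without_permutations(self):
        table = self._contrast_table([1.0, 2.0, 3.0, 4.0, 5.0])
        out = enr.gene_set_score(table, enr.GeneSet("x", list(table.index)), n_permutations=0)
        assert out["score"] == pytest.approx(3.0)
        assert out["p_value"] is None

    def test_small_overlap_refused(self):
        table = self._contrast_table([1.0] * 10)
        with pytest.raises(ValueError, match="need >= 5"):
            enr.gene_set_score(table, enr.GeneSet("x", ["g0", "g1"]))

    def test_gmt_roundtrip(self, tmp_path):
        gs = enr.GeneSet("core_up", ["a", "b", "c"], {"fdr_threshold": 0.01})
        gs.write_gmt(tmp_path / "s.gmt")
        back = enr.GeneSet.read_gmt(tmp_path / "s.gmt")
        assert back.name == "core_up" and back.genes == ["a", "b", "c"]


class TestDifferentialPipeline:
    def test_null_type_i_error_calibrated(self, marker_genes):
        prog = default_program(marker_genes, seed=13)
        graft, host = sim.simulate_counts(prog, 5, seed=14)
        table = enr.differential_enrichment(graft, host)
        frac = (table["p_core_rim_graft"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_marker_fold_recovered_within_twofold(self, marker_genes):
        prog = default_program(marker_genes, marker_gene="g0000", seed=21)
        graft, host = sim.simulate_counts(prog, 5, seed=22)
        table = enr.differential_enrichment(graft, host)
        out = enr.gene_fold_summary(table, "g0000")
        assert 16 <= out["fold_tumor_host"] <= 64  # truth 32
        assert 8 <= out["fold_core_rim"] <= 32  # truth 16

    def test_label_permutation_destroys_marker(self, marker_genes):
        prog = default_program(marker_genes[:500], marker_gene="g0000", seed=31)
        graft, host = sim.simulate_counts(prog, 5, seed=32)
        rng = np.random.default_rng(0)
        qs = []
        for _ in range(5):
            gm = graft.sample_meta.copy()
            gm["compartment"] = rng.permutation(gm["compartment"].to_numpy())
            shuffled = SpeciesCountMatrix(graft.counts, "graft", gm)
            table = enr.differential_enrichment(shuffled, host)
            qs.append(table.loc["g0000", "q_core_rim_graft"])
        assert np.median(qs) > 0.5

    def test_thin_contrast_marked_unavailable(self, marker_genes):
        prog = default_program(marker_genes[:50], seed=41)
        graft, host = sim.simulate_counts(prog, 2, seed=42)
        thin_cols = list(host.sample_meta.index[host.sample_meta["compartment"] == "core"])[:1] + \
            list(host.sample_meta.index[host.sample_meta["compartment"] == "rim"])
        host_thin = SpeciesCountMatrix(
            host.counts[thin_cols], "host", host.sample_meta.loc[thin_cols]
        )
        table = enr.differential_enrichment(graft, host_thin)
        assert "core_rim_host" in table.attrs["unavailable"]
        assert table["q_core_rim_host"].isna().all()
        assert table["q_core_rim_graft"].notna().all()

    def test_knockdown_depletes_core_gene_set(self, marker_genes):
        """Removing the core program in a knockdown condition must yield a
        negative core-set score with permutation p < 0.01."""
        genes = marker_genes[:400]
        core_genes = genes[:25]
        prog = default_program(genes, seed=51)
        means = prog.means.copy()
        means.loc[core_genes, ("graft", "core")] *= 8  # core-enriched program
        prog = type(prog)(means, prog.dispersion, prog.graft_fraction)
        kd_prog = remove_core_program(prog, core_genes)
        control, _ = sim.simulate_counts(prog, 5, seed=52)
        kd, _ = sim.simulate_counts(kd_prog, 5, seed=53, condition="KD")
        contrast = enr.condition_contrast(
            kd.select(compartment="core"), control.select(compartment="core")
        )
        out = enr.gene_set_score(contrast, enr.GeneSet("core_up", core_genes), seed=1)
        assert out["score"] < 0
        assert out["p_value"] < 0.01

    def test_enrichment_tsv_roundtrip(self, tmp_path, marker_genes):
        prog = default_program(marker_genes[:30], seed=61)
        graft, host = sim.simulate_counts(prog, 3, seed=62)
        table = enr.differential_enrichment(graft, host)
        enr.write_enrichment_tsv(table, tmp_path / "t.tsv")
        back = enr.read_enrichment_tsv(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back, table, check_exact=False)
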