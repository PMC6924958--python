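"""Tests of the twelve-comparison design, the three-rule filter, and the
translatome classification."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_filter, brute_force_labels
from conftest import make_comparison_set

from axotrap import (SimConfig, apply_filter, background_overlap_audit,
                     classify_translatome, generate_counts, run_comparisons,
                     summarize_classification)
from axotrap.comparisons import COMPARISON_NAMES, TRAP_COMPARISONS
from axotrap.filtering import CLASSIFICATION_COLUMNS
from axotrap.simulate import expected_labels


def random_comparison_set(seed, n_genes=80):
    """A fixture ComparisonSet with random significance patterns."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    entries = {}
    for name in COMPARISON_NAMES:
        col = {}
        for g in genes:
            u = rng.random()
            if u < 0.05:
                col[g] = (0.0, None)  # untested
            elif u < 0.45:
                col[g] = (float(rng.normal(0, 2)), float(rng.uniform(0, 0.05)))
            else:
                col[g] = (float(rng.normal(0, 0.3)), float(rng.uniform(0.05, 1)))
        entries[name] = col
    return make_comparison_set(genes, entries)


class TestRunComparisons:
    def test_twelve_tables_on_valid_design(self, small_sim):
        _, cm, _ = small_sim
        cs = run_comparisons(cm)
        assert len(cs.tables) == 12
        assert set(cs.tables) == set(COMPARISON_NAMES)

    def test_missing_cell_named_in_error(self, small_sim):
        _, cm, _ = small_sim
        drop = cm.samples_in(fraction="transcriptome", compartment="axon",
                             condition="trained")
        reduced = type(cm)(cm.counts.drop(columns=drop), cm.sample_sheet)
        with pytest.raises(ValueError, match="transcriptome.*axon.*trained"):
            run_comparisons(reduced)

    def test_planted_enrichment_recovered(self):
        """Planted axon-enriched genes are significant with positive sign in
        both TRAP axon-vs-cortex tables for >=90% of genes."""
        cfg = SimConfig(n_genes=2000, n_replicates=6, enrich_lfc=2.0,
                        dispersion=0.05, seed=8)
        cm, truth = generate_counts(cfg)
        cs = run_comparisons(cm)
        enriched = truth.index[truth["label"] == "axon_enriched"]
        for cond in ("control", "trained"):
            t = cs[f"trap_axon_vs_cortex_{cond}"].loc[enriched]
            hit = (t["padj"] < 0.05) & (t["log2fc"] > 0)
            assert hit.mean() >= 0.90


class TestApplyFilter:
    def test_same_sign_transcriptome_mirror_excludes(self):
        cs = make_comparison_set(["g0"], {
            "trap_axon_vs_cortex_control": {"g0": (2.0, 0.001)},
            "txm_axon_vs_cortex_control": {"g0": (1.5, 0.01)},
            "trap_vs_txm_axon_control": {"g0": (1.0, 0.001)},
        })
        dec = apply_filter(cs)
        row = dec[(dec.gene_id == "g0")
                  & (dec.comparison == "trap_axon_vs_cortex_control")].iloc[0]
        assert not row["survives"] and row["audit_code"] == "transcriptome_mirror"

    def test_opposite_sign_transcriptome_does_not_exclude(self):
        cs = make_comparison_set(["g0"], {
            "trap_axon_vs_cortex_control": {"g0": (2.0, 0.001)},
            "txm_axon_vs_cortex_control": {"g0": (-1.5, 0.01)},
            "trap_vs_txm_axon_control": {"g0": (1.0, 0.001)},
        })
        dec = apply_filter(cs)
        row = dec[(dec.gene_id == "g0")
                  & (dec.comparison == "trap_axon_vs_cortex_control")].iloc[0]
        assert row["survives"] and row["audit_code"] == "pass"

    def test_missing_enrichment_confirmation_excludes(self):
        cs = make_comparison_set(["g0"], {
            "trap_axon_vs_cortex_control": {"g0": (2.0, 0.001)},
            # axon-control TRAP-vs-transcriptome not significant
        })
        dec = apply_filter(cs)
        row = dec[(dec.gene_id == "g0")
                  & (dec.comparison == "trap_axon_vs_cortex_control")].iloc[0]
        assert not row["survives"] and row["audit_code"] == "not_trap_enriched"

    def test_not_de_never_survives(self):
        cs = make_comparison_set(["g0"], {})
        dec = apply_filter(cs)
        assert not dec["survives"].any()
        assert (dec["audit_code"] == "not_de").all()

    def test_untested_gene_distinct_audit_code(self):
        cs = make_comparison_set(["g0"], {
            "trap_trained_vs_control_axon": {"g0": (0.0, None)},
        })
        dec = apply_filter(cs)
        row = dec[(dec.gene_id == "g0")
                  & (dec.comparison == "trap_trained_vs_control_axon")].iloc[0]
        assert not row["survives"] and row["audit_code"] == "untested"

    def test_lenient_scope_skips_rule3_for_learning(self):
        cs = make_comparison_set(["g0"], {
            "trap_trained_vs_control_axon": {"g0": (2.0, 0.001)},
            # no TRAP-vs-transcriptome enrichment anywhere
        })
        strict = apply_filter(cs, strict_enrichment_confirm=True)
        lenient = apply_filter(cs, strict_enrichment_confirm=False)
        comp = "trap_trained_vs_control_axon"
        assert not strict[(strict.comparison == comp)].iloc[0]["survives"]
        assert lenient[(lenient.comparison == comp)].iloc[0]["survives"]

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("strict", [True, False])
    def test_matches_brute_force_oracle(self, seed, strict):
        cs = random_comparison_set(seed)
        dec = apply_filter(cs, strict_enrichment_confirm=strict)
        oracle = brute_force_filter(cs, strict=strict)
        for comp in TRAP_COMPARISONS:
            sub = dec[dec.comparison == comp].set_index("gene_id")
            for gene in cs.gene_ids:
                surv, code = oracle[comp][gene]
                assert sub.loc[gene, "survives"] == surv, (comp, gene)
                assert sub.loc[gene, "audit_code"] == code, (comp, gene)


class TestClassification:
    def test_all_null_gives_all_none(self):
        cs = make_comparison_set([f"g{i}" for i in range(10)], {})
        c = classify_translatome(apply_filter(cs))
        assert (c.table["label"] == "none").all()
        assert c.summary["n_translatome"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_labels_match_brute_force(self, seed):
        cs = random_comparison_set(seed)
        c = classify_translatome(apply_filter(cs))
        oracle = brute_force_labels(cs)
        assert c.table["label"].to_dict() == oracle

    def test_partition_identities(self):
        cs = random_comparison_set(99)
        c = classify_translatome(apply_filter(cs))
        s = c.summary
        labels = c.table["label"]
        assert s["n_axonal"] == s["n_axonal_only"] + s["n_shared"]
        assert s["n_translatome"] == s["n_axonal"] + s["n_cortex_only"]
        assert labels.isin(["axonal_only", "shared", "cortex_only", "none"]).all()
        assert (s["n_regulated"] + s["n_axon_enriched_only"]
                + s["n_cortex_enriched_only"] + s["n_enriched_both_areas"]
                == s["n_translatome"])

    def test_alpha_monotonicity(self):
        """A stricter FDR level never adds a gene to the translatome."""
        cs = random_comparison_set(7)
        loose = set(classify_translatome(apply_filter(cs, alpha=0.05)).translatome)
        strict = set(classify_translatome(apply_filter(cs, alpha=0.01)).translatome)
        assert strict <= loose

    def test_parameter_recovery(self):
        """Planted axonal genes recovered at >=80%; few nulls slip in."""
        sens, null_in = [], []
        for seed in range(10):
            cfg = SimConfig(n_genes=2000, n_replicates=6, effect_lfc=2.0,
                            dispersion=0.05, seed=seed)
            cm, truth = generate_counts(cfg)
            c = classify_translatome(apply_filter(run_comparisons(cm)))
            planted = truth.index[truth["label"].isin(
                ["axon_up", "axon_down", "axon_enriched"])]
            pred = set(c.axonal)
            sens.append(len(pred & set(planted)) / len(planted))
            nulls = truth.index[truth["label"] == "null"]
            null_in.append(len(set(c.translatome) & set(nulls)) / len(nulls))
        assert np.mean(sens) >= 0.80
        assert np.mean(null_in) <= 0.05


def published_counts_table():
    """A fixture classification table carrying the study-scale counts:
    1482 axonal (1028 shared + 454 axonal-only), 703 cortex-only;
    1647 of the 2185 translatome genes learning-regulated, with 415
    cortex-enriched-only and 123 axon-enriched-only among the rest."""
    n = 2300
    genes = [f"g{i}" for i in range(n)]
    t = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                     columns=CLASSIFICATION_COLUMNS[:-1])
    for c in ("axon_enriched_control", "axon_enriched_trained",
              "cortex_enriched_control", "cortex_enriched_trained"):
        t[c] = False
    label = np.array(["none"] * n, dtype=object)
    i = 0
    # 1028 shared: regulated in both areas
    t.iloc[i:i + 1028, t.columns.get_loc("axon_regulated_dir")] = 1
    t.iloc[i:i + 1028, t.columns.get_loc("cortex_regulated_dir")] = -1
    label[i:i + 1028] = "shared"; i += 1028
    # 331 axonal-only regulated + 123 axonal-only enriched = 454
    t.iloc[i:i + 331, t.columns.get_loc("axon_regulated_dir")] = 1
    label[i:i + 331] = "axonal_only"; i += 331
    t.iloc[i:i + 123, t.columns.get_loc("axon_enriched_control")] = True
    label[i:i + 123] = "axonal_only"; i += 123
    # 288 cortex-only regulated + 415 cortex-only enriched = 703
    t.iloc[i:i + 288, t.columns.get_loc("cortex_regulated_dir")] = 1
    label[i:i + 288] = "cortex_only"; i += 288
    t.iloc[i:i + 415, t.columns.get_loc("cortex_enriched_trained")] = True
    label[i:i + 415] = "cortex_only"; i += 415
    t["label"] = label
    return t


class TestPublishedCountsFixture:
    def test_summary_reproduces_printed_arithmetic(self):
        s = summarize_classification(published_counts_table())
        assert s["n_axonal"] == 1482
        assert s["n_shared"] == 1028
        assert s["n_cortex_only"] == 703
        assert s["n_translatome"] == 2185
        assert s["shared_of_translatome_pct"] == 47
        assert s["n_regulated"] == 1647
        assert s["regulated_pct"] == 75
        assert s["cortex_enriched_only_pct"] == 19
        assert s["axon_enriched_only_pct"] == 6


class TestBackgroundOverlapAudit:
    def _classification(self, table):
        from axotrap import TranslatomeClassification
        return TranslatomeClassification(table=table,
                                         summary=summarize_classification(table))

    def test_identical_runs_full_intersection(self):
        c = self._classification(published_counts_table())
        rep = background_overlap_audit(c, c)
        assert rep["main"]["overlap_of_translatome_pct"] == 47
        assert rep["n_axon_regulated_main"] == rep["n_axon_regulated_control"]
        assert len(rep["axon_regulated_intersection"]) == rep["n_axon_regulated_main"]

    def test_disjoint_regulated_sets_empty_intersection(self):
        t1 = published_counts_table()
        t2 = t1.copy()
        # swap regulated flags onto previously unlabeled genes
        t2["axon_regulated_dir"] = 0
        t2.loc[t2.index[-50:], "axon_regulated_dir"] = 1
        c1, c2 = self._classification(t1), self._classification(t2)
        rep = background_overlap_audit(c1, c2)
        assert rep["axon_regulated_intersection"] == []

    def test_universe_mismatch_rejected(self):
        t1 = published_counts_table()
        t2 = t1.iloc[:-5]
        with pytest.raises(ValueError, match="universe"):
            background_overlap_audit(self._classification(t1),
                                     self._classification(t2))

    def test_permuted_labels_match_density_product(self):
        """Random relabeling: expected overlap of the two regulated sets is
        roughly the product of their densities."""
        rng = np.random.default_rng(0)
        t1 = published_counts_table()
        t2 = t1.copy()
        perm = rng.permutation(len(t2))
        for col in t2.columns:
            t2[col] = t2[col].to_numpy()[perm]
        c1, c2 = self._classification(t1), self._classification(t2)
        rep = background_overlap_audit(c1, c2)
        n = len(t1)
        d1 = rep["n_axon_regulated_main"] / n
        d2 = rep["n_axon_regulated_control"] / n
        expected = d1 * d2 * n
        observed = len(rep["axon_regulated_intersection"])
        assert abs(observed - expected) < 4 * np.sqrt(expected)
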