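"""I/O, instrument selection, harmonization and diagnostics tests."""

import numpy as np
import pandas as pd
import pytest

import mrmediate as mm
from mrmediate.sumstats import DROPPED_PALINDROMIC, SIGN_FLIPPED, UNCHANGED

from conftest import harmonize_all, make_mediation_study


def _write(tmp_path, text, name="stats.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


WELL_FORMED = (
    "variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
    "rs1\tA\tG\t0.3\t0.05\t0.01\t5e-7\t10000\n"
    "rs2\tC\tT\t0.6\t-0.02\t0.02\t0.3\t10000\n"
    "rs3\tG\tC\t0.1\t0.01\t0.005\t0.04\t10000\n"
)


class TestReadSummaryStats:
    def test_reads_well_formed_file(self, tmp_path):
        tab = mm.read_summary_stats(_write(tmp_path, WELL_FORMED))
        assert len(tab) == 3
        assert tab.df["beta"].tolist() == [0.05, -0.02, 0.01]

    def test_row_with_nonpositive_se_is_dropped(self, tmp_path):
        text = WELL_FORMED.replace("0.02\t0.3", "0\t0.3")
        tab = mm.read_summary_stats(_write(tmp_path, text))
        assert len(tab) == 2
        assert "rs2" not in set(tab.df["variant_id"])

    def test_duplicate_variant_id_is_hard_error(self, tmp_path):
        text = WELL_FORMED.replace("rs2", "rs1")
        with pytest.raises(ValueError, match="duplicate"):
            mm.read_summary_stats(_write(tmp_path, text))

    def test_missing_required_column_names_it(self, tmp_path):
        text = WELL_FORMED.replace("\tse", "\tnonsense")
        with pytest.raises(ValueError, match="se"):
            mm.read_summary_stats(_write(tmp_path, text))

    def test_column_synonyms_are_resolved(self, tmp_path):
        text = WELL_FORMED.replace("variant_id", "SNP").replace("effect_allele", "A1") \
                          .replace("other_allele", "A2").replace("pval", "P")
        tab = mm.read_summary_stats(_write(tmp_path, text))
        assert list(tab.df.columns[:1]) == ["variant_id"]
        assert len(tab) == 3

    def test_non_biallelic_codes_dropped_with_rest_retained(self, tmp_path):
        text = WELL_FORMED.replace("C\tT", "CT\tT")
        tab = mm.read_summary_stats(_write(tmp_path, text))
        assert len(tab) == 2


def _exposure_table(pvals, ids=None):
    n = len(pvals)
    ids = ids or [f"v{i}" for i in range(n)]
    return mm.SummaryStats(pd.DataFrame({
        "variant_id": ids,
        "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.01, "pval": pvals,
    }), name="exposure")


class TestSelectInstruments:
    def test_independent_significant_variants_all_kept(self):
        tab = _exposure_table([1e-9, 1e-10, 1e-12, 2e-8, 4e-8])
        ld = pd.DataFrame(np.eye(5), index=tab.df["variant_id"], columns=tab.df["variant_id"])
        kept = mm.select_instruments(tab, 5e-8, ld, 0.01)
        assert sorted(kept) == sorted(tab.df["variant_id"])

    def test_correlated_pair_keeps_smaller_pvalue(self):
        tab = _exposure_table([1e-9, 1e-8], ids=["a", "b"])
        ld = pd.DataFrame([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]],
                          index=["a", "b"], columns=["a", "b"])
        assert mm.select_instruments(tab, 5e-8, ld, 0.01) == ["a"]

    def test_no_candidates_is_an_error(self):
        with pytest.raises(ValueError, match="no instruments"):
            mm.select_instruments(_exposure_table([0.5, 0.2]))

    def test_greedy_rule_matches_literal_reimplementation(self, rng):
        # oracle: direct transcription of the stated rule, quadratic and slow
        def oracle(pvals, ids, r2, thr_p, thr_r2):
            cand = sorted((p, i) for p, i in zip(pvals, ids) if p < thr_p)
            kept, removed = [], set()
            for p, i in cand:
                if i in removed:
                    continue
                kept.append(i)
                for q, j in cand:
                    if j not in removed and j != i and r2.loc[i, j] >= thr_r2:
                        removed.add(j)
            return kept

        for trial in range(40):
            n = int(rng.integers(2, 13))
            ids = [f"v{i}" for i in range(n)]
            pvals = 10.0 ** rng.uniform(-12, -5, n)
            pvals[0] = 1e-9  # keep the candidate set non-empty
            A = rng.normal(size=(n, n + 3))
            corr = np.corrcoef(A)
            ld = pd.DataFrame(corr, index=ids, columns=ids)
            kept = mm.select_instruments(_exposure_table(list(pvals), ids), 5e-8, ld, 0.1)
            assert kept == oracle(pvals, ids, ld**2, 5e-8, 0.1)
            # pruning invariant: no kept pair at or above the threshold
            sub = (ld.loc[kept, kept].to_numpy() ** 2)
            np.fill_diagonal(sub, 0.0)
            assert (sub < 0.1).all()


def _pair_tables(exp_alleles, out_alleles, out_beta=0.1, exp_eaf=0.3, out_eaf=0.3):
    exp = mm.SummaryStats(pd.DataFrame({
        "variant_id": ["v1"], "effect_allele": [exp_alleles[0]],
        "other_allele": [exp_alleles[1]], "eaf": [exp_eaf],
        "beta": [0.1], "se": [0.01], "pval": [1e-9],
    }), name="exposure")
    out = mm.SummaryStats(pd.DataFrame({
        "variant_id": ["v1"], "effect_allele": [out_alleles[0]],
        "other_allele": [out_alleles[1]], "eaf": [out_eaf],
        "beta": [out_beta], "se": [0.02], "pval": [0.01],
    }), name="outcome")
    return exp, out


class TestHarmonize:
    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp, out = _pair_tables(("A", "G"), ("G", "A"))
        h = mm.harmonize(exp, out)
        assert h.outcome_beta[0] == pytest.approx(-0.1)
        assert h.flags["outcome"].iloc[0] == SIGN_FLIPPED

    def test_strand_complement_keeps_orientation(self):
        exp, out = _pair_tables(("A", "G"), ("T", "C"))
        h = mm.harmonize(exp, out)
        assert h.outcome_beta[0] == pytest.approx(0.1)

    def test_strand_complement_and_swap_flips_sign(self):
        exp, out = _pair_tables(("A", "G"), ("C", "T"))
        h = mm.harmonize(exp, out)
        assert h.outcome_beta[0] == pytest.approx(-0.1)

    def test_palindromic_with_ambiguous_frequency_dropped(self):
        exp, out = _pair_tables(("A", "T"), ("A", "T"), exp_eaf=0.5, out_eaf=0.5)
        h = mm.harmonize(exp, out)
        assert h.n_variants == 0
        assert h.flags["outcome"].iloc[0] == DROPPED_PALINDROMIC

    def test_palindromic_orientation_inferred_from_frequency(self):
        exp, out = _pair_tables(("A", "T"), ("A", "T"), exp_eaf=0.2, out_eaf=0.25)
        h = mm.harmonize(exp, out)
        assert h.outcome_beta[0] == pytest.approx(0.1)
        assert h.flags["outcome"].iloc[0] == UNCHANGED
        # opposite-side frequencies imply the other orientation
        exp, out = _pair_tables(("A", "T"), ("T", "A"), exp_eaf=0.2, out_eaf=0.8)
        h = mm.harmonize(exp, out)
        assert h.outcome_beta[0] == pytest.approx(-0.1)

    def test_palindromic_policies(self):
        exp, out = _pair_tables(("A", "T"), ("A", "T"), exp_eaf=0.2, out_eaf=0.8)
        assert mm.harmonize(exp, out, policy="infer").n_variants == 1
        assert mm.harmonize(exp, out, policy="same-side").n_variants == 0
        exp, out = _pair_tables(("A", "T"), ("A", "T"), exp_eaf=0.2, out_eaf=0.25)
        assert mm.harmonize(exp, out, policy="drop-all").n_variants == 0

    def test_incompatible_allele_pair_dropped_not_retained(self):
        exp, out = _pair_tables(("A", "G"), ("A", "C"))
        h = mm.harmonize(exp, out)
        assert h.n_variants == 0
        assert h.flags["outcome"].iloc[0] == "dropped_incompatible"

    def test_variant_missing_from_outcome_dropped(self):
        exp, out = _pair_tables(("A", "G"), ("A", "G"))
        out.df["variant_id"] = ["v2"]
        h = mm.harmonize(exp, out)
        assert h.n_variants == 0
        assert h.flags["outcome"].iloc[0] == "dropped_missing"

    def test_corrupted_files_harmonize_to_clean_dataset(self):
        model = mm.build_true_model(dict(
            n_variants=300, seed=17, theta_direct=0.3,
            mediators=[dict(name="m1", alpha=0.4, beta=0.5, delta_sd=0.02)],
            outcome_type="continuous",
        ))
        base = dict(n={"exposure": 3_037_499, "m1": 800_000, "outcome": 200_000}, seed=4)
        clean = mm.generate_summary_stats(model, mm.SampleDesign(**base))
        corrupt = mm.generate_summary_stats(
            model, mm.SampleDesign(**base, swap_rate=0.4, strand_flip_rate=0.3))
        h1 = mm.harmonize(clean["exposure"], clean["outcome"], {"m1": clean["m1"]},
                          instruments=list(model.variant_id))
        h2 = mm.harmonize(corrupt["exposure"], corrupt["outcome"], {"m1": corrupt["m1"]},
                          instruments=list(model.variant_id))
        assert np.array_equal(h1.variant_id, h2.variant_id)
        # an exposure row swapped on disk flips the whole variant's
        # orientation; all betas flip together so every ratio is unchanged
        sign = np.sign(h1.exposure_beta) * np.sign(h2.exposure_beta)
        np.testing.assert_allclose(h1.outcome_beta, sign * h2.outcome_beta, atol=1e-14)
        np.testing.assert_allclose(h1.mediator_beta, sign[:, None] * h2.mediator_beta,
                                   atol=1e-14)
        np.testing.assert_allclose(h1.outcome_beta / h1.exposure_beta,
                                   h2.outcome_beta / h2.exposure_beta, atol=1e-12)

    def test_harmonization_is_idempotent(self):
        model, tables = make_mediation_study(seed=23, n_variants=200)
        h1 = harmonize_all(model, tables)
        tabs2 = h1.to_tables()
        h2 = mm.harmonize(tabs2["exposure"], tabs2["outcome"], {"m1": tabs2["m1"]})
        assert np.array_equal(h2.variant_id, h1.variant_id)
        np.testing.assert_array_equal(h2.outcome_beta, h1.outcome_beta)
        np.testing.assert_array_equal(h2.mediator_beta, h1.mediator_beta)
        assert (h2.flags[["m1", "outcome"]].to_numpy() == UNCHANGED).all()


class TestInstrumentDiagnostics:
    def test_f_statistic_definition(self):
        h = mm.HarmonizedDataset(
            variant_id=np.array(["v1", "v2"]),
            effect_allele=np.array(["A", "C"]), other_allele=np.array(["G", "T"]),
            eaf=np.array([0.5, 0.5]),
            exposure_beta=np.array([0.02, 0.0]), exposure_se=np.array([0.004, 0.01]),
            outcome_beta=np.zeros(2), outcome_se=np.ones(2),
        )
        d = mm.instrument_diagnostics(h)
        assert d.f_stat[0] == pytest.approx(25.0)
        assert d.f_stat[1] == 0.0
        assert d.r2[1] == 0.0
        assert d.r2[0] == pytest.approx(2 * 0.25 * 0.02**2)

    def test_total_r2_tracks_analytic_variance_explained(self):
        model = mm.build_true_model(dict(n_variants=500, seed=31))
        n_rep = 30
        vals = []
        for r in range(n_rep):
            design = mm.SampleDesign(n={"exposure": 3_037_499, "outcome": 141_014},
                                     seed=300_000 + r)
            tabs = mm.generate_summary_stats(model, design)
            h = mm.harmonize(tabs["exposure"], tabs["outcome"],
                             instruments=list(model.variant_id))
            vals.append(mm.instrument_diagnostics(h).total_r2)
        vals = np.array(vals)
        # analytic expectation over the retained variants (harmonization drops
        # frequency-ambiguous palindromic ones); E[beta^2] = gamma^2 + se^2
        # adds a small known noise term
        kept = np.isin(model.variant_id, h.variant_id)
        het = 2 * model.eaf[kept] * (1 - model.eaf[kept])
        se2 = 1.0 / (2 * 3_037_499 * model.eaf[kept] * (1 - model.eaf[kept]))
        expected = np.sum(het * (model.gamma[kept] ** 2 + se2))
        mc_se = vals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(vals.mean() - expected) <= 3 * mc_se
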