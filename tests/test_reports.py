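"""Factor characterization and sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

from psylink import (
    PipelineConfig,
    SyntheticCorpusSpec,
    confound_associations,
    drug_scores,
    factor_report,
    fit_pipeline,
    generate_corpus,
    generate_drug_panel,
    split_by_median_age,
    split_by_sex,
    subgroup_stability,
    word_saliences,
)


@pytest.fixture(scope="module")
def fitted_study():
    spec = SyntheticCorpusSpec(
        n_drugs=10,
        n_receptors=12,
        n_reports_per_drug=60,
        vocab_size=150,
        n_topics=6,
        n_factors=2,
        mean_doc_length=200,
        seed=7,
    )
    panel = generate_drug_panel(spec)
    reports, truth = generate_corpus(panel, spec, (0.85, 0.6))
    cfg = PipelineConfig(k=25, per_drug=None, n_perm=100, seed=7)
    result = fit_pipeline(reports, panel, cfg)
    return spec, panel, reports, truth, result


class TestWordSaliences:
    def test_concentrated_factor_is_scaled_component(self, fitted_study):
        *_, result = fitted_study
        lsa, model = result.lsa, result.model.truncated(1)
        model.a[:, 0] = 0.0
        model.a[0, 0] = 2.0
        sal = word_saliences(lsa, model, 0)
        np.testing.assert_allclose(sal, 2.0 * lsa.R[0] * lsa.W[:, 0], atol=1e-12)

    def test_factor_sign_flip_flips_saliences(self, fitted_study):
        *_, result = fitted_study
        sal = word_saliences(result.lsa, result.model, 0)
        flipped = result.model.truncated(result.model.h)
        flipped.flip_factor(0)
        np.testing.assert_allclose(
            word_saliences(result.lsa, flipped, 0), -sal, atol=1e-12
        )

    def test_k_mismatch_rejected(self, fitted_study):
        *_, result = fitted_study
        from psylink import fit_lsa

        other = fit_lsa(np.random.default_rng(0).normal(size=(30, 20)), k=5)
        with pytest.raises(ValueError, match="k="):
            word_saliences(other, result.model, 0)

    def test_planted_signature_words_lead_the_recovered_factor(self, fitted_study):
        _, _, _, truth, result = fitted_study
        r = np.corrcoef(result.model.b[:, 0], truth.true_b[:, 0])[0, 1]
        sal = word_saliences(result.lsa, result.model, 0) * np.sign(r)
        vocab = result.vocabulary
        top10 = [vocab.words[i] for i in np.argsort(-sal)[:10]]
        pos_pole = set(truth.signature_words(truth.factor_topic_pair(0)[0]))
        assert sum(w in pos_pole for w in top10) >= 8


class TestDrugScores:
    def test_mean_fingerprint_scores_zero(self, fitted_study):
        _, panel, _, _, result = fitted_study
        model = result.model
        # a hypothetical drug at the panel's Y-mean has exactly score 0
        scores = (model.mean_y - model.mean_y) @ model.b[:, 0]
        assert scores == 0.0

    def test_identical_fingerprints_identical_scores(self, fitted_study):
        _, panel, _, _, result = fitted_study
        import pandas as pd

        from psylink import AffinityPanel

        ki = pd.concat([panel.ki_nM, panel.ki_nM.iloc[[0]].rename(index={panel.drugs[0]: "clone"})])
        twin = AffinityPanel(ki)
        s = drug_scores(twin, result.model, 0)
        assert s["clone"] == pytest.approx(s[panel.drugs[0]])

    def test_best_aligned_drug_scores_highest(self, fitted_study):
        _, panel, _, _, result = fitted_study
        model = result.model
        fp = panel.npki.to_numpy() - model.mean_y
        expected_top = panel.drugs[int(np.argmax(fp @ model.b[:, 0]))]
        s = drug_scores(panel, result.model, 0)
        assert s.idxmax() == expected_top

    def test_one_entry_per_drug(self, fitted_study):
        _, panel, _, _, result = fitted_study
        assert set(drug_scores(panel, result.model, 0).index) == set(panel.drugs)


class TestFactorReport:
    def test_report_fields_and_disjoint_poles(self, fitted_study):
        _, panel, _, _, result = fitted_study
        rep = factor_report(
            result.vocabulary,
            result.lsa,
            result.model,
            result.permutation.p_values,
            panel,
            0,
            top_words=15,
        )
        pos = {w for w, _ in rep.top_words_positive}
        neg = {w for w, _ in rep.top_words_negative}
        assert pos.isdisjoint(neg)
        assert all(v > 0 for _, v in rep.top_words_positive)
        assert all(v < 0 for _, v in rep.top_words_negative)
        mags = [abs(v) for _, v in rep.top_words_positive]
        assert mags == sorted(mags, reverse=True)
        assert set(rep.drug_scores) == set(panel.drugs)
        assert rep.rho == pytest.approx(result.model.rho[0])

    def test_report_is_json_serializable(self, fitted_study, tmp_path):
        _, panel, _, _, result = fitted_study
        rep = factor_report(
            result.vocabulary,
            result.lsa,
            result.model,
            result.permutation.p_values,
            panel,
            0,
        )
        rep.save(tmp_path / "factor1.json")
        assert (tmp_path / "factor1.json").stat().st_size > 0


class TestConfoundAssociations:
    def test_variate_equal_to_distinct_words_gives_r_one(self, fitted_study):
        _, panel, reports, _, result = fitted_study
        from psylink.corpus import tokenize

        model = result.model.truncated(1)
        model.U[:, 0] = [len(set(tokenize(t.text))) for t in result.testimonials]
        meta = pd.DataFrame(
            {"drug": panel.drugs, "avg_duration_hours": np.arange(1.0, len(panel.drugs) + 1)}
        )
        table = confound_associations(result.testimonials, meta, model)
        assert table.loc[1, "U_distinct_words"] == pytest.approx(1.0)

    def test_constant_duration_reported_as_nan(self, fitted_study):
        _, panel, _, _, result = fitted_study
        meta = pd.DataFrame(
            {"drug": panel.drugs, "avg_duration_hours": [2.0] * len(panel.drugs)}
        )
        table = confound_associations(result.testimonials, meta, result.model)
        assert np.isnan(table["U_duration_hours"]).all()

    def test_missing_drug_duration_rejected(self, fitted_study):
        _, panel, _, _, result = fitted_study
        meta = pd.DataFrame({"drug": panel.drugs[:-1], "avg_duration_hours": [1.0] * (len(panel.drugs) - 1)})
        with pytest.raises(KeyError, match=panel.drugs[-1]):
            confound_associations(result.testimonials, meta, result.model)

    def test_independent_duration_within_drug_level_null_bound(self, fitted_study):
        # duration varies only between drugs, so the null bound comes from
        # permuting durations across drugs, not across reports
        _, panel, _, _, result = fitted_study
        rng = np.random.default_rng(0)
        model = result.model.truncated(1)
        n_inside = 0
        n_draws = 20
        for _ in range(n_draws):
            durations = rng.uniform(0.5, 20, len(panel.drugs))
            meta = pd.DataFrame(
                {"drug": panel.drugs, "avg_duration_hours": durations}
            )
            obs = abs(
                confound_associations(result.testimonials, meta, model).loc[
                    1, "U_duration_hours"
                ]
            )
            # drug-level permutation null of the same Pearson statistic
            drug_of = {d: i for i, d in enumerate(panel.drugs)}
            idx = np.array([drug_of[t.drug] for t in result.testimonials])
            null = [
                abs(np.corrcoef(model.U[:, 0], rng.permutation(durations)[idx])[0, 1])
                for _ in range(99)
            ]
            if obs <= np.quantile(null, 0.95):
                n_inside += 1
        assert n_inside >= 0.9 * n_draws - 1


class TestSubgroups:
    def test_median_age_split_covers_all_aged_reports(self, fitted_study):
        _, _, reports, _, _ = fitted_study
        groups = split_by_median_age(reports)
        assert set(groups) == {"younger", "older"}
        assert len(groups["younger"]) + len(groups["older"]) == len(
            [t for t in reports if t.age is not None]
        )

    def test_sex_split_requires_two_categories(self):
        from psylink import Testimonial

        reports = [Testimonial("a", "d", "x", sex="female")]
        with pytest.raises(ValueError, match="two sex categories"):
            split_by_sex(reports)

    def test_degenerate_grouping_rejected(self, fitted_study):
        _, panel, reports, _, _ = fitted_study
        with pytest.raises(ValueError):
            subgroup_stability(reports, panel, lambda ts: {"all": list(ts)})

    def test_split_half_stability_of_strong_leading_factor(self, fitted_study):
        spec, panel, reports, truth, _ = fitted_study
        halves = lambda ts: {
            "first": [t for i, t in enumerate(ts) if i % 2 == 0],
            "second": [t for i, t in enumerate(ts) if i % 2 == 1],
        }
        cfg = PipelineConfig(k=25, per_drug=None, n_perm=25, seed=7)
        out = subgroup_stability(reports, panel, halves, cfg)
        assert out["similarity"].loc["first", "second"] > 0.8
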