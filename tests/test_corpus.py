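"""Vocabulary filters, count matrix and the tf-idf transform."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from psylink import (
    Testimonial,
    balanced_subsample,
    build_vocabulary,
    count_matrix,
    read_corpus_jsonl,
    tfidf_transform,
    tokenize,
    write_corpus_jsonl,
)


def tfidf_scalar_oracle(counts: np.ndarray) -> np.ndarray:
    """Entry-by-entry application of the printed tf-idf formula."""
    n_docs, n_words = counts.shape
    out = np.zeros((n_docs, n_words))
    for j in range(n_docs):
        total = counts[j].sum()
        for i in range(n_words):
            if counts[j, i] == 0 or total == 0:
                continue
            tf = counts[j, i] / total
            n_w = int((counts[:, i] > 0).sum())
            out[j, i] = tf * math.log(n_docs / (1 + n_w))
    return out


class TestTokenizer:
    def test_punctuation_and_digits_are_separators(self):
        assert tokenize("Mind-blowing!! 2x the usual; wow.") == [
            "mind", "blowing", "x", "the", "usual", "wow",
        ]

    def test_lowercases(self):
        assert tokenize("Universe UNIVERSE universe") == ["universe"] * 3


class TestBuildVocabulary:
    def test_filters_applied_in_order(self):
        # "an" is short AND stoplisted; "xy" short; "love" frequent enough
        reports = [
            Testimonial("a", "d", "an an an love love love rare"),
            Testimonial("b", "d", "an xy love peace peace peace"),
        ]
        vocab = build_vocabulary(reports, stoplist=["an"], min_count=3)
        assert set(vocab.words) == {"love", "peace"}

    def test_min_count_boundary(self):
        reports = [Testimonial("a", "d", "six " * 6 + "seven " * 7)]
        vocab = build_vocabulary(reports, stoplist=[], min_count=7)
        assert "seven" in vocab and "six" not in vocab

    def test_toy_corpus_exact_vocabulary(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus, stoplist=["the", "and", "under"], min_count=2)
        # surviving: length>=3, count>=2, not stoplisted
        assert set(vocab.words) == {"universe", "love", "colors"}
        assert vocab.corpus_frequency["love"] == 4

    def test_stoplist_matching_case_insensitive(self):
        reports = [Testimonial("a", "d", "LOVE love peace peace")]
        vocab = build_vocabulary(reports, stoplist=["Love"], min_count=2)
        assert set(vocab.words) == {"peace"}

    def test_empty_vocabulary_names_responsible_filter(self):
        with pytest.raises(ValueError, match="stoplist"):
            build_vocabulary(
                [Testimonial("a", "d", "love love love")],
                stoplist=["love"],
                min_count=2,
            )
        with pytest.raises(ValueError, match="corpus count"):
            build_vocabulary(
                [Testimonial("a", "d", "love")], stoplist=[], min_count=2
            )

    def test_removing_a_report_never_increases_frequencies(self, toy_corpus):
        full = build_vocabulary(toy_corpus, stoplist=[], min_count=1)
        reduced = build_vocabulary(toy_corpus[:-1], stoplist=[], min_count=1)
        for w, n in reduced.corpus_frequency.items():
            assert n <= full.corpus_frequency[w]


class TestCountMatrix:
    def test_known_counts(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus, stoplist=[], min_count=1)
        M = count_matrix(toy_corpus, vocab)
        assert M[0, vocab.index["universe"]] == 2
        assert M[0, vocab.index["love"]] == 3
        assert M[0, vocab.index["voices"]] == 1

    def test_total_conserves_in_vocab_tokens(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus, stoplist=[], min_count=1)
        total_tokens = sum(
            1 for t in toy_corpus for tok in tokenize(t.text) if tok in vocab
        )
        assert count_matrix(toy_corpus, vocab).sum() == total_tokens

    def test_out_of_vocab_row_is_zero(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus, stoplist=[], min_count=1)
        extra = toy_corpus + [Testimonial("t4", "drugB", "zzzq zzzq")]
        M = count_matrix(extra, vocab)
        assert M[3].nnz == 0

    def test_duplicate_ids_rejected(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus, stoplist=[], min_count=1)
        with pytest.raises(ValueError, match="duplicate"):
            count_matrix(toy_corpus + [toy_corpus[0]], vocab)


class TestTfidf:
    def test_worked_example(self):
        # 3 docs; doc1 = {x:2, y:2}; y occurs only in doc1
        counts = sp.csr_matrix(np.array([[2, 2], [3, 0], [1, 0]]))
        T = tfidf_transform(counts).toarray()
        assert T[0, 1] == pytest.approx(0.5 * math.log(3 / 2), abs=1e-12)

    def test_zero_counts_stay_zero(self, rng):
        counts = sp.csr_matrix(rng.poisson(0.5, size=(8, 12)))
        T = tfidf_transform(counts).toarray()
        assert np.all(T[counts.toarray() == 0] == 0)

    def test_ubiquitous_word_gets_negative_weight(self):
        counts = sp.csr_matrix(np.array([[1, 5], [1, 0], [1, 2]]))
        T = tfidf_transform(counts).toarray()
        # column 0 present in all 3 docs: idf = log(3/4) < 0
        assert np.all(T[:, 0] < 0)

    def test_matches_scalar_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            shape = (int(rng.integers(2, 21)), int(rng.integers(2, 51)))
            counts = rng.poisson(1.0, size=shape)
            counts[counts.sum(axis=1) == 0, 0] = 1  # no empty docs
            got = tfidf_transform(sp.csr_matrix(counts)).toarray()
            np.testing.assert_allclose(got, tfidf_scalar_oracle(counts), atol=1e-12)

    def test_empty_row_warns_and_passes_through(self):
        counts = sp.csr_matrix(np.array([[1, 2], [0, 0]]))
        with pytest.warns(UserWarning, match="no\\s+in-vocabulary"):
            T = tfidf_transform(counts)
        assert T[1].nnz == 0


class TestBalancedSubsample:
    @staticmethod
    def _corpus(n_a=500, n_b=34):
        reports = [Testimonial(f"a{i}", "drugA", "x") for i in range(n_a)]
        reports += [Testimonial(f"b{i}", "drugB", "x") for i in range(n_b)]
        return reports

    def test_caps_large_and_keeps_small_drugs(self):
        sub = balanced_subsample(self._corpus(), per_drug=300, seed=0)
        by_drug = {}
        for t in sub:
            by_drug[t.drug] = by_drug.get(t.drug, 0) + 1
        assert by_drug == {"drugA": 300, "drugB": 34}

    def test_no_replacement(self):
        sub = balanced_subsample(self._corpus(), per_drug=300, seed=0)
        ids = [t.id for t in sub]
        assert len(ids) == len(set(ids))

    def test_deterministic_under_seed(self):
        c = self._corpus()
        s1 = [t.id for t in balanced_subsample(c, 300, seed=7)]
        s2 = [t.id for t in balanced_subsample(c, 300, seed=7)]
        s3 = [t.id for t in balanced_subsample(c, 300, seed=8)]
        assert s1 == s2 and s1 != s3


@settings(max_examples=25, deadline=None)
@given(
    texts=st.lists(
        st.text(alphabet="abc xyz.!", min_size=0, max_size=40), min_size=1, max_size=8
    )
)
def test_count_matrix_is_nonnegative_and_conserving(texts):
    reports = [Testimonial(f"t{i}", "d", txt) for i, txt in enumerate(texts)]
    try:
        vocab = build_vocabulary(reports, stoplist=[], min_count=1)
    except ValueError:
        return  # corpora with no valid word are rejected explicitly
    M = count_matrix(reports, vocab)
    assert (M.data >= 0).all()
    in_vocab = sum(1 for t in reports for tok in tokenize(t.text) if tok in vocab)
    assert M.sum() == in_vocab


def test_corpus_jsonl_round_trip(tmp_path, toy_corpus):
    path = tmp_path / "corpus.jsonl"
    enriched = [
        Testimonial(t.id, t.drug, t.text, age=30 + i, sex="female")
        for i, t in enumerate(toy_corpus)
    ]
    write_corpus_jsonl(enriched, path)
    assert read_corpus_jsonl(path) == enriched
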