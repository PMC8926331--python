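"""Bag-of-words encoding of experience reports.

The free text of each testimonial is reduced to word counts over a
filtered vocabulary, then reweighted by tf-idf. The filters run in a
fixed order: strip punctuation/special characters (tokenization keeps
alphabetic runs only), drop words of fewer than three characters, drop
words occurring fewer than `min_count` times in the whole corpus, drop
stoplisted words (function words plus drug names), with all matching done
on lowercased forms.

tf-idf uses a document-length-normalized term frequency and a smoothed
inverse document frequency::

    tfidf(w, t) = f(w,t) / sum_k f(k,t) * log(N / (1 + n_w))

where N is the number of testimonials and n_w the number of testimonials
*containing* w (not its total count). Note the smoothing makes idf
negative for a word present in every document.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from .fingerprints import _load_resource_text, load_drug_metadata

_TOKEN_RE = re.compile(r"[A-Za-z]+")

DEFAULT_MIN_COUNT = 7
DEFAULT_MIN_WORD_LENGTH = 3


@dataclass
class Testimonial:
    """One experience report: free text tagged with the drug taken."""

    __test__ = False  # not a test class, despite the name

    id: str
    drug: str
    text: str
    age: float | None = None
    sex: str | None = None


def tokenize(text: str) -> list[str]:
    """Lowercased alphabetic tokens; punctuation, digits and other special
    characters act as separators."""
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


def default_stoplist(include_drug_names: bool = True) -> frozenset[str]:
    """Packaged function-word stoplist, optionally extended with the drug
    names of the packaged drug table (matched case-insensitively; multiword
    names contribute their alphabetic parts)."""
    words = {
        ln.strip().lower()
        for ln in _load_resource_text("stoplist.txt").splitlines()
        if ln.strip() and not ln.startswith("#")
    }
    if include_drug_names:
        for name in load_drug_metadata()["drug"]:
            words.update(tokenize(name))
    return frozenset(words)


@dataclass
class Vocabulary:
    words: list[str]
    corpus_frequency: dict[str, int]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("word\tindex\tcorpus_frequency\n")
            for i, w in enumerate(self.words):
                fh.write(f"{w}\t{i}\t{self.corpus_frequency[w]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Vocabulary":
        words: list[str] = []
        freq: dict[str, int] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                w, _i, n = line.rstrip("\n").split("\t")
                words.append(w)
                freq[w] = int(n)
        return cls(words, freq)


def build_vocabulary(
    testimonials: Sequence[Testimonial],
    stoplist: Iterable[str] | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    min_word_length: int = DEFAULT_MIN_WORD_LENGTH,
) -> Vocabulary:
    """Build the filtered vocabulary over a corpus.

    Filters, in order: tokenization (strips punctuation/special chars),
    minimum word length, minimum corpus-wide occurrence count, stoplist.
    Raises a ValueError naming the responsible filter if nothing survives.
    """
    if not testimonials:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    stop = (
        frozenset(w.lower() for w in stoplist)
        if stoplist is not None
        else default_stoplist()
    )
    totals: Counter[str] = Counter()
    for t in testimonials:
        totals.update(tokenize(t.text))
    if not totals:
        raise ValueError("empty vocabulary: tokenization produced no words")
    long_enough = {w: n for w, n in totals.items() if len(w) >= min_word_length}
    if not long_enough:
        raise ValueError("empty vocabulary: minimum word length filter removed all words")
    frequent = {w: n for w, n in long_enough.items() if n >= min_count}
    if not frequent:
        raise ValueError("empty vocabulary: minimum corpus count filter removed all words")
    kept = {w: n for w, n in frequent.items() if w not in stop}
    if not kept:
        raise ValueError("empty vocabulary: stoplist removed all words")
    words = sorted(kept)
    return Vocabulary(words, kept)


def count_matrix(
    testimonials: Sequence[Testimonial], vocab: Vocabulary
) -> sp.csr_matrix:
    """Sparse testimonial x word matrix M of raw token counts; tokens outside
    the vocabulary are ignored. Report ids must be unique."""
    ids = [t.id for t in testimonials]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate testimonial ids: {dupes[:5]}")
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for j, t in enumerate(testimonials):
        counts = Counter(tok for tok in tokenize(t.text) if tok in vocab)
        for w, c in counts.items():
            rows.append(j)
            cols.append(vocab.index[w])
            vals.append(c)
    M = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(testimonials), len(vocab)), dtype=np.int64
    )
    return M


def tfidf_transform(M: sp.spmatrix) -> sp.csr_matrix:
    """Apply the length-normalized tf x smoothed idf reweighting to a count
    matrix. Zero counts stay exactly zero; an all-zero row (report with no
    in-vocabulary token) passes through as zeros with a warning."""
    M = sp.csr_matrix(M, dtype=float)
    n_docs = M.shape[0]
    if n_docs == 0 or M.shape[1] == 0:
        raise ValueError("count matrix must be nonempty")
    row_totals = np.asarray(M.sum(axis=1)).ravel()
    if (row_totals == 0).any():
        warnings.warn(
            f"{int((row_totals == 0).sum())} testimonial(s) contain no "
            "in-vocabulary token; their tf-idf rows are zero",
            stacklevel=2,
        )
    # documents containing each word, not total occurrences
    n_w = np.asarray((M > 0).sum(axis=0)).ravel()
    idf = np.log(n_docs / (1.0 + n_w))
    safe_totals = np.where(row_totals > 0, row_totals, 1.0)
    tf = sp.diags(1.0 / safe_totals) @ M
    return sp.csr_matrix(tf @ sp.diags(idf))


def balanced_subsample(
    testimonials: Sequence[Testimonial], per_drug: int, seed: int
) -> list[Testimonial]:
    """Class-rebalancing subsample: for each drug draw `per_drug` reports
    without replacement (all of them if a drug has fewer), deterministic
    under `seed`. Original corpus order is preserved in the output."""
    if per_drug < 1:
        raise ValueError("per_drug must be >= 1")
    rng = np.random.default_rng(seed)
    by_drug: dict[str, list[int]] = {}
    for j, t in enumerate(testimonials):
        by_drug.setdefault(t.drug, []).append(j)
    keep: list[int] = []
    for drug in sorted(by_drug):
        idx = np.array(by_drug[drug])
        if len(idx) <= per_drug:
            keep.extend(idx.tolist())
        else:
            keep.extend(rng.choice(idx, size=per_drug, replace=False).tolist())
    keep.sort()
    return [testimonials[j] for j in keep]


def read_corpus_jsonl(path: str | Path) -> list[Testimonial]:
    """Load a corpus from JSON-lines records {id, drug, text, age?, sex?}."""
    out: list[Testimonial] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                Testimonial(
                    id=str(rec["id"]),
                    drug=rec["drug"],
                    text=rec["text"],
                    age=rec.get("age"),
                    sex=rec.get("sex"),
                )
            )
    return out


def write_corpus_jsonl(
    testimonials: Iterable[Testimonial], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for t in testimonials:
            rec = {"id": t.id, "drug": t.drug, "text": t.text}
            if t.age is not None:
                rec["age"] = t.age
            if t.sex is not None:
                rec["sex"] = t.sex
            fh.write(json.dumps(rec) + "\n")


def iter_drugs(testimonials: Iterable[Testimonial]) -> Iterator[str]:
    seen: set[str] = set()
    for t in testimonials:
        if t.drug not in seen:
            seen.add(t.drug)
            yield t.drug
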