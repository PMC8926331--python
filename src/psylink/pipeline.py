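"""End-to-end orchestration: corpus -> LSA -> CCA -> permutation test.

`fit_pipeline` wires the stages together with one configuration object so
the same procedure can be re-run on subgroups (sensitivity analyses) or
from the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import corpus as corpus_mod
from .cca import CcaModel
from .corpus import Testimonial, Vocabulary
from .fingerprints import AffinityPanel
from .lsa import LsaModel, fit_lsa
from .permutation import PermutationResult, permutation_test, select_significant


@dataclass
class PipelineConfig:
    k: int = 50
    h: int | None = None
    per_drug: int | None = 300
    min_count: int = corpus_mod.DEFAULT_MIN_COUNT
    min_word_length: int = corpus_mod.DEFAULT_MIN_WORD_LENGTH
    stoplist: Sequence[str] | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    ridge: float = 0.0
    seed: int = 0


@dataclass
class PipelineResult:
    testimonials: list[Testimonial]
    vocabulary: Vocabulary
    lsa: LsaModel
    model: CcaModel  # all fitted factors
    significant: CcaModel  # truncated to permutation-significant factors
    permutation: PermutationResult
    X: np.ndarray
    Y: np.ndarray
    config: PipelineConfig


def fit_pipeline(
    testimonials: Sequence[Testimonial],
    panel: AffinityPanel,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on a corpus and affinity panel.

    Stages: optional balanced per-drug subsampling, vocabulary building,
    count matrix, tf-idf, LSA at k components, CCA between the semantic
    coordinates and the per-testimonial npKi fingerprints, and the
    max-statistic permutation test whose significant factors define the
    retained model.
    """
    cfg = config or PipelineConfig()
    reports = list(testimonials)
    if cfg.per_drug is not None:
        reports = corpus_mod.balanced_subsample(reports, cfg.per_drug, cfg.seed)
    vocab = corpus_mod.build_vocabulary(
        reports,
        stoplist=cfg.stoplist,
        min_count=cfg.min_count,
        min_word_length=cfg.min_word_length,
    )
    M = corpus_mod.count_matrix(reports, vocab)
    tfidf = corpus_mod.tfidf_transform(M)
    lsa = fit_lsa(tfidf, cfg.k, seed=cfg.seed)
    X = lsa.document_coordinates()
    Y = panel.expand_to_testimonials([t.drug for t in reports])
    model, perm = permutation_test(
        X,
        Y,
        h=cfg.h,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        alpha=cfg.alpha,
        ridge=cfg.ridge,
    )
    model.receptor_names = panel.receptors
    significant = select_significant(perm, model)
    return PipelineResult(
        testimonials=reports,
        vocabulary=vocab,
        lsa=lsa,
        model=model,
        significant=significant,
        permutation=perm,
        X=X,
        Y=Y,
        config=cfg,
    )


def config_for_subgroup(config: PipelineConfig, seed: int | None = None) -> PipelineConfig:
    """Copy a configuration for a subgroup refit (same settings; optionally
    a different seed for the subsampling draw)."""
    return replace(config, seed=config.seed if seed is None else seed)
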