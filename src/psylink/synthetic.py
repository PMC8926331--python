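"""Synthetic study generator with planted receptor-semantic covariation.

Stands in for the real study inputs (a web corpus of experience reports,
an assay-derived affinity panel, an atlas-derived transcription table) so
that every downstream stage can be tested end to end, with the generative
ground truth recorded.

Generative model
----------------
* **Panel.** Ki values are drawn log-uniformly over 1 nM - 100 uM (the
  span of real binding assays); a configurable fraction of entries is
  missing, and each drug keeps at least one strong measured target so its
  npKi normalization is well defined.
* **Latent factors.** Receptor-side factor directions ``true_b`` are the
  leading right singular vectors of the drug-level centered npKi table,
  so the per-drug receptor scores of distinct factors are exactly
  uncorrelated. Each report inherits its drug's receptor score v (constant
  within drug, mirroring the repeated fingerprint rows of the real design)
  and draws a semantic-side score u = rho*v + sqrt(1-rho^2)*eps, eps ~
  N(0,1): the planted canonical correlation rho is realized marginally
  across reports, through between-drug variation plus within-drug
  semantic noise.
* **Words.** Each factor drives an opposing pair of topics whose mixture
  shares move *linearly* with the semantic score: share(pole+/-) ~
  w_pole * (1 +/- c*u). The semantic noise eps is a (rescaled) truncated
  normal and the per-factor gain c is set from the attainable score range
  so shares never need clipping — the expected word counts are then an
  exactly linear function of the latent scores, and the generator plants
  *only* the requested factors (no higher-order between-drug semantic
  structure leaks in). Remaining topics get bounded uniform share noise
  scaled by ``noise_scale``; the pole pairs cancel in the normalizer, so
  normalization preserves linearity. Each topic owns a disjoint
  signature-word block (Dirichlet weights plus a uniform background
  share), and word counts are Poisson with expected counts = document
  length x the mixed word distribution. Document lengths are log-normal
  around ``mean_doc_length``.

``noise_scale = 0`` switches off every nuisance source — background
topics flat, document length fixed, counts set to their rounded
expectations — so that, with a planted correlation of 1, reports of the
same drug become identical and the pipeline recovers the factor exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .corpus import Testimonial
from .fingerprints import AffinityPanel, panel_receptor_names

#: baseline mixture weight of a factor pole topic relative to a background topic
POLE_TOPIC_WEIGHT = 2.0
#: truncation bound (in SDs) of the within-drug semantic noise
SEMANTIC_NOISE_BOUND = 2.8
#: safety margin keeping pole shares strictly positive
GAIN_SAFETY = 0.98
#: probability mass a topic spreads uniformly over the whole vocabulary
TOPIC_BACKGROUND_MASS = 0.2
#: log-normal sigma of document lengths (scaled by noise_scale)
DOC_LENGTH_SIGMA = 0.4

_LETTERS = "abcdefghijklmnopqrstuvwxyz"

#: SD of a standard normal truncated at +/-SEMANTIC_NOISE_BOUND
_TRUNCNORM_SD = float(
    scipy.stats.truncnorm.std(-SEMANTIC_NOISE_BOUND, SEMANTIC_NOISE_BOUND)
)


def _truncated_normal(
    rng: np.random.Generator, shape: tuple[int, ...]
) -> np.ndarray:
    draws = scipy.stats.truncnorm.rvs(
        -SEMANTIC_NOISE_BOUND, SEMANTIC_NOISE_BOUND, size=shape, random_state=rng
    )
    return draws / _TRUNCNORM_SD


def _word_label(i: int) -> str:
    # purely alphabetic synthetic words ("waaaa", "waaab", ...) that survive
    # the tokenizer and length filter
    s = ""
    for _ in range(4):
        s = _LETTERS[i % 26] + s
        i //= 26
    return "w" + s


@dataclass
class SyntheticCorpusSpec:
    """Study-scale configuration of the generator.

    Defaults mirror the reference study design where it is fixed (27 drugs,
    a 40-target panel) and a desk-scale stand-in elsewhere (500-word
    vocabulary against the real 14k; 200 reports per drug against the real
    balanced draw of 300; long documents, as real experience reports run to
    hundreds of words).
    """

    n_drugs: int = 27
    n_receptors: int = 40
    n_reports_per_drug: int = 200
    vocab_size: int = 500
    n_topics: int = 10
    n_factors: int = 2
    noise_scale: float = 1.0
    mean_doc_length: int = 500
    missing_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_drugs": self.n_drugs,
            "n_receptors": self.n_receptors,
            "n_reports_per_drug": self.n_reports_per_drug,
            "vocab_size": self.vocab_size,
            "n_topics": self.n_topics,
            "n_factors": self.n_factors,
            "mean_doc_length": self.mean_doc_length,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be a positive count, got {v}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if not 0 <= self.missing_frac <= 1:
            raise ValueError("missing_frac must lie in [0, 1]")
        if self.n_factors > min(self.n_topics // 2, self.n_receptors, self.n_drugs - 1):
            raise ValueError(
                "n_factors must satisfy n_factors <= min(n_topics // 2, "
                "n_receptors, n_drugs - 1): each factor needs an opposing "
                "topic pair and a receptor-side degree of freedom"
            )

    @property
    def n_reports(self) -> int:
        return self.n_drugs * self.n_reports_per_drug

    @property
    def drug_names(self) -> list[str]:
        return [f"drug{i + 1:02d}" for i in range(self.n_drugs)]

    @property
    def receptor_names(self) -> list[str]:
        real = panel_receptor_names()
        if self.n_receptors <= len(real):
            return real[: self.n_receptors]
        return real + [f"R{i + 1}" for i in range(len(real), self.n_receptors)]


@dataclass
class GroundTruth:
    """Record of the planted generative structure."""

    planted_canonical_correlations: list[float]
    true_a: np.ndarray  # topics x factors log-activation loadings
    true_b: np.ndarray  # receptors x factors, unit-norm columns
    topic_word_loadings: np.ndarray  # topics x vocabulary
    seed: int
    vocabulary: list[str] = field(default_factory=list)
    topic_blocks: list[list[int]] = field(default_factory=list)
    semantic_scores: np.ndarray | None = None  # u, reports x factors
    receptor_scores: np.ndarray | None = None  # v, reports x factors

    def __post_init__(self) -> None:
        rhos = list(self.planted_canonical_correlations)
        if any(not 0 < r <= 1 for r in rhos):
            raise ValueError("planted correlations must lie in (0, 1]")
        if any(r2 >= r1 for r1, r2 in zip(rhos, rhos[1:])):
            raise ValueError("planted correlations must be strictly decreasing")
        norms = np.linalg.norm(self.true_b, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("true_b columns must be unit-norm")

    def factor_topic_pair(self, factor: int) -> tuple[int, int]:
        """(positive-pole, negative-pole) topic indices of one factor."""
        return 2 * factor, 2 * factor + 1

    def signature_words(self, topic: int) -> list[str]:
        """The words of a topic's dedicated signature block."""
        return [self.vocabulary[i] for i in self.topic_blocks[topic]]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted_canonical_correlations": self.planted_canonical_correlations,
                    "true_a": self.true_a.tolist(),
                    "true_b": self.true_b.tolist(),
                    "topic_word_loadings": self.topic_word_loadings.tolist(),
                    "seed": self.seed,
                    "vocabulary": self.vocabulary,
                    "topic_blocks": self.topic_blocks,
                    "semantic_scores": None
                    if self.semantic_scores is None
                    else self.semantic_scores.tolist(),
                    "receptor_scores": None
                    if self.receptor_scores is None
                    else self.receptor_scores.tolist(),
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_canonical_correlations=d["planted_canonical_correlations"],
            true_a=np.array(d["true_a"]),
            true_b=np.array(d["true_b"]),
            topic_word_loadings=np.array(d["topic_word_loadings"]),
            seed=d["seed"],
            vocabulary=d["vocabulary"],
            topic_blocks=d["topic_blocks"],
            semantic_scores=None
            if d["semantic_scores"] is None
            else np.array(d["semantic_scores"]),
            receptor_scores=None
            if d["receptor_scores"] is None
            else np.array(d["receptor_scores"]),
        )


def generate_drug_panel(spec: SyntheticCorpusSpec) -> AffinityPanel:
    """Random affinity panel: Ki log-uniform over 1 nM - 100 uM with
    `spec.missing_frac` of entries missing; every drug keeps one strong
    measured target (1-1000 nM) so npKi normalization is defined."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    shape = (spec.n_drugs, spec.n_receptors)
    ki = 10.0 ** rng.uniform(0.0, 5.0, size=shape)
    missing = rng.random(shape) < spec.missing_frac
    ki[missing] = np.nan
    anchor_cols = rng.integers(0, spec.n_receptors, size=spec.n_drugs)
    anchor_ki = 10.0 ** rng.uniform(0.0, 3.0, size=spec.n_drugs)
    ki[np.arange(spec.n_drugs), anchor_cols] = anchor_ki
    table = pd.DataFrame(
        ki, index=spec.drug_names, columns=spec.receptor_names
    )
    return AffinityPanel(table)


def _topic_word_distributions(
    spec: SyntheticCorpusSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[list[int]]]:
    blocks: list[list[int]] = []
    bounds = np.linspace(0, spec.vocab_size, spec.n_topics + 1).astype(int)
    phi = np.zeros((spec.n_topics, spec.vocab_size))
    for t in range(spec.n_topics):
        idx = list(range(bounds[t], bounds[t + 1]))
        blocks.append(idx)
        w = rng.gamma(5.0, size=len(idx))
        phi[t, idx] = (1.0 - TOPIC_BACKGROUND_MASS) * w / w.sum()
    phi += TOPIC_BACKGROUND_MASS / spec.vocab_size
    return phi, blocks


def generate_corpus(
    panel: AffinityPanel,
    spec: SyntheticCorpusSpec,
    planted_rho: tuple[float, ...] = (0.8, 0.6),
) -> tuple[list[Testimonial], GroundTruth]:
    """Generate testimonials whose semantic structure covaries with the
    panel's npKi fingerprints at the planted canonical correlations.

    Raises a configuration error when the panel cannot support the
    requested number of factors (the drug-level centered fingerprint table
    must have rank >= n_factors, i.e. nonzero receptor-side variance along
    every planted direction).
    """
    planted = [float(r) for r in planted_rho]
    if len(planted) != spec.n_factors:
        raise ValueError(
            f"planted_rho has {len(planted)} entries but spec.n_factors="
            f"{spec.n_factors}"
        )
    if any(not 0 < r <= 1 for r in planted):
        raise ValueError("planted correlations must lie in (0, 1]")
    if any(r2 >= r1 for r1, r2 in zip(planted, planted[1:])):
        raise ValueError("planted correlations must be strictly decreasing")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    npki = panel.npki.to_numpy(dtype=float)
    Z = npki - npki.mean(axis=0)
    Uz, sz, Vzt = scipy.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(sz > 1e-10 * sz[0]))
    if spec.n_factors > rank:
        raise ValueError(
            f"planted correlations infeasible: drug-level fingerprint table "
            f"has rank {rank} < n_factors={spec.n_factors} "
            "(receptor-side variance is zero along some planted direction)"
        )
    F = spec.n_factors
    true_b = Vzt[:F].T  # unit-norm columns
    # per-drug receptor scores, exactly uncorrelated across factors;
    # scaled to unit population variance over reports (equal drug counts)
    drug_scores = Uz[:, :F] * np.sqrt(spec.n_drugs)

    drug_idx = np.repeat(np.arange(spec.n_drugs), spec.n_reports_per_drug)
    v = drug_scores[drug_idx]  # reports x F, constant within drug
    rho_arr = np.array(planted)
    # bounded within-drug semantic noise (rescaled truncated normal, unit
    # variance); boundedness lets the topic shares below stay strictly
    # positive without any clipping, keeping expected counts exactly
    # linear in the latent scores
    eps = _truncated_normal(rng, v.shape)
    u = v * rho_arr + eps * np.sqrt(1.0 - rho_arr**2)

    phi, blocks = _topic_word_distributions(spec, rng)
    vocabulary = [_word_label(i) for i in range(spec.vocab_size)]
    # per-factor gain: the largest attainable |u| maps to just under a
    # full share swing, so shares stay in (0, 2 * baseline)
    u_bound = rho_arr * np.abs(drug_scores).max(axis=0) + np.sqrt(
        1.0 - rho_arr**2
    ) * (SEMANTIC_NOISE_BOUND / _TRUNCNORM_SD)
    gain = GAIN_SAFETY / u_bound
    true_a = np.zeros((spec.n_topics, F))
    for f in range(F):
        true_a[2 * f, f] = gain[f]
        true_a[2 * f + 1, f] = -gain[f]
    weights = np.ones(spec.n_topics)
    weights[: 2 * F] = POLE_TOPIC_WEIGHT
    m_raw = np.tile(weights, (spec.n_reports, 1))
    swing = u * gain  # in (-1, 1) by construction
    for f in range(F):
        m_raw[:, 2 * f] = weights[2 * f] * (1.0 + swing[:, f])
        m_raw[:, 2 * f + 1] = weights[2 * f + 1] * (1.0 - swing[:, f])
    n_background = spec.n_topics - 2 * F
    if n_background > 0 and spec.noise_scale > 0:
        z = np.clip(
            spec.noise_scale * rng.uniform(-1.0, 1.0, (spec.n_reports, n_background)),
            -0.95,
            None,
        )
        m_raw[:, 2 * F :] *= 1.0 + z
    # pole pairs cancel in the row sum, so normalizing keeps expected
    # counts linear in u
    mix = m_raw / m_raw.sum(axis=1, keepdims=True)

    if spec.noise_scale > 0:
        mu = np.log(spec.mean_doc_length) - 0.5 * (
            DOC_LENGTH_SIGMA * spec.noise_scale
        ) ** 2
        lengths = rng.lognormal(mu, DOC_LENGTH_SIGMA * spec.noise_scale, spec.n_reports)
    else:
        lengths = np.full(spec.n_reports, float(spec.mean_doc_length))

    rates = mix @ phi * lengths[:, None]
    if spec.noise_scale > 0:
        counts = rng.poisson(rates)
    else:
        counts = np.rint(rates).astype(np.int64)

    drug_names = panel.drugs
    ages = rng.integers(18, 66, size=spec.n_reports)
    sexes = rng.choice(np.array(["female", "male"]), size=spec.n_reports)
    testimonials: list[Testimonial] = []
    word_arr = np.array(vocabulary)
    for j in range(spec.n_reports):
        tokens = np.repeat(word_arr, counts[j])
        rng.shuffle(tokens)
        testimonials.append(
            Testimonial(
                id=f"r{j + 1:06d}",
                drug=drug_names[drug_idx[j]],
                text=" ".join(tokens),
                age=int(ages[j]),
                sex=str(sexes[j]),
            )
        )
    truth = GroundTruth(
        planted_canonical_correlations=planted,
        true_a=true_a,
        true_b=true_b,
        topic_word_loadings=phi,
        seed=spec.seed,
        vocabulary=vocabulary,
        topic_blocks=blocks,
        semantic_scores=u,
        receptor_scores=v,
    )
    return testimonials, truth


def generate_region_expression(
    n_regions: int,
    receptor_names: list[str],
    seed: int = 0,
    anchor_receptors: list[str] | None = None,
    n_anchor_regions: int = 0,
    anchor_strength: float = 3.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Random region x receptor transcription table of positive levels
    (log-normal), optionally with an anchor block: the first
    `n_anchor_regions` regions (labelled with a 'Vis' tag) get elevated
    expression of `anchor_receptors`, for exercising the sign-anchoring
    rule. Returns (table, anchor labels)."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions (z-scoring undefined below that)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    levels = rng.lognormal(0.0, 0.5, size=(n_regions, len(receptor_names)))
    labels = [
        f"region_{i + 1:03d}_Vis" if i < n_anchor_regions else f"region_{i + 1:03d}"
        for i in range(n_regions)
    ]
    table = pd.DataFrame(levels, index=labels, columns=receptor_names)
    anchors = labels[:n_anchor_regions]
    if anchor_receptors:
        missing = [r for r in anchor_receptors if r not in receptor_names]
        if missing:
            raise KeyError(f"anchor receptors not in panel: {missing}")
        table.loc[anchors, anchor_receptors] += anchor_strength
    return table, anchors
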