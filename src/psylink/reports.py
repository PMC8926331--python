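"""Human-readable characterization of receptor-experience factors.

Each significant factor is summarized by (i) signed word saliences — the
back-projection of the factor's semantic canonical vector through the LSA
word weights, salience = W diag(R) a, whose positive and negative entries
define the factor's two experiential poles; (ii) per-drug association
scores — the factor's receptor variate evaluated at each drug's centered
fingerprint, score(d) = (npKi(d) - mean_Y) . b; (iii) the receptor weights
b themselves; and (iv) the extreme regions of its anatomical projection.

Also implemented here are the sensitivity analyses: correlations of the
canonical variates with language complexity (distinct words per report)
and typical drug duration, and subgroup refits (age / sex splits) whose
receptor-side vectors are compared by Pearson correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .anatomy import FactorAnatomy
from .cca import CcaModel, compare_models
from .corpus import Testimonial, Vocabulary, tokenize
from .fingerprints import AffinityPanel
from .lsa import LsaModel
from .pipeline import PipelineConfig, PipelineResult, fit_pipeline


@dataclass
class FactorReport:
    factor_index: int
    rho: float
    p_value: float
    top_words_positive: list[tuple[str, float]]
    top_words_negative: list[tuple[str, float]]
    drug_scores: dict[str, float]
    receptor_weights: dict[str, float]
    region_extremes: dict[str, list[str]] | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def word_saliences(
    lsa: LsaModel, model: CcaModel, factor: int
) -> np.ndarray:
    """Signed per-word salience of one factor: W diag(R) a_factor.

    Positive entries load on the factor's positive experiential pole,
    negative entries on the opposite pole; magnitude ranks the words."""
    if lsa.k != model.a.shape[0]:
        raise ValueError(
            f"component mismatch: LSA has k={lsa.k} but the CCA semantic "
            f"side has {model.a.shape[0]} inputs"
        )
    return (lsa.W * lsa.R) @ model.a[:, factor]


def drug_scores(
    panel: AffinityPanel, model: CcaModel, factor: int
) -> pd.Series:
    """Signed association of each drug with one factor: the receptor
    variate at the drug's fingerprint, (npKi(d) - mean_Y) . b_factor.
    Constant across a drug's testimonials by construction."""
    fp = panel.npki.to_numpy(dtype=float)
    scores = (fp - model.mean_y) @ model.b[:, factor]
    return pd.Series(scores, index=panel.drugs)


def _ranked_words(
    salience: np.ndarray, vocab: Vocabulary, top_n: int
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    # deterministic: sort by |salience| descending, ties lexicographic
    order = sorted(
        range(len(salience)), key=lambda i: (-abs(salience[i]), vocab.words[i])
    )
    pos = [(vocab.words[i], float(salience[i])) for i in order if salience[i] > 0]
    neg = [(vocab.words[i], float(salience[i])) for i in order if salience[i] < 0]
    return pos[:top_n], neg[:top_n]


def factor_report(
    result_vocab: Vocabulary,
    lsa: LsaModel,
    model: CcaModel,
    p_values: np.ndarray,
    panel: AffinityPanel,
    factor: int,
    anatomy: FactorAnatomy | None = None,
    top_words: int = 30,
    top_regions: int = 10,
) -> FactorReport:
    """Assemble the full report of one factor from fitted artifacts (pure
    function of its inputs: nothing is refitted)."""
    sal = word_saliences(lsa, model, factor)
    pos, neg = _ranked_words(sal, result_vocab, top_words)
    scores = drug_scores(panel, model, factor)
    receptors = (
        model.receptor_names
        if model.receptor_names is not None
        else [f"receptor_{i + 1}" for i in range(model.b.shape[0])]
    )
    return FactorReport(
        factor_index=factor,
        rho=float(model.rho[factor]),
        p_value=float(p_values[factor]),
        top_words_positive=pos,
        top_words_negative=neg,
        drug_scores={d: float(s) for d, s in scores.sort_values(ascending=False).items()},
        receptor_weights={r: float(w) for r, w in zip(receptors, model.b[:, factor])},
        region_extremes=None
        if anatomy is None
        else anatomy.top_regions(factor, top_regions),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")  # undefined under zero variance
    return float(np.corrcoef(x, y)[0, 1])


def confound_associations(
    testimonials: Sequence[Testimonial],
    metadata: pd.DataFrame,
    model: CcaModel,
) -> pd.DataFrame:
    """Pearson correlations of each factor's variates with two potential
    confounds: language complexity (distinct words per report) and the
    drug's typical experience duration in hours.

    `metadata` needs columns ``drug`` and ``avg_duration_hours`` covering
    every drug in the corpus. Zero-variance confounds yield NaN
    (undefined correlation). Rows: one per factor; columns:
    (variate U|V) x (distinct_words | duration_hours)."""
    duration_of = dict(
        zip(metadata["drug"], metadata["avg_duration_hours"].astype(float))
    )
    missing = sorted({t.drug for t in testimonials} - set(duration_of))
    if missing:
        raise KeyError(f"metadata lacks durations for drugs: {missing}")
    distinct = np.array(
        [len(set(tokenize(t.text))) for t in testimonials], dtype=float
    )
    duration = np.array([duration_of[t.drug] for t in testimonials])
    rows = []
    for i in range(model.h):
        rows.append(
            {
                "factor": i + 1,
                "U_distinct_words": _pearson(model.U[:, i], distinct),
                "U_duration_hours": _pearson(model.U[:, i], duration),
                "V_distinct_words": _pearson(model.V[:, i], distinct),
                "V_duration_hours": _pearson(model.V[:, i], duration),
            }
        )
    return pd.DataFrame(rows).set_index("factor")


def split_by_median_age(
    testimonials: Sequence[Testimonial],
) -> dict[str, list[Testimonial]]:
    """Older/younger subgroups at the median reported age (reports without
    an age are dropped)."""
    aged = [t for t in testimonials if t.age is not None]
    if not aged:
        raise ValueError("no testimonial carries an age")
    cut = float(np.median([t.age for t in aged]))
    return {
        "younger": [t for t in aged if t.age < cut],
        "older": [t for t in aged if t.age >= cut],
    }


def split_by_sex(
    testimonials: Sequence[Testimonial],
) -> dict[str, list[Testimonial]]:
    groups: dict[str, list[Testimonial]] = {}
    for t in testimonials:
        if t.sex is not None:
            groups.setdefault(t.sex, []).append(t)
    if len(groups) < 2:
        raise ValueError("need at least two sex categories to form subgroups")
    return groups


def subgroup_stability(
    testimonials: Sequence[Testimonial],
    panel: AffinityPanel,
    grouping: Callable[[Sequence[Testimonial]], dict[str, list[Testimonial]]],
    config: PipelineConfig | None = None,
) -> dict[str, object]:
    """Refit the entire pipeline per subgroup and compare receptor-side
    canonical vectors pairwise (sign-aligned, greedily matched Pearson r).

    Drugs absent from a subgroup are dropped from that refit with a
    warning; an empty subgroup is an error. Returns the subgroup fits and
    a pairwise similarity table of leading matched factors."""
    groups = grouping(testimonials)
    if any(len(g) == 0 for g in groups.values()):
        empty = [k for k, g in groups.items() if len(g) == 0]
        raise ValueError(f"empty subgroup(s): {empty}")
    if len(groups) < 2:
        raise ValueError("grouping produced fewer than two subgroups")
    fits: dict[str, PipelineResult] = {}
    for name, members in groups.items():
        fits[name] = fit_pipeline(members, panel, config)
    names = sorted(fits)
    sim = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    matches: dict[tuple[str, str], dict] = {}
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            m1, m2 = fits[n1].model, fits[n2].model
            comp = compare_models(m1, m2)
            matches[(n1, n2)] = comp
            lead = float(comp["similarity"][0]) if len(comp["similarity"]) else np.nan
            sim.loc[n1, n2] = sim.loc[n2, n1] = lead
    return {"fits": fits, "similarity": sim, "comparisons": matches}
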