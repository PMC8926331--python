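"""Projecting receptor-side factors onto regional gene transcription.

Each significant factor's receptor vector b is mapped into anatomy by a
dot product with a region x receptor table of receptor gene transcription
levels (in the reference analysis: Allen Human Brain Atlas probe averages
over six donors mapped to the 200-region Schaefer-Yeo parcellation; any
table with matching receptor names works). Preprocessing z-scores each
receptor's transcription across regions and then shifts the whole table
so its global minimum is zero — all-nonnegative expression keeps the
directionality of the projection interpretable.

Factor scores per region ("genetic factor expression") are demeaned and
variance-scaled per factor. Because a CCA factor's overall sign is
arbitrary, signs are anchored anatomically: the pole more strongly
expressed in a designated anchor set of regions (visual-cortex parcels in
the reference analysis) is made positive by a joint sign flip of the
factor on both sides, which leaves every canonical correlation untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cca import CcaModel


@dataclass
class RegionExpression:
    """Preprocessed region x receptor transcription table (z-scored columns,
    global minimum shifted to zero)."""

    expression: pd.DataFrame

    @property
    def regions(self) -> list[str]:
        return list(self.expression.index)

    @property
    def receptors(self) -> list[str]:
        return list(self.expression.columns)


@dataclass
class FactorAnatomy:
    """Region x factor genetic-factor-expression scores (per-factor mean 0,
    SD 1) and the anchor region set used for sign orientation, if any."""

    scores: pd.DataFrame
    anchor_regions: list[str] | None = None

    def write_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t")

    def top_regions(self, factor: int, n: int = 10) -> dict[str, list[str]]:
        """Top-n region labels at each pole of one factor (0-based index)."""
        col = self.scores.iloc[:, factor].sort_values()
        return {
            "positive": list(col.index[::-1][:n]),
            "negative": list(col.index[:n]),
        }


def preprocess_expression(
    raw: pd.DataFrame,
    receptors: Sequence[str] | None = None,
    shift: str = "global",
    ddof: int = 0,
) -> RegionExpression:
    """Z-score each receptor column across regions, then shift to a zero
    minimum.

    `receptors` reorders/matches columns by name (order-insensitive);
    `shift="global"` subtracts the single global minimum (default),
    `shift="per-column"` shifts each column separately. Z-scoring uses the
    population SD (ddof=0) by default.
    """
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 regions to z-score across regions")
    if receptors is not None:
        missing = [r for r in receptors if r not in raw.columns]
        if missing:
            raise KeyError(f"expression table lacks receptors: {missing}")
        raw = raw.loc[:, list(receptors)]
    values = raw.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=ddof)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        names = [raw.columns[i] for i in zero_var]
        raise ValueError(
            f"zero-variance transcription column(s), z-score undefined: {names}"
        )
    z = (values - values.mean(axis=0)) / sd
    if shift == "global":
        z = z - z.min()
    elif shift == "per-column":
        z = z - z.min(axis=0)
    else:
        raise ValueError(f"unknown shift mode: {shift!r}")
    return RegionExpression(
        pd.DataFrame(z, index=raw.index, columns=raw.columns)
    )


def project_factors(
    expr: RegionExpression, model: CcaModel
) -> FactorAnatomy:
    """Genetic factor expression: scores = expression . b, then per-factor
    demeaning and unit-variance scaling (population SD) across regions."""
    if model.h < 1:
        raise ValueError("model has no factors to project")
    if model.receptor_names is not None:
        unmatched = [
            r for r in model.receptor_names if r not in expr.expression.columns
        ]
        if unmatched:
            raise KeyError(f"expression table lacks receptors: {unmatched}")
        table = expr.expression.loc[:, model.receptor_names]
    else:
        if expr.expression.shape[1] != model.b.shape[0]:
            raise ValueError(
                "receptor count mismatch between expression table and model"
            )
        table = expr.expression
    raw_scores = table.to_numpy(dtype=float) @ model.b
    mu = raw_scores.mean(axis=0)
    sd = raw_scores.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("degenerate factor: constant projection across regions")
    scores = (raw_scores - mu) / sd
    return FactorAnatomy(
        pd.DataFrame(
            scores,
            index=expr.expression.index,
            columns=[f"factor_{i + 1}" for i in range(model.h)],
        )
    )


def orient_signs(
    anatomy: FactorAnatomy,
    model: CcaModel,
    anchor_regions: Sequence[str],
) -> tuple[FactorAnatomy, CcaModel]:
    """Anchor each factor's sign: if the mean score over the anchor regions
    is negative, jointly flip the factor (b, a, U, V and the regional
    scores). Ties (anchor mean exactly zero) keep the fit-time sign.
    Returns a re-oriented copy; canonical correlations are unchanged."""
    anchors = list(anchor_regions)
    if not anchors:
        raise ValueError("anchor_regions must be nonempty")
    unknown = [r for r in anchors if r not in anatomy.scores.index]
    if unknown:
        raise KeyError(f"unknown anchor region label(s): {unknown}")
    scores = anatomy.scores.copy()
    oriented = model.truncated(model.h)  # deep-ish copy of factor arrays
    anchor_means = scores.loc[anchors].mean(axis=0).to_numpy()
    for i, m in enumerate(anchor_means):
        if m < 0:
            oriented.flip_factor(i)
            scores.iloc[:, i] *= -1.0
    return FactorAnatomy(scores, anchor_regions=anchors), oriented


def visual_anchor_labels(
    region_labels: Sequence[str], pattern: str = "Vis"
) -> list[str]:
    """Convenience selector for visual-network parcels: region labels whose
    name contains `pattern` (matches the naming scheme of the Schaefer-Yeo
    atlas, where visual-network parcels carry a 'Vis' tag)."""
    hits = [r for r in region_labels if pattern in r]
    if not hits:
        raise ValueError(f"no region label contains {pattern!r}")
    return hits
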