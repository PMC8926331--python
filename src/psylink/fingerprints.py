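"""Drug x receptor affinity fingerprints.

Binding strengths are inhibition constants (Ki, in nM): the ligand
concentration occupying half the receptors in a competition assay, so
*lower* Ki means *higher* affinity. For cross-drug comparison each drug's
Ki vector is converted to a potency-normalized scale::

    pKi  = -log10(Ki in molar)
    npKi = 4 + pKi - pKiMax

where pKiMax is the drug's strongest measured affinity. The strongest
target of every drug therefore sits at npKi = 4, each npKi unit spans one
order of magnitude of Ki, and unmeasured or non-significant entries
(Ki > 10,000 nM, i.e. weaker than 10 uM) are set to the floor value 0.
Potency is factored out, so drugs of very different dose ranges can be
compared by their binding *pattern*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Ki above this value (in nM) counts as non-significant binding.
DEFAULT_NONSIGNIFICANT_NM = 10_000.0

#: npKi assigned to the strongest measured target of each drug.
NPKI_CEILING = 4.0


def _load_resource_text(name: str) -> str:
    return (_importlib_resources.files("psylink.resources") / name).read_text()


def panel_receptor_names() -> list[str]:
    """The packaged 40-target binding panel (receptors, transporters, channels)."""
    lines = _load_resource_text("receptor_panel.txt").splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def load_drug_metadata() -> pd.DataFrame:
    """Packaged drug overview table: class, testimonial count, average duration."""
    with _importlib_resources.as_file(
        _importlib_resources.files("psylink.resources") / "drug_table.csv"
    ) as path:
        meta = pd.read_csv(path)
    if (meta["n_testimonials"] < 1).any():
        raise ValueError("drug metadata: testimonial counts must be >= 1")
    if (meta["avg_duration_hours"] <= 0).any():
        raise ValueError("drug metadata: durations must be positive")
    return meta


def ki_from_ic50(ic50: float, agonist_conc: float, ec50: float) -> float:
    """Cheng-Prusoff conversion: Ki = IC50 / (1 + [A]/EC50).

    `ic50` is the inhibitor concentration halving activity, `agonist_conc`
    the fixed agonist concentration [A] of the assay and `ec50` the agonist
    concentration giving half-maximal stimulation. Units cancel between
    [A] and EC50, so Ki is returned in the units of `ic50`.
    """
    if ic50 <= 0 or ec50 <= 0:
        raise ValueError("ic50 and ec50 must be positive concentrations")
    if agonist_conc < 0:
        raise ValueError("agonist concentration cannot be negative")
    return ic50 / (1.0 + agonist_conc / ec50)


def normalize_npki(
    ki_nM: np.ndarray | Sequence[float],
    nonsignificant_threshold_nM: float = DEFAULT_NONSIGNIFICANT_NM,
) -> np.ndarray:
    """Normalize one drug's Ki vector (nM; NaN = missing) to npKi in [0, 4].

    Measured entries above the threshold are treated exactly like missing
    ones (floor value 0). Raises if no entry is measured at or below the
    threshold, since pKiMax is then undefined.
    """
    ki = np.asarray(ki_nM, dtype=float)
    measured = np.isfinite(ki) & (ki <= nonsignificant_threshold_nM)
    if not measured.any():
        raise ValueError("npKi undefined: no measured Ki at or below threshold")
    if (ki[measured] <= 0).any():
        raise ValueError("Ki values must be positive concentrations")
    # pKi in molar units from Ki given in nM: pKi = 9 - log10(Ki_nM)
    pki = 9.0 - np.log10(ki[measured])
    npki = np.zeros_like(ki)
    # grouping (pKi - pKiMax) first keeps the per-drug maximum at exactly 4.0
    npki[measured] = np.maximum(NPKI_CEILING + (pki - pki.max()), 0.0)
    return npki


@dataclass
class AffinityPanel:
    """Drug x receptor Ki table plus its npKi normalization.

    ``ki_nM`` is a drugs-by-receptors DataFrame with NaN for missing
    assays; ``npki`` is computed row-wise with :func:`normalize_npki`.
    """

    ki_nM: pd.DataFrame
    nonsignificant_threshold_nM: float = DEFAULT_NONSIGNIFICANT_NM
    npki: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        values = np.vstack(
            [
                normalize_npki(row, self.nonsignificant_threshold_nM)
                for row in self.ki_nM.to_numpy(dtype=float)
            ]
        )
        self.npki = pd.DataFrame(
            values, index=self.ki_nM.index, columns=self.ki_nM.columns
        )

    @property
    def drugs(self) -> list[str]:
        return list(self.ki_nM.index)

    @property
    def receptors(self) -> list[str]:
        return list(self.ki_nM.columns)

    @classmethod
    def from_assays(
        cls,
        assays: pd.DataFrame,
        threshold_nM: float = DEFAULT_NONSIGNIFICANT_NM,
        replicate_average: str = "geometric",
    ) -> "AffinityPanel":
        """Build a panel from long-form assay rows (drug, receptor, ki_nM).

        Replicated assays for one (drug, receptor) pair are averaged on the
        log scale by default (geometric mean), consistent with the pKi
        normalization; ``replicate_average="arithmetic"`` averages raw Ki.
        """
        if replicate_average == "geometric":
            agg = assays.groupby(["drug", "receptor"])["ki_nM"].apply(
                lambda v: float(np.exp(np.mean(np.log(v))))
            )
        elif replicate_average == "arithmetic":
            agg = assays.groupby(["drug", "receptor"])["ki_nM"].mean()
        else:
            raise ValueError(f"unknown replicate_average: {replicate_average!r}")
        wide = agg.unstack("receptor")
        wide.index.name = None
        wide.columns.name = None
        return cls(wide, threshold_nM)

    @classmethod
    def read_csv(
        cls, path: str | Path, threshold_nM: float = DEFAULT_NONSIGNIFICANT_NM
    ) -> "AffinityPanel":
        """Read a panel CSV: first column drug names, other columns receptors,
        cells Ki in nM, empty cell = missing assay."""
        ki = pd.read_csv(path, index_col=0)
        return cls(ki, threshold_nM)

    def to_csv(self, path: str | Path) -> None:
        self.ki_nM.to_csv(path)

    def expand_to_testimonials(self, drug_labels: Sequence[str]) -> np.ndarray:
        """Per-testimonial receptor matrix Y: row j is the npKi fingerprint of
        the drug taken in testimonial j. Rows repeat within a drug, so
        rank(Y) is at most the number of distinct drugs."""
        unknown = sorted({d for d in drug_labels if d not in self.npki.index})
        if unknown:
            raise KeyError(f"drugs absent from the affinity panel: {unknown}")
        return self.npki.loc[list(drug_labels)].to_numpy(dtype=float)
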