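"""Inter-rater agreement on categorical landmark labels.

Cohen's kappa corrects the raw per-case agreement between two raters for
the agreement expected by chance from their label marginals:

    kappa = (p_o - p_e) / (1 - p_e)

where p_o is the fraction of cases with identical labels and
p_e = sum_k marginal_a(k) * marginal_b(k). Labels are treated as nominal
(unweighted kappa); the label alphabet can be vertebral levels (T1..L5) or
any other finite set. The module is a harness for externally supplied label
CSVs (schema: case_id,landmark,label) — reproducing any particular study's
kappa values requires that study's radiographs and observers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedKappaError, ValidationError

__all__ = [
    "RaterLabels",
    "KappaResult",
    "cohen_kappa",
    "agreement_table",
    "mean_absolute_difference",
    "agreement_band",
]


@dataclass(frozen=True)
class RaterLabels:
    """Ordered per-case categorical labels from one rater."""

    cases: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.cases) != len(self.labels):
            raise ValidationError("cases and labels must have equal length")
        if any(lab is None or str(lab) == "" for lab in self.labels):
            raise ValidationError("missing labels are not allowed")

    def __len__(self) -> int:
        return len(self.cases)

    @classmethod
    def from_csv(cls, path, landmark: str | None = None) -> "RaterLabels":
        """Read a ``case_id,landmark,label`` CSV, optionally filtering to one
        landmark (SEV/IEV/AV)."""
        df = pd.read_csv(path, dtype=str)
        required = {"case_id", "label"}
        if not required.issubset(df.columns):
            raise ValidationError(f"CSV must have columns {sorted(required)}")
        if landmark is not None:
            if "landmark" not in df.columns:
                raise ValidationError("CSV has no 'landmark' column to filter on")
            df = df[df["landmark"] == landmark]
        if df["label"].isna().any():
            raise ValidationError("missing labels are not allowed")
        return cls(tuple(df["case_id"]), tuple(df["label"]))


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected agreement between two raters."""

    observed_agreement: float
    expected_agreement: float
    kappa: float
    n_cases: int

    @property
    def band(self) -> str:
        return agreement_band(self.kappa)


def agreement_band(kappa: float) -> str:
    """Conventional verbal band for a kappa value (reporting only).

    0.7-0.9 counts as good agreement; above 0.9 excellent; no computation
    depends on these bands.
    """
    if kappa > 0.9:
        return "excellent"
    if kappa >= 0.7:
        return "good"
    if kappa >= 0.4:
        return "moderate"
    if kappa >= 0.0:
        return "poor"
    return "worse than chance"


def _check_pair(a: RaterLabels, b: RaterLabels) -> None:
    if a.cases != b.cases:
        raise ValidationError("raters must label the same cases in the same order")
    if len(a) < 2:
        raise ValidationError("need at least 2 cases")


def agreement_table(a: RaterLabels, b: RaterLabels) -> pd.DataFrame:
    """K x K contingency counts over the union label alphabet.

    Rows index rater a's labels, columns rater b's; the grand total equals
    the number of cases, and kappa computed from this table equals
    :func:`cohen_kappa`'s output.
    """
    _check_pair(a, b)
    alphabet = sorted(set(a.labels) | set(b.labels))
    table = pd.crosstab(
        pd.Categorical(list(a.labels), categories=alphabet),
        pd.Categorical(list(b.labels), categories=alphabet),
        dropna=False,
    )
    return table.reindex(index=alphabet, columns=alphabet, fill_value=0)


def cohen_kappa(a: RaterLabels, b: RaterLabels) -> KappaResult:
    """Unweighted Cohen's kappa between two raters.

    Raises
    ------
    UndefinedKappaError
        When expected agreement is 1 (both raters constant on the same
        single label), leaving kappa undefined.
    """
    table = agreement_table(a, b).to_numpy(dtype=float)
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if 1.0 - p_e < 1e-12:
        raise UndefinedKappaError(
            "expected agreement is 1; kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        observed_agreement=float(p_o),
        expected_agreement=float(p_e),
        kappa=float(kappa),
        n_cases=int(n),
    )


def mean_absolute_difference(x, y) -> float:
    """Mean over cases of |x_i - y_i| (inter-observer error on angles)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValidationError("x and y must be equal-length 1-D with n >= 1")
    return float(np.mean(np.abs(x - y)))
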