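"""Biochemical AD classification from CSF ELISA markers.

Two rules are implemented. The primary rule calls a sample AD when CSF
t-tau exceeds 400 ng/l AND at least one amyloid criterion holds: Ab1-42
below 550 ng/l, or the Ab1-42/Ab1-40 ratio below 0.065 (when Ab1-40 was
measured). The Hulstaert index is an Ab1-42/t-tau composite,
Ab1-42 / (240 + 1.18 * t-tau), with values below 1 classified as AD.

All inequalities are strict as worded ("above", "below"): boundary values
classify as non-AD. Samples missing t-tau or Ab1-42 cannot be evaluated and
are excluded, unless ``control_override`` marks them as known non-AD
controls (young controls without any AD indication enrolled despite missing
clinical chemistry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .datatypes import SampleMeta

__all__ = [
    "ClinicalThresholds",
    "Label",
    "classify_primary",
    "hulstaert_index",
    "classify_hulstaert",
    "classify_cohort",
    "labels_as_series",
]

Label = Literal["AD", "non_AD", "excluded"]


@dataclass(frozen=True)
class ClinicalThresholds:
    """Cutoffs in ng/l (concentrations) / dimensionless (ratio, index)."""

    ttau_cut: float = 400.0
    ab42_cut: float = 550.0
    ratio_cut: float = 0.065
    hulstaert_intercept: float = 240.0
    hulstaert_slope: float = 1.18
    hulstaert_cut: float = 1.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_THRESHOLDS = ClinicalThresholds()


def _check_nonneg(meta: SampleMeta) -> None:
    for name in ("t_tau", "ab42", "ab40"):
        v = getattr(meta, name)
        if v is not None and v < 0:
            raise ValueError(f"sample {meta.sample_id}: negative {name}")


def classify_primary(
    meta: SampleMeta, thresholds: ClinicalThresholds = DEFAULT_THRESHOLDS
) -> Label:
    """Primary biochemical rule: t-tau AND (Ab42 OR Ab42/Ab40 ratio).

    Missing Ab1-40 disables only the ratio branch (one cohort lacked Ab1-40
    measurements yet was classified on the Ab1-42 criterion alone).
    """
    _check_nonneg(meta)
    if meta.t_tau is None or meta.ab42 is None:
        return "non_AD" if meta.control_override else "excluded"
    tau_high = meta.t_tau > thresholds.ttau_cut
    ab42_low = meta.ab42 < thresholds.ab42_cut
    ratio_low = (
        meta.ab40 is not None
        and meta.ab40 > 0
        and meta.ab42 / meta.ab40 < thresholds.ratio_cut
    )
    return "AD" if tau_high and (ab42_low or ratio_low) else "non_AD"


def hulstaert_index(
    ab42: float, t_tau: float, thresholds: ClinicalThresholds = DEFAULT_THRESHOLDS
) -> float:
    """Ab1-42 / (240 + 1.18 * t-tau), ng/l in, dimensionless out."""
    if ab42 is None or t_tau is None:
        raise ValueError("hulstaert_index requires both ab42 and t_tau")
    if ab42 < 0 or t_tau < 0:
        raise ValueError("concentrations must be >= 0")
    return ab42 / (thresholds.hulstaert_intercept + thresholds.hulstaert_slope * t_tau)


def classify_hulstaert(
    meta: SampleMeta, thresholds: ClinicalThresholds = DEFAULT_THRESHOLDS
) -> Label:
    """AD iff the Hulstaert index falls strictly below the cutoff of one."""
    _check_nonneg(meta)
    if meta.t_tau is None or meta.ab42 is None:
        return "non_AD" if meta.control_override else "excluded"
    score = hulstaert_index(meta.ab42, meta.t_tau, thresholds)
    return "AD" if score < thresholds.hulstaert_cut else "non_AD"


def classify_cohort(
    metas: Iterable[SampleMeta],
    rule: Literal["primary", "hulstaert"] = "primary",
    thresholds: ClinicalThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Label every sample; returns sample_id, cohort, label, reason.

    Excluded samples carry the missing marker in ``reason``; summary counts
    are available via ``.groupby(["cohort", "label"]).size()`` on the result.
    """
    if rule not in ("primary", "hulstaert"):
        raise ValueError(f"unknown rule {rule!r}")
    classify = classify_primary if rule == "primary" else classify_hulstaert
    rows = []
    for meta in metas:
        label = classify(meta, thresholds)
        if label == "excluded":
            missing = [n for n in ("t_tau", "ab42") if getattr(meta, n) is None]
            reason = f"missing {'+'.join(missing)}"
        elif meta.control_override and (meta.t_tau is None or meta.ab42 is None):
            reason = "control_override"
        else:
            reason = rule
        rows.append(
            {
                "sample_id": meta.sample_id,
                "cohort": meta.cohort,
                "label": label,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def labels_as_series(label_table: pd.DataFrame) -> pd.Series:
    """AD/non_AD labels indexed by sample_id; excluded samples dropped."""
    kept = label_table[label_table["label"] != "excluded"]
    return kept.set_index("sample_id")["label"]
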