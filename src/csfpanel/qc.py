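"""Filtering, transformation, completeness/abundance QC and CV reporting.

The QC conventions follow standard label-free proteomics practice: proteins
with too few observations across the whole dataset are dropped, intensities
are log10-transformed for statistics, Z-scores are computed per protein
within a sample stratum (cohort or global), and assay precision is
summarized as coefficients of variation over replicate triples on the
linear intensity scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import IntensityMatrix, SampleMeta, Scale

__all__ = [
    "filter_min_observations",
    "log10_transform",
    "completeness_curve",
    "zscore",
    "group_median_profile",
    "cumulative_intensity_fraction",
    "compute_cv_report",
    "biological_cv",
    "CVReport",
]

logger = logging.getLogger(__name__)


def filter_min_observations(matrix: IntensityMatrix, min_obs: int = 20) -> IntensityMatrix:
    """Keep proteins quantified in at least ``min_obs`` samples; order preserved."""
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    counts = matrix.values.notna().sum(axis=1)
    keep = counts[counts >= min_obs].index
    if len(keep) == 0:
        logger.warning("all %d proteins fall below min_obs=%d", matrix.n_proteins, min_obs)
    return matrix.subset_proteins(keep)


def log10_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log10; missing entries stay missing."""
    if matrix.scale is not Scale.LINEAR:
        raise ValueError("matrix is already log10-scaled")
    vals = matrix.values.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("cannot log10-transform non-positive intensities")
    return replace(matrix, values=np.log10(matrix.values), scale=Scale.LOG10)


def completeness_curve(matrix: IntensityMatrix) -> pd.Series:
    """Number of proteins present in >= k samples, for k = 1..n_samples.

    Non-increasing in k; the value at k=1 counts proteins with any
    observation.
    """
    counts = matrix.values.notna().sum(axis=1).to_numpy()
    ks = np.arange(1, matrix.n_samples + 1)
    curve = [(counts >= k).sum() for k in ks]
    return pd.Series(curve, index=pd.Index(ks, name="min_samples"), name="n_proteins")


def _strata(
    metadata: Sequence[SampleMeta], samples: Sequence[str], stratum: str
) -> dict[str, list[str]]:
    meta_by_id = {m.sample_id: m for m in metadata}
    if stratum == "global":
        return {"all": list(samples)}
    if stratum == "within_cohort":
        out: dict[str, list[str]] = {}
        for s in samples:
            out.setdefault(meta_by_id[s].cohort, []).append(s)
        return out
    raise ValueError(f"stratum must be 'within_cohort' or 'global', got {stratum!r}")


def zscore(
    matrix: IntensityMatrix,
    metadata: Sequence[SampleMeta],
    stratum: Literal["within_cohort", "global"] = "within_cohort",
) -> IntensityMatrix:
    """Per-protein Z-scores over present values within each sample stratum.

    Uses the n-1 (sample) standard deviation. A protein with fewer than two
    present values, or zero variance, within a stratum becomes all-missing
    there: a zero-spread protein carries no ranking information and a fake
    Z of 0 would feed spurious certainty into clustering and classifiers.
    """
    if matrix.scale is not Scale.LOG10:
        raise ValueError("zscore expects a log10-scale matrix")
    out = matrix.values.copy()
    for _, cols in _strata(metadata, matrix.samples, stratum).items():
        block = matrix.values[cols]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        z = block.sub(mean, axis=0).div(sd, axis=0)
        z[sd.isna() | (sd == 0)] = np.nan
        out[cols] = z
    return replace(matrix, values=out, scale=Scale.LOG10)


def group_median_profile(
    zmatrix: IntensityMatrix, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """groups x proteins table of median Z over present values per group."""
    rows = {}
    for name, sample_ids in groups.items():
        if len(sample_ids) == 0:
            raise ValueError(f"group {name!r} is empty")
        rows[name] = zmatrix.values[list(sample_ids)].median(axis=1)
    return pd.DataFrame(rows).T


def cumulative_intensity_fraction(matrix: IntensityMatrix, top_k: int) -> float:
    """Fraction of summed per-protein median intensity held by the top k proteins."""
    if matrix.scale is not Scale.LINEAR:
        raise ValueError("cumulative_intensity_fraction expects linear intensities")
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    medians = matrix.values.median(axis=1).dropna().sort_values(ascending=False)
    total = medians.sum()
    if total == 0 or len(medians) == 0:
        return 0.0
    return float(medians.iloc[: min(top_k, len(medians))].sum() / total)


@dataclass
class CVReport:
    """Per-protein CV summary on the linear intensity scale.

    ``per_protein`` has columns intra_cv and inter_cv (fractions, NaN when
    no candidate triple had >= 2 present values) and optionally
    biological_cv. ``n_below_threshold`` counts proteins whose intra- and
    inter-plate CVs both fall under the threshold.
    """

    per_protein: pd.DataFrame
    cv_threshold: float
    n_intra_below: int
    n_inter_below: int
    n_below_threshold: int


def _candidate_cv(values: np.ndarray) -> float | None:
    """sd/mean over present values of one triple; None if < 2 present."""
    present = values[~np.isnan(values)]
    if present.size < 2:
        return None
    mean = present.mean()
    if mean == 0:
        return None
    return float(present.std(ddof=1) / mean)


def compute_cv_report(
    matrix: IntensityMatrix,
    plate_ids: Mapping[str, str],
    cv_threshold: float = 0.20,
) -> CVReport:
    """CVs over all intra- and inter-plate combinations of three replicates.

    Intra-plate candidates are all 3-subsets of replicates within one plate;
    inter-plate candidates take one replicate from each of three distinct
    plates. Per candidate, CV = sample sd / mean over present values;
    candidates with fewer than two present values are excluded. The
    per-protein CV is the median over candidates.
    """
    if matrix.scale is not Scale.LINEAR:
        raise ValueError("CVs are computed on linear intensities")
    plates: dict[str, list[str]] = {}
    for s in matrix.samples:
        if s not in plate_ids:
            raise ValueError(f"sample {s!r} has no plate assignment")
        plates.setdefault(plate_ids[s], []).append(s)
    if any(len(reps) < 3 for reps in plates.values()):
        raise ValueError("intra-plate CVs need >= 3 replicates per plate")
    if len(plates) < 3:
        raise ValueError("inter-plate CVs need >= 3 plates")

    intra_triples = [
        list(c) for reps in plates.values() for c in itertools.combinations(reps, 3)
    ]
    inter_triples = [
        [a, b, c]
        for p1, p2, p3 in itertools.combinations(sorted(plates), 3)
        for a in plates[p1]
        for b in plates[p2]
        for c in plates[p3]
    ]

    vals = matrix.values
    records = []
    for pid in matrix.protein_ids:
        row = vals.loc[pid]
        intra = [cv for t in intra_triples if (cv := _candidate_cv(row[t].to_numpy())) is not None]
        inter = [cv for t in inter_triples if (cv := _candidate_cv(row[t].to_numpy())) is not None]
        records.append(
            {
                "protein_id": pid,
                "intra_cv": float(np.median(intra)) if intra else np.nan,
                "inter_cv": float(np.median(inter)) if inter else np.nan,
            }
        )
    per_protein = pd.DataFrame(records).set_index("protein_id")
    n_intra = int((per_protein["intra_cv"] < cv_threshold).sum())
    n_inter = int((per_protein["inter_cv"] < cv_threshold).sum())
    n_both = int(
        (
            (per_protein["intra_cv"] < cv_threshold)
            & (per_protein["inter_cv"] < cv_threshold)
        ).sum()
    )
    return CVReport(
        per_protein=per_protein,
        cv_threshold=cv_threshold,
        n_intra_below=n_intra,
        n_inter_below=n_inter,
        n_below_threshold=n_both,
    )


def biological_cv(
    matrix: IntensityMatrix, metadata: Sequence[SampleMeta]
) -> pd.Series:
    """Per-protein biological CV: CV within each cohort, median across cohorts."""
    if matrix.scale is not Scale.LINEAR:
        raise ValueError("CVs are computed on linear intensities")
    cohorts: dict[str, list[str]] = {}
    for m in metadata:
        if m.sample_id in set(matrix.samples):
            cohorts.setdefault(m.cohort, []).append(m.sample_id)
    per_cohort = {}
    for cohort, cols in cohorts.items():
        block = matrix.values[cols]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        cv = sd / mean
        cv[block.notna().sum(axis=1) < 2] = np.nan
        per_cohort[cohort] = cv
    return pd.DataFrame(per_cohort).median(axis=1).rename("biological_cv")
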