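"""Synthetic multi-cohort CSF proteomics studies with known ground truth.

The generator emulates the statistical structure a label-free DIA CSF
study presents to the analysis: three cohorts with fixed group sizes
(29/31, 26/12+16, 33/26+24; 197 samples, 88 AD and 109 non-AD), ~1,500
protein groups whose median log10 intensities span about six orders of
magnitude, abundance-dependent missingness (low-abundance proteins drop
out more often, left-censoring-like), an AD signature of 40 proteins
(35 elevated in AD, 5 reduced; median absolute effect log10(1.3)),
co-regulated protein blocks driven by per-sample latent factors (a
neuronal block and a blood-contamination block), and clinical covariates
coupled to disease status: ELISA t-tau proportional to the designated
tau-like protein's linear intensity, lower Ab1-42 in AD, and MMSE scores
per group in the one cohort that assessed cognition.

Generative model per protein p and sample j:

    log10 I[p, j] = base_p + cohort_offset + status_effect_p
                    + sum_c loading_cp * factor_cj + Normal(0, noise_sd)

with entries set missing with probability logistic((m - log10 I) / s),
so the missing rate decreases with abundance. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log10
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationCatalog,
    AnnotationTerm,
    IntensityMatrix,
    ProteinRecord,
    SampleMeta,
    Scale,
    StudyBundle,
)

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "SignatureEffect",
    "ClusterSpec",
    "ClinicalCoupling",
    "SimulationConfig",
    "GroundTruth",
    "default_study_config",
    "simulate_study",
    "simulate_replicate_plates",
    "signature_term_catalog",
]


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    is_ad: bool
    control_override: bool = False
    age_mean: float = 70.0
    age_sd: float = 8.0
    has_clinical: bool = True
    has_ab40: bool = True
    has_mmse: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group {self.label}: size must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    name: str
    groups: tuple[GroupSpec, ...]


@dataclass(frozen=True)
class SignatureEffect:
    protein_index: int
    effect_log10: float  # signed: positive = elevated in AD

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect_log10):
            raise ValueError("effect sizes must be finite")


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    protein_indices: tuple[int, ...]
    loading: float  # log10 units per unit latent factor


@dataclass
class ClinicalCoupling:
    """How ELISA/cognitive covariates derive from status and intensities.

    t-tau is proportional to the tau-like protein's linear intensity plus
    Gaussian noise sized to reach ``ttau_target_r`` (Pearson, linear
    space). Ab1-42/Ab1-40 and MMSE are drawn per group; ``noise_scale``
    multiplies every clinical noise term (0 gives the noiseless coupling).
    """

    ttau_scale: float = 2.5e-4  # ng/l per linear intensity unit
    ttau_target_r: float = 0.8
    ab42_ad: tuple[float, float] = (450.0, 100.0)  # mean, sd in ng/l
    ab42_ctrl: tuple[float, float] = (800.0, 150.0)
    ab40: tuple[float, float] = (9000.0, 1500.0)
    mmse_ad: tuple[float, float] = (22.7, 4.5)
    mmse_ctrl: tuple[float, float] = (27.7, 1.9)
    noise_scale: float = 1.0


@dataclass
class SimulationConfig:
    cohorts: tuple[CohortSpec, ...]
    n_proteins: int = 1500
    base_abundance: tuple[float, float] = (6.0, 1.2)  # log10 mean, sd
    signature_base: tuple[float, float, float] = (6.5, 0.8, 5.0)  # mean, sd, floor
    sample_noise_sd: float = 0.1
    signature: tuple[SignatureEffect, ...] = ()
    missingness_midpoint: float | None = 4.756  # 15th pctile of base; None = complete
    missingness_slope: float = 0.5
    clusters: tuple[ClusterSpec, ...] = ()
    clinical: ClinicalCoupling = field(default_factory=ClinicalCoupling)
    cohort_offsets: dict[str, float] = field(default_factory=dict)
    mapt_index: int | None = None
    mapt_base_log10: float | None = 6.0  # pinned tau-like abundance
    enforce_rule_labels: bool = True
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.missingness_slope <= 0:
            raise ValueError("missingness slope must be > 0")
        idx = [e.protein_index for e in self.signature]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate protein index in signature")
        if any(i < 0 or i >= self.n_proteins for i in idx):
            raise ValueError("signature protein index out of range")
        for c in self.clusters:
            if any(i < 0 or i >= self.n_proteins for i in c.protein_indices):
                raise ValueError(f"cluster {c.name}: protein index out of range")

    @property
    def n_samples(self) -> int:
        return sum(g.n for c in self.cohorts for g in c.groups)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    status: pd.Series  # sample_id -> bool (True = AD)
    signature: pd.DataFrame  # protein_id, effect_log10, direction
    cluster_members: dict[str, list[str]]
    latent_factors: pd.DataFrame  # samples x clusters
    mapt_protein_id: str | None


def default_study_config(seed: int = 0) -> SimulationConfig:
    """The study conditions: 3 cohorts, 197 samples, 1,500 proteins, 40 effects.

    Group sizes are 29 AD / 31 controls (Sweden-like, no Ab1-40), 26 AD /
    12 + 16 controls (Magdeburg/Kiel-like; the 16 Kiel-like controls are
    young, lack clinical chemistry and carry control_override), and 33 AD /
    26 + 24 controls (Berlin-like, with MMSE). The signature holds 35
    proteins elevated and 5 reduced in AD with median absolute effect
    log10(1.3); the tau-like protein gets the largest effect (0.5 log10,
    ~3.2-fold) and drives simulated ELISA t-tau.
    """
    sweden = CohortSpec(
        "Sweden",
        (
            GroupSpec("AD", 29, True, has_ab40=False),
            GroupSpec("biochemical-control", 31, False, has_ab40=False),
        ),
    )
    magdeburg = CohortSpec(
        "Magdeburg",
        (
            GroupSpec("AD", 26, True),
            GroupSpec("biochemical-control", 12, False),
            GroupSpec(
                "kiel-control",
                16,
                False,
                control_override=True,
                age_mean=32.0,
                age_sd=12.0,
                has_clinical=False,
            ),
        ),
    )
    berlin = CohortSpec(
        "Berlin",
        (
            GroupSpec("AD", 33, True, has_mmse=True),
            GroupSpec("depression-control", 26, False, has_mmse=True),
            GroupSpec("SCI-control", 24, False, has_mmse=True),
        ),
    )

    # 40 effects whose median |effect| is exactly log10(1.3) both as planted
    # and, because the ladder is narrow, among the significant subset the
    # analysis selects. The tau-like protein alone gets 0.50 (~3.2-fold),
    # reproducing tau as the dominant outlier. Five low-ladder proteins
    # point downward (reduced in AD).
    med = log10(1.3)
    low = np.linspace(0.095, med, 20)
    high = np.linspace(med, 0.16, 19)
    magnitudes = np.concatenate([low, high, [0.50]])
    signs = np.ones(40)
    signs[[2, 5, 9, 13, 17]] = -1.0  # the 5 AD-reduced proteins
    signature = tuple(
        SignatureEffect(protein_index=i, effect_log10=float(m * s))
        for i, (m, s) in enumerate(zip(magnitudes, signs))
    )
    mapt_index = 39  # the 0.50-effect protein

    up_idx = [e.protein_index for e in signature if e.effect_log10 > 0]
    clusters = (
        # co-release of neuronal proteins: part of the up-signature plus bystanders
        ClusterSpec("neuronal", tuple(up_idx[:15]) + tuple(range(100, 110)), 0.06),
        # blood contamination of CSF during sampling: non-signature proteins
        ClusterSpec("blood", tuple(range(200, 240)), 0.15),
    )

    return SimulationConfig(
        cohorts=(sweden, magdeburg, berlin),
        n_proteins=1500,
        signature=signature,
        clusters=clusters,
        cohort_offsets={"Sweden": 0.0, "Magdeburg": 0.05, "Berlin": -0.05},
        mapt_index=mapt_index,
        seed=seed,
    )


def _protein_records(config: SimulationConfig) -> list[ProteinRecord]:
    records = []
    for i in range(config.n_proteins):
        gene = "MAPT" if i == config.mapt_index else f"GENE{i:04d}"
        records.append(ProteinRecord(protein_id=f"P{i:05d}", gene_name=gene))
    return records


def simulate_study(
    config: SimulationConfig, seed: int | None = None
) -> tuple[StudyBundle, GroundTruth]:
    """Draw one study bundle plus its ground truth; deterministic given seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_prot, n_samp = config.n_proteins, config.n_samples

    base_mean, base_sd = config.base_abundance
    base = rng.normal(base_mean, base_sd, size=n_prot)
    sig_idx = np.array([e.protein_index for e in config.signature], dtype=int)
    if sig_idx.size:
        m, sd, floor = config.signature_base
        draws = rng.normal(m, sd, size=sig_idx.size)
        while np.any(draws < floor):  # truncate: biomarkers must be quantifiable
            redo = draws < floor
            draws[redo] = rng.normal(m, sd, size=int(redo.sum()))
        base[sig_idx] = draws
    if config.mapt_index is not None and config.mapt_base_log10 is not None:
        base[config.mapt_index] = config.mapt_base_log10

    effects = np.zeros(n_prot)
    for e in config.signature:
        effects[e.protein_index] = e.effect_log10

    # sample bookkeeping
    sample_ids: list[str] = []
    metas: list[SampleMeta] = []
    status = np.zeros(n_samp, dtype=bool)
    cohort_of = np.empty(n_samp, dtype=object)
    j = 0
    cl = config.clinical
    for cohort in config.cohorts:
        for grp in cohort.groups:
            for k in range(grp.n):
                sid = f"{cohort.name}_{grp.label}_{k:02d}"
                sample_ids.append(sid)
                status[j] = grp.is_ad
                cohort_of[j] = cohort.name
                j += 1

    offsets = np.array([config.cohort_offsets.get(c, 0.0) for c in cohort_of])

    factors = rng.normal(size=(n_samp, len(config.clusters)))
    loadings = np.zeros((n_prot, len(config.clusters)))
    for c, spec in enumerate(config.clusters):
        loadings[list(spec.protein_indices), c] = spec.loading

    logi = (
        base[:, None]
        + offsets[None, :]
        + np.outer(effects, status.astype(float))
        + loadings @ factors.T
        + rng.normal(0.0, config.sample_noise_sd, size=(n_prot, n_samp))
    )

    if config.missingness_midpoint is not None:
        p_miss = 1.0 / (
            1.0
            + np.exp(-(config.missingness_midpoint - logi) / config.missingness_slope)
        )
        missing = rng.random(size=logi.shape) < p_miss
    else:
        missing = np.zeros(logi.shape, dtype=bool)

    linear = np.power(10.0, logi)
    linear[missing] = np.nan

    # clinical covariates
    ttau_signal = None
    ttau_noise_sd = 0.0
    if config.mapt_index is not None:
        ttau_signal = cl.ttau_scale * np.power(10.0, logi[config.mapt_index])
        r = cl.ttau_target_r
        ttau_noise_sd = float(np.std(ttau_signal)) * np.sqrt(max(1.0 / r**2 - 1.0, 0.0))

    from .clinical import classify_primary  # deferred: avoids import cycle risk

    j = 0
    for cohort in config.cohorts:
        for grp in cohort.groups:
            for _ in range(grp.n):
                sid = sample_ids[j]
                age = float(np.clip(rng.normal(grp.age_mean, grp.age_sd), 18.0, 95.0))
                sex = "female" if rng.random() < config.female_fraction else "male"
                t_tau = ab42 = ab40 = None
                mmse = None
                if grp.has_clinical:
                    # Enrollment mirrors the study design: biochemical groups
                    # are defined BY the classification rule, so clinical
                    # values are redrawn until the sample satisfies its
                    # group's rule (bounded rejection sampling).
                    signal = float(ttau_signal[j]) if ttau_signal is not None else None
                    for _try in range(100):
                        t_tau = (
                            max(signal + cl.noise_scale * rng.normal(0.0, ttau_noise_sd), 1.0)
                            if signal is not None
                            else None
                        )
                        mu, sd = cl.ab42_ad if grp.is_ad else cl.ab42_ctrl
                        ab42 = float(
                            np.clip(mu + cl.noise_scale * rng.normal(0.0, sd), 1.0, None)
                        )
                        if grp.has_ab40:
                            mu40, sd40 = cl.ab40
                            ab40 = float(
                                np.clip(mu40 + cl.noise_scale * rng.normal(0.0, sd40), 1.0, None)
                            )
                        if not config.enforce_rule_labels or t_tau is None:
                            break
                        probe = SampleMeta(
                            sample_id=sid, cohort=cohort.name,
                            t_tau=t_tau, ab42=ab42, ab40=ab40,
                        )
                        if (classify_primary(probe) == "AD") == grp.is_ad:
                            break
                if grp.has_mmse:
                    mu_m, sd_m = cl.mmse_ad if grp.is_ad else cl.mmse_ctrl
                    mmse = int(np.clip(round(mu_m + cl.noise_scale * rng.normal(0.0, sd_m)), 0, 30))
                metas.append(
                    SampleMeta(
                        sample_id=sid,
                        cohort=cohort.name,
                        group_label=grp.label,
                        age=age,
                        sex=sex,
                        t_tau=t_tau,
                        ab42=ab42,
                        ab40=ab40,
                        mmse=mmse,
                        control_override=grp.control_override,
                    )
                )
                j += 1

    records = _protein_records(config)
    values = pd.DataFrame(
        linear, index=pd.Index([r.protein_id for r in records], name="protein_id"),
        columns=sample_ids,
    )
    matrix = IntensityMatrix(proteins=records, values=values, scale=Scale.LINEAR)
    bundle = StudyBundle(matrix=matrix, metadata=metas)

    pid = [r.protein_id for r in records]
    truth = GroundTruth(
        status=pd.Series(status, index=sample_ids, name="is_ad"),
        signature=pd.DataFrame(
            {
                "protein_id": [pid[e.protein_index] for e in config.signature],
                "effect_log10": [e.effect_log10 for e in config.signature],
                "direction": [int(np.sign(e.effect_log10)) for e in config.signature],
            }
        ).set_index("protein_id"),
        cluster_members={
            c.name: [pid[i] for i in c.protein_indices] for c in config.clusters
        },
        latent_factors=pd.DataFrame(
            factors, index=sample_ids, columns=[c.name for c in config.clusters]
        ),
        mapt_protein_id=pid[config.mapt_index] if config.mapt_index is not None else None,
    )
    return bundle, truth


def simulate_replicate_plates(
    n_replicates_per_plate: int = 5,
    n_plates: int = 3,
    cv_linear: float = 0.10,
    plate_sd_log10: float = 0.01,
    n_proteins: int = 500,
    seed: int = 0,
) -> tuple[IntensityMatrix, dict[str, str]]:
    """Pooled-sample replicate design for CV estimation.

    One pooled profile is replicated with multiplicative lognormal noise of
    fractional sd ``cv_linear`` plus a small per-plate factor (day-to-day
    drift). Returns the matrix and a sample_id -> plate_id mapping.
    """
    if n_replicates_per_plate < 3:
        raise ValueError("need >= 3 replicates per plate")
    if n_plates < 2:
        raise ValueError("need >= 2 plates")
    rng = np.random.default_rng(seed)
    base = rng.normal(6.0, 1.2, size=n_proteins)
    # lognormal sigma giving fractional sd cv_linear on the linear scale
    sigma = np.sqrt(np.log1p(cv_linear**2))
    plate_factor = rng.normal(0.0, plate_sd_log10, size=n_plates)
    cols, plate_ids = [], {}
    data = np.empty((n_proteins, n_plates * n_replicates_per_plate))
    j = 0
    for p in range(n_plates):
        for r in range(n_replicates_per_plate):
            sid = f"plate{p + 1}_rep{r + 1}"
            noise = rng.normal(0.0, sigma, size=n_proteins)
            data[:, j] = np.power(10.0, base + plate_factor[p] + noise / np.log(10))
            cols.append(sid)
            plate_ids[sid] = f"plate{p + 1}"
            j += 1
    records = [ProteinRecord(protein_id=f"P{i:05d}") for i in range(n_proteins)]
    values = pd.DataFrame(
        data, index=pd.Index([r.protein_id for r in records], name="protein_id"),
        columns=cols,
    )
    return IntensityMatrix(proteins=records, values=values, scale=Scale.LINEAR), plate_ids


def signature_term_catalog(
    config: SimulationConfig,
    n_extra_members: int = 15,
    n_random_terms: int = 20,
    seed: int = 0,
) -> AnnotationCatalog:
    """GMT-style catalog with a neuron-projection-like term plus decoys.

    The neuron-projection-like term covers every AD-elevated signature
    protein plus ``n_extra_members`` bystanders, mirroring how neuronal
    annotation terms capture the AD CSF signature. Random decoy terms give
    the enrichment's multiple-testing correction something to correct.
    """
    rng = np.random.default_rng(seed)
    pid = [r.protein_id for r in _protein_records(config)]
    up = [pid[e.protein_index] for e in config.signature if e.effect_log10 > 0]
    non_sig = [
        p
        for i, p in enumerate(pid)
        if i not in {e.protein_index for e in config.signature}
    ]
    extras = list(rng.choice(non_sig, size=n_extra_members, replace=False))
    terms = {
        "GOCC_NEURON_PROJECTION_LIKE": AnnotationTerm(
            term_id="GOCC_NEURON_PROJECTION_LIKE",
            category="GOCC",
            description="synthetic neuronal term covering the AD-elevated signature",
            members=frozenset(up + extras),
        )
    }
    for t in range(n_random_terms):
        size = int(rng.integers(10, 61))
        members = frozenset(rng.choice(pid, size=size, replace=False))
        tid = f"GOBP_RANDOM_{t:02d}"
        terms[tid] = AnnotationTerm(
            term_id=tid, category="GOBP", description="synthetic decoy term",
            members=members,
        )
    return AnnotationCatalog(terms=terms)
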