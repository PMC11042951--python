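"""Synthetic bulk-RNA-seq cohorts with known stemness ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline can be exercised and validated
without any external download:

* log-normal TPM-like expression (``exp`` of Gaussian log-abundance),
  which guarantees non-negative values;
* a training cohort in which a subset of *signature genes* is shifted up
  (on the log scale) in pluripotent-labeled samples relative to
  differentiated-progenitor samples;
* a multi-tissue cohort in which each sample carries a latent stemness
  level that declines (or rises) linearly with the age-bin midpoint and
  responds to sex, region and death-code covariates;
* a proliferation marker gene (``MKI67``) and a proliferation gene set
  positively coupled, and a senescence gene set negatively coupled, to the
  latent stemness;
* a shared subject pool with a per-subject latent factor, so the same
  subject appears in several tissues and cross-tissue correlation
  structure exists by construction.

Randomness is governed by a single integer seed expanded into independent
substreams (gene baselines, subject pool, one stream per tissue, training
cohort) keyed by stable CRC32 hashes, so adding or removing a tissue does
not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    SAMPLE_TABLE_COLUMNS,
    GeneSet,
    age_bin_to_midpoint,
    AGE_BIN_MIDPOINTS,
)

__all__ = [
    "TissueSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_tissue_panel",
    "simulate_training_cohort",
    "simulate_cohort",
]

_HARDY_LEVELS = ("hardy_0", "hardy_1", "hardy_2", "hardy_3", "hardy_4")
_AGE_BINS = tuple(AGE_BIN_MIDPOINTS)
_MEAN_AGE = 50.0  # centre of the 25..75 midpoint range


@dataclass(frozen=True)
class TissueSpec:
    """Ground-truth description of one simulated tissue.

    ``beta_age`` is the latent-stemness change per year of age (the
    generative analogue of the age coefficient the covariate model
    estimates).  ``shared_factor_loading`` couples the tissue to the
    per-subject latent factor and thereby creates cross-tissue
    correlation; a loading of 0 gives a tissue whose stemness is
    unrelated to the rest of the body (a "brain-like" tissue).
    ``has_sex=False`` restricts the tissue to female subjects (a sex
    organ), so sex is a single-level covariate there.
    """

    name: str
    n_samples: int = 300
    beta_age: float = -0.02
    has_sex: bool = True
    n_regions: int = 1
    sex_effect: float = 0.2
    region_effects: tuple[float, ...] = ()
    shared_factor_loading: float = 0.6

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"tissue {self.name!r}: n_samples must be >= 2")
        if self.n_regions < 1:
            raise ValueError(f"tissue {self.name!r}: n_regions must be >= 1")
        if self.region_effects and len(self.region_effects) != self.n_regions:
            raise ValueError(
                f"tissue {self.name!r}: region_effects length must equal n_regions"
            )


def default_tissue_panel() -> tuple[TissueSpec, ...]:
    """The default 10-tissue study panel.

    Eight tissues lose latent stemness with age at -0.02/yr (one of them,
    ``brain_like``, has zero shared-factor loading), one single-sex
    ``uterus_like`` tissue gains stemness with age, and one ``null_like``
    tissue has no age effect at all.
    """
    negative = [
        TissueSpec("adipose_like"),
        TissueSpec("artery_like"),
        TissueSpec("brain_like", shared_factor_loading=0.0),
        TissueSpec("colon_like"),
        TissueSpec(
            "esophagus_like", n_regions=3, region_effects=(0.0, 0.15, 0.3)
        ),
        TissueSpec("heart_like", n_regions=2, region_effects=(0.0, 0.2)),
        TissueSpec("lung_like"),
        TissueSpec("skin_like"),
    ]
    positive = TissueSpec("uterus_like", beta_age=0.02, has_sex=False)
    null = TissueSpec("null_like", beta_age=0.0)
    return (*negative, positive, null)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with the study-condition defaults."""

    n_genes: int = 1200
    n_signature_genes: int = 100
    n_prolif_genes: int = 50
    n_senesc_genes: int = 50
    n_stem_train: int = 50
    n_diff_train: int = 100
    tissues: tuple[TissueSpec, ...] = field(default_factory=default_tissue_panel)
    seed: int = 0
    noise_sd: float = 0.3          # gene-level log-scale noise
    signature_effect: float = 1.5  # log-scale shift of signature genes per unit latent
    coupling_prolif: float = 0.5   # log-scale slope of proliferation genes on latent
    coupling_senesc: float = -0.5  # log-scale slope of senescence genes on latent
    n_subjects: int = 450
    residual_sd: float = 0.8       # latent-stemness residual s.d.
    base_mean: float = 2.0         # mean log baseline abundance
    base_sd: float = 1.0           # s.d. of log baseline abundance across genes
    sex_age_confound: float = 0.0  # slope of P(male) on (age-50)/50 in the pool

    def __post_init__(self) -> None:
        reserved = self.n_signature_genes + self.n_prolif_genes + self.n_senesc_genes
        if reserved >= self.n_genes:
            raise ValueError("signature + proliferation + senescence sets must leave background genes")
        if min(self.n_signature_genes, self.n_stem_train, self.n_diff_train) < 2:
            raise ValueError("all counts must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("tissue names must be unique")


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters and latent variables behind a cohort."""

    beta_age: dict[str, float]
    signature_genes: tuple[str, ...]
    proliferation_genes: tuple[str, ...]
    senescence_genes: tuple[str, ...]
    latent: pd.Series            # per-sample latent stemness
    subject_factor: pd.Series    # per-subject shared factor

    def gene_sets(self) -> list[GeneSet]:
        return [
            GeneSet("signature", frozenset(self.signature_genes), "simulated stemness signature"),
            GeneSet("proliferation", frozenset(self.proliferation_genes), "simulated proliferation set"),
            GeneSet("senescence", frozenset(self.senescence_genes), "simulated senescence set"),
        ]


def _substream(seed: int, *keys: object) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode("utf-8")) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _gene_universe(cfg: SimulationConfig) -> tuple[list[str], dict[str, np.ndarray]]:
    """Gene ids plus boolean masks for the three functional sets.

    The first proliferation gene is named ``MKI67`` so the marker-gene
    path is exercised by name, as it would be on real data.
    """
    ids = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    n_sig, n_pro, n_sen = (
        cfg.n_signature_genes,
        cfg.n_prolif_genes,
        cfg.n_senesc_genes,
    )
    ids[n_sig] = "MKI67"
    masks = {
        "signature": np.zeros(cfg.n_genes, dtype=bool),
        "proliferation": np.zeros(cfg.n_genes, dtype=bool),
        "senescence": np.zeros(cfg.n_genes, dtype=bool),
    }
    masks["signature"][:n_sig] = True
    masks["proliferation"][n_sig : n_sig + n_pro] = True
    masks["senescence"][n_sig + n_pro : n_sig + n_pro + n_sen] = True
    return ids, masks


def _base_levels(cfg: SimulationConfig, seed: int) -> np.ndarray:
    rng = _substream(seed, "genes")
    return rng.normal(cfg.base_mean, cfg.base_sd, size=cfg.n_genes)


def simulate_training_cohort(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a signature-training cohort.

    Returns an expression matrix (genes x samples) containing
    ``n_stem_train`` pluripotent-labeled samples and ``n_diff_train``
    differentiated-progenitor samples, plus a boolean per-sample label
    marking the pluripotent ones.  Signature genes are shifted up by
    ``signature_effect`` on the log scale in the pluripotent samples
    only, so after mean-centering across the whole cohort the
    pluripotent class has a positive mean on exactly those genes — the
    structure one-class training exploits.
    """
    seed = cfg.seed if seed is None else seed
    ids, masks = _gene_universe(cfg)
    base = _base_levels(cfg, seed)
    rng = _substream(seed, "train")

    n_total = cfg.n_stem_train + cfg.n_diff_train
    stem = np.zeros(n_total, dtype=bool)
    stem[: cfg.n_stem_train] = True
    sample_ids = [
        f"stem_{i:04d}" if s else f"diff_{i - cfg.n_stem_train:04d}"
        for i, s in enumerate(stem)
    ]

    log_x = base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_total))
    log_x += cfg.signature_effect * np.outer(masks["signature"], stem.astype(float))
    X = pd.DataFrame(np.exp(log_x), index=pd.Index(ids, name="gene_id"), columns=sample_ids)
    labels = pd.Series(stem, index=sample_ids, name="is_stem")
    return X, labels


def _subject_pool(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    rng = _substream(seed, "subjects")
    n = cfg.n_subjects
    bins = rng.choice(len(_AGE_BINS), size=n)
    age_bin = np.array(_AGE_BINS)[bins]
    age_years = np.array([age_bin_to_midpoint(b) for b in age_bin])
    p_male = np.clip(
        0.5 + cfg.sex_age_confound * (age_years - _MEAN_AGE) / 50.0, 0.05, 0.95
    )
    sex = np.where(rng.random(n) < p_male, "male", "female")
    death = rng.choice(_HARDY_LEVELS, size=n)
    factor = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"SUBJ-{i:04d}" for i in range(n)],
            "age_bin": age_bin,
            "age_years": age_years,
            "sex": sex,
            "death": death,
            "factor": factor,
        }
    ).set_index("subject_id")


def simulate_cohort(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a multi-tissue cohort over a shared subject pool.

    Per tissue ``t`` and sample ``j`` of subject ``s``, the latent
    stemness is

    ``l = beta_age_t * (age_s - 50) + sex_effect_t * [male]
    + region_effect + loading_t * u_s + N(0, residual_sd)``

    with ``u_s`` the shared subject factor.  Log expression of gene ``g``
    is ``base_g + slope_g * l + N(0, noise_sd)`` where ``slope_g`` is
    ``signature_effect`` on signature genes, ``coupling_prolif`` on
    proliferation genes (including MKI67), ``coupling_senesc`` on
    senescence genes and 0 on background genes; TPM-like values are its
    exponential.

    Returns ``(expression, sample_table, ground_truth)``.
    """
    seed = cfg.seed if seed is None else seed
    ids, masks = _gene_universe(cfg)
    base = _base_levels(cfg, seed)
    pool = _subject_pool(cfg, seed)

    slope = (
        cfg.signature_effect * masks["signature"]
        + cfg.coupling_prolif * masks["proliferation"]
        + cfg.coupling_senesc * masks["senescence"]
    )

    blocks: list[pd.DataFrame] = []
    rows: list[dict[str, object]] = []
    latents: dict[str, float] = {}

    for spec in cfg.tissues:
        rng = _substream(seed, "tissue", spec.name)
        eligible = pool if spec.has_sex else pool[pool["sex"] == "female"]
        picked = eligible.index.to_numpy()[
            rng.integers(0, len(eligible), size=spec.n_samples)
        ]
        sub = pool.loc[picked]

        region_idx = rng.integers(0, spec.n_regions, size=spec.n_samples)
        region_effects = (
            np.asarray(spec.region_effects)
            if spec.region_effects
            else np.zeros(spec.n_regions)
        )

        latent = (
            spec.beta_age * (sub["age_years"].to_numpy() - _MEAN_AGE)
            + spec.sex_effect * (sub["sex"].to_numpy() == "male")
            + region_effects[region_idx]
            + spec.shared_factor_loading * sub["factor"].to_numpy()
            + rng.normal(0.0, cfg.residual_sd, size=spec.n_samples)
        )

        sample_ids = [f"{spec.name}-s{i:04d}" for i in range(spec.n_samples)]
        log_x = (
            base[:, None]
            + np.outer(slope, latent)
            + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, spec.n_samples))
        )
        blocks.append(
            pd.DataFrame(np.exp(log_x), index=pd.Index(ids, name="gene_id"), columns=sample_ids)
        )
        for k, sid in enumerate(sample_ids):
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": picked[k],
                    "tissue": spec.name,
                    "region": f"{spec.name} - region {region_idx[k]}",
                    "age_bin": sub["age_bin"].iloc[k],
                    "age_years": float(sub["age_years"].iloc[k]),
                    "sex": "female" if not spec.has_sex else sub["sex"].iloc[k],
                    "death": sub["death"].iloc[k],
                }
            )
            latents[sid] = float(latent[k])

    expression = pd.concat(blocks, axis=1)
    table = pd.DataFrame(rows, columns=list(SAMPLE_TABLE_COLUMNS))
    for col in ("age_bin", "sex", "death", "region"):
        table[col] = table[col].astype("string")

    truth = GroundTruth(
        beta_age={t.name: t.beta_age for t in cfg.tissues},
        signature_genes=tuple(np.array(ids)[masks["signature"]]),
        proliferation_genes=tuple(np.array(ids)[masks["proliferation"]]),
        senescence_genes=tuple(np.array(ids)[masks["senescence"]]),
        latent=pd.Series(latents, name="latent_stemness"),
        subject_factor=pool["factor"].copy(),
    )
    return expression, table, truth
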