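"""Synthetic ependymoma cohort generator.

Emulates the statistical structure a methylation-based survival analysis
assumes: ten molecular types in realistic proportions, type-specific CpG
signatures on a beta-value matrix, a platform batch shift on a CpG subset,
type-dependent exponential event hazards modified multiplicatively by
covariate hazard ratios (1q gain, 6q loss, combined CDKN2A/B loss, subtotal
resection, male sex), and independent uniform censoring.

The exponential law is calibrated from a single survivor fraction per type:
lambda_type = -ln(S60) / 60 per month, so the baseline five-year PFS of a
covariate-free sample is exactly the configured fraction. Subtype labels
carry their own multiplicative hazard modifiers so that subtype-resolved
survival is strictly more informative than type-level survival.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv import AUTOSOMAL_ARMS, CNVProfile
from .preprocess import EPIC, FOUR50K, BetaMatrix
from .survival import NED, RELAPSE, SurvivalRecord, binarize_at_horizon


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


# Molecular-type mix of a large retrospective ependymoma cohort (n = 2023).
_TYPE_COUNTS = {
    "EPN-PFA": 969,
    "EPN-PFB": 308,
    "EPN-ZFTA": 228,
    "MPE": 181,
    "SP-EPN": 143,
    "PF-SE": 119,
    "ST-SE": 26,
    "EPN-MYCN": 17,
    "EPN-YAP": 17,
    "SP-SE": 15,
}
DEFAULT_TYPE_PROPORTIONS = {t: c / 2023 for t, c in _TYPE_COUNTS.items()}

# Five-year progression-free survival fractions per molecular type. The
# EPN-MYCN value follows from its median PFS of 31 months under the
# exponential law (2^(-60/31)); EPN-YAP, ST-SE and SP-SE are set to values
# typical for indolent entities (see docs/methods.md).
DEFAULT_FIVE_YEAR_PFS = {
    "EPN-PFA": 0.42,
    "EPN-PFB": 0.77,
    "EPN-ZFTA": 0.48,
    "MPE": 0.68,
    "SP-EPN": 0.84,
    "PF-SE": 0.82,
    "ST-SE": 0.90,
    "EPN-MYCN": 2 ** (-60 / 31),
    "EPN-YAP": 0.80,
    "SP-SE": 0.90,
}

# Ten-year overall survival fractions used for the OS endpoint.
DEFAULT_TEN_YEAR_OS = {
    "EPN-PFA": 0.56,
    "EPN-PFB": 0.86,
    "EPN-ZFTA": 0.62,
    "MPE": 0.95,
    "SP-EPN": 0.95,
    "PF-SE": 0.95,
    "ST-SE": 0.95,
    "EPN-MYCN": 0.32,
    "EPN-YAP": 0.90,
    "SP-SE": 0.95,
}

# Proportional effects on the event hazard. The CNV ratios reproduce the
# direction and rough magnitude implied by printed stratum survivor
# fractions (e.g. 5-y PFS 49% balanced vs 28%/26%/10% for 1q/6q/combined).
DEFAULT_HAZARD_RATIOS = {
    "gain_1q": 1.8,
    "loss_6q": 1.9,
    "cdkn2ab_loss": 2.0,
    "resection_str": 1.5,
    "sex_male": 1.2,
}

# Subtype labels per type with within-type fractions and hazard modifiers
# (geometric mean ~1 so the type-level survivor fraction stays calibrated).
DEFAULT_SUBTYPES: dict[str, list[tuple[str, float, float]]] = {
    "EPN-PFA": [
        ("PFA-1a", 0.15, 0.70), ("PFA-1b", 0.13, 0.85), ("PFA-1c", 0.14, 1.90),
        ("PFA-1d", 0.09, 1.00), ("PFA-1e", 0.12, 0.80), ("PFA-1f", 0.06, 1.20),
        ("PFA-2a", 0.15, 1.00), ("PFA-2b", 0.13, 0.90), ("PFA-2c", 0.03, 1.30),
    ],
    "EPN-PFB": [
        ("PFB-1", 0.39, 0.80), ("PFB-2", 0.17, 1.00), ("PFB-3", 0.23, 1.10),
        ("PFB-4", 0.15, 1.40), ("PFB-5", 0.06, 0.90),
    ],
    "EPN-ZFTA": [
        ("ZFTA-RELA-A", 0.87, 1.00), ("ZFTA-RELA-B", 0.02, 1.30),
        ("ZFTA-FUS-C", 0.07, 0.70), ("ZFTA-FUS-D", 0.02, 1.10),
        ("ZFTA-FUS-E", 0.02, 0.80),
    ],
    "MPE": [("MPE-A", 0.37, 1.40), ("MPE-B", 0.63, 0.80)],
    "SP-SE": [("SP-SE-A", 0.80, 1.00), ("SP-SE-B", 0.20, 1.00)],
}

# 1q/6q category probabilities (balanced, 1q only, 6q only, combined).
_PFA_1Q6Q_PROBS = (0.7399, 0.1527, 0.0599, 0.0475)
_BACKGROUND_1Q6Q_PROBS = (0.93, 0.04, 0.02, 0.01)
# CDKN2A/B category probabilities (flat, combined, 2B only, 2A only).
_ZFTA_CDKN_PROBS = (0.62, 0.25, 0.10, 0.03)
_BACKGROUND_CDKN_PROBS = (0.95, 0.02, 0.02, 0.01)

_BETA_CONCENTRATION = 30.0  # beta-distribution concentration around CpG means


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    Sizes default to a desk-scale cohort; proportions, survivor fractions
    and hazard ratios default to the study conditions documented in
    docs/methods.md.
    """

    n_samples: int = 500
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    five_year_pfs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIVE_YEAR_PFS)
    )
    ten_year_os: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEN_YEAR_OS)
    )
    covariate_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_RATIOS)
    )
    subtypes: dict[str, list[tuple[str, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SUBTYPES.items()}
    )
    n_cpgs: int = 2000
    n_informative: int = 400
    n_batch_cpgs: int = 100
    batch_shift: float = 0.3
    epic_fraction: float = 0.3
    censor_max_months: float = 240.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"type_proportions must sum to 1, got {total!r}"
            )
        for t in self.type_proportions:
            s = self.five_year_pfs.get(t)
            if s is None or not (0 < s <= 1):
                raise ConfigurationError(
                    f"five_year_pfs[{t!r}] must be in (0, 1], got {s!r}"
                )
            s_os = self.ten_year_os.get(t)
            if s_os is None or not (0 < s_os <= 1):
                raise ConfigurationError(
                    f"ten_year_os[{t!r}] must be in (0, 1], got {s_os!r}"
                )
        for name, hr in self.covariate_hazard_ratios.items():
            if not hr > 0:
                raise ConfigurationError(f"hazard ratio {name!r} must be > 0")
        if self.n_informative + self.n_batch_cpgs > self.n_cpgs:
            raise ConfigurationError(
                "n_informative + n_batch_cpgs must not exceed n_cpgs"
            )
        if not (0 < self.batch_shift < 1):
            raise ConfigurationError("batch_shift must be in (0, 1)")
        if not (0 <= self.epic_fraction <= 1):
            raise ConfigurationError("epic_fraction must be in [0, 1]")
        if not self.censor_max_months > 0:
            raise ConfigurationError("censor_max_months must be positive")


@dataclass
class SimulatedCohort:
    """All tables share one identical sample-id ordering."""

    beta: BetaMatrix
    annotations: pd.DataFrame
    cnv: dict[str, CNVProfile]
    pfs: dict[str, SurvivalRecord]
    os: dict[str, SurvivalRecord]
    truth: dict
    config: CohortConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.annotations["sample_id"])


def _rate_per_month(survivor_fraction: float, horizon: float) -> float:
    return -math.log(survivor_fraction) / horizon


def _draw_beta_values(rng: np.random.Generator, means: np.ndarray) -> np.ndarray:
    """Unimodal draws on (0,1) around per-cell means via a beta distribution."""
    m = np.clip(means, 0.02, 0.98)
    a = m * _BETA_CONCENTRATION
    b = (1.0 - m) * _BETA_CONCENTRATION
    return rng.beta(a, b)


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> SimulatedCohort:
    """Generate a cohort; identical config and seed give identical output.

    One global seed streams to named sub-generators (types, clinical, cnv,
    beta, survival, censoring) so each component is independently
    reproducible.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    streams = {
        name: np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), i])))
        for i, name in enumerate(
            ["types", "clinical", "cnv", "beta", "survival", "censoring"]
        )
    }
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    types = sorted(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types])
    type_of = streams["types"].choice(types, size=n, p=probs / probs.sum())

    subtype_of = np.empty(n, dtype=object)
    subtype_hazard = np.ones(n)
    for i, t in enumerate(type_of):
        defs = config.subtypes.get(t)
        if defs:
            names = [d[0] for d in defs]
            fracs = np.array([d[1] for d in defs], dtype=float)
            j = streams["types"].choice(len(defs), p=fracs / fracs.sum())
            subtype_of[i] = names[j]
            subtype_hazard[i] = defs[j][2]
        else:
            subtype_of[i] = t

    clin = streams["clinical"]
    age_group = clin.choice(["<4", "4-18", ">18"], size=n, p=[0.35, 0.31, 0.34])
    age_years = np.where(
        age_group == "<4",
        clin.uniform(0, 4, n),
        np.where(age_group == "4-18", clin.uniform(4, 18, n), clin.uniform(18, 80, n)),
    ).round(1)
    sex = clin.choice(["male", "female"], size=n, p=[0.58, 0.42])
    resection = clin.choice(["GTR", "STR"], size=n, p=[0.64, 0.36])
    loc_map = {
        "EPN-PFA": "posterior_fossa", "EPN-PFB": "posterior_fossa",
        "PF-SE": "posterior_fossa", "EPN-ZFTA": "supratentorial",
        "EPN-YAP": "supratentorial", "ST-SE": "supratentorial",
        "SP-EPN": "spinal", "MPE": "spinal", "EPN-MYCN": "spinal",
        "SP-SE": "spinal",
    }
    localization = np.array([loc_map.get(t, "posterior_fossa") for t in type_of])

    cnv_rng = streams["cnv"]
    cnv: dict[str, CNVProfile] = {}
    gain_1q = np.zeros(n, dtype=int)
    loss_6q = np.zeros(n, dtype=int)
    cdkn2a_loss = np.zeros(n, dtype=int)
    cdkn2b_loss = np.zeros(n, dtype=int)
    for i, sid in enumerate(sample_ids):
        arm_vals = {a: float(cnv_rng.uniform(-0.08, 0.08)) for a in AUTOSOMAL_ARMS}
        p1q6q = _PFA_1Q6Q_PROBS if type_of[i] == "EPN-PFA" else _BACKGROUND_1Q6Q_PROBS
        cat = cnv_rng.choice(4, p=p1q6q)
        if cat in (1, 3):
            arm_vals["1q"] = float(cnv_rng.uniform(0.25, 0.8))
            gain_1q[i] = 1
        if cat in (2, 3):
            arm_vals["6q"] = float(-cnv_rng.uniform(0.25, 0.8))
            loss_6q[i] = 1
        pc = _ZFTA_CDKN_PROBS if type_of[i] == "EPN-ZFTA" else _BACKGROUND_CDKN_PROBS
        ccat = cnv_rng.choice(4, p=pc)
        gene_vals = {
            "CDKN2A": float(cnv_rng.uniform(-0.2, 0.2)),
            "CDKN2B": float(cnv_rng.uniform(-0.2, 0.2)),
        }
        if ccat in (1, 3):  # combined or 2A-only
            gene_vals["CDKN2A"] = float(-cnv_rng.uniform(0.5, 1.2))
            cdkn2a_loss[i] = 1
        if ccat in (1, 2):  # combined or 2B-only
            gene_vals["CDKN2B"] = float(-cnv_rng.uniform(0.5, 1.2))
            cdkn2b_loss[i] = 1
        cnv[sid] = CNVProfile(arm_values=arm_vals, gene_values=gene_vals)

    # --- beta matrix ---
    beta_rng = streams["beta"]
    cpg_ids = [f"cg{i:07d}" for i in range(config.n_cpgs)]
    perm = beta_rng.permutation(config.n_cpgs)
    per_type = config.n_informative // len(types)
    informative_ids: dict[str, list[str]] = {}
    pos = 0
    for t in types:
        informative_ids[t] = [cpg_ids[j] for j in perm[pos : pos + per_type]]
        pos += per_type
    n_inf_used = pos
    batch_idx = perm[n_inf_used : n_inf_used + config.n_batch_cpgs]
    batch_ids = [cpg_ids[j] for j in batch_idx]

    baseline = beta_rng.uniform(0.15, 0.85, size=config.n_cpgs)
    # batch-affected probes live in the unsaturated range so the platform
    # shift is not erased by clipping at 1 (the generator's contract is a
    # mean platform difference of ~batch_shift on these probes)
    if batch_idx.size:
        baseline[batch_idx] = beta_rng.uniform(
            0.15, max(0.2, 0.9 - config.batch_shift), size=batch_idx.size
        )
    means = np.tile(baseline, (n, 1))
    col_of = {c: j for j, c in enumerate(cpg_ids)}
    for t in types:
        type_means = beta_rng.uniform(0.15, 0.85, size=per_type)
        rows = np.flatnonzero(type_of == t)
        cols = np.array([col_of[c] for c in informative_ids[t]], dtype=int)
        if rows.size and cols.size:
            means[np.ix_(rows, cols)] = type_means
    values = _draw_beta_values(beta_rng, means)

    platform = np.where(
        streams["clinical"].uniform(size=n) < config.epic_fraction, EPIC, FOUR50K
    )
    epic_rows = np.flatnonzero(platform == EPIC)
    shifted = values[np.ix_(epic_rows, batch_idx)] + config.batch_shift
    n_clipped = int((shifted > 1.0).sum())
    values[np.ix_(epic_rows, batch_idx)] = np.clip(shifted, 0.0, 1.0)

    beta = BetaMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=cpg_ids),
        platform=pd.Series(platform, index=sample_ids, name="platform"),
    )

    # --- survival ---
    surv_rng = streams["survival"]
    cens_rng = streams["censoring"]
    hr = config.covariate_hazard_ratios
    covariate_product = np.ones(n)
    covariate_product *= np.where(gain_1q == 1, hr.get("gain_1q", 1.0), 1.0)
    covariate_product *= np.where(loss_6q == 1, hr.get("loss_6q", 1.0), 1.0)
    combined_cdkn = (cdkn2a_loss == 1) & (cdkn2b_loss == 1)
    covariate_product *= np.where(combined_cdkn, hr.get("cdkn2ab_loss", 1.0), 1.0)
    covariate_product *= np.where(resection == "STR", hr.get("resection_str", 1.0), 1.0)
    covariate_product *= np.where(sex == "male", hr.get("sex_male", 1.0), 1.0)

    lam_pfs = np.array(
        [_rate_per_month(config.five_year_pfs[t], 60.0) for t in type_of]
    )
    lam_os = np.array(
        [_rate_per_month(config.ten_year_os[t], 120.0) for t in type_of]
    )
    hazard_pfs = lam_pfs * subtype_hazard * covariate_product
    hazard_os = lam_os * subtype_hazard * covariate_product

    pfs: dict[str, SurvivalRecord] = {}
    os_rec: dict[str, SurvivalRecord] = {}
    true_hazard = {}
    for i, sid in enumerate(sample_ids):
        c_pfs = cens_rng.uniform(0.0, config.censor_max_months)
        c_os = cens_rng.uniform(0.0, config.censor_max_months)
        if hazard_pfs[i] > 0:
            e_pfs = surv_rng.exponential(1.0 / hazard_pfs[i])
        else:
            e_pfs = math.inf
        if hazard_os[i] > 0:
            e_os = surv_rng.exponential(1.0 / hazard_os[i])
        else:
            e_os = math.inf
        t_pfs = max(min(e_pfs, c_pfs), 1e-6)
        t_os = max(min(e_os, c_os), 1e-6)
        pfs[sid] = SurvivalRecord(t_pfs, int(e_pfs <= c_pfs), "PFS")
        os_rec[sid] = SurvivalRecord(t_os, int(e_os <= c_os), "OS")
        true_hazard[sid] = float(hazard_pfs[i])

    annotations = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "platform": platform,
            "age_years": age_years,
            "age_group": age_group,
            "sex": sex,
            "localization": localization,
            "resection": resection,
            "molecular_type": type_of,
            "molecular_subtype": subtype_of,
            "gain_1q": gain_1q,
            "loss_6q": loss_6q,
            "cdkn2a_loss": cdkn2a_loss,
            "cdkn2b_loss": cdkn2b_loss,
            "detection_p": streams["clinical"].uniform(0.001, 0.04, n).round(4),
            "pfs_months": [pfs[s].time_months for s in sample_ids],
            "pfs_event": [pfs[s].event for s in sample_ids],
            "os_months": [os_rec[s].time_months for s in sample_ids],
            "os_event": [os_rec[s].event for s in sample_ids],
        }
    )

    truth = {
        "true_type": {s: str(t) for s, t in zip(sample_ids, type_of)},
        "true_subtype": {s: str(t) for s, t in zip(sample_ids, subtype_of)},
        "true_hazard_pfs": true_hazard,
        "informative_cpg_ids": informative_ids,
        "batch_cpg_ids": batch_ids,
        "n_beta_clipped": n_clipped,
        "seed": int(seed),
    }
    return SimulatedCohort(
        beta=beta, annotations=annotations, cnv=cnv, pfs=pfs, os=os_rec,
        truth=truth, config=config,
    )


def inject_known_signal(
    cohort: SimulatedCohort,
    effect: float,
    n_signal_cpgs: int = 50,
    horizon: float = 60.0,
) -> SimulatedCohort:
    """Shift a designated CpG block between eventual-relapse and eventual-NED
    samples by ``effect`` (half up, half down), recording the block in truth.

    The block is chosen from background CpGs (neither type-informative nor
    batch-shifted) so the injected signal is the only outcome-linked content
    there. ``effect = 0`` is the identity; samples with indeterminate outcome
    at the horizon are left untouched.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if effect > 1:
        raise ValueError("effect must be <= 1 (beta values live in [0,1])")
    reserved = set(cohort.truth["batch_cpg_ids"])
    for ids in cohort.truth["informative_cpg_ids"].values():
        reserved.update(ids)
    background = [c for c in cohort.beta.cpg_ids if c not in reserved]
    if len(background) < n_signal_cpgs:
        raise ValueError("not enough background CpGs for the signal block")
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence([int(cohort.truth["seed"]), 997]))
    )
    block = sorted(rng.choice(background, size=n_signal_cpgs, replace=False))

    statuses = {
        s: binarize_at_horizon(cohort.pfs[s], horizon).status
        for s in cohort.sample_ids
    }
    values = cohort.beta.values.copy()
    if effect > 0:
        relapse_rows = [s for s, st in statuses.items() if st == RELAPSE]
        ned_rows = [s for s, st in statuses.items() if st == NED]
        values.loc[relapse_rows, block] = np.clip(
            values.loc[relapse_rows, block] + effect / 2, 0.0, 1.0
        )
        values.loc[ned_rows, block] = np.clip(
            values.loc[ned_rows, block] - effect / 2, 0.0, 1.0
        )
    truth = dict(cohort.truth)
    truth["signal_cpg_ids"] = list(block)
    truth["signal_effect"] = float(effect)
    return SimulatedCohort(
        beta=BetaMatrix(values=values, platform=cohort.beta.platform.copy()),
        annotations=cohort.annotations,
        cnv=cohort.cnv,
        pfs=cohort.pfs,
        os=cohort.os,
        truth=truth,
        config=cohort.config,
    )


# --- on-disk formats -------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, out_dir) -> None:
    """Write beta matrix (gzip TSV, rows = CpGs), sample sheet TSV, CNV long
    TSV and truth JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.beta.values.T.to_csv(
        out / "beta.tsv.gz", sep="\t", index_label="cpg_id", compression="gzip"
    )
    cohort.annotations.to_csv(out / "samples.tsv", sep="\t", index=False)
    rows = []
    for sid in cohort.sample_ids:
        prof = cohort.cnv[sid]
        for feat, lr in list(prof.arm_values.items()) + list(prof.gene_values.items()):
            rows.append({"sample_id": sid, "feature": feat, "log_ratio": lr})
    pd.DataFrame(rows).to_csv(out / "cnv.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)


def read_cohort(in_dir) -> SimulatedCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    from .cnv import profiles_from_table

    in_dir = Path(in_dir)
    beta_df = pd.read_csv(in_dir / "beta.tsv.gz", sep="\t", index_col="cpg_id").T
    ann = pd.read_csv(in_dir / "samples.tsv", sep="\t")
    ann["sample_id"] = ann["sample_id"].astype(str)
    beta_df.index = beta_df.index.astype(str)
    platform = pd.Series(
        ann["platform"].to_numpy(), index=ann["sample_id"], name="platform"
    )
    beta = BetaMatrix(values=beta_df.loc[ann["sample_id"]], platform=platform)
    cnv_tab = pd.read_csv(in_dir / "cnv.tsv", sep="\t")
    cnv = profiles_from_table(cnv_tab)
    pfs = {
        r.sample_id: SurvivalRecord(r.pfs_months, int(r.pfs_event), "PFS")
        for r in ann.itertuples()
    }
    os_rec = {
        r.sample_id: SurvivalRecord(r.os_months, int(r.os_event), "OS")
        for r in ann.itertuples()
    }
    with open(in_dir / "truth.json") as fh:
        truth = json.load(fh)
    return SimulatedCohort(
        beta=beta, annotations=ann, cnv=cnv, pfs=pfs, os=os_rec, truth=truth,
        config=CohortConfig(n_samples=len(ann), seed=truth.get("seed", 0)),
    )
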