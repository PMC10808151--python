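"""Arm-level and focal copy-number calling from log-ratio summaries.

Input is one summarized log-ratio per autosomal chromosome arm (44 arms,
1p..22q) and per gene of interest (at minimum
CDKN2A and CDKN2B). Calls use fixed symmetric thresholds: 0.1 for arms and
0.4 for focal events, with strict inequalities so a value exactly at the
threshold stays BALANCED. No distinction is made between heterozygous and
homozygous changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

GAIN = "GAIN"
LOSS = "LOSS"
BALANCED = "BALANCED"

# both arms of the 22 autosomes, matching the array CNV annotation's
# 44-arm summary; a caller-supplied arm list can restrict this
AUTOSOMAL_ARMS: tuple[str, ...] = tuple(
    f"{c}{a}" for c in range(1, 23) for a in ("p", "q")
)

ARM_THRESHOLD = 0.1
FOCAL_THRESHOLD = 0.4

# 1q/6q status categories
STATUS_BALANCED = "BALANCED"
GAIN_1Q_ONLY = "GAIN_1Q_ONLY"
LOSS_6Q_ONLY = "LOSS_6Q_ONLY"
COMBINED = "COMBINED"

# CDKN2A/B status categories
FLAT = "FLAT"
CDKN2A_ONLY_LOSS = "CDKN2A_ONLY_LOSS"
CDKN2B_ONLY_LOSS = "CDKN2B_ONLY_LOSS"
COMBINED_LOSS = "COMBINED_LOSS"


@dataclass
class CNVProfile:
    """Per-sample summarized log-ratios for chromosome arms and focal genes."""

    arm_values: dict[str, float]
    gene_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in list(self.arm_values.items()) + list(self.gene_values.items()):
            if not pd.notna(v) or v in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite log-ratio for {name!r}")


@dataclass
class ArmCallSet:
    arm_calls: dict[str, str]
    gene_calls: dict[str, str] = field(default_factory=dict)


def _call(value: float, threshold: float) -> str:
    if value > threshold:
        return GAIN
    if value < -threshold:
        return LOSS
    return BALANCED


def call_arms(
    profile: CNVProfile,
    threshold: float = ARM_THRESHOLD,
    required_arms: Sequence[str] = AUTOSOMAL_ARMS,
) -> ArmCallSet:
    """GAIN if log-ratio > threshold, LOSS if < -threshold, else BALANCED."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    missing = [a for a in required_arms if a not in profile.arm_values]
    if missing:
        raise ValueError(f"profile missing arm(s): {', '.join(missing)}")
    calls = {a: _call(v, threshold) for a, v in profile.arm_values.items()}
    return ArmCallSet(arm_calls=calls)


def call_focal(
    profile: CNVProfile, threshold: float = FOCAL_THRESHOLD
) -> dict[str, str]:
    """Focal gene calls with the focal threshold; same strict rule as arms."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    return {g: _call(v, threshold) for g, v in profile.gene_values.items()}


def status_1q6q(calls: ArmCallSet) -> str:
    """Prognostic 1q-gain / 6q-loss category for posterior fossa group A."""
    for arm in ("1q", "6q"):
        if arm not in calls.arm_calls:
            raise ValueError(f"missing arm call for {arm}")
    gain1q = calls.arm_calls["1q"] == GAIN
    loss6q = calls.arm_calls["6q"] == LOSS
    if gain1q and loss6q:
        return COMBINED
    if gain1q:
        return GAIN_1Q_ONLY
    if loss6q:
        return LOSS_6Q_ONLY
    return STATUS_BALANCED


def status_cdkn2ab(gene_calls: Mapping[str, str]) -> str:
    """CDKN2A/B loss category; gains at these loci map to FLAT."""
    for g in ("CDKN2A", "CDKN2B"):
        if g not in gene_calls:
            raise ValueError(f"missing gene call for {g}")
    a = gene_calls["CDKN2A"] == LOSS
    b = gene_calls["CDKN2B"] == LOSS
    if a and b:
        return COMBINED_LOSS
    if a:
        return CDKN2A_ONLY_LOSS
    if b:
        return CDKN2B_ONLY_LOSS
    return FLAT


def aberration_burden(calls: ArmCallSet) -> int:
    """Number of non-BALANCED arms (0..44)."""
    return sum(1 for c in calls.arm_calls.values() if c != BALANCED)


def cohort_arm_frequencies(call_sets: Sequence[ArmCallSet]) -> pd.DataFrame:
    """Per-arm gain/loss/balanced fractions across a cohort.

    Returns a DataFrame indexed by arm with columns gain_fraction,
    loss_fraction, balanced_fraction summing to 1 per arm.
    """
    if len(call_sets) == 0:
        raise ValueError("cohort_arm_frequencies requires at least one call set")
    arms = sorted(call_sets[0].arm_calls, key=_arm_sort_key)
    rows = {}
    n = len(call_sets)
    for arm in arms:
        calls = [cs.arm_calls[arm] for cs in call_sets]
        rows[arm] = {
            "gain_fraction": calls.count(GAIN) / n,
            "loss_fraction": calls.count(LOSS) / n,
            "balanced_fraction": calls.count(BALANCED) / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _arm_sort_key(arm: str):
    return (int(arm[:-1]), arm[-1])


def load_arm_definitions(path) -> tuple[str, ...]:
    """Arm names from a whitespace/tab-separated definition file with
    columns: arm name, chromosome, start, end (1-based inclusive). Lines
    starting with '#' are ignored; a header row naming the first column
    'arm' is skipped."""
    arms = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#") or parts[0].lower() == "arm":
                continue
            arms.append(parts[0])
    if not arms:
        raise ValueError(f"no arm definitions found in {path}")
    if len(set(arms)) != len(arms):
        raise ValueError("duplicate arm names in definition file")
    return tuple(arms)


def profiles_from_table(table: pd.DataFrame) -> dict[str, CNVProfile]:
    """Build per-sample profiles from a long TSV table.

    Expected columns: sample_id, feature (arm name like '1q' or gene symbol),
    log_ratio. Features matching the autosomal arm names become arm values;
    everything else is treated as a focal gene.
    """
    required = {"sample_id", "feature", "log_ratio"}
    if not required.issubset(table.columns):
        raise ValueError(f"CNV table needs columns {sorted(required)}")
    arm_set = set(AUTOSOMAL_ARMS)
    profiles: dict[str, CNVProfile] = {}
    for sample_id, sub in table.groupby("sample_id", sort=False):
        arms, genes = {}, {}
        for feat, lr in zip(sub["feature"], sub["log_ratio"]):
            (arms if feat in arm_set else genes)[feat] = float(lr)
        profiles[str(sample_id)] = CNVProfile(arm_values=arms, gene_values=genes)
    return profiles


def call_table(
    profiles: Mapping[str, CNVProfile],
    arm_threshold: float = ARM_THRESHOLD,
    focal_threshold: float = FOCAL_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample call summary: 1q/6q status, CDKN2A/B status, burden."""
    rows = []
    for sid, prof in profiles.items():
        calls = call_arms(prof, arm_threshold)
        calls.gene_calls = call_focal(prof, focal_threshold)
        rows.append(
            {
                "sample_id": sid,
                "status_1q6q": status_1q6q(calls),
                "status_cdkn2ab": status_cdkn2ab(calls.gene_calls),
                "aberration_burden": aberration_burden(calls),
                "gain_1q": int(calls.arm_calls["1q"] == GAIN),
                "loss_6q": int(calls.arm_calls["6q"] == LOSS),
                "cdkn2a_loss": int(calls.gene_calls["CDKN2A"] == LOSS),
                "cdkn2b_loss": int(calls.gene_calls["CDKN2B"] == LOSS),
            }
        )
    return pd.DataFrame(rows)
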