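"""Probe-level QC and feature preparation for methylation beta matrices.

The pipeline mirrors the standard 450k/EPIC harmonisation steps: drop
samples failing detection-p QC, keep only probes shared between the two
array generations, exclude blacklisted probes (sex chromosomes, SNPs,
cross-reactive), remove probes showing a platform batch effect, then rank
probes by variance for feature selection. All filters are idempotent and
report telescoping counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FOUR50K = "450k"
EPIC = "EPIC"
PLATFORMS = (FOUR50K, EPIC)


@dataclass
class BetaMatrix:
    """Samples x CpGs matrix of methylation beta values in [0, 1].

    ``values`` is a DataFrame with sample ids as the index and CpG ids as
    columns; ``platform`` maps every sample id to '450k' or 'EPIC'.
    """

    values: pd.DataFrame
    platform: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate CpG ids")
        vals = self.values.to_numpy()
        if vals.size and ((vals < 0) | (vals > 1)).any():
            raise ValueError("beta values outside [0, 1]")
        missing = set(self.values.index) - set(self.platform.index)
        if missing:
            raise ValueError(f"platform undefined for samples: {sorted(missing)}")
        bad = set(self.platform.loc[list(self.values.index)]) - set(PLATFORMS)
        if bad:
            raise ValueError(f"unknown platform labels: {sorted(bad)}")
        self.platform = self.platform.loc[self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(
            values=self.values.loc[list(sample_ids)],
            platform=self.platform.loc[list(sample_ids)],
        )

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(
            values=self.values.loc[:, list(cpg_ids)], platform=self.platform
        )


@dataclass
class ProbeBlacklist:
    """Probe exclusion list with a reason tag per id."""

    reasons: dict[str, str] = field(default_factory=dict)

    VALID_REASONS = ("sex_chromosome", "snp", "cross_reactive")

    @property
    def cpg_ids(self) -> set[str]:
        return set(self.reasons)

    @classmethod
    def from_file(cls, path) -> "ProbeBlacklist":
        """One id per line, or whitespace-separated columns with the reason
        tag in the last column."""
        reasons = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                reason = parts[-1] if len(parts) > 1 and parts[-1] in cls.VALID_REASONS else "cross_reactive"
                reasons[parts[0]] = reason
        return cls(reasons=reasons)


@dataclass
class FilterReport:
    """Telescoping probe counts through the filtering stages."""

    n_input_cpgs: int = 0
    n_after_intersection: int = 0
    n_blacklisted: int = 0
    n_batch_removed: int = 0
    n_final: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_cpgs": self.n_input_cpgs,
            "n_after_intersection": self.n_after_intersection,
            "n_blacklisted": self.n_blacklisted,
            "n_batch_removed": self.n_batch_removed,
            "n_final": self.n_final,
            "removed_ids": {k: sorted(v) for k, v in self.removed_ids.items()},
            "notes": list(self.notes),
        }


def drop_failed_samples(
    beta: BetaMatrix, detection_p: Mapping[str, float], alpha: float = 0.05
) -> BetaMatrix:
    """Drop samples whose detection p-value exceeds ``alpha``.

    Samples exactly at the threshold are kept (the QC rule excludes p-values
    strictly greater than alpha). A missing QC value is an error.
    """
    missing = [s for s in beta.sample_ids if s not in detection_p]
    if missing:
        raise ValueError(f"missing detection p-value for sample(s): {missing}")
    keep = [s for s in beta.sample_ids if detection_p[s] <= alpha]
    if not keep:
        logger.warning("all samples failed detection-p QC (alpha=%s)", alpha)
        return BetaMatrix(
            values=beta.values.iloc[0:0], platform=beta.platform.iloc[0:0]
        )
    return beta.subset_samples(keep)


def intersect_platform_probes(
    beta: BetaMatrix, shared_probe_list: Iterable[str]
) -> BetaMatrix:
    """Keep only probes present on both array generations, order preserved."""
    shared = set(shared_probe_list)
    if not shared:
        raise ValueError("shared probe list is empty")
    keep = [c for c in beta.cpg_ids if c in shared]
    if not keep:
        raise ValueError("no probes remain after platform intersection")
    return beta.subset_cpgs(keep)


def exclude_blacklist(beta: BetaMatrix, bl: ProbeBlacklist) -> BetaMatrix:
    """Remove blacklisted probes (sex-chromosome / SNP / cross-reactive)."""
    drop = bl.cpg_ids
    keep = [c for c in beta.cpg_ids if c not in drop]
    return beta.subset_cpgs(keep)


def filter_batch_cpgs(
    beta: BetaMatrix, mean_diff: float = 0.2, alpha: float = 0.01
) -> tuple[BetaMatrix, list[str]]:
    """Remove probes showing a platform batch effect between 450k and EPIC.

    A probe is removed iff BOTH conditions hold: the absolute difference of
    platform means exceeds ``mean_diff`` AND the Welch two-sided t-test
    p-value, Bonferroni-corrected by the number of probes tested here, is
    below ``alpha``. Requires at least two samples per platform so the
    within-group variances are defined.
    """
    plat = beta.platform.to_numpy()
    mask_epic = plat == EPIC
    n_epic, n_450k = int(mask_epic.sum()), int((~mask_epic).sum())
    if n_epic < 2 or n_450k < 2:
        raise ValueError(
            f"need >= 2 samples per platform, got 450k={n_450k}, EPIC={n_epic}"
        )
    x = beta.values.to_numpy()
    a, b = x[mask_epic], x[~mask_epic]
    delta = np.abs(a.mean(axis=0) - b.mean(axis=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance probes give nan p
        _, pvals = stats.ttest_ind(a, b, axis=0, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)
    n_tested = x.shape[1]
    removed = (delta > mean_diff) & (pvals * n_tested < alpha)
    removed_ids = [c for c, r in zip(beta.cpg_ids, removed) if r]
    keep = [c for c, r in zip(beta.cpg_ids, removed) if not r]
    return beta.subset_cpgs(keep), removed_ids


def select_top_variable(beta: BetaMatrix, k: int = 10_000) -> list[str]:
    """Ids of the ``k`` highest-variance probes, ties broken by id.

    Variance is computed over the samples present in ``beta`` only — callers
    must pass training samples exclusively to avoid information leakage.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if beta.values.shape[1] == 0 or beta.values.shape[0] == 0:
        raise ValueError("empty beta matrix")
    var = beta.values.to_numpy().var(axis=0, ddof=1) if beta.values.shape[0] > 1 \
        else np.zeros(beta.values.shape[1])
    order = sorted(zip(beta.cpg_ids, var), key=lambda cv: (-cv[1], cv[0]))
    return [c for c, _ in order[: min(k, len(order))]]


def run_probe_filters(
    beta: BetaMatrix,
    shared_probe_list: Iterable[str] | None = None,
    blacklist: ProbeBlacklist | None = None,
    mean_diff: float = 0.2,
    alpha: float = 0.01,
) -> tuple[BetaMatrix, FilterReport]:
    """Full probe-filter cascade with a telescoping report."""
    report = FilterReport(n_input_cpgs=len(beta.cpg_ids))
    if shared_probe_list is not None:
        before = set(beta.cpg_ids)
        beta = intersect_platform_probes(beta, shared_probe_list)
        report.removed_ids["intersection"] = sorted(before - set(beta.cpg_ids))
    report.n_after_intersection = len(beta.cpg_ids)
    if blacklist is not None:
        before = set(beta.cpg_ids)
        beta = exclude_blacklist(beta, blacklist)
        report.removed_ids["blacklist"] = sorted(before - set(beta.cpg_ids))
    report.n_blacklisted = report.n_after_intersection - len(beta.cpg_ids)
    beta, batch_removed = filter_batch_cpgs(beta, mean_diff=mean_diff, alpha=alpha)
    report.removed_ids["batch"] = sorted(batch_removed)
    report.n_batch_removed = len(batch_removed)
    report.n_final = len(beta.cpg_ids)
    report.notes.append(
        "batch filter: Welch t-test; Bonferroni over probes entering this stage"
    )
    return beta, report
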