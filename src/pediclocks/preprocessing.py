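"""Probe filtering, platform intersection and KNN imputation.

These mirror the standard pre-analysis steps on beta matrices: removing
probes whose target CpG is near a SNP, probes aligning to multiple genomic
locations and probes on the X/Y chromosomes; restricting joint analyses of
450K and EPIC cohorts to the shared probe set; and K-nearest-neighbour
imputation of missing betas.

Mask lists are user-supplied plain-text files (one probe id per line); the
published SNP/cross-reactive lists are external artifacts and are not
bundled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = ["ProbeMaskSet", "filter_probes", "intersect_platforms", "knn_impute"]


@dataclass
class ProbeMaskSet:
    """Probe-id sets to remove: SNP-proximal, multi-mapping, X/Y-chromosome.

    The sets may overlap; filtering removes their union.
    """

    snp_proximal: set[str] = field(default_factory=set)
    multi_mapping: set[str] = field(default_factory=set)
    sex_chromosome: set[str] = field(default_factory=set)

    @property
    def union(self) -> set[str]:
        return self.snp_proximal | self.multi_mapping | self.sex_chromosome


def filter_probes(
    beta: BetaMatrix, masks: ProbeMaskSet
) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove masked probes; report removal counts per category.

    A probe is counted once, under the first matching category in the order
    snp_proximal, multi_mapping, sex_chromosome.  An all-masked result is
    allowed (with a warning) and returned as an empty-probe report.
    """
    report = {"snp_proximal": 0, "multi_mapping": 0, "sex_chromosome": 0}
    keep = []
    for probe in beta.values.index:
        if probe in masks.snp_proximal:
            report["snp_proximal"] += 1
        elif probe in masks.multi_mapping:
            report["multi_mapping"] += 1
        elif probe in masks.sex_chromosome:
            report["sex_chromosome"] += 1
        else:
            keep.append(probe)
    report["kept"] = len(keep)
    if not keep:
        warnings.warn("all probes removed by masks", stacklevel=2)
        # return a 0-probe frame without tripping the non-empty invariant
        out = BetaMatrix.__new__(BetaMatrix)
        out.values = beta.values.iloc[0:0]
        return out, report
    return BetaMatrix(beta.values.loc[keep]), report


def intersect_platforms(a: BetaMatrix, b: BetaMatrix) -> tuple[BetaMatrix, BetaMatrix]:
    """Restrict two beta matrices to their shared probe set, same order."""
    shared = [p for p in a.values.index if p in set(b.values.index)]
    if not shared:
        raise ValueError("no shared probes between the two platforms")
    return BetaMatrix(a.values.loc[shared]), BetaMatrix(b.values.loc[shared])


def knn_impute(beta: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Impute missing betas from the k nearest probe rows.

    For a missing value at (probe i, sample s) the imputed value is the mean
    of sample s's observed betas at the k probes nearest to probe i, where
    nearness is the Euclidean distance between probe rows computed over the
    samples both probes observe.  Imputed values are clipped to [0, 1];
    observed values are never altered.  ``k`` larger than the number of
    candidate probes is reduced with a warning; a probe with no observed
    value at all is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = beta.values
    vals = df.to_numpy(dtype=float, copy=True)
    obs = np.isfinite(vals)
    fully_missing = np.where(~obs.any(axis=1))[0]
    if fully_missing.size:
        raise ValueError(
            f"probe(s) with no observed value: {list(df.index[fully_missing][:5])}"
        )
    if not (~obs).any():
        return BetaMatrix(df.copy())

    n_probes = vals.shape[0]
    if k > n_probes - 1:
        warnings.warn(
            f"k={k} exceeds available probes; reduced to {n_probes - 1}", stacklevel=2
        )
        k = max(1, n_probes - 1)

    filled = vals.copy()
    rows_with_missing = np.where((~obs).any(axis=1))[0]
    for i in rows_with_missing:
        # distances from probe i to all other probes over common samples
        common = obs & obs[i]
        diff = np.where(common, vals - vals[i], 0.0)
        n_common = common.sum(axis=1)
        with np.errstate(invalid="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1))
        dist[i] = np.inf
        dist[n_common == 0] = np.inf
        order = np.argsort(dist, kind="stable")
        for s in np.where(~obs[i])[0]:
            # nearest probes that observe sample s
            donors = [j for j in order if np.isfinite(dist[j]) and obs[j, s]]
            if not donors:
                raise ValueError(
                    f"no donor probes observe sample {df.columns[s]!r} "
                    f"for probe {df.index[i]!r}"
                )
            picked = donors[:k]
            filled[i, s] = float(np.clip(np.mean(vals[picked, s]), 0.0, 1.0))
    out = pd.DataFrame(filled, index=df.index, columns=df.columns)
    return BetaMatrix(out)
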