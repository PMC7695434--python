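"""Reference-based cell-type deconvolution and composition sensitivity.

Whole-blood methylation is a mixture over cell populations, and clocks can
be sensitive to the mixing proportions.  :func:`estimate_proportions`
implements the classic reference-based approach: each sample's beta vector
is projected onto reference cell-type profiles by constrained least
squares with non-negative weights summing to at most one (the unexplained
remainder absorbs cell types missing from the reference).

:func:`clock_vs_composition` then correlates per-sample age estimates (or
mitotic scores) with the estimated proportions, with Benjamini-Hochberg
correction over each clock's family of cell types.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stats import bh_adjust
from .types import AgeEstimates, BetaMatrix, CellReference

logger = logging.getLogger(__name__)

__all__ = ["estimate_proportions", "clock_vs_composition"]


def _solve_simplex_ls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A w - b||^2  s.t.  w >= 0, sum(w) <= 1.

    Solved as non-negative least squares over (w, slack) with the equality
    sum(w) + slack = 1 enforced by a heavy penalty row; accuracy is well
    below 1e-6 for the scales involved (betas in [0, 1]).
    """
    p, c = A.shape
    scale = max(1.0, float(np.abs(A).max()))
    mu = 1e6 * scale
    A_aug = np.zeros((p + 1, c + 1))
    A_aug[:p, :c] = A
    A_aug[p, :] = mu
    b_aug = np.concatenate([b, [mu]])
    w, _ = optimize.nnls(A_aug, b_aug)
    return np.clip(w[:c], 0.0, None)


def estimate_proportions(beta: BetaMatrix, ref: CellReference) -> pd.DataFrame:
    """Estimate cell-type proportions per sample.

    Returns a DataFrame indexed by sample id with one column per reference
    cell type plus ``residual_norm``; weights are non-negative and sum to at
    most one.  Probes missing in a sample are omitted from that sample's
    fit.  A rank-deficient reference over the shared probes is solved
    anyway with a warning.
    """
    shared = [p for p in ref.profiles.index if p in set(beta.values.index)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 probes shared between beta matrix and reference")
    A_full = ref.profiles.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(A_full) < A_full.shape[1]:
        warnings.warn(
            "reference profiles are rank-deficient over shared probes; "
            "proportions may not be identifiable",
            stacklevel=2,
        )
    B = beta.values.loc[shared]
    rows = {}
    for s in beta.sample_ids:
        b = B[s].to_numpy(dtype=float)
        mask = np.isfinite(b)
        A = A_full[mask]
        w = _solve_simplex_ls(A, b[mask])
        resid = float(np.linalg.norm(A @ w - b[mask]))
        rows[s] = np.concatenate([w, [resid]])
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(ref.cell_types) + ["residual_norm"]
    )
    out.index.name = "sample_id"
    return out


def clock_vs_composition(
    estimates: AgeEstimates, proportions: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each clock's estimate with each cell type.

    Score-only clocks contribute their score, coefficient clocks their
    methylation age in years.  BH adjustment is applied within each clock's
    family of cell types.  Constant proportion columns (undefined r) are
    reported missing and excluded from the BH family.
    """
    cell_types = [c for c in proportions.columns if c != "residual_norm"]
    records = []
    for clock in estimates.clocks:
        tab = estimates.for_clock(clock).set_index("sample_id")
        y = tab["score"].where(tab["score"].notna(), tab["methylation_age_years"])
        common = [s for s in y.index if s in proportions.index]
        if len(common) < 3:
            raise ValueError(f"fewer than 3 overlapping samples for clock {clock!r}")
        yv = y.reindex(common).to_numpy(dtype=float)
        for ct in cell_types:
            xv = proportions.loc[common, ct].to_numpy(dtype=float)
            ok = np.isfinite(xv) & np.isfinite(yv)
            if ok.sum() < 3 or np.std(xv[ok]) == 0 or np.std(yv[ok]) == 0:
                records.append((clock, ct, int(ok.sum()), np.nan, np.nan))
                continue
            r, p = stats.pearsonr(xv[ok], yv[ok])
            records.append((clock, ct, int(ok.sum()), float(r), float(p)))
    out = pd.DataFrame(
        records, columns=["clock", "cell_type", "n", "pearson_r", "p_value"]
    )
    out["adj_p_value"] = np.nan
    for clock, idx in out.groupby("clock").groups.items():
        sub = out.loc[idx]
        valid = sub.index[sub["p_value"].notna()]
        if len(valid):
            out.loc[valid, "adj_p_value"] = bh_adjust(
                out.loc[valid, "p_value"].to_numpy()
            )
    return out
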