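"""Synthetic methylome cohorts with known ground truth.

The generator emulates the statistical structure that pediatric clock
evaluation assumes, so the whole pipeline can run and be tested at desk
scale without downloads:

* ages drawn uniformly on a pediatric range (0-18 years by default);
* age-responsive CpGs whose mean beta follows the *transformed* age
  ``F(age)`` (log-linear with a 20-year anchor), capturing the fast
  early-childhood methylation change that saturates later;
* a logistic link keeping betas inside (0, 1) (default), or a linear link
  under which an exactly age-consistent clock exists in closed form;
* age-independent noise CpGs, optional per-tissue offsets, and optional
  per-group acceleration offsets applied to the age *before* the transform,
  so a consistent clock reads back chronological age plus the offset —
  the structure of a tumor cohort with subtype-specific acceleration;
* additive truncated-Gaussian measurement noise, clipped to [0, 1].

:func:`make_consistent_clock` turns the ground truth into a
:class:`~pediclocks.types.ClockModel` whose predictions recover the
simulated ages, serving as an independent oracle for the clock engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .transforms import TransformSpec, loglinear_forward
from .types import BetaMatrix, CellReference, ClockModel, SampleSheet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "make_consistent_clock",
    "simulate_mixtures",
    "simulate_cell_reference",
    "simulate_tumor_cohort",
    "BLOOD_CELL_TYPES",
]

BLOOD_CELL_TYPES = ["CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran"]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings.

    ``group_offsets`` maps a group label to an acceleration offset in years
    added to the chronological age on the transformed-age scale (i.e. the
    methylome looks ``offset`` years older); ``group_sd_years`` adds
    within-group spread to those offsets.  ``tissue_offsets`` maps a tissue
    label to the scale of per-CpG mean shifts for that tissue.
    """

    n_samples: int = 200
    age_range_years: tuple[float, float] = (0.0, 18.0)
    n_age_cpgs: int = 30
    n_noise_cpgs: int = 20
    beta_noise_sd: float = 0.02
    anchor_years: float = 20.0
    link: str = "logistic"
    tissue_offsets: dict | None = None
    group_offsets: dict | None = None
    group_sd_years: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.beta_noise_sd < 0:
            raise ValueError("beta_noise_sd must be >= 0")
        lo, hi = self.age_range_years
        if not (0 <= lo < hi <= 120):
            raise ValueError("age range must satisfy 0 <= lo < hi <= 120")
        if self.link not in ("logistic", "linear"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.n_age_cpgs < 1:
            raise ValueError("need at least one age-responsive CpG")


@dataclass
class GroundTruth:
    """Everything the generator knows: per-CpG response parameters
    (``params`` with columns kind/a/b), per-sample true and effective ages,
    and the configuration used."""

    params: pd.DataFrame
    ages: pd.Series
    effective_ages: pd.Series
    acceleration: pd.Series
    config: SimulationConfig = field(repr=False)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """Generate a cohort; deterministic for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    lo, hi = config.age_range_years
    ages = rng.uniform(lo, hi, n)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    tissues = list(config.tissue_offsets) if config.tissue_offsets else ["blood"]
    tissue = np.array([tissues[i % len(tissues)] for i in range(n)])
    groups = list(config.group_offsets) if config.group_offsets else [None]
    group = np.array([groups[i % len(groups)] for i in range(n)], dtype=object)

    accel = np.zeros(n)
    if config.group_offsets:
        for g, off in config.group_offsets.items():
            mask = group == g
            accel[mask] = off + rng.normal(0.0, config.group_sd_years, mask.sum())
    effective = np.clip(ages + accel, -0.99, None)
    F = loglinear_forward(effective, config.anchor_years)

    n_age, n_noise = config.n_age_cpgs, config.n_noise_cpgs
    probe_ids = [f"cg{j:06d}" for j in range(n_age + n_noise)]
    if config.link == "linear":
        a = rng.uniform(0.66, 0.78, n_age)
        b = rng.uniform(0.05, 0.18, n_age)
        mean_age = a[:, None] + b[:, None] * F[None, :]
    else:
        a = rng.uniform(-0.5, 0.5, n_age)
        b = rng.uniform(0.2, 1.0, n_age)
        mean_age = _logistic(a[:, None] + b[:, None] * F[None, :])
    noise_levels = rng.uniform(0.1, 0.9, n_noise)
    mean_noise = np.repeat(noise_levels[:, None], n, axis=1)
    means = np.vstack([mean_age, mean_noise]) if n_noise else mean_age

    if config.tissue_offsets:
        n_probes = means.shape[0]
        offsets = {
            t: rng.normal(0.0, float(scale), n_probes)
            for t, scale in config.tissue_offsets.items()
        }
        for t in tissues:
            cols = np.where(tissue == t)[0]
            means[:, cols] += offsets[t][:, None]

    betas = means
    if config.beta_noise_sd > 0:
        betas = betas + rng.normal(0.0, config.beta_noise_sd, betas.shape)
    betas = np.clip(betas, 0.0, 1.0)

    beta = BetaMatrix(pd.DataFrame(betas, index=probe_ids, columns=sample_ids))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "age_years": ages,
                "tissue": tissue,
                "group": [g if g is not None else pd.NA for g in group],
                "cohort": "simulated",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    params = pd.DataFrame(
        {
            "kind": ["age"] * n_age + ["noise"] * n_noise,
            "a": np.concatenate([a, np.full(n_noise, np.nan)]),
            "b": np.concatenate([b, np.full(n_noise, np.nan)]),
            "level": np.concatenate([np.full(n_age, np.nan), noise_levels]),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    truth = GroundTruth(
        params=params,
        ages=pd.Series(ages, index=sample_ids, name="age_years"),
        effective_ages=pd.Series(effective, index=sample_ids, name="effective_age_years"),
        acceleration=pd.Series(accel, index=sample_ids, name="acceleration_years"),
        config=config,
    )
    return beta, sheet, truth


def make_consistent_clock(
    truth: GroundTruth, k: int | None = None, name: str = "sim_consistent"
) -> ClockModel:
    """Build a clock whose predictions recover the simulated ages.

    Under the linear link the construction is exact: with per-CpG response
    ``beta_j = a_j + b_j F(age)``, weights ``w_j = 1/(k b_j)`` and intercept
    ``-sum_j w_j a_j`` give a linear predictor identically equal to
    ``F(age)``, so the clock inverts to the chronological (or offset) age.
    Under the logistic link the weights are fitted by least squares on the
    noiseless mean response over the cohort's own age distribution, which
    is consistent only to the accuracy of that local linearisation.
    """
    cfg = truth.config
    age_probes = truth.params.index[truth.params["kind"] == "age"]
    if k is not None:
        age_probes = age_probes[:k]
    kk = len(age_probes)
    if kk == 0:
        raise ValueError("ground truth has no age-responsive CpGs")
    a = truth.params.loc[age_probes, "a"].to_numpy()
    b = truth.params.loc[age_probes, "b"].to_numpy()
    if cfg.link == "linear":
        w = 1.0 / (kk * b)
        intercept = -float(np.sum(w * a))
    else:
        F = loglinear_forward(truth.effective_ages.to_numpy(), cfg.anchor_years)
        M = _logistic(a[:, None] + b[:, None] * F[None, :]).T  # samples x CpGs
        design = np.column_stack([np.ones(M.shape[0]), M])
        coef, *_ = np.linalg.lstsq(design, F, rcond=None)
        intercept, w = float(coef[0]), coef[1:]
    return ClockModel(
        name=name,
        intercept=float(intercept),
        coefficients={p: float(wj) for p, wj in zip(age_probes, w)},
        transform=TransformSpec("loglinear", cfg.anchor_years),
        native_unit="years",
    )


def simulate_cell_reference(
    n_probes: int = 200,
    cell_types: list[str] | None = None,
    seed: int = 0,
) -> CellReference:
    """Synthetic discriminating reference profiles (probe x cell type).

    Profiles are drawn independently per probe and cell type, which makes
    the columns mutually well separated — an idealisation of sorted-cell
    reference panels.
    """
    cell_types = cell_types or list(BLOOD_CELL_TYPES)
    rng = np.random.default_rng(seed)
    probes = [f"cgref{j:05d}" for j in range(n_probes)]
    profiles = rng.uniform(0.05, 0.95, (n_probes, len(cell_types)))
    return CellReference(pd.DataFrame(profiles, index=probes, columns=cell_types))


def simulate_mixtures(
    ref: CellReference,
    weights,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Mix reference profiles with known weights plus truncated noise.

    ``weights`` is an (n_samples x n_cell_types) array/DataFrame of
    non-negative rows summing to at most 1.  Returns the mixed beta matrix
    and the true weights as a DataFrame.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim == 1:
        W = W[None, :]
    if W.shape[1] != len(ref.cell_types):
        raise ValueError("weight columns must match reference cell types")
    if np.any(W < 0) or np.any(W.sum(axis=1) > 1 + 1e-8):
        raise ValueError("weights must be >= 0 with row sums <= 1")
    rng = np.random.default_rng(seed)
    A = ref.profiles.to_numpy(dtype=float)
    mixed = A @ W.T
    if noise_sd > 0:
        mixed = mixed + rng.normal(0.0, noise_sd, mixed.shape)
    mixed = np.clip(mixed, 0.0, 1.0)
    sample_ids = [f"M{i:04d}" for i in range(W.shape[0])]
    beta = BetaMatrix(pd.DataFrame(mixed, index=ref.probe_ids, columns=sample_ids))
    truth = pd.DataFrame(W, index=sample_ids, columns=ref.cell_types)
    return beta, truth


def simulate_tumor_cohort(
    base: SimulationConfig,
    group_offsets: dict[str, float],
    group_sd_years: float = 3.0,
    n_per_group: int = 60,
    seed: int | None = None,
) -> tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """Cohort with >= 2 groups carrying ordered acceleration offsets.

    Each group's offset (years) is applied on the transformed-age scale
    before betas are generated, so a consistent clock reads back
    chronological age plus offset.  Group sizes are exactly ``n_per_group``.
    """
    if len(group_offsets) < 2:
        raise ValueError("need at least 2 groups")
    cfg = replace(
        base,
        n_samples=n_per_group * len(group_offsets),
        group_offsets=dict(group_offsets),
        group_sd_years=group_sd_years,
        seed=base.seed if seed is None else seed,
    )
    return simulate_cohort(cfg)
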