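"""Synthetic multi-site cohort generator for ROI time series and phenotypes.

Each subject's ROI signals follow a one-factor equicorrelation model: at
volume t,

    x_t = sqrt(rho(t)) * c_t * 1 + sqrt(1 - rho(t)) * e_t,

where c_t is a scalar standard-normal signal shared by all regions, e_t are
independent standard normals per region, and region k's instantaneous
coupling

    rho_k(t) = clip(rho_target + s_k * alpha_target * sin(2*pi*t/P + phi))

oscillates sinusoidally with period P ~ 180 s and a random per-subject
phase. The sign s_k is +1 for one half of the regions and -1 for the other,
so the two subnetworks strengthen and weaken their coupling in antiphase.
Both choices matter for the variability statistic. A fluctuation applied
uniformly to every region would shift all entries of a windowed
connectivity profile together, and profile-wise Pearson correlation removes
uniform shifts -- V would not respond at all; antiphase modulation changes
the *pattern* of connectivity over time (same-sign pairs track rho + a(t)
while cross-sign pairs track sqrt((rho+a)(rho-a))), which V is built to
detect. And the period must be longer than the sliding window, otherwise
within-window averaging cancels the oscillation before the windowed FC
matrices ever see it.

Each series is then passed through an AR(1) filter (hemodynamic-like
autocorrelation) and re-standardized; because every region gets the same
filter, the expected full-scan pairwise Pearson correlation stays rho_target
when alpha_target = 0 (for alpha_target > 0 cross-sign pairs sit slightly
below it, a second-order bias of about alpha^2 / (2 rho)). rho_target sets
static FC strength; alpha_target sets the temporal fluctuation of windowed
connectivity and hence V.

Cohort structure: age uniform over the configured range; the two diagnostic
groups get different age slopes on rho_target (the patient slope more
negative), which induces a diagnosis-by-age interaction in measured FC
strength; alpha_target increases with age so V rises with age in both
groups. Sites differ in scan length (150-250 volumes at TR = 2 s). All
randomness derives from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_core import SubjectRecord, TimeSeriesMatrix

__all__ = ["SiteSpec", "SimulationConfig", "simulate_subject", "simulate_phenotypes", "simulate_cohort"]

#: clip bounds keeping per-subject correlation targets strictly inside (0, 1)
CLIP_LO, CLIP_HI = 0.02, 0.95


@dataclass(frozen=True)
class SiteSpec:
    site_id: str
    n_volumes: int
    tr_s: float = 2.0


DEFAULT_SITES = (
    SiteSpec("site01", 200, 2.0),
    SiteSpec("site02", 150, 2.0),
    SiteSpec("site03", 240, 2.0),
    SiteSpec("site04", 180, 2.0),
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Slopes are per year of age on the correlation target, centered at the
    midpoint of ``age_range``; the patient slope is more negative than the
    control slope so measured FC strength declines faster with age in the
    patient group. ``alpha_age_slope`` makes connectivity fluctuation (and
    hence V) increase with age in both groups.
    """

    n_per_group: int = 150
    age_range: tuple[float, float] = (18.0, 65.0)
    rho0: float = 0.40
    slope_hc: float = -0.0010
    slope_mdd: float = -0.0025
    alpha0: float = 0.15
    alpha_age_slope: float = 0.002
    subject_noise_sd: float = 0.05
    ar_coef: float = 0.3
    n_rois: int = 58
    sites: tuple[SiteSpec, ...] = DEFAULT_SITES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rho0 < 1):
            raise ValueError("rho0 must be in (0, 1)")
        if self.alpha0 < 0 or self.subject_noise_sd < 0:
            raise ValueError("amplitudes and noise SDs must be >= 0")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must be in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        for s in self.sites:
            if s.n_volumes < 2 or s.tr_s <= 0:
                raise ValueError(f"invalid site spec {s}")


def simulate_subject(
    rho_target: float,
    alpha_target: float,
    n_volumes: int,
    tr_s: float,
    n_rois: int,
    ar_coef: float,
    seed: int | np.random.Generator,
    subject_id: str = "sim",
) -> TimeSeriesMatrix:
    """Simulate one subject's ROI time series from the one-factor model."""
    if not (0 < rho_target < 1):
        raise ValueError("rho_target must be in (0, 1)")
    if alpha_target < 0:
        raise ValueError("alpha_target must be >= 0")
    if rho_target - alpha_target <= 0 or rho_target + alpha_target >= 1:
        raise ValueError("rho_target +/- alpha_target must stay inside (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    period_vol = max(2.0, 180.0 / tr_s)  # slow coupling fluctuation (~180 s period)
    phi = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_volumes)
    wave = alpha_target * np.sin(2 * np.pi * t / period_vol + phi)
    # antiphase modulation: first half of the regions couple more strongly
    # while the second half couples more weakly, and vice versa
    sign = np.where(np.arange(n_rois) < n_rois // 2, 1.0, -1.0)
    rho_tk = np.clip(rho_target + wave[:, None] * sign[None, :], 1e-6, 1 - 1e-6)
    shared = rng.standard_normal(n_volumes)
    noise = rng.standard_normal((n_volumes, n_rois))
    x = np.sqrt(rho_tk) * shared[:, None] + np.sqrt(1 - rho_tk) * noise
    if ar_coef > 0:
        for v in range(1, n_volumes):
            x[v] = ar_coef * x[v - 1] + x[v]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    labels = tuple(f"ROI{i+1:03d}" for i in range(n_rois))
    return TimeSeriesMatrix(subject_id=subject_id, tr_s=tr_s, data=x, roi_labels=labels)


def _clip_targets(rho: float, alpha: float) -> tuple[float, float]:
    rho = float(np.clip(rho, CLIP_LO, CLIP_HI))
    alpha = float(np.clip(alpha, 0.0, min(rho - CLIP_LO, (1 - CLIP_LO) - rho)))
    return rho, alpha


def simulate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-subject phenotypes and simulation targets (no time series).

    Returns one row per subject with SubjectRecord fields plus rho_target,
    alpha_target, n_volumes and tr_s. Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    mid = 0.5 * (lo + hi)
    n_sites = len(config.sites)
    rows = []
    for group, slope in (("MDD", config.slope_mdd), ("HC", config.slope_hc)):
        for i in range(config.n_per_group):
            age = rng.uniform(lo, hi)
            sex = "female" if rng.random() < 0.5 else "male"
            education = max(0.0, rng.normal(12.0, 4.0))
            fd = float(np.clip(rng.normal(0.07, 0.03), 0.0, 0.2))
            site = config.sites[rng.integers(n_sites)]
            rho = config.rho0 + slope * (age - mid) + rng.normal(0, config.subject_noise_sd)
            alpha = (
                config.alpha0
                + config.alpha_age_slope * (age - mid)
                + rng.normal(0, config.subject_noise_sd)
            )
            rho, alpha = _clip_targets(rho, alpha)
            row = {
                "subject_id": f"{'mdd' if group == 'MDD' else 'hc'}{i+1:04d}",
                "diagnosis": group,
                "age": age,
                "sex": sex,
                "education": education,
                "site": site.site_id,
                "mean_fd": fd,
                "illness_duration": np.nan,
                "hamd": np.nan,
                "hama": np.nan,
                "episodicity": None,
                "rho_target": rho,
                "alpha_target": alpha,
                "n_volumes": site.n_volumes,
                "tr_s": site.tr_s,
            }
            if group == "MDD":
                # clinical scores with realistic availability fractions
                if rng.random() < 0.84:
                    row["hamd"] = max(0.0, rng.normal(20.6, 7.8))
                if rng.random() < 0.58:
                    row["hama"] = max(0.0, rng.normal(19.4, 8.9))
                if rng.random() < 0.77:
                    row["illness_duration"] = max(1.0, rng.normal(38.5, 60.6))
                if rng.random() < 0.62:
                    row["episodicity"] = "first" if rng.random() < 0.6 else "recurrent"
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectRecord], dict[str, TimeSeriesMatrix]]:
    """Simulate phenotypes and ROI time series for a full multi-site cohort.

    Fully reproducible from ``config.seed``; per-subject series seeds are
    derived from the root seed so cohorts of different sizes share no streams.
    """
    pheno = simulate_phenotypes(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(pheno))
    records: list[SubjectRecord] = []
    series: dict[str, TimeSeriesMatrix] = {}
    for (idx, row), child in zip(pheno.iterrows(), children):
        rec = SubjectRecord(
            subject_id=row["subject_id"],
            diagnosis=row["diagnosis"],
            age=float(row["age"]),
            sex=row["sex"],
            education=float(row["education"]),
            site=row["site"],
            mean_fd=float(row["mean_fd"]),
            illness_duration=None if pd.isna(row["illness_duration"]) else float(row["illness_duration"]),
            hamd=None if pd.isna(row["hamd"]) else float(row["hamd"]),
            hama=None if pd.isna(row["hama"]) else float(row["hama"]),
            episodicity=row["episodicity"] if isinstance(row["episodicity"], str) else None,
        )
        records.append(rec)
        series[rec.subject_id] = simulate_subject(
            rho_target=float(row["rho_target"]),
            alpha_target=float(row["alpha_target"]),
            n_volumes=int(row["n_volumes"]),
            tr_s=float(row["tr_s"]),
            n_rois=config.n_rois,
            ar_coef=config.ar_coef,
            seed=np.random.default_rng(child),
            subject_id=rec.subject_id,
        )
    return records, series
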