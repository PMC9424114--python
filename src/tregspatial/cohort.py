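"""Synthetic tissue-core cohort generator.

Emulates the data the pipeline was designed for, at desk scale: circular
TMA cores (0.6 or 1.0 mm) carrying a few hundred segmented cells each,
with

* right-skewed immune infiltration across samples (a shared lognormal
  sample effect plus per-category effects), which also induces the strong
  across-sample correlation between the FOXP3+ and triple-positive-Treg
  density scores;
* a controllable short-range attraction of Treg labels toward CD8+ cells
  (weight exp(theta * exp(-d / sigma)), d = distance to the nearest CD8+
  cell), whose theta = 0 case is exactly the permutation test's null;
* two-component lognormal marker intensities with a per-sample random
  effect on the CD25 and FOXP3 positive components, and a Gaussian-copula
  dependence between CD25 and FOXP3 within triple-positive Tregs; the
  shipped defaults are calibrated so that across samples the mean CD25
  (10th-90th percentile near 3.9-9.1) and mean FOXP3 (near 1.3-4.8) in
  tp-Tregs, the pooled CD25-High/FOXP3-High fraction (near 16%), and the
  FOXP3-vs-tp-Treg density correlation (near 0.85) match the cohorts this
  pipeline targets;
* a clinical table with realistic covariate marginals and
  proportional-hazards survival (exponential baseline, uniform censoring,
  administrative censoring at 60 months).

Everything is deterministic given the master seed; per-sample substreams
are derived from (seed, sample index) so generation order is irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .io import ClinicalRecord, SampleCellTable, TissueOutline

log = logging.getLogger("tregspatial")

MARKERS = ("CD3", "CD4", "CD8", "CD25", "FOXP3")

#: which markers are truly positive per generated category
CATEGORY_MARKERS = {
    "CD8": ("CD3", "CD8"),
    "FOXP3": ("CD3", "CD4", "FOXP3"),
    "tpTreg": ("CD3", "CD4", "CD25", "FOXP3"),
    "other": (),
}

#: shipped positivity thresholds for synthetic data (well inside the gap
#: between the negative and positive intensity components)
DEFAULT_THRESHOLDS = {"CD3": 1.0, "CD4": 1.0, "CD8": 1.0, "CD25": 0.8, "FOXP3": 0.2}


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions."""

    n_samples: int = 100
    core_diameter_mm: float = 1.0  # alternative: 0.6
    cell_density_per_mm2: float = 400.0  # desk-scale runtime choice
    # baseline category proportions (modulated by infiltration effects)
    p_cd8: float = 0.15
    p_foxp3: float = 0.10
    p_tptreg: float = 0.05
    # spatial attraction of Treg labels toward CD8+ cells
    theta: float = 0.0
    sigma_um: float = 20.0
    #: category counts fixed at exact proportions (no infiltration noise);
    #: used for spatial test calibration runs
    fixed_counts: bool = False
    # infiltration random effects (log scale)
    infiltration_sd: float = 0.7  # shared across immune categories
    category_sd: float = 0.36  # independent per category
    # intensity model: negative components, log-normal (log-mean, log-sd)
    neg_log: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CD3": (np.log(0.2), 0.5),
            "CD4": (np.log(0.2), 0.5),
            "CD8": (np.log(0.2), 0.5),
            "CD25": (np.log(0.2), 0.5),
            "FOXP3": (np.log(0.05), 0.5),
        }
    )
    # positive components for markers without a sample effect
    pos_log: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CD3": (np.log(4.0), 0.5),
            "CD4": (np.log(3.0), 0.5),
            "CD8": (np.log(4.0), 0.5),
        }
    )
    # CD25 / FOXP3 positive components: per-sample random effect on the
    # log-mean plus cell-level spread; calibrated to the printed
    # across-sample percentile ranges
    cd25_sample_log_mean: float = 1.571
    cd25_sample_log_sd: float = 0.188
    cd25_cell_log_sd: float = 0.70
    foxp3_sample_log_mean: float = 0.645
    foxp3_sample_log_sd: float = 0.40
    foxp3_cell_log_sd: float = 0.80
    #: Gaussian-copula correlation of CD25/FOXP3 within tp-Tregs,
    #: calibrated to the pooled High/High fraction
    rho_cell: float = 0.90
    #: optional bimodal sample effect on log-CD25 for cutoff testing:
    #: (separation in log units, probability of the upper mode)
    cd25_bimodal: tuple[float, float] | None = None
    # epithelial region: per-sample cancer cell fraction ~ Beta(a, b)
    epithelial_beta: tuple[float, float] = (5.0, 6.0)
    # survival model
    n_patients: int = 1000
    baseline_hazard_per_month: float = 0.0075
    cohort2_hazard_ratio: float = 1.2  # baseline shift absorbed by stratification
    log_hr: Mapping[str, float] = field(
        default_factory=lambda: {
            "ieCD8_high": np.log(0.62),
            "mean_cd25_high": np.log(1.35),
            "proximity_significant": np.log(1.36),
            "pT3": np.log(1.50),
            "pT4": np.log(3.00),
            "pN1": np.log(1.54),
            "pN2": np.log(2.34),
            "msi": np.log(0.72),
            "age_per_year": np.log(1.04),
        }
    )
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "mean_cd25_high": 0.14,
            "proximity_significant": 0.18,
        }
    )
    censoring_max_months: float = 120.0
    fraction_death_events: float = 0.25  # RFS events recorded as deaths
    seed: int = 0

    def __post_init__(self):
        if self.p_cd8 + self.p_foxp3 + self.p_tptreg >= 1.0:
            raise ValueError("immune category proportions must leave room for 'other'")
        for name in ("core_diameter_mm", "cell_density_per_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.theta < 0:
            raise ValueError("attraction theta must be >= 0")

    @property
    def proportions(self) -> dict[str, float]:
        return {
            "CD8": self.p_cd8,
            "FOXP3": self.p_foxp3,
            "tpTreg": self.p_tptreg,
            "other": 1.0 - self.p_cd8 - self.p_foxp3 - self.p_tptreg,
        }


def spatial_calibration_config(
    theta: float = 0.0, n_samples: int = 100, seed: int = 0
) -> SyntheticConfig:
    """Standard configuration for spatial-test calibration runs.

    Fixed category counts (so theta = 0 is exactly the permutation null)
    on 1.0 mm cores at 1600 cells/mm2 — a realistic tissue cellularity at
    which cell spacing matches the 20 µm attraction range.  Used for the
    type-I-error and power characterization of the proximity test.
    """
    return SyntheticConfig(
        n_samples=n_samples,
        theta=theta,
        fixed_counts=True,
        cell_density_per_mm2=1600.0,
        seed=seed,
    )


def _rng(config_seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(config_seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# point patterns and labels


def sample_positions(outline: TissueOutline, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform (binomial) points inside the outline, by rejection."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = outline.geometry.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(64, int(1.6 * (n - len(out)) * (maxx - minx) * (maxy - miny)
                        / max(outline.area_um2, 1.0)))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        inside = shapely.contains_xy(outline.geometry, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[inside]])
    return out[:n]


def _weighted_subset(weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling without replacement (Gumbel top-k)."""
    if k == 0:
        return np.empty(0, int)
    gumbel = -np.log(-np.log(rng.uniform(size=len(weights))))
    keys = np.log(weights) + gumbel
    return np.argpartition(-keys, k - 1)[:k]


def assign_labels_with_attraction(
    coords: np.ndarray,
    counts: Mapping[str, int],
    theta: float,
    sigma_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign categories to fixed positions with CD8-Treg attraction.

    CD8 labels are a uniform subset.  Treg labels (tpTreg, then FOXP3) are
    drawn without replacement with weight exp(theta * exp(-d / sigma)),
    where d is the distance to the nearest CD8+ cell; theta = 0 reduces to
    a uniform assignment.  Category counts are preserved exactly.
    """
    n = len(coords)
    total = sum(counts.get(c, 0) for c in ("CD8", "FOXP3", "tpTreg", "other"))
    if total != n:
        raise ValueError(f"category counts sum to {total}, expected {n}")
    labels = np.full(n, "other", dtype=object)
    idx = np.arange(n)
    cd8_idx = rng.choice(idx, size=counts.get("CD8", 0), replace=False)
    labels[cd8_idx] = "CD8"
    remaining = np.setdiff1d(idx, cd8_idx, assume_unique=False)

    if len(cd8_idx) and theta > 0:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(coords[cd8_idx]).query(coords[remaining], k=1)
        weights = np.exp(theta * np.exp(-d / sigma_um))
    else:
        weights = np.ones(len(remaining))

    for cat in ("tpTreg", "FOXP3"):
        k = counts.get(cat, 0)
        pick = _weighted_subset(weights, k, rng)
        labels[remaining[pick]] = cat
        keep = np.setdiff1d(np.arange(len(remaining)), pick, assume_unique=False)
        remaining = remaining[keep]
        weights = weights[keep]
    return labels.astype(str)


# ---------------------------------------------------------------------------
# intensities


def sample_intensities(
    categories: np.ndarray,
    config: SyntheticConfig,
    cd25_sample_effect: float,
    foxp3_sample_effect: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-cell marker intensities given true categories.

    Markers that define a cell's category are drawn from the positive
    component, the rest from the negative background.  Within tp-Tregs the
    CD25 and FOXP3 values share a Gaussian copula with correlation
    ``rho_cell``; the per-sample effects shift the positive log-means of
    CD25 and FOXP3 for the whole sample.
    """
    n = len(categories)
    out = {}
    for marker in MARKERS:
        mu, sd = config.neg_log[marker]
        out[marker] = np.exp(rng.normal(mu, sd, n))

    for cat, markers in CATEGORY_MARKERS.items():
        mask = categories == cat
        m = int(mask.sum())
        if m == 0:
            continue
        if cat == "tpTreg":
            rho = config.rho_cell
            z1 = rng.standard_normal(m)
            z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(m)
            out["CD25"][mask] = np.exp(cd25_sample_effect + config.cd25_cell_log_sd * z1)
            out["FOXP3"][mask] = np.exp(foxp3_sample_effect + config.foxp3_cell_log_sd * z2)
        for marker in markers:
            if cat == "tpTreg" and marker in ("CD25", "FOXP3"):
                continue
            if marker == "FOXP3":  # FOXP3-only Tregs share the sample effect
                out["FOXP3"][mask] = np.exp(
                    foxp3_sample_effect
                    + config.foxp3_cell_log_sd * rng.standard_normal(m)
                )
            else:
                mu, sd = config.pos_log[marker]
                out[marker][mask] = np.exp(rng.normal(mu, sd, m))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# samples


def _sample_effects(config: SyntheticConfig, rng: np.random.Generator):
    """Draw the per-sample random effects (infiltration + intensity)."""
    g = rng.normal(-config.infiltration_sd**2 / 2.0, config.infiltration_sd)
    h = {
        cat: rng.normal(-config.category_sd**2 / 2.0, config.category_sd)
        for cat in ("CD8", "FOXP3", "tpTreg")
    }
    if config.cd25_bimodal is not None:
        delta, p_hi = config.cd25_bimodal
        centre = config.cd25_sample_log_mean + (
            delta / 2.0 if rng.uniform() < p_hi else -delta / 2.0
        )
        a = rng.normal(centre, config.cd25_sample_log_sd)
    else:
        a = rng.normal(config.cd25_sample_log_mean, config.cd25_sample_log_sd)
    b = rng.normal(config.foxp3_sample_log_mean, config.foxp3_sample_log_sd)
    return g, h, a, b


def generate_sample(
    config: SyntheticConfig, index: int, return_truth: bool = False
):
    """One synthetic tissue core; deterministic given (master seed, index)."""
    rng = _rng(config.seed, 11, int(index))
    outline = TissueOutline.disc(config.core_diameter_mm)
    area = outline.area_mm2
    n_expected = config.cell_density_per_mm2 * area

    g, h, a, b = _sample_effects(config, rng)
    props = config.proportions
    if config.fixed_counts:
        n_total = int(round(n_expected))
        counts = {c: int(round(props[c] * n_total)) for c in ("CD8", "FOXP3", "tpTreg")}
    else:
        n_total = int(rng.poisson(n_expected))
        counts = {
            c: int(rng.poisson(props[c] * n_expected * np.exp(g + h[c])))
            for c in ("CD8", "FOXP3", "tpTreg")
        }
        n_immune = sum(counts.values())
        if n_immune > n_total:  # crowded core: keep total cellularity
            n_total = n_immune
    counts["other"] = n_total - sum(counts.values())

    coords = sample_positions(outline, n_total, rng)
    labels = assign_labels_with_attraction(
        coords, counts, config.theta, config.sigma_um, rng
    )
    intensities = sample_intensities(labels, config, a, b, rng)

    # epithelial (cancer) region: central disc holding a Beta-drawn fraction
    f_epi = rng.beta(*config.epithelial_beta)
    radius = config.core_diameter_mm * 1000.0 / 2.0
    r_epi = radius * np.sqrt(f_epi)
    centre = np.array([radius, radius])
    d_centre = np.hypot(*(coords - centre).T)
    region = np.where(d_centre <= r_epi, "epithelial", "stromal")

    cells = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "region": region})
    for m in MARKERS:
        cells[m] = intensities[m].to_numpy()
    table = SampleCellTable(
        sample_id=f"S{index:04d}",
        series_id="2" if index % 2 else "1",
        core_diameter_mm=config.core_diameter_mm,
        cells=cells,
        outline=outline,
    )
    if return_truth:
        return table, pd.Series(labels, name="category")
    return table


def generate_samples(config: SyntheticConfig) -> list[SampleCellTable]:
    return [generate_sample(config, i) for i in range(config.n_samples)]


# ---------------------------------------------------------------------------
# clinical cohort with proportional-hazards survival


def _draw_covariates(config: SyntheticConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    stage = rng.choice(["I", "II", "III", "IV"], n, p=[0.177, 0.390, 0.265, 0.168])
    pT = np.empty(n, object)
    pN = np.empty(n, object)
    for i, s in enumerate(stage):
        if s == "I":
            pT[i] = rng.choice(["1", "2"], p=[0.35, 0.65])
            pN[i] = "0"
        elif s == "II":
            pT[i] = rng.choice(["3", "4"], p=[0.88, 0.12])
            pN[i] = "0"
        else:
            pT[i] = rng.choice(["2", "3", "4"], p=[0.12, 0.74, 0.14])
            pN[i] = rng.choice(["1", "2"], p=[0.65, 0.35]) if s == "III" else rng.choice(
                ["0", "1", "2"], p=[0.25, 0.40, 0.35]
            )
    df = pd.DataFrame(
        {
            "tnm_stage": stage,
            "pT": pT.astype(str),
            "pN": pN.astype(str),
            "age": np.clip(rng.normal(72.0, 11.0, n), 27, 97),
            "sex": rng.choice(["female", "male"], n, p=[0.52, 0.48]),
            "location": rng.choice(
                ["right", "left", "rectum", "synchronous"], n, p=[0.40, 0.31, 0.265, 0.025]
            ),
            "msi": rng.choice(["MSI", "MSS"], n, p=[0.155, 0.845]),
            "braf": rng.choice(["wt", "mut"], n, p=[0.845, 0.155]),
            "kras": rng.choice(["wt", "mut"], n, p=[0.69, 0.31]),
            "r_status": rng.choice(["R0", "R1", "R2"], n, p=[0.80, 0.03, 0.17]),
            "adjuvant_chemo": rng.uniform(size=n) < 0.16,
            "preop_radio": rng.uniform(size=n) < 0.05,
            "synchronous_primary": rng.uniform(size=n) < 0.023,
            "cohort": rng.choice(["1", "2"], n, p=[0.5, 0.5]),
            "ieCD8_high": rng.uniform(size=n) < 0.5,
        }
    )
    df["synchronous_primary"] |= df["location"] == "synchronous"
    for feat, prev in config.prevalence.items():
        df[feat] = rng.uniform(size=n) < prev
    return df


def _linear_predictor(cov: pd.DataFrame, log_hr: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(cov))
    lp += log_hr.get("ieCD8_high", 0.0) * cov["ieCD8_high"].to_numpy(float)
    lp += log_hr.get("mean_cd25_high", 0.0) * cov["mean_cd25_high"].to_numpy(float)
    lp += log_hr.get("proximity_significant", 0.0) * cov[
        "proximity_significant"
    ].to_numpy(float)
    lp += log_hr.get("pT3", 0.0) * (cov["pT"] == "3").to_numpy(float)
    lp += log_hr.get("pT4", 0.0) * (cov["pT"] == "4").to_numpy(float)
    lp += log_hr.get("pN1", 0.0) * (cov["pN"] == "1").to_numpy(float)
    lp += log_hr.get("pN2", 0.0) * (cov["pN"] == "2").to_numpy(float)
    lp += log_hr.get("msi", 0.0) * (cov["msi"] == "MSI").to_numpy(float)
    lp += log_hr.get("age_per_year", 0.0) * (cov["age"].to_numpy(float) - 72.0)
    return lp


def _survival_records(
    cov: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
    patient_ids: Sequence[str],
) -> list[ClinicalRecord]:
    n = len(cov)
    lp = _linear_predictor(cov, config.log_hr)
    base = np.where(
        cov["cohort"].to_numpy() == "2",
        config.baseline_hazard_per_month * config.cohort2_hazard_ratio,
        config.baseline_hazard_per_month,
    )
    t_event = rng.exponential(1.0 / (base * np.exp(lp)))
    c_time = rng.uniform(0.0, config.censoring_max_months, n)
    observed_event = t_event <= c_time
    is_death = rng.uniform(size=n) < config.fraction_death_events

    records = []
    for i in range(n):
        r = cov.iloc[i]
        followup = float(min(c_time[i], config.censoring_max_months))
        relapse = death = None
        if observed_event[i]:
            t = float(max(t_event[i], 0.01))
            followup = max(followup, t)
            if is_death[i]:
                death = t
            else:
                relapse = t
        records.append(
            ClinicalRecord(
                patient_id=str(patient_ids[i]),
                age=float(r["age"]),
                sex=r["sex"],
                tnm_stage=r["tnm_stage"],
                pT=r["pT"],
                pN=r["pN"],
                r_status=r["r_status"],
                location=r["location"],
                msi=r["msi"],
                braf=r["braf"],
                kras=r["kras"],
                adjuvant_chemo=bool(r["adjuvant_chemo"]),
                preop_radio=bool(r["preop_radio"]),
                synchronous_primary=bool(r["synchronous_primary"]),
                followup_months=followup,
                relapse_months=relapse,
                death_months=death,
                cohort=r["cohort"],
            )
        )
    return records


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ClinicalRecord], pd.DataFrame]:
    """Clinical cohort under proportional hazards.

    Immune features (intraepithelial-CD8 High, mean-CD25 class High,
    CD8-tp-Treg proximity) are drawn at their configured prevalences and
    tied to the hazard through the configured log-HRs; the event process is
    an exponential baseline (per cohort) with uniform censoring.  Returns
    the clinical records plus the per-patient feature frame (the features
    are what a full image-pipeline run would have produced per sample).
    """
    rng = _rng(config.seed, 77)
    n = config.n_patients
    cov = _draw_covariates(config, n, rng)
    ids = [f"P{i:04d}" for i in range(n)]
    records = _survival_records(cov, config, rng, ids)
    features = cov[
        ["ieCD8_high", "mean_cd25_high", "proximity_significant", "pT", "pN",
         "msi", "age", "cohort"]
    ].copy()
    features.insert(0, "patient_id", ids)
    return records, features


def attach_survival(
    features: pd.DataFrame, config: SyntheticConfig
) -> list[ClinicalRecord]:
    """Survival outcomes for externally computed per-sample features.

    ``features`` must carry ``patient_id`` plus any of the immune feature
    columns (``ieCD8_high``, ``mean_cd25_high``, ``proximity_significant``);
    the remaining covariates are drawn from the configured marginals and the
    same proportional-hazards event process as :func:`generate_cohort` is
    applied.  Used to chain the image pipeline's outputs into the survival
    stage on fully synthetic runs.
    """
    rng = _rng(config.seed, 78)
    n = len(features)
    cov = _draw_covariates(config, n, rng)
    for col in ("ieCD8_high", "mean_cd25_high", "proximity_significant"):
        if col in features.columns:
            cov[col] = np.asarray(features[col], bool)
    return _survival_records(cov, config, rng, list(features["patient_id"]))
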