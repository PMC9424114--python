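"""Per-cell marker scoring and per-sample immunophenotyping.

Cells are called positive/negative per marker by thresholding the mean
fluorescence intensity (closed threshold: intensity >= tau is positive).
Each cell is then placed into exactly one of four categories — CD8+,
FOXP3+, triple-positive Treg (CD4+/CD25+/FOXP3+), or other — with the
precedence tpTreg > FOXP3 > CD8 > other for the rare co-positive cells.

Per-sample infiltration is scored as positive cells per mm2 of tissue and
analysed as log2(density + 1), since infiltration densities are heavily
right-skewed and samples with zero positive cells must be retained.

Triple-positive Tregs are profiled into a 2x2 of CD25 {High, Low} x
FOXP3 {High, Low} using the nearest-rank 75th percentile of the (scoped)
positive-cell intensities as the threshold for both markers, with High
meaning strictly above the threshold.  Per-sample mean CD25 across
tp-Tregs is dichotomized High/Low by a per-series cutoff; samples with no
tp-Tregs form a separate Negative class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import kde_valley_cutoff, nearest_rank_percentile
from .io import SampleCellTable

log = logging.getLogger("tregspatial")

CATEGORIES = ("CD8", "FOXP3", "tpTreg", "other")


# ---------------------------------------------------------------------------
# thresholds


@dataclass(frozen=True)
class MarkerThresholds:
    """Positivity thresholds keyed by (series_id, marker).

    Thresholds are set per stain and patient series; they are required
    inputs — the optional :func:`suggest_threshold` helper proposes a value
    from the intensity distribution but is never applied silently.
    """

    values: Mapping[tuple[str, str], float]

    def get(self, series_id: str, marker: str) -> float:
        key = (str(series_id), marker)
        if key in self.values:
            tau = self.values[key]
        elif ("*", marker) in self.values:
            tau = self.values[("*", marker)]
        else:
            raise KeyError(
                f"no positivity threshold for marker '{marker}' in series '{series_id}'"
            )
        if tau < 0:
            raise ValueError(f"threshold for {marker} must be >= 0, got {tau}")
        return float(tau)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "MarkerThresholds":
        """Build from a nested mapping ``{series: {marker: tau}}`` or
        ``{series: {stain: {marker: tau}}}`` (the stain level is flattened)."""
        flat = {}
        for series, entry in mapping.items():
            for k, v in entry.items():
                if isinstance(v, Mapping):  # stain level
                    for marker, tau in v.items():
                        flat[(str(series), marker)] = float(tau)
                else:
                    flat[(str(series), k)] = float(v)
        return cls(flat)


def suggest_threshold(intensities) -> float:
    """Propose a positivity threshold at the density valley between the
    negative and positive intensity components (log scale)."""
    arr = np.asarray(intensities, float)
    arr = arr[arr > 0]
    return float(np.exp(kde_valley_cutoff(np.log(arr))))


# ---------------------------------------------------------------------------
# positivity and categories


def call_positivity(
    table: SampleCellTable, thresholds: MarkerThresholds
) -> pd.DataFrame:
    """Boolean positive/negative call per marker (intensity >= tau).

    Every marker column in the table must have a threshold for the table's
    series; per-marker positive counts are logged.
    """
    calls = {}
    for marker in table.markers:
        tau = thresholds.get(table.series_id, marker)
        calls[marker] = table.intensity(marker) >= tau
    out = pd.DataFrame(calls, index=table.cells.index)
    for marker in out.columns:
        log.debug(
            "sample %s: %d/%d %s+ cells",
            table.sample_id, int(out[marker].sum()), len(out), marker,
        )
    return out


def assign_category(calls: pd.DataFrame) -> pd.Series:
    """One mutually exclusive category per cell: CD8 / FOXP3 / tpTreg / other.

    Precedence for co-positive cells is tpTreg > FOXP3 > CD8 > other; the
    number of precedence conflicts (cells positive both for CD8 and for a
    Treg phenotype) is logged.
    """
    for m in ("CD4", "CD25", "FOXP3", "CD8"):
        if m not in calls.columns:
            raise ValueError(f"category assignment requires a call for '{m}'")
    cd4 = calls["CD4"].to_numpy(bool)
    cd25 = calls["CD25"].to_numpy(bool)
    foxp3 = calls["FOXP3"].to_numpy(bool)
    cd8 = calls["CD8"].to_numpy(bool)

    tp = cd4 & cd25 & foxp3
    cat = np.where(tp, "tpTreg", np.where(foxp3, "FOXP3", np.where(cd8, "CD8", "other")))
    n_conflict = int(np.sum(cd8 & (tp | foxp3)))
    if n_conflict:
        log.debug("%d cells positive for CD8 and a Treg phenotype (precedence applied)",
                  n_conflict)
    return pd.Series(pd.Categorical(cat, categories=CATEGORIES), index=calls.index,
                     name="category")


# ---------------------------------------------------------------------------
# densities


@dataclass(frozen=True)
class InfiltrationScore:
    sample_id: str
    target: str
    compartment: str  # whole / intraepithelial / stromal
    n_pos: int
    area_mm2: float
    density: float  # cells per mm2
    log2_density: float  # log2(density + 1)


def infiltration_density(
    table: SampleCellTable,
    positive: np.ndarray | pd.Series,
    target: str,
    compartment: str = "whole",
    area_mm2: float | None = None,
    compartment_areas_mm2: Mapping[str, float] | None = None,
) -> InfiltrationScore:
    """Infiltration score: positive cells per mm2, with log2(x + 1).

    ``positive`` is a per-cell boolean vector (a marker call column or a
    category indicator).  Area for the whole core comes from the outline
    (or ``area_mm2``); compartment scores need region labels and the
    compartment area from the tissue segmentation.
    """
    pos = np.asarray(positive, bool)
    if pos.shape[0] != table.n_cells:
        raise ValueError("positive vector length does not match cell count")

    if compartment == "whole":
        area = area_mm2
        if area is None and table.outline is not None:
            area = table.outline.area_mm2
        mask = np.ones(table.n_cells, bool)
    elif compartment in ("intraepithelial", "stromal"):
        region = "epithelial" if compartment == "intraepithelial" else "stromal"
        regions = table.cells["region"].to_numpy()
        if (regions == "unassigned").all():
            raise ValueError(
                f"compartment '{compartment}' requested but sample "
                f"{table.sample_id} has no region labels"
            )
        mask = regions == region
        area = None if compartment_areas_mm2 is None else compartment_areas_mm2.get(compartment)
    else:
        raise ValueError(f"unknown compartment '{compartment}'")

    if area is None or area <= 0:
        raise ValueError(
            f"no positive tissue area available for compartment '{compartment}' "
            f"of sample {table.sample_id}"
        )
    n_pos = int(np.sum(pos & mask))
    density = n_pos / area
    return InfiltrationScore(
        sample_id=table.sample_id,
        target=target,
        compartment=compartment,
        n_pos=n_pos,
        area_mm2=float(area),
        density=float(density),
        log2_density=float(np.log2(density + 1.0)),
    )


def cancer_fractions(
    table: SampleCellTable,
    epithelial_area_mm2: float | None = None,
    total_area_mm2: float | None = None,
) -> tuple[float, float | None]:
    """Cancer cell fraction and (when areas are known) cancer area fraction.

    Cell fraction = cells in the epithelial (cancer) region / all cells;
    area fraction = epithelial region area / total tissue area.
    """
    if table.n_cells == 0:
        raise ValueError(f"sample {table.sample_id} has no cells")
    regions = table.cells["region"].to_numpy()
    cell_fraction = float(np.mean(regions == "epithelial"))
    area_fraction = None
    if epithelial_area_mm2 is not None and total_area_mm2 is not None:
        if total_area_mm2 <= 0:
            raise ValueError("total area must be positive")
        area_fraction = float(epithelial_area_mm2 / total_area_mm2)
    return cell_fraction, area_fraction


def dichotomize(scores, cutoff="median") -> tuple[pd.Series, float]:
    """High/Low labels on per-sample scores (High iff score > cutoff).

    With ``cutoff="median"`` the cutoff is the median of the scores
    themselves (>= 2 samples required); boundary values fall Low.
    Returns (labels, cutoff value).
    """
    s = pd.Series(scores, dtype=float)
    if isinstance(cutoff, str):
        if cutoff != "median":
            raise ValueError(f"unknown cutoff mode '{cutoff}'")
        if len(s) < 2:
            raise ValueError("median dichotomization needs at least 2 samples")
        cut = float(np.median(s.to_numpy()))
    else:
        cut = float(cutoff)
    labels = pd.Series(np.where(s.to_numpy() > cut, "High", "Low"), index=s.index)
    if (labels == "Low").all():
        log.warning("dichotomize: all %d scores fell Low (cutoff %.6g)", len(s), cut)
    return labels, cut


# ---------------------------------------------------------------------------
# Treg profiling


@dataclass
class TregProfile:
    """Per-sample triple-positive Treg summary."""

    sample_id: str
    series_id: str
    n_tpTreg: int
    counts: dict = field(default_factory=dict)  # keys HH, HL, LH, LL (CD25 first)
    cd25_threshold: float | None = None
    foxp3_threshold: float | None = None
    mean_cd25: float | None = None
    mean_foxp3: float | None = None
    mean_cd25_class: str | None = None  # High / Low / Negative


def treg_subgroup_profile(
    tables: Sequence[SampleCellTable],
    categories: Mapping[str, pd.Series],
    scope: str = "pooled",
) -> tuple[list[TregProfile], dict]:
    """Profile triple-positive Tregs per sample.

    The CD25 and FOXP3 High/Low thresholds are the nearest-rank 75th
    percentiles of the positive (tp-Treg) cell intensities, computed either
    pooled per series (default) or per sample; High means strictly above
    the threshold.  Returns per-sample profiles and cohort-level summary
    including the pooled fraction of CD25-High/FOXP3-High cells.
    """
    if scope not in ("pooled", "per-sample"):
        raise ValueError(f"unknown scope '{scope}'")

    per_sample = {}
    for t in tables:
        cat = categories[t.sample_id]
        tp = np.asarray(cat == "tpTreg", bool)
        per_sample[t.sample_id] = (
            t, t.intensity("CD25")[tp], t.intensity("FOXP3")[tp]
        )

    pooled_thresholds = {}
    if scope == "pooled":
        by_series: dict[str, list] = {}
        for t, cd25, foxp3 in per_sample.values():
            by_series.setdefault(t.series_id, []).append((cd25, foxp3))
        for series, chunks in by_series.items():
            cd25_all = np.concatenate([c for c, _ in chunks])
            foxp3_all = np.concatenate([f for _, f in chunks])
            if cd25_all.size == 0:
                pooled_thresholds[series] = (None, None)
            else:
                pooled_thresholds[series] = (
                    nearest_rank_percentile(cd25_all, 0.75),
                    nearest_rank_percentile(foxp3_all, 0.75),
                )

    profiles = []
    n_hh = 0
    n_total = 0
    for t, cd25, foxp3 in per_sample.values():
        n = cd25.size
        prof = TregProfile(sample_id=t.sample_id, series_id=t.series_id, n_tpTreg=n)
        if n == 0:
            prof.counts = {"HH": 0, "HL": 0, "LH": 0, "LL": 0}
            prof.mean_cd25_class = "Negative"
        else:
            if scope == "pooled":
                tau25, taufx = pooled_thresholds[t.series_id]
            else:
                tau25 = nearest_rank_percentile(cd25, 0.75)
                taufx = nearest_rank_percentile(foxp3, 0.75)
            hi25 = cd25 > tau25
            hifx = foxp3 > taufx
            prof.cd25_threshold = tau25
            prof.foxp3_threshold = taufx
            prof.counts = {
                "HH": int(np.sum(hi25 & hifx)),
                "HL": int(np.sum(hi25 & ~hifx)),
                "LH": int(np.sum(~hi25 & hifx)),
                "LL": int(np.sum(~hi25 & ~hifx)),
            }
            prof.mean_cd25 = float(cd25.mean())
            prof.mean_foxp3 = float(foxp3.mean())
            n_hh += prof.counts["HH"]
            n_total += n
        profiles.append(prof)

    summary = {
        "n_tpTreg_total": n_total,
        "high_high_fraction": (n_hh / n_total) if n_total else float("nan"),
        "scope": scope,
    }
    return profiles, summary


def classify_mean_cd25(
    profiles: Sequence[TregProfile],
    cutoff="auto",
    min_samples_auto: int = 30,
) -> dict[str, float]:
    """Assign the per-sample mean-CD25 class: High / Low / Negative.

    Samples with no tp-Tregs are Negative.  The High/Low cutoff is set per
    series, either explicitly or (``"auto"``) at the deepest density-valley
    between the two largest modes of the per-sample mean-CD25 distribution
    (Gaussian KDE, Silverman bandwidth); the chosen cutoff is returned per
    series for manual confirmation.  ``"auto"`` on a unimodal distribution
    raises, instructing a manual cutoff.
    """
    by_series: dict[str, list[TregProfile]] = {}
    for p in profiles:
        by_series.setdefault(p.series_id, []).append(p)

    cutoffs: dict[str, float] = {}
    for series, profs in by_series.items():
        means = np.array([p.mean_cd25 for p in profs if p.n_tpTreg > 0], float)
        if isinstance(cutoff, str) and cutoff == "auto":
            if means.size < min_samples_auto:
                raise ValueError(
                    f"series {series}: automatic cutoff needs >= {min_samples_auto} "
                    f"samples with tp-Tregs, got {means.size}"
                )
            cut = kde_valley_cutoff(means, min_n=min_samples_auto)
        elif isinstance(cutoff, Mapping):
            cut = float(cutoff[series])
        else:
            cut = float(cutoff)
        cutoffs[series] = cut
        for p in profs:
            if p.n_tpTreg == 0:
                p.mean_cd25_class = "Negative"
            else:
                p.mean_cd25_class = "High" if p.mean_cd25 > cut else "Low"
        log.info("series %s: mean-CD25 cutoff %.4g", series, cut)
    return cutoffs


def profiles_to_frame(profiles: Sequence[TregProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "sample_id": p.sample_id,
                "series_id": p.series_id,
                "n_tpTreg": p.n_tpTreg,
                "n_HH": p.counts.get("HH", 0),
                "n_HL": p.counts.get("HL", 0),
                "n_LH": p.counts.get("LH", 0),
                "n_LL": p.counts.get("LL", 0),
                "cd25_threshold": p.cd25_threshold,
                "foxp3_threshold": p.foxp3_threshold,
                "mean_cd25": p.mean_cd25,
                "mean_foxp3": p.mean_foxp3,
                "mean_cd25_class": p.mean_cd25_class,
            }
        )
    return pd.DataFrame(rows)
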