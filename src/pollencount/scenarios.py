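"""Scenario grid, correlation against manual counts, and group summaries.

A *scenario* is a named pair of particle filters (size window in pixel^2,
circularity window) — one for the red channel (total pollen), one for the
green channel (viable pollen).  The catalog holds the original parameter set
S0 (asymmetric size windows: red 60-800, green 100-800, circularity 0.4-1
for both) and the 2x3 optimization grid S1-S6 crossing size windows
{100-900, 200-900} with circularity windows {0.4-1, 0.5-1, 0.6-1}, applied
identically to both channels.

Scenario evaluation correlates automatic counts with manual (or synthetic
ground-truth) counts per scenario: the Pearson r over total counts and over
percent-viability values, with two-sided p-values.  The best scenario
maximizes r over counts, tie-broken by r over viability, then by name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import ParticleFilter, RgbImage, ScenarioSpec
from .pipeline import (
    ImageCountResult,
    PipelineConfig,
    filter_particles,
    measure_channels,
    percent_viability,
)

__all__ = [
    "ManualCount",
    "ScenarioEvaluation",
    "UndefinedCorrelationError",
    "scenario_catalog",
    "run_scenarios",
    "pearson_correlation",
    "evaluate_scenarios",
    "select_best_scenario",
    "summarize_by_group",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on degenerate input."""


@dataclass(frozen=True)
class ManualCount:
    """Human tally of one micrograph: all grains and the dark-blue (viable) ones."""

    image_id: str
    manual_total: int
    manual_viable: int

    def __post_init__(self) -> None:
        if self.manual_total < 0 or self.manual_viable < 0:
            raise ValueError("manual counts must be non-negative")
        if self.manual_viable > self.manual_total:
            raise ValueError(
                f"{self.image_id}: manual_viable ({self.manual_viable}) exceeds "
                f"manual_total ({self.manual_total})"
            )

    @property
    def manual_pv(self) -> float | None:
        return percent_viability(self.manual_viable, self.manual_total)


@dataclass(frozen=True)
class ScenarioEvaluation:
    """Agreement of one scenario's automatic counts with manual counts.

    r_count / r_viability are Pearson correlations over per-image (automatic,
    manual) pairs of total counts and of PV values; NaN when fewer than 3
    usable pairs or zero variance.  n_excluded_viability counts images
    dropped pairwise from the viability correlation for undefined automatic
    PV.
    """

    scenario_name: str
    r_count: float
    p_count: float
    r_viability: float
    p_viability: float
    n_images: int
    n_excluded_viability: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r_count)


def scenario_catalog() -> list[ScenarioSpec]:
    """The seven catalogued scenarios: original S0 plus the S1-S6 grid."""
    circ_04 = (0.4, 1.0)
    catalog = [
        ScenarioSpec(
            "S0",
            red_filter=ParticleFilter(60, 800, *circ_04),
            green_filter=ParticleFilter(100, 800, *circ_04),
        )
    ]
    sizes = [(100, 900), (200, 900)]
    circs = [(0.4, 1.0), (0.5, 1.0), (0.6, 1.0)]
    # S1/S2 share circularity 0.4-1, S3/S4 0.5-1, S5/S6 0.6-1; odd numbers
    # take the wide size window, even numbers the narrow one.
    idx = 1
    for circ in circs:
        for size in sizes:
            f = ParticleFilter(*size, *circ)
            catalog.append(ScenarioSpec(f"S{idx}", red_filter=f, green_filter=f))
            idx += 1
    return catalog


def run_scenarios(
    images: list[RgbImage],
    scenarios: list[ScenarioSpec],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Count every image under every scenario.

    Returns a DataFrame with one row per (image, scenario): columns
    image_id, scenario_name, total_count, viable_count, viability_pct
    (NaN when undefined), over_100, error (empty string on success).
    Failures on individual images are recorded in the error column; the
    batch continues.

    The heavy pipeline stages are scenario-independent, so each image is
    segmented and measured once and every scenario merely re-filters the
    measured particles; results are identical to running the full chain per
    pair.
    """
    if not images:
        raise ValueError("no images to process")
    config = config or PipelineConfig()
    rows = []
    for image in images:
        try:
            red_particles, green_particles = measure_channels(image, config)
        except Exception as exc:  # record, keep processing the batch
            for sc in scenarios:
                rows.append(
                    {
                        "image_id": image.id,
                        "scenario_name": sc.name,
                        "total_count": np.nan,
                        "viable_count": np.nan,
                        "viability_pct": np.nan,
                        "over_100": False,
                        "error": str(exc),
                    }
                )
            continue
        for sc in scenarios:
            total = len(filter_particles(red_particles, sc.red_filter))
            viable = len(filter_particles(green_particles, sc.green_filter))
            pv = percent_viability(viable, total) if total > 0 else None
            rows.append(
                {
                    "image_id": image.id,
                    "scenario_name": sc.name,
                    "total_count": total,
                    "viable_count": viable,
                    "viability_pct": np.nan if pv is None else pv,
                    "over_100": bool(pv is not None and pv > 100.0),
                    "error": "",
                }
            )
    columns = [
        "image_id",
        "scenario_name",
        "total_count",
        "viable_count",
        "viability_pct",
        "over_100",
        "error",
    ]
    return pd.DataFrame(rows, columns=columns)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment r with a two-sided p-value (t-transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise UndefinedCorrelationError(
            f"need at least 3 pairs for a defined correlation, got {len(x)}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def evaluate_scenarios(
    results: pd.DataFrame,
    manual: list[ManualCount],
    include_over_100: bool = True,
) -> list[ScenarioEvaluation]:
    """Correlate automatic counts and viability with manual counts per scenario.

    Every image in ``results`` needs a manual count.  Images with undefined
    automatic PV (no pollen detected) are excluded pairwise from the
    viability correlation and tallied in n_excluded_viability; setting
    ``include_over_100`` to False additionally excludes images whose
    automatic PV exceeds 100%.  A scenario with fewer than 3 usable pairs or
    degenerate variance gets NaN correlations (flagged undefined).
    """
    by_id = {m.image_id: m for m in manual}
    missing = set(results["image_id"]) - set(by_id)
    if missing:
        raise ValueError(f"no manual counts for images: {sorted(missing)}")

    evaluations = []
    for name, group in results.groupby("scenario_name", sort=True):
        ok = group[group["error"] == ""]
        auto_total = ok["total_count"].to_numpy(dtype=float)
        man_total = np.array([by_id[i].manual_total for i in ok["image_id"]], float)

        viab = ok[ok["viability_pct"].notna()]
        if not include_over_100:
            viab = viab[~viab["over_100"]]
        n_excl = len(ok) - len(viab)
        auto_pv = viab["viability_pct"].to_numpy(dtype=float)
        man_pv = np.array(
            [by_id[i].manual_pv for i in viab["image_id"]], dtype=float
        )

        def _safe(x, y):
            try:
                return pearson_correlation(x, y)
            except UndefinedCorrelationError:
                return (float("nan"), float("nan"))

        r_c, p_c = _safe(auto_total, man_total)
        r_v, p_v = _safe(auto_pv, man_pv)
        evaluations.append(
            ScenarioEvaluation(
                scenario_name=str(name),
                r_count=r_c,
                p_count=p_c,
                r_viability=r_v,
                p_viability=p_v,
                n_images=len(ok),
                n_excluded_viability=n_excl,
            )
        )
    return evaluations


def select_best_scenario(evaluations: list[ScenarioEvaluation]) -> str:
    """Scenario with the highest count correlation.

    Ties break on the viability correlation, then on the scenario name
    (lexicographic) — correlating the raw counts is the primary evidence
    that the filter windows capture the grains, viability agreement is the
    secondary criterion, and the name gives a deterministic last resort.
    """
    defined = [e for e in evaluations if e.defined]
    if not defined:
        raise ValueError("no scenario has a defined evaluation")

    def key(e: ScenarioEvaluation):
        r_v = e.r_viability if not math.isnan(e.r_viability) else -np.inf
        return (-e.r_count, -r_v, e.scenario_name)

    return min(defined, key=key).scenario_name


def summarize_by_group(
    results: list[ImageCountResult] | pd.DataFrame,
    groups: dict[str, str],
) -> pd.DataFrame:
    """Per-group descriptive statistics of total count and viability.

    ``groups`` maps image_id to a group label (e.g. genotype).  Returns one
    row per group with n, mean, sd (sample, n-1), min and max of the total
    count and of PV; images with undefined PV are excluded from the PV
    statistics and counted in n_excluded_pv.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(
            {
                "image_id": [r.image_id for r in results],
                "total_count": [r.total_count for r in results],
                "viability_pct": [
                    np.nan if r.viability_pct is None else r.viability_pct
                    for r in results
                ],
            }
        )
    unmapped = set(df["image_id"]) - set(groups)
    if unmapped:
        raise ValueError(f"images not mapped to any group: {sorted(unmapped)}")
    df["group"] = df["image_id"].map(groups)

    rows = []
    for label in sorted(set(groups.values())):
        sub = df[df["group"] == label]
        pv = sub["viability_pct"].dropna()
        tc = sub["total_count"]
        rows.append(
            {
                "group": label,
                "n": len(sub),
                "total_mean": tc.mean() if len(sub) else np.nan,
                "total_sd": tc.std(ddof=1) if len(sub) > 1 else np.nan,
                "total_min": tc.min() if len(sub) else np.nan,
                "total_max": tc.max() if len(sub) else np.nan,
                "pv_mean": pv.mean() if len(pv) else np.nan,
                "pv_sd": pv.std(ddof=1) if len(pv) > 1 else np.nan,
                "pv_min": pv.min() if len(pv) else np.nan,
                "pv_max": pv.max() if len(pv) else np.nan,
                "n_excluded_pv": int(sub["viability_pct"].isna().sum()),
            }
        )
    return pd.DataFrame(rows)
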