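"""Image loading, batch processing and CSV export.

The results CSV mirrors the measurement table a slide-scanning session
produces: one row per image with the total count, viable count and percent
viability under the scenario used.  The dialect is fixed (comma-separated,
UTF-8, header row, '.' decimal separator, PV to 2 decimals, undefined PV as
an empty field) so reruns are byte-identical and spreadsheets import it
unambiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .imaging import ParticleFilter, RgbImage, ScenarioSpec
from .pipeline import ImageCountResult, PipelineConfig, process_image
from .scenarios import (
    ManualCount,
    ScenarioEvaluation,
    evaluate_scenarios,
    run_scenarios,
    scenario_catalog,
)

__all__ = [
    "ImageReadError",
    "RunConfig",
    "read_image",
    "discover_images",
    "resolve_scenario",
    "write_results_csv",
    "read_results_csv",
    "read_manual_csv",
    "read_groups_csv",
    "write_evaluations_csv",
    "batch_process",
]

logger = logging.getLogger("pollencount")

IMAGE_PATTERNS = ("*.png", "*.tif", "*.tiff", "*.jpg", "*.jpeg")

RESULT_COLUMNS = (
    "image_id",
    "total_count",
    "viable_count",
    "viability_pct",
    "scenario_name",
    "error",
)


class ImageReadError(IOError):
    """Raised when an input image cannot be read or is not 8-bit RGB."""


def read_image(path: str | Path) -> RgbImage:
    """Load one 8-bit RGB micrograph (TIFF/PNG/JPEG); id = file name."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageReadError(f"{path.name}: cannot read image ({exc})") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageReadError(
            f"{path.name}: expected an RGB image, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise ImageReadError(f"{path.name}: expected 8-bit channels, got {arr.dtype}")
    return RgbImage(arr, id=path.name)


def discover_images(path: str | Path) -> list[Path]:
    """Image files under a directory (or the single given file), sorted by name."""
    path = Path(path)
    if path.is_file():
        return [path]
    files = {p for pat in IMAGE_PATTERNS for p in path.glob(pat)}
    files |= {p for pat in IMAGE_PATTERNS for p in path.glob(pat.upper())}
    return sorted(files, key=lambda p: p.name)


def resolve_scenario(
    name: str | None = None,
    size_min: float | None = None,
    size_max: float | None = None,
    circ_min: float | None = None,
    circ_max: float | None = None,
) -> ScenarioSpec:
    """Look a scenario up by name, or build one from explicit bounds.

    Explicit bounds define a custom scenario applied identically to both
    channels; all four bounds must then be given.
    """
    if name is not None:
        for sc in scenario_catalog():
            if sc.name == name:
                return sc
        raise ValueError(
            f"unknown scenario {name!r}; catalogued: "
            f"{[s.name for s in scenario_catalog()]}"
        )
    bounds = (size_min, size_max, circ_min, circ_max)
    if any(b is None for b in bounds):
        raise ValueError(
            "either a scenario name or all of size_min/size_max/circ_min/circ_max"
        )
    f = ParticleFilter(size_min, size_max, circ_min, circ_max)
    return ScenarioSpec(
        f"custom({size_min:g}-{size_max:g}; {circ_min:g}-{circ_max:g})",
        red_filter=f,
        green_filter=f,
    )


def _format_row(r: ImageCountResult, error: str = "") -> str:
    pv = "" if r.viability_pct is None else f"{r.viability_pct:.2f}"
    return f"{r.image_id},{r.total_count},{r.viable_count},{pv},{r.scenario_name},{error}"


def write_results_csv(
    results: list[ImageCountResult],
    path: str | Path,
    errors: dict[str, str] | None = None,
    overwrite: bool = False,
) -> None:
    """Write the fixed-dialect results table; refuses to clobber by default."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    errors = errors or {}
    lines = [",".join(RESULT_COLUMNS)]
    lines += [_format_row(r, errors.get(r.image_id, "")) for r in results]
    for image_id, msg in errors.items():
        if not any(r.image_id == image_id for r in results):
            lines.append(f"{image_id},,,,,{_sanitize(msg)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _sanitize(msg: str) -> str:
    return msg.replace(",", ";").replace("\n", " ")


def read_results_csv(path: str | Path) -> list[ImageCountResult]:
    """Parse a results CSV back into records (error rows are skipped)."""
    df = pd.read_csv(path, dtype={"image_id": str, "scenario_name": str})
    out = []
    for _, row in df.iterrows():
        if isinstance(row.get("error"), str) and row["error"]:
            continue
        if pd.isna(row["total_count"]):
            continue
        pv = None if pd.isna(row["viability_pct"]) else float(row["viability_pct"])
        out.append(
            ImageCountResult(
                image_id=row["image_id"],
                total_count=int(row["total_count"]),
                viable_count=int(row["viable_count"]),
                viability_pct=pv,
                over_100=bool(pv is not None and pv > 100.0),
                scenario_name=row["scenario_name"],
            )
        )
    return out


def read_manual_csv(path: str | Path) -> list[ManualCount]:
    """Manual counts: CSV with header image_id, manual_total, manual_viable."""
    df = pd.read_csv(path, dtype={"image_id": str})
    required = {"image_id", "manual_total", "manual_viable"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: manual-count CSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return [
        ManualCount(row.image_id, int(row.manual_total), int(row.manual_viable))
        for row in df.itertuples()
    ]


def read_groups_csv(path: str | Path) -> dict[str, str]:
    """Group map: CSV with header image_id, group."""
    df = pd.read_csv(path, dtype=str)
    if not {"image_id", "group"}.issubset(df.columns):
        raise ValueError(f"{path}: group CSV needs columns image_id, group")
    return dict(zip(df["image_id"], df["group"]))


def write_evaluations_csv(
    evaluations: list[ScenarioEvaluation], path: str | Path, overwrite: bool = False
) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    lines = [
        "scenario_name,r_count,p_count,r_viability,p_viability,n_images,n_excluded_viability"
    ]
    for e in evaluations:
        lines.append(
            f"{e.scenario_name},{e.r_count:.6f},{e.p_count:.3e},"
            f"{e.r_viability:.6f},{e.p_viability:.3e},{e.n_images},"
            f"{e.n_excluded_viability}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class RunConfig:
    """One batch run: where the images are, how to count, where results go."""

    input_path: str | Path
    scenario: ScenarioSpec
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    output_csv: str | Path = "results.csv"
    manual_csv: str | Path | None = None
    evaluation_csv: str | Path | None = None
    overwrite: bool = False


def batch_process(
    config: RunConfig,
) -> tuple[list[ImageCountResult], list[ScenarioEvaluation] | None]:
    """Process every image under the input path and write the results CSV.

    Unreadable or failing images are logged and recorded with an error flag;
    the run continues and exits successfully as long as at least one image
    was readable.  When a manual-count CSV is configured, the full scenario
    catalog is additionally swept over the readable images and the
    per-scenario correlations are written to the evaluation CSV.
    """
    paths = discover_images(config.input_path)
    if not paths:
        raise FileNotFoundError(f"no images found under {config.input_path}")

    results: list[ImageCountResult] = []
    errors: dict[str, str] = {}
    images: list[RgbImage] = []
    for p in paths:
        try:
            img = read_image(p)
            results.append(process_image(img, config.scenario, config.pipeline))
            images.append(img)
            logger.info("processed %s", p.name)
        except Exception as exc:
            errors[p.name] = str(exc)
            logger.warning("failed on %s: %s", p.name, exc)
    if not results:
        raise ImageReadError(f"no readable images under {config.input_path}")
    write_results_csv(results, config.output_csv, errors, config.overwrite)

    evaluations = None
    if config.manual_csv is not None:
        manual = read_manual_csv(config.manual_csv)
        table = run_scenarios(images, scenario_catalog(), config.pipeline)
        evaluations = evaluate_scenarios(table, manual)
        eval_path = config.evaluation_csv or (
            Path(config.output_csv).with_name(
                Path(config.output_csv).stem + "_evaluation.csv"
            )
        )
        write_evaluations_csv(evaluations, eval_path, config.overwrite)
    return results, evaluations
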