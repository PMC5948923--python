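"""Experiment orchestration: the trueness replication, the segmentation
method-effect comparison, and the interlaboratory precision replication.

Each experiment is fully determined by a design dataclass plus one integer
seed; reruns are bit-reproducible. The module also bundles the reference
interlaboratory precision table (12 broad-leaved tree entities, three canopy
classes × four LAI levels, 4 laboratories × 4 replicates after screening)
from which the headline stratified aggregates can be recomputed without any
simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from canopylai.agreement import PairedComparison, TruenessResult, paired_t, trueness_metrics
from canopylai.imaging import (
    GrayscaleImage,
    SegmentationConfig,
    auto_threshold,
    cover_to_lai,
    measure_cover,
    segment,
)
from canopylai.precision import (
    InterlabPrecision,
    InterlabPrecisionResults,
    PrecisionResult,
    Stratum,
    StratumSummary,
    stratify_summaries,
)
from canopylai.synthetic import (
    AcquisitionModel,
    BinaryScene,
    EstimateMatrix,
    SceneSpec,
    VarianceComponents,
    generate_boolean_scene,
    render_acquisition,
    simulate_estimate_matrix,
    simulate_user_thresholds,
)

__all__ = [
    "TruenessDesign",
    "PrecisionDesign",
    "StudyConfig",
    "TruenessExperimentResult",
    "MethodEffectResult",
    "PrecisionExperimentResult",
    "run_trueness_experiment",
    "run_method_effect_experiment",
    "run_precision_experiment",
    "load_reference_precision_table",
    "reference_precision_results",
    "DEFAULT_STRATA",
]

_MAX_SEED = 2**31 - 1

#: Strata used for the headline aggregates: overall, the three LAI ranges
#: (high > 5, intermediate 2.5–4, low < 1.5; bounds strict) and the three
#: canopy classes.
DEFAULT_STRATA = [
    Stratum("overall"),
    Stratum("high_lai", lai_gt=5.0),
    Stratum("intermediate_lai", lai_gt=2.5, lai_lt=4.0),
    Stratum("low_lai", lai_lt=1.5),
    Stratum("sparse_or_continuous_high_scaffold",
            canopy_class="sparse_or_continuous_high_scaffold"),
    Stratum("plantation_row_low_scaffold",
            canopy_class="plantation_row_low_scaffold"),
    Stratum("sparse_medium_scaffold", canopy_class="sparse_medium_scaffold"),
]


def load_reference_precision_table() -> pd.DataFrame:
    """The bundled 12-entity reference precision table (printed values)."""
    with resources.files("canopylai.data").joinpath(
        "reference_precision_table.csv"
    ).open("r") as fh:
        return pd.read_csv(fh, keep_default_na=False)


def reference_precision_results() -> list[PrecisionResult]:
    """Reference table rows as :class:`PrecisionResult` objects.

    Standard deviations are reconstructed from the printed means and
    relative standard deviations (``S = mean·RSD/100``).
    """
    df = load_reference_precision_table()
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PrecisionResult(
                entity_id=row.entity_id,
                mean_estimate=row.mean_lai,
                S_r=row.mean_lai * row.rsd_r / 100.0,
                S_R=row.mean_lai * row.rsd_R / 100.0,
                r=row.r,
                R=row.R,
                RSD_r=row.rsd_r,
                RSD_R=row.rsd_R,
                labs_used=int(row.labs_used),
                canopy_class=row.canopy_class,
            )
        )
    return out


# ---------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class TruenessDesign:
    """The artificial-canopy trueness experiment.

    14 cover levels evenly spaced over [0.30, 0.85], one Boolean scene per
    level, four replicate grayscale acquisitions per scene under the default
    acquisition model, auto-threshold segmentation, and the same Poisson
    inversion applied to estimated and reference covers.
    """

    n_levels: int = 14
    cover_min: float = 0.30
    cover_max: float = 0.85
    replicates: int = 4
    scene_size: int = 1200
    circle_radius: int = 10
    cover_tolerance: float = 0.005
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def covers(self) -> np.ndarray:
        if not 0 < self.cover_min < self.cover_max < 1:
            raise ValueError("cover range must satisfy 0 < min < max < 1")
        return np.linspace(self.cover_min, self.cover_max, self.n_levels)


def _default_entities() -> tuple[tuple[str, str, float], ...]:
    df = load_reference_precision_table()
    return tuple(
        (row.entity_id, row.canopy_class, float(row.mean_lai))
        for row in df.itertuples(index=False)
    )


@dataclass(frozen=True)
class PrecisionDesign:
    """The interlaboratory precision experiment.

    ``entities`` is a tuple of (entity_id, canopy_class, true mean LAI) —
    by default the three canopy classes × four quartile LAI levels of the
    reference study. ``mode`` selects the fast generative route (laboratory
    and replicate effects drawn from the stated variance components) or the
    mechanistic image route (each laboratory picks its own segmentation
    threshold on rendered scenes).
    """

    entities: tuple[tuple[str, str, float], ...] = field(
        default_factory=_default_entities
    )
    p_labs: int = 4
    n_replicates: int = 4
    variance: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(sigma_within=0.2, sigma_between=0.1)
    )
    mode: str = "components"  # or "images"
    # image-mode knobs
    scene_size: int = 400
    circle_radius: int = 6
    max_image_cover: float = 0.90
    user_bias_sd: float = 10.0
    session_sd: float = 3.0
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)

    def __post_init__(self) -> None:
        if self.mode not in ("components", "images"):
            raise ValueError("mode must be 'components' or 'images'")
        if self.p_labs < 3:
            raise ValueError("Grubbs screening needs at least 3 laboratories")


@dataclass(frozen=True)
class StudyConfig:
    """Top-level study configuration: both experiments plus seeds/output."""

    trueness: TruenessDesign = field(default_factory=TruenessDesign)
    precision: PrecisionDesign = field(default_factory=PrecisionDesign)
    method_effect_scenes: int = 60
    method_effect_bias: float = 6.0
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "trueness" in raw:
            t = dict(raw["trueness"])
            if "acquisition" in t:
                t["acquisition"] = AcquisitionModel(**t["acquisition"])
            if "segmentation" in t:
                t["segmentation"] = SegmentationConfig(**t["segmentation"])
            kwargs["trueness"] = TruenessDesign(**t)
        if "precision" in raw:
            p = dict(raw["precision"])
            if "variance" in p:
                p["variance"] = VarianceComponents(**p["variance"])
            if "acquisition" in p:
                p["acquisition"] = AcquisitionModel(**p["acquisition"])
            if "entities" in p:
                p["entities"] = tuple(tuple(e) for e in p["entities"])
            kwargs["precision"] = PrecisionDesign(**p)
        for key in ("method_effect_scenes", "method_effect_bias", "seed", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# experiments


@dataclass(frozen=True)
class TruenessExperimentResult:
    """Trueness metrics on both scales plus the per-level table."""

    lai: TruenessResult
    cover: TruenessResult
    table: pd.DataFrame
    scenes: list[BinaryScene]


def run_trueness_experiment(
    design: TruenessDesign | None = None, seed: int = 0
) -> TruenessExperimentResult:
    """Run the artificial-canopy trueness loop.

    For each cover level: generate a Boolean scene, render the replicate
    acquisitions, auto-threshold and segment each, and average the replicate
    LAI estimates. References are the exact scene covers pushed through the
    same Poisson inversion, so the agreement metrics compare like with like.
    Metrics are returned on the LAI scale (headline) and the cover scale.
    """
    design = design or TruenessDesign()
    rng = np.random.default_rng(seed)
    rows = []
    scenes = []
    for level, cover in enumerate(design.covers()):
        spec = SceneSpec(
            target_cover=float(cover),
            circle_radius=design.circle_radius,
            width=design.scene_size,
            height=design.scene_size,
            cover_tolerance=design.cover_tolerance,
            seed=int(rng.integers(_MAX_SEED)),
        )
        scene = generate_boolean_scene(spec)
        scenes.append(scene)
        cover_estimates = []
        for _ in range(design.replicates):
            model = dataclasses.replace(
                design.acquisition, seed=int(rng.integers(_MAX_SEED))
            )
            img = GrayscaleImage(render_acquisition(scene, model))
            mask = segment(img, design.segmentation)
            cover_estimates.append(measure_cover(mask, img.geometry))
        cover_estimates = np.asarray(cover_estimates)
        lai_estimates = np.array([cover_to_lai(c) for c in cover_estimates])
        rows.append(
            {
                "level": level,
                "target_cover": float(cover),
                "achieved_cover": scene.achieved_cover,
                "reference_lai": cover_to_lai(scene.achieved_cover),
                "mean_cover_estimate": float(cover_estimates.mean()),
                "mean_lai_estimate": float(lai_estimates.mean()),
                "sd_lai_estimate": float(lai_estimates.std(ddof=1)),
                "n_replicates": design.replicates,
            }
        )
    table = pd.DataFrame(rows)
    lai_metrics = trueness_metrics(
        table["mean_lai_estimate"], table["reference_lai"]
    )
    cover_metrics = trueness_metrics(
        table["mean_cover_estimate"], table["achieved_cover"]
    )
    return TruenessExperimentResult(
        lai=lai_metrics, cover=cover_metrics, table=table, scenes=scenes
    )


@dataclass(frozen=True)
class MethodEffectResult:
    """Sky-vs-green segmentation comparison on rendered scenes."""

    comparison: PairedComparison
    table: pd.DataFrame


def run_method_effect_experiment(
    n_scenes: int = 60,
    auto_bias: float = 6.0,
    design: TruenessDesign | None = None,
    seed: int = 0,
) -> MethodEffectResult:
    """Segment the same rendered scenes with both threshold conventions.

    Scene covers are evenly spaced over the design's cover range. The sky
    method resolves its auto threshold ``auto_bias`` grey levels below Otsu,
    the green method the same amount above — the mechanism by which users
    anchored on opposite pixel categories split the mixed pixels differently.
    Returns the paired t-test on the green − sky LAI differences.
    """
    design = design or TruenessDesign()
    rng = np.random.default_rng(seed)
    covers = np.linspace(design.cover_min, design.cover_max, n_scenes)
    sky_cfg = SegmentationConfig(method="sky", threshold="auto", auto_bias=auto_bias)
    green_cfg = SegmentationConfig(method="green", threshold="auto", auto_bias=auto_bias)
    rows = []
    for i, cover in enumerate(covers):
        spec = SceneSpec(
            target_cover=float(cover),
            circle_radius=design.circle_radius,
            width=design.scene_size,
            height=design.scene_size,
            cover_tolerance=design.cover_tolerance,
            seed=int(rng.integers(_MAX_SEED)),
        )
        scene = generate_boolean_scene(spec)
        model = dataclasses.replace(
            design.acquisition, seed=int(rng.integers(_MAX_SEED))
        )
        img = GrayscaleImage(render_acquisition(scene, model))
        lai_sky = cover_to_lai(measure_cover(segment(img, sky_cfg)))
        lai_green = cover_to_lai(measure_cover(segment(img, green_cfg)))
        rows.append(
            {
                "image_id": f"scene_{i:03d}",
                "achieved_cover": scene.achieved_cover,
                "lai_sky": lai_sky,
                "lai_green": lai_green,
            }
        )
    table = pd.DataFrame(rows)
    comparison = paired_t(table["lai_green"], table["lai_sky"])
    return MethodEffectResult(comparison=comparison, table=table)


@dataclass(frozen=True)
class PrecisionExperimentResult:
    """Fitted precision replication plus its stratified aggregates."""

    fit: InterlabPrecisionResults
    table: pd.DataFrame
    summaries: list[StratumSummary]


def _image_mode_matrix(
    entity_id: str,
    canopy_class: str,
    true_mean: float,
    design: PrecisionDesign,
    rng: np.random.Generator,
) -> EstimateMatrix:
    """Drive the full image pipeline with simulated per-user thresholds."""
    cover = min(1.0 - np.exp(-true_mean), design.max_image_cover)
    spec = SceneSpec(
        target_cover=float(cover),
        circle_radius=design.circle_radius,
        width=design.scene_size,
        height=design.scene_size,
        seed=int(rng.integers(_MAX_SEED)),
    )
    scene = generate_boolean_scene(spec)
    ref_img = GrayscaleImage(
        render_acquisition(
            scene, dataclasses.replace(design.acquisition, seed=int(rng.integers(_MAX_SEED)))
        )
    )
    optimal = auto_threshold(ref_img)
    thresholds = simulate_user_thresholds(
        optimal,
        design.user_bias_sd,
        design.session_sd,
        design.p_labs,
        design.n_replicates,
        seed=int(rng.integers(_MAX_SEED)),
    )
    values = np.empty((design.p_labs, design.n_replicates))
    for l in range(design.p_labs):
        for k in range(design.n_replicates):
            model = dataclasses.replace(
                design.acquisition, seed=int(rng.integers(_MAX_SEED))
            )
            img = GrayscaleImage(render_acquisition(scene, model))
            cfg = SegmentationConfig(
                method="sky", threshold=int(round(thresholds[l, k]))
            )
            est_cover = min(measure_cover(segment(img, cfg)), 0.999999)
            values[l, k] = cover_to_lai(est_cover)
    return EstimateMatrix(
        values=values, entity_id=entity_id, canopy_class=canopy_class,
        true_mean=true_mean,
    )


def run_precision_experiment(
    design: PrecisionDesign | None = None, seed: int = 0
) -> PrecisionExperimentResult:
    """Simulate the laboratory × replicate design and fit the precision model.

    In ``components`` mode each entity's matrix is drawn from the stated
    within/between-laboratory variance components; in ``images`` mode the
    matrices come from the full scene → render → user-threshold → inversion
    pipeline. Stratified aggregates use the default strata that have members.
    """
    design = design or PrecisionDesign()
    rng = np.random.default_rng(seed)
    matrices = []
    for entity_id, canopy_class, true_mean in design.entities:
        if design.mode == "components":
            matrices.append(
                simulate_estimate_matrix(
                    true_mean,
                    design.variance,
                    design.p_labs,
                    design.n_replicates,
                    seed=int(rng.integers(_MAX_SEED)),
                    entity_id=entity_id,
                    canopy_class=canopy_class,
                )
            )
        else:
            matrices.append(
                _image_mode_matrix(entity_id, canopy_class, true_mean, design, rng)
            )
    fit = InterlabPrecision(matrices).fit()
    populated = []
    for st in DEFAULT_STRATA:
        if any(st.contains(x.mean_estimate, x.canopy_class) for x in fit.results):
            populated.append(st)
    summaries = stratify_summaries(fit.results, populated)
    return PrecisionExperimentResult(fit=fit, table=fit.table, summaries=summaries)
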