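"""End-to-end orchestration: synth -> preprocess -> features -> PCA.

A single ``RunConfig`` (JSON round-trippable) drives the whole run; one seed
governs all randomness through spawned substreams so identical configs give
identical outputs.  Also houses the compressive-force-per-cell utility for
the nut-on-coverslip loading experiment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import feature_space as fs
from . import features as ft
from . import preprocess as pp
from . import synthetic as syn

__all__ = [
    "RunConfig",
    "CompressionExperiment",
    "force_per_cell",
    "run_pipeline",
]

logger = logging.getLogger("nucleomorph")


# --------------------------------------------------------------------------
# Compressive force utility
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CompressionExperiment:
    """Nut-on-coverslip compression: load mass, buoyancy-equivalent mass, g, cells.

    Defaults are the documented experiment: a 23 g parafilm-wrapped nut whose
    submerged portion displaces medium equivalent to 1.1 g, g = 10 m/s^2,
    shared by ~10,000 cells.
    """

    load_mass_g: float = 23.0
    submerged_equivalent_mass_g: float = 1.1
    gravity_m_s2: float = 10.0
    n_cells: int = 10_000

    def __post_init__(self):
        if self.load_mass_g <= 0 or self.gravity_m_s2 <= 0:
            raise ValueError("load mass and gravity must be positive")
        if self.submerged_equivalent_mass_g < 0:
            raise ValueError("submerged-equivalent mass must be >= 0")
        if self.submerged_equivalent_mass_g >= self.load_mass_g:
            raise ValueError("submerged-equivalent mass must be below the load mass")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def force_per_cell(exp: CompressionExperiment) -> float:
    """Compressive force per cell in micro-newtons.

    (load mass - buoyancy-equivalent mass) in kg times g, divided by the
    number of cells: ``((m - m_b) * 1e-3 * g / n) * 1e6`` uN.
    """
    newtons = (exp.load_mass_g - exp.submerged_equivalent_mass_g) * 1e-3 * exp.gravity_m_s2
    return newtons / exp.n_cells * 1e6


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All stage parameters for one reproducible run."""

    preset: str = "two-populations"  # single | field | two-populations | grating
    seed: int = 0
    # synth
    n_per_group: int = 15
    area_ratio: float = 2.0
    length_scale_ratio: float = 2.0
    concavity_shift: float = 0.0
    n_fields: int = 4
    nuclei_per_field: int = 5
    n_frames: int = 4
    noise_sd: float = 0.02
    max_shift_px: float = 2.0
    background_amplitude: float = 0.1
    bit_depth: int = 12
    pixel_size_um: float = 0.2
    # preprocess
    rolling_ball_radius_px: float = 50.0
    median_radius_px: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px: int = 200
    border_policy: str = "drop_touching"
    # features / pca
    directions: str = "radial"  # radial | major-minor
    impute: str = "drop"
    n_components: int = 3
    save_images: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def acquisition_spec(self, seed: int) -> syn.AcquisitionSpec:
        return syn.AcquisitionSpec(
            n_frames=self.n_frames,
            noise_sd=self.noise_sd,
            max_shift_px=self.max_shift_px,
            background_amplitude=self.background_amplitude,
            bit_depth=self.bit_depth,
            pixel_size_um=self.pixel_size_um,
            seed=seed,
        )

    def segmentation_params(self) -> pp.SegmentationParams:
        return pp.SegmentationParams(
            rolling_ball_radius_px=self.rolling_ball_radius_px,
            median_radius_px=self.median_radius_px,
            threshold_method=self.threshold_method,
            fixed_threshold=self.fixed_threshold,
            min_area_px=self.min_area_px,
            border_policy=self.border_policy,
        )


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _synthesize(config: RunConfig) -> tuple:
    """Generate (stacks, labels) per the preset; labels may be None for 'field'."""
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in
             np.random.SeedSequence(config.seed).spawn(max(config.n_fields, 2))]
    if config.preset == "two-populations":
        delta = syn.PopulationDelta(
            area_ratio=config.area_ratio,
            length_scale_ratio=config.length_scale_ratio,
            concavity_shift=config.concavity_shift,
        )
        stacks, labels, truths = syn.generate_two_populations(
            config.n_per_group, delta, config.acquisition_spec(seeds[0])
        )
        return stacks, labels, truths
    if config.preset in ("single", "grating"):
        rng = np.random.default_rng(seeds[0])
        kind = "cosine_grating" if config.preset == "grating" else "bandpass_noise"
        shape = syn.ShapeSpec(area_um2=150.0, aspect_ratio=1.3, seed=seeds[0])
        tex = syn.TextureSpec(
            length_scale_um=0.8, texture_kind=kind, seed=seeds[1 % len(seeds)]
        )
        stack, gt = syn.generate_field(
            [shape], [tex], config.acquisition_spec(seeds[0]), field_shape=(160, 160)
        )
        return [stack], [""], [gt]
    if config.preset == "field":
        stacks, labels, truths = [], [], []
        for f in range(config.n_fields):
            rng = np.random.default_rng(seeds[f])
            shapes, texs = [], []
            for _ in range(config.nuclei_per_field):
                shapes.append(
                    syn.ShapeSpec(
                        area_um2=float(rng.uniform(80, 200)),
                        aspect_ratio=float(rng.uniform(1.0, 2.0)),
                        orientation=float(rng.uniform(0, np.pi)),
                        seed=int(rng.integers(2**31 - 1)),
                    )
                )
                texs.append(
                    syn.TextureSpec(
                        length_scale_um=float(rng.uniform(0.5, 1.5)),
                        seed=int(rng.integers(2**31 - 1)),
                    )
                )
            stack, gt = syn.generate_field(
                shapes, texs, config.acquisition_spec(seeds[f]), field_shape=(360, 360)
            )
            stacks.append(stack)
            labels.append("")
            truths.append(gt)
        return stacks, labels, truths
    raise ValueError(f"unknown preset {config.preset!r}")


def preprocess_stack(stack_array: np.ndarray, config: RunConfig) -> "pp.NucleusImage":
    """Align, average, background-subtract and median-filter one frame stack."""
    stack = pp.FrameStack(stack_array, config.pixel_size_um, config.bit_depth)
    if stack.n_frames > 1:
        stack = pp.align_frames(stack)
    image = pp.average_frames(stack)
    image = pp.subtract_background(image, config.rolling_ball_radius_px)
    image = pp.denoise_median(image, config.median_radius_px)
    return image


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute synth -> preprocess -> features -> PCA and write all outputs.

    Writes the resolved config, a per-nucleus feature CSV, long-format
    decorrelation-curve CSV, PCA loadings/scores/variance CSVs, a separation
    JSON (when >= 2 labeled groups) and a run manifest.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    stacks, labels, truths = _synthesize(config)
    seg_params = config.segmentation_params()

    feature_rows, curve_rows, fvs, fv_labels = [], [], [], []
    n_segmented = 0
    for i, (stack_array, label) in enumerate(zip(stacks, labels)):
        image = preprocess_stack(stack_array, config)
        if config.save_images:
            import tifffile

            tifffile.imwrite(out / f"field_{i:03d}.tif", stack_array.astype(np.float32))
        for j, (mask, crop) in enumerate(pp.segment_nuclei(image, seg_params)):
            nucleus_id = f"f{i:03d}_n{j:02d}"
            fv, curve = ft.extract_features(crop, mask, return_curve=True,
                                            nucleus_id=nucleus_id)
            n_segmented += 1
            from scipy import ndimage as ndi

            row = {
                "nucleus_id": nucleus_id,
                "group": label,
                **fv.to_dict(),
                "inscribed_radius_px": float(
                    ndi.distance_transform_edt(mask.pixels).max()
                ),
                "length_scale_missing": fv.autocorrelation_length_scale_um is None,
            }
            feature_rows.append(row)
            fvs.append(fv)
            fv_labels.append(label)
            if fv.autocorrelation_length_scale_um is None:
                logger.info("nucleus %s: length-scale missing (degenerate texture "
                            "or inscribed circle too small)", nucleus_id)
            if curve is not None:
                if config.directions == "major-minor":
                    for name, (d, c) in ft.major_minor_curves(curve, mask).items():
                        for dd, cc in zip(d, c):
                            curve_rows.append(
                                {"nucleus_id": nucleus_id, "direction": name,
                                 "distance_um": dd * config.pixel_size_um,
                                 "mean_coefficient": cc}
                            )
                else:
                    for dd, cc in zip(curve.shift_distances, curve.mean_coefficients):
                        curve_rows.append(
                            {"nucleus_id": nucleus_id, "direction": "radial",
                             "distance_um": dd * config.pixel_size_um,
                             "mean_coefficient": cc}
                        )

    features_df = pd.DataFrame(feature_rows)
    features_df.to_csv(out / "features.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(out / "decorrelation_curves.csv", index=False)

    manifest = {
        "preset": config.preset,
        "seed": config.seed,
        "n_fields": len(stacks),
        "n_nuclei_generated": sum(len(t.records) for t in truths),
        "n_nuclei_segmented": n_segmented,
        "n_missing_length_scale": int(
            sum(1 for fv in fvs if fv.autocorrelation_length_scale_um is None)
        ),
    }

    have_groups = len({l for l in fv_labels if l}) >= 2
    if have_groups and len(fvs) >= 3:
        matrix, lab, n_dropped = fs.build_feature_matrix(fvs, fv_labels,
                                                         impute=config.impute)
        z, _ = fs.standardize(matrix)
        model = fs.fit_pca(z)
        model.loadings.to_csv(out / "pca_loadings.csv")
        scores = model.scores.copy()
        scores["group"] = lab.to_numpy()
        scores.to_csv(out / "pca_scores.csv", index=False)
        pd.DataFrame(
            {
                "component": model.loadings.columns,
                "variance": model.component_variances,
                "pct_explained": model.variance_explained_pct,
                "cumulative_pct": np.cumsum(model.variance_explained_pct),
            }
        ).to_csv(out / "pca_variance.csv", index=False)
        report = fs.group_separation(model, lab.to_numpy(), config.n_components)
        manifest["n_rows_dropped_missing"] = n_dropped
        manifest["silhouette"] = report.silhouette
        manifest["nearest_centroid_accuracy"] = report.nearest_centroid_accuracy
        manifest["variance_explained_first_k_pct"] = fs.variance_explained(
            model, min(config.n_components, len(model.component_variances))
        )
        (out / "separation.json").write_text(
            json.dumps(
                {
                    "silhouette": report.silhouette,
                    "nearest_centroid_accuracy": report.nearest_centroid_accuracy,
                    "top_loadings": report.top_loadings,
                    "centroids": report.centroids.to_dict(),
                    "excluded_groups": list(report.excluded_groups),
                },
                indent=2,
            )
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
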