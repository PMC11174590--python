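"""End-to-end pipeline: simulate -> extract -> features -> search -> screen -> model.

A :class:`RunConfig` bundles every stage's parameters and seeds; a run
writes all intermediate tables, the results grid, and a manifest
(config + seeds + library versions) to an output directory, so any stage
can be re-run standalone from the previous stage's serialized outputs and
a rerun from the same manifest reproduces results.csv.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import raster_io, synthetic_scene
from .glcm_texture import GlcmConfig, scene_texture_table
from .models import BpnnSpec, ElmSpec, SplitSpec, XgbSpec, run_matrix, split
from .screening import build_combinations, records_frame, screen
from .texture_index_search import best_index_columns, search_all
from .types import TEXTURE_FEATURE_NAMES, SceneConfig, TreatmentDesign
from .vegetation_indices import compute_all_vis

__all__ = ["RunConfig", "validate_config", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    design: TreatmentDesign = TreatmentDesign()
    scene: SceneConfig = SceneConfig()
    glcm: GlcmConfig = GlcmConfig()
    split: SplitSpec = SplitSpec()
    elm: ElmSpec = ElmSpec()
    xgb: XgbSpec = XgbSpec()
    bpnn: BpnnSpec = BpnnSpec()
    alpha: float = 0.05
    red_edge_band: int = 4
    osavi_canonical: bool = False
    msavi_as_printed: bool = False
    #: compute best texture-index pairs on all samples (as published
    #: workflows do) instead of the leakage-free training-only default
    search_on_all_samples: bool = False
    #: permutations for the selection-adjusted p of each family's best pair
    permutation_test: int = 0
    make_plots: bool = False

    def with_seed(self, seed: int) -> "RunConfig":
        """Derive all stage seeds from one master seed."""
        return dataclasses.replace(
            self,
            scene=dataclasses.replace(self.scene, seed=seed),
            split=dataclasses.replace(self.split, seed=seed + 1),
            elm=dataclasses.replace(self.elm, seed=seed + 2),
            xgb=dataclasses.replace(self.xgb, seed=seed + 3),
            bpnn=dataclasses.replace(self.bpnn, seed=seed + 4),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        kwargs = {}
        nested = {
            "design": TreatmentDesign,
            "scene": SceneConfig,
            "glcm": GlcmConfig,
            "split": SplitSpec,
            "elm": ElmSpec,
            "xgb": XgbSpec,
            "bpnn": BpnnSpec,
        }
        for key, value in payload.items():
            if key in nested:
                value = dict(value)
                for f in dataclasses.fields(nested[key]):
                    if f.name in value and isinstance(value[f.name], list):
                        value[f.name] = tuple(value[f.name])
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty means the config is usable."""
    problems = []
    if not 0 < config.alpha < 1:
        problems.append(f"alpha must lie in (0, 1), got {config.alpha}")
    if config.red_edge_band not in (4, 5):
        problems.append(f"red_edge_band must be 4 or 5, got {config.red_edge_band}")
    if config.permutation_test < 0:
        problems.append("permutation_test must be >= 0")
    rows, cols = config.scene.plot_size_px
    if min(rows, cols) < config.glcm.window:
        problems.append(
            f"plot_size_px {config.scene.plot_size_px} smaller than the GLCM "
            f"window {config.glcm.window}"
        )
    return problems


def _library_versions() -> dict[str, str]:
    import scipy
    import sklearn
    import xgboost

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


def _stage(name):
    """Decorator: re-raise stage failures with the stage name attached."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


@_stage("simulate")
def stage_simulate(config: RunConfig, out: Path):
    scene, table = synthetic_scene.simulate(config.design, config.scene)
    synthetic_scene.write_scene(scene, table, out / "scene")
    return scene, table


@_stage("extract")
def stage_extract(scene, table, out: Path) -> pd.DataFrame:
    samples = raster_io.extract_samples(scene, table)
    samples.to_csv(out / "reflectance.csv", index=False)
    return samples


@_stage("features")
def stage_features(config: RunConfig, scene, samples: pd.DataFrame, out: Path):
    vi = compute_all_vis(
        samples,
        osavi_canonical=config.osavi_canonical,
        msavi_as_printed=config.msavi_as_printed,
        red_edge_band=config.red_edge_band,
    )
    vi_out = pd.concat([samples[["plot_id", "season"]], vi], axis=1)
    vi_out.to_csv(out / "vegetation_indices.csv", index=False)
    tex = scene_texture_table(scene, config.glcm)
    # align texture rows with the sample table's row order
    tex = (
        samples[["plot_id", "season"]]
        .merge(tex, on=["plot_id", "season"], how="left", sort=False)
    )
    if tex[list(TEXTURE_FEATURE_NAMES)].isna().any().any():
        raise ValueError("texture extraction missing for some plot-season rows")
    tex.to_csv(out / "texture_features.csv", index=False)
    return vi, tex[list(TEXTURE_FEATURE_NAMES)]


@_stage("search")
def stage_search(config: RunConfig, tex: pd.DataFrame, moisture: np.ndarray, out: Path):
    if config.search_on_all_samples:
        search_rows = np.arange(len(tex))
    else:
        search_rows, _ = split(len(tex), config.split)
    hits, matrices = search_all(
        tex.iloc[search_rows],
        moisture[search_rows],
        n_permutations=config.permutation_test,
        seed=config.split.seed,
    )
    hit_rows = [
        {
            "family": h.family,
            "feature_i": h.feature_i,
            "feature_j": h.feature_j,
            "r": h.r,
            "p": h.p,
            "n": h.n,
            "n_singular_pairs": h.n_singular_pairs,
            "p_permutation": h.p_permutation,
        }
        for h in hits.values()
    ]
    pd.DataFrame(hit_rows).to_csv(out / "texture_index_hits.csv", index=False)
    for fam, mat in matrices.items():
        mat.to_csv(out / f"texture_index_r_{fam}.csv")
    ti_columns = best_index_columns(hits, tex)  # materialized on all samples
    return hits, matrices, ti_columns


@_stage("screen")
def stage_screen(config: RunConfig, vi, tex, ti_columns, moisture, out: Path):
    vi_rec = screen(vi, moisture, config.alpha)
    tex_rec = screen(tex, moisture, config.alpha)
    ti_rec = screen(ti_columns, moisture, config.alpha)
    screening = pd.concat(
        [
            records_frame(vi_rec).assign(family="vegetation_index"),
            records_frame(tex_rec).assign(family="texture_feature"),
            records_frame(ti_rec).assign(family="texture_index"),
        ],
        ignore_index=True,
    )
    screening.to_csv(out / "screening.csv", index=False)
    combos = build_combinations(vi_rec, tex_rec, ti_rec)
    (out / "combinations.json").write_text(
        json.dumps({k: list(v.columns) for k, v in combos.items()}, indent=1)
    )
    return combos


@_stage("model")
def stage_model(config: RunConfig, features: pd.DataFrame, moisture, combos, out: Path):
    reports, results = run_matrix(
        features,
        moisture,
        combos,
        split_spec=config.split,
        elm=config.elm,
        xgb=config.xgb,
        bpnn=config.bpnn,
    )
    results.to_csv(out / "results.csv", index=False)
    train_idx, val_idx = split(len(features), config.split)
    pred_rows = []
    for rep in reports:
        for idx, pred, sname in (
            (train_idx, rep.train_pred, "train"),
            (val_idx, rep.val_pred, "validation"),
        ):
            for i, p in zip(idx, pred):
                pred_rows.append(
                    {
                        "model": rep.model,
                        "combination": rep.combination,
                        "split": sname,
                        "sample": int(i),
                        "observed": float(np.asarray(moisture)[i]),
                        "predicted": float(p),
                    }
                )
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
    return reports, results


def _plot_outputs(matrices, reports, moisture, train_idx, val_idx, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(moisture, dtype=float)
    for fam, mat in matrices.items():
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title(f"{fam}: r with leaf moisture")
        fig.colorbar(im, ax=ax)
        fig.savefig(out / f"heatmap_{fam}.png", dpi=120)
        plt.close(fig)
    for rep in reports:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(y[train_idx], rep.train_pred, c="tab:red", label="train", s=18)
        ax.scatter(y[val_idx], rep.val_pred, c="tab:blue", label="validation", s=18)
        lims = [y.min() - 1, y.max() + 1]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_title(
            f"{rep.model} / {rep.combination} "
            f"(val R2={rep.metrics_val['R2']:.3f})"
        )
        ax.set_xlabel("observed moisture (%)")
        ax.set_ylabel("predicted moisture (%)")
        ax.legend()
        fig.savefig(out / f"scatter_{rep.model}_{rep.combination}.png", dpi=120)
        plt.close(fig)


def run_all(config: RunConfig, out_dir) -> pd.DataFrame:
    """Run the full pipeline into ``out_dir``; returns the results grid."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scene, table = stage_simulate(config, out)
    samples = stage_extract(scene, table, out)
    moisture = samples["moisture_pct"].to_numpy(dtype=float)
    vi, tex = stage_features(config, scene, samples, out)
    hits, matrices, ti_columns = stage_search(config, tex, moisture, out)
    combos = stage_screen(config, vi, tex, ti_columns, moisture, out)
    features = pd.concat([vi, tex, ti_columns], axis=1)
    reports, results = stage_model(config, features, moisture, combos, out)
    if config.make_plots:
        train_idx, val_idx = split(len(features), config.split)
        _plot_outputs(matrices, reports, moisture, train_idx, val_idx, out)

    manifest = {
        "config": config.to_dict(),
        "n_samples": int(len(samples)),
        "library_versions": _library_versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return results
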