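"""Scaled-down end-to-end replication of the validation experiment.

Pipeline per case: cohort draw -> thin phantom ("real TSCT") -> 5 mm
degradation ("conventional CT") -> virtual thin reconstruction
("virtual TSCT") -> automated size measurement perturbed by two
simulated observers on all three sources -> T staging -> agreement
statistics (ICC per source, Pearson-vs-real comparison, ANCOVA, kappa
against the real-TSCT gold standard and against pathological staging).

Everything is deterministic under the configured seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .agreestats import (
    ancova_modality_observer,
    cohen_kappa,
    compare_dependent_r,
    icc_agreement,
    interpret_kappa,
)
from .grid import VolumeGrid, empty_like_template
from .mpr_measure import ObserverModel, measure_size, simulate_observer
from .phantom import CohortParams, generate_cohort, generate_phantom
from .slabsim import SliceCondition, degrade
from .staging import TCategory, assign_t
from .vtsgan import ModelState, baseline_interp, infer, load_model

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "write_report",
    "read_report",
    "train_toy_model",
]

SOURCES = ("conventional", "virtual_tsct", "real_tsct")
REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class StudyConfig:
    n_cases: int = 93
    in_plane_mm: float = 1.0
    thin_mm: float = 1.0
    margin_mm: float = 4.0
    conventional_thickness_mm: float = 5.0
    conventional_interval_mm: float = 5.0
    model: str = "baseline"  # "baseline" | "identity" | checkpoint path
    observer_sd_mm: float = 1.0
    observer_rounding_mm: float = 1.0
    solid_threshold_hu: float = -300.0
    total_threshold_hu: float = -700.0
    seed_cohort: int = 11
    seed_phantom: int = 22
    seed_observer_a: int = 33
    seed_observer_b: int = 44
    cohort: CohortParams = field(default_factory=CohortParams)

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")


@dataclass
class StudyReport:
    config: dict
    per_case: pd.DataFrame
    icc: dict
    pearson: dict
    ancova: dict
    kappa_clinical: dict
    kappa_pathological: dict
    underestimation_median_mm: float
    schema_version: int = REPORT_SCHEMA_VERSION


def _case_grid(total_mm: float, cfg: StudyConfig) -> VolumeGrid:
    extent = max(total_mm + 2 * cfg.margin_mm + 2.0, 30.0)
    nxy = int(np.ceil(extent / cfg.in_plane_mm))
    nz = int(np.ceil(extent / cfg.thin_mm))
    spacing = (cfg.in_plane_mm, cfg.in_plane_mm, cfg.thin_mm)
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip((nxy, nxy, nz), spacing))
    return empty_like_template((nxy, nxy, nz), spacing, origin)


def _stage(total_mm: float, solid_mm: float) -> TCategory:
    # observed sizes can drift past the stage 0-I ceiling; stay defined
    solid = float(min(solid_mm, 40.0))
    total = float(max(total_mm, solid))
    return assign_t(total, solid, max_total_mm=max(60.0, total))


def train_toy_model(
    seed: int = 0,
    n_volumes: int = 20,
    per_volume: int = 8,
    epochs: int = 80,
    patch_shape: tuple[int, int, int] = (20, 20, 20),
    base_channels: int = 16,
    depth: int = 4,
    lambda_adv: float = 0.1,
    adv_every: int = 8,
    study_config: StudyConfig | None = None,
):
    """Train a small CPU-budget model on freshly generated phantoms.

    Phantoms mirror the study cohort (part-solid weighted); patches are
    degraded with random slice conditions in [3, 8] mm.  Returns the
    trained :class:`~vtsct.vtsgan.ModelState`.
    """
    from .vtsgan import ModelConfig, TrainConfig, make_training_pairs
    from .vtsgan import train as train_model

    cfg = study_config or StudyConfig()
    cohort = generate_cohort(n_volumes, cfg.cohort, seed=seed + 5000)
    vols = []
    for i, truth in enumerate(cohort):
        grid = _case_grid(truth.true_total_mm, cfg)
        vol, _ = generate_phantom(truth.spec, grid, seed=seed + 6000 + i)
        vols.append(vol)
    pairs = make_training_pairs(
        vols, per_volume, seed=seed, patch_shape=patch_shape, focus_fraction=0.6
    )
    mcfg = ModelConfig(
        patch_shape=patch_shape,
        base_channels=base_channels,
        depth=depth,
        lambda_adv=lambda_adv,
    )
    tcfg = TrainConfig(epochs=epochs, adv_every=adv_every)
    return train_model(pairs, mcfg, tcfg, seed=seed)


def run_study(
    config: StudyConfig, model: ModelState | None = None
) -> StudyReport:
    """Run the full phantom study and return the statistics battery.

    ``model`` overrides ``config.model`` when given; otherwise the
    config selects the linear baseline, the identity shortcut (virtual
    = real, for degenerate checks) or a saved checkpoint.
    """
    cfg = config
    if model is None and cfg.model not in ("baseline", "identity"):
        model = load_model(cfg.model)
    cond = SliceCondition(
        thickness_mm=cfg.conventional_thickness_mm,
        interval_mm=cfg.conventional_interval_mm,
        source_thin_mm=cfg.thin_mm,
    )
    cohort = generate_cohort(cfg.n_cases, cfg.cohort, seed=cfg.seed_cohort)
    obs_models = {
        "A": ObserverModel(cfg.observer_sd_mm, cfg.observer_rounding_mm, cfg.seed_observer_a),
        "B": ObserverModel(cfg.observer_sd_mm, cfg.observer_rounding_mm, cfg.seed_observer_b),
    }
    obs_rngs = {k: np.random.default_rng(m.seed) for k, m in obs_models.items()}

    rows = []
    for i, truth in enumerate(cohort):
        grid = _case_grid(truth.true_total_mm, cfg)
        thin, _ = generate_phantom(truth.spec, grid, seed=cfg.seed_phantom + i)
        conventional = degrade(thin, cond)
        if model is not None:
            virtual = infer(model, conventional, cond, target_thin_mm=cfg.thin_mm)
        elif cfg.model == "identity":
            virtual = thin
        else:
            virtual = baseline_interp(conventional, cond, cfg.thin_mm)
        volumes = {
            "conventional": conventional,
            "virtual_tsct": virtual,
            "real_tsct": thin,
        }
        row = {
            "case_id": i,
            "nodule_type": truth.spec.nodule_type.value,
            "true_total_mm": truth.true_total_mm,
            "true_solid_mm": truth.true_solid_mm,
            "invasive_mm": truth.invasive_size_mm,
        }
        for src, vol in volumes.items():
            m = measure_size(
                vol, cfg.solid_threshold_hu, cfg.total_threshold_hu, source=src
            )
            row[f"{src}_solid_auto"] = m.solid_mm
            row[f"{src}_total_auto"] = m.total_mm
            for obs in ("A", "B"):
                om = simulate_observer(m, obs_models[obs], rng=obs_rngs[obs])
                row[f"{src}_solid_{obs}"] = om.solid_mm
                row[f"{src}_total_{obs}"] = om.total_mm
                row[f"{src}_stage_{obs}"] = _stage(om.total_mm, om.solid_mm).name
        row["path_stage"] = _stage(
            max(truth.true_total_mm, truth.invasive_size_mm), truth.invasive_size_mm
        ).name
        rows.append(row)
    df = pd.DataFrame(rows)

    # --- agreement battery ---
    icc = {}
    for src in SOURCES:
        est, ci, p = icc_agreement(df[f"{src}_solid_A"], df[f"{src}_solid_B"])
        icc[src] = {"icc": est, "ci": list(ci), "p": p}

    n = len(df)
    pearson = {}
    for obs in ("A", "B"):
        real = df[f"real_tsct_solid_{obs}"].to_numpy(float)
        conv = df[f"conventional_solid_{obs}"].to_numpy(float)
        virt = df[f"virtual_tsct_solid_{obs}"].to_numpy(float)
        r_conv = float(np.corrcoef(conv, real)[0, 1])
        r_virt = float(np.corrcoef(virt, real)[0, 1])
        r_cv = float(np.corrcoef(virt, conv)[0, 1])
        stat, p = compare_dependent_r(
            np.clip(r_virt, -0.9999, 0.9999),
            np.clip(r_conv, -0.9999, 0.9999),
            np.clip(r_cv, -0.9999, 0.9999),
            n,
        )
        pearson[obs] = {
            "r_conventional": r_conv,
            "r_virtual": r_virt,
            "r_virtual_vs_conventional": r_cv,
            "compare_stat": stat,
            "compare_p": p,
        }

    long = []
    for obs in ("A", "B"):
        for mod in ("conventional", "virtual_tsct"):
            for _, r in df.iterrows():
                long.append(
                    {
                        "case_id": r["case_id"],
                        "observer": obs,
                        "modality": mod,
                        "solid_mm": r[f"{mod}_solid_{obs}"],
                        "real_solid_mm": r[f"real_tsct_solid_{obs}"],
                    }
                )
    aov = ancova_modality_observer(pd.DataFrame(long))
    ancova = {
        factor: {"F": float(aov.loc[factor, "F"]), "p": float(aov.loc[factor, "p"])}
        for factor in aov.index
    }
    ancova["covariate_coef"] = aov.attrs["covariate_coef"]

    categories = [c.name for c in TCategory]
    gold = df["real_tsct_stage_B"]
    kappa_clinical = {}
    for obs in ("A", "B"):
        kappa_clinical[obs] = {}
        for src in ("conventional", "virtual_tsct"):
            k, ci, p = cohen_kappa(df[f"{src}_stage_{obs}"], gold, categories)
            kappa_clinical[obs][src] = {
                "kappa": k,
                "ci": list(ci),
                "p": p,
                "band": interpret_kappa(float(np.clip(k, -1, 1)))
                if np.isfinite(k)
                else None,
            }
    kappa_pathological = {}
    for obs in ("A", "B"):
        kappa_pathological[obs] = {}
        for src in SOURCES:
            k, ci, p = cohen_kappa(df[f"{src}_stage_{obs}"], df["path_stage"], categories)
            kappa_pathological[obs][src] = {
                "kappa": k,
                "ci": list(ci),
                "p": p,
                "band": interpret_kappa(float(np.clip(k, -1, 1)))
                if np.isfinite(k)
                else None,
            }

    under = float(
        np.median(df["conventional_solid_auto"] - df["real_tsct_solid_auto"])
    )
    return StudyReport(
        config=asdict(cfg),
        per_case=df,
        icc=icc,
        pearson=pearson,
        ancova=ancova,
        kappa_clinical=kappa_clinical,
        kappa_pathological=kappa_pathological,
        underestimation_median_mm=under,
    )


def write_report(report: StudyReport, path: str | Path) -> str:
    """Write the report as JSON plus a human-readable text summary.

    ``path`` is the JSON destination; a ``.txt`` sibling is written
    alongside.  Returns the rendered text summary.
    """
    path = Path(path)
    payload = {
        "schema_version": report.schema_version,
        "config": report.config,
        "icc": report.icc,
        "pearson": report.pearson,
        "ancova": report.ancova,
        "kappa_clinical": report.kappa_clinical,
        "kappa_pathological": report.kappa_pathological,
        "underestimation_median_mm": report.underestimation_median_mm,
        "per_case": report.per_case.to_dict(orient="records"),
    }
    path.write_text(json.dumps(payload, indent=1, default=_jsonify))

    lines = [
        "Phantom validation study",
        "========================",
        f"cases: {len(report.per_case)}",
        "",
        "Inter-observer ICC (solid size):",
    ]
    for src, d in report.icc.items():
        lines.append(
            f"  {src:<14} ICC={d['icc']:.3f}  95% CI {d['ci'][0]:.3f}-{d['ci'][1]:.3f}  P={d['p']:.3g}"
        )
    lines.append("")
    lines.append("Correlation with real TSCT (per observer):")
    for obs, d in report.pearson.items():
        lines.append(
            f"  observer {obs}: r_conv={d['r_conventional']:.3f} "
            f"r_virtual={d['r_virtual']:.3f}  compare P={d['compare_p']:.3g}"
        )
    lines.append("")
    lines.append("Clinical T agreement vs real-TSCT gold standard (kappa):")
    for obs, srcs in report.kappa_clinical.items():
        for src, d in srcs.items():
            lines.append(
                f"  observer {obs} {src:<14} k={d['kappa']:.3f} "
                f"95% CI {d['ci'][0]:.3f}-{d['ci'][1]:.3f} P={d['p']:.3g} [{d['band']}]"
            )
    lines.append("")
    lines.append("Clinical vs pathological T agreement (kappa):")
    for obs, srcs in report.kappa_pathological.items():
        for src, d in srcs.items():
            lines.append(
                f"  observer {obs} {src:<14} k={d['kappa']:.3f} "
                f"95% CI {d['ci'][0]:.3f}-{d['ci'][1]:.3f} P={d['p']:.3g} [{d['band']}]"
            )
    lines.append("")
    lines.append(
        "ANCOVA: "
        + ", ".join(
            f"{f} P={d['p']:.3g}"
            for f, d in report.ancova.items()
            if isinstance(d, dict)
        )
    )
    lines.append(
        f"Median (conventional - real) solid size: "
        f"{report.underestimation_median_mm:+.2f} mm"
    )
    text = "\n".join(lines)
    path.with_suffix(".txt").write_text(text)
    return text


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, CohortParams):
        return asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
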