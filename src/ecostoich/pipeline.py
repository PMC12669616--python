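"""End-to-end study pipeline: simulate/load -> stoichiometry -> factorial
ANOVA -> ordination + envfit -> PLS path models.

Stage functions are plain library calls over DataFrames; ``run_pipeline``
sequences them, writes every stage's outputs under an output directory and
records a JSON manifest (input hash, seed, per-stage status). Two runs with
the same config and seed produce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import factorial_stats, ordination, path_model, stoichiometry
from .synthetic_data import (
    DEPTH_MIDPOINTS,
    DEPTHS,
    ENZYMES,
    FRACTIONS,
    VARIABLES,
    ZONES,
    generate_dataset,
    preset_study_design,
)

logger = logging.getLogger(__name__)

#: Predictor set for both ordinations: physicochemistry + biomass +
#: numeric-coded depth (layer midpoint, cm) and mining distance (band
#: midpoint, m).
RDA_PREDICTORS = [
    "pH", "SMC", "salinity", "SOC", "TN", "TP", "AP", "NO3_N", "NH4_N",
    "MBC", "MBN", "MBP", "depth_cm", "mining_distance",
]
#: Responses of the enzyme/stoichiometry ordination.
RDA_ENZYME_RESPONSES = ["BG", "NAG", "LAP", "ALP", "ECN", "ECP", "ENP"]
#: Responses of the limitation ordination.
RDA_LIMITATION_RESPONSES = ["vector_length", "vector_angle"]

STAGES = ["stoich", "anova", "rda", "envfit", "sem"]


@dataclass
class RunConfig:
    input_path: str | None = None     # exactly one of input_path / simulate
    simulate: bool = False
    seed: int = 0
    out_dir: str = "ecostoich_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    alpha: float = 0.05
    n_perm: int = 999
    n_boot: int = 5000
    ratio_convention: str = "ratio_of_logs"
    rescale: float = 1.0

    def validate(self) -> None:
        if bool(self.input_path) == bool(self.simulate):
            raise ValueError("exactly one input source: --input or simulate")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")


def analysis_frame(
    samples: pd.DataFrame,
    convention: str = "ratio_of_logs",
    rescale: float = 1.0,
) -> pd.DataFrame:
    """Enzyme-fraction rows joined with per-sample stoichiometry and the
    numeric depth coding (layer midpoint, cm)."""
    df = samples
    if "fraction" in df.columns:
        df = df[df["fraction"] == "enzyme"].reset_index(drop=True)
    st = stoichiometry.compute_stoichiometry(
        df, convention=convention, rescale=rescale
    )
    stoich_cols = [c for c in st.columns if c not in df.columns]
    out = pd.concat([df.reset_index(drop=True), st[stoich_cols]], axis=1)
    out["depth_cm"] = out["depth_layer"].map(DEPTH_MIDPOINTS)
    if out["depth_cm"].isna().any():
        raise ValueError("unrecognized depth layer label(s)")
    return out


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.violations


def validate_table(path) -> ValidationReport:
    """Schema, range, positivity and factorial-completeness checks."""
    report = ValidationReport()
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    required = ["zone", "depth_layer", "plot_id", "fraction"]
    missing = [c for c in required + list(VARIABLES) if c not in df.columns]
    if missing:
        report.violations.append(f"missing column(s): {missing}")
        return report
    for idx, row in df.iterrows():
        for e in ENZYMES:
            v = row[e]
            if pd.isna(v):
                continue
            if v <= 0:
                report.violations.append(f"row {idx}: {e} activity <= 0 ({v})")
            elif v <= 1:
                report.violations.append(
                    f"row {idx}: {e} activity <= 1 working unit ({v})"
                )
    bad_smc = df.index[(df["SMC"] < 0) | (df["SMC"] > 100)]
    for idx in bad_smc:
        report.violations.append(f"row {idx}: SMC outside [0, 100]")
    bad_ph = df.index[(df["pH"] <= 0) | (df["pH"] >= 14)]
    for idx in bad_ph:
        report.violations.append(f"row {idx}: pH outside (0, 14)")
    if "mining_distance" in df.columns:
        bands = {"littoral": (0, 20), "riparian": (30, 60), "upland": (70, 100)}
        for idx, row in df.iterrows():
            band = bands.get(row["zone"])
            if band and not (band[0] <= row["mining_distance"] <= band[1]):
                report.violations.append(
                    f"row {idx}: mining_distance {row['mining_distance']} outside "
                    f"{row['zone']} band {band}"
                )
    have = set(map(tuple, df[["zone", "depth_layer", "fraction"]].drop_duplicates()
                   .itertuples(index=False)))
    zones = sorted(df["zone"].unique())
    depths = sorted(df["depth_layer"].unique())
    expect_zones = zones if set(zones) - set(ZONES) else ZONES
    expect_depths = depths if set(depths) - set(DEPTHS) else DEPTHS
    for z in expect_zones:
        for d in expect_depths:
            for f in FRACTIONS:
                if (z, d, f) not in have:
                    report.warnings.append(f"incomplete factorial: missing cell "
                                           f"({z}, {d}, {f})")
    return report


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in order; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "config": {
            "alpha": config.alpha, "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "ratio_convention": config.ratio_convention,
            "rescale": config.rescale,
        },
    }
    if config.simulate:
        design = preset_study_design(seed=config.seed)
        samples = generate_dataset(design, seed=config.seed)
        sample_path = out / "samples.csv"
        samples.to_csv(sample_path, index=False)
    else:
        sample_path = Path(config.input_path)
        samples = pd.read_csv(sample_path)
    manifest["input"] = {"path": str(sample_path),
                         "sha256": _hash_file(sample_path),
                         "n_rows": len(samples)}
    frame = None
    rng = np.random.default_rng(config.seed)

    def record(stage, status, **extra):
        manifest["stages"][stage] = {"status": status, **extra}

    try:
        if "stoich" in config.stages or {"rda", "envfit", "sem"} & set(config.stages):
            frame = analysis_frame(samples, convention=config.ratio_convention,
                                   rescale=config.rescale)
        if "stoich" in config.stages:
            d = out / "stoich"
            d.mkdir(exist_ok=True)
            st_cols = ["zone", "depth_layer", "plot_id", "ECN", "ECP", "ENP",
                       "x", "y", "vector_length", "vector_angle",
                       "angle_class", "quadrant_class"]
            frame[st_cols].to_csv(d / "stoichiometry.csv", index=False)
            cells, grand = stoichiometry.summarize_cells(frame)
            cells.to_csv(d / "cell_summary.csv", index=False)
            with open(d / "grand_means.json", "w") as fh:
                json.dump(grand, fh, indent=2)
            record("stoich", "completed", n_samples=len(frame))
        if "anova" in config.stages:
            d = out / "anova"
            d.mkdir(exist_ok=True)
            af = frame if frame is not None else analysis_frame(samples)
            exclude = {"zone", "depth_layer", "plot_id", "fraction",
                       "depth_cm", "mining_distance", "x", "y"}
            numeric = [c for c in af.columns if c not in exclude
                       and pd.api.types.is_numeric_dtype(af[c])]
            letters = factorial_stats.run_study_contrasts(
                af, variables=numeric, alpha=config.alpha)
            letters.to_csv(d / "letters.csv", index=False)
            rows = []
            for var in numeric:
                res = factorial_stats.two_way_anova(
                    af[var], af["zone"], af["depth_layer"])
                t = res.to_frame()
                t.insert(0, "variable", var)
                rows.append(t)
            pd.concat(rows).to_csv(d / "two_way_anova.csv", index=False)
            record("anova", "completed", n_variables=len(numeric))
        ords = {}
        if "rda" in config.stages or "envfit" in config.stages:
            d = out / "rda"
            d.mkdir(exist_ok=True)
            X = frame[RDA_PREDICTORS]
            for tag, responses in (("enzymes", RDA_ENZYME_RESPONSES),
                                   ("limitation", RDA_LIMITATION_RESPONSES)):
                res = ordination.rda_fit(frame[responses], X)
                ords[tag] = res
                res.site_scores.to_csv(d / f"{tag}_site_scores.csv", index=False)
                res.response_scores.to_csv(d / f"{tag}_response_scores.csv")
                pd.DataFrame({
                    "axis": [f"RDA{i+1}" for i in range(res.n_constrained_axes)],
                    "eigenvalue": res.eigenvalues,
                    "proportion_explained_pct": res.proportion_explained,
                }).to_csv(d / f"{tag}_eigenvalues.csv", index=False)
            reg = ordination.limitation_regression(
                frame["vector_length"], frame["vector_angle"])
            with open(d / "limitation_regression.json", "w") as fh:
                json.dump(reg, fh, indent=2)
            record("rda", "completed",
                   proportions={t: list(map(float, o.proportion_explained[:2]))
                                for t, o in ords.items()})
        if "envfit" in config.stages:
            d = out / "envfit"
            d.mkdir(exist_ok=True)
            for tag, res in ords.items():
                tab = ordination.envfit_table(
                    res, frame[RDA_PREDICTORS], n_perm=config.n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)))
                tab.to_csv(d / f"{tag}_envfit.csv", index=False)
            record("envfit", "completed", n_perm=config.n_perm)
        if "sem" in config.stages:
            d = out / "sem"
            d.mkdir(exist_ok=True)
            summary = {}
            for target in ("C", "P"):
                spec = path_model.study_path_spec(target)
                boot = path_model.bootstrap_paths(
                    frame, spec, n_boot=config.n_boot,
                    seed=int(rng.integers(0, 2**31 - 1)))
                boot["paths"].to_csv(d / f"{target}_paths.csv", index=False)
                boot["total_effects"].to_csv(
                    d / f"{target}_total_effects.csv", index=False)
                fit = path_model.fit_pls(frame, spec)
                summary[target] = {
                    "r2": fit.r2,
                    "srmr": path_model.srmr(fit, frame),
                    "n_iter": fit.n_iter,
                    "bootstrap_failures": boot["n_failed"],
                }
            with open(d / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            record("sem", "completed", n_boot=config.n_boot)
    except Exception as exc:
        failing = next((s for s in config.stages
                        if s not in manifest["stages"]), "unknown")
        record(failing, "failed", error=str(exc))
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
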