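"""End-to-end orchestration of the integrated leaf trait analysis.

One call runs the full cascade on a specimen table (or a generated
scenario): preservation filtering, per-site subsampling, TCT spectra,
quantitative-trait summaries, herbivory metrics with rarefaction, LM_A
imputation, and the multivariate stage (trait PCA and the five-model GLM
suite).  Every stage writes a CSV into the output directory and appends a
row-count line to the run manifest, which also records the seeds and
input hashes — the dataset cascade is the main audit object.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assemblage_io import (
    Assemblage,
    build_dataset4,
    filter_dataset2,
    read_assemblage,
    sample_dataset3,
    write_assemblage,
    write_incidence_matrix,
)
from .herbivory import (
    BelowCutoffError,
    dam_percent,
    default_dt_catalog,
    dto,
    dtr_observed,
    rarefy_analytic,
)
from .lma_impute import ImputationSpec, impute_lma, imputation_report
from .quant_traits import species_summary
from .stats_models import (
    ModelFormula,
    anova_type2,
    fit_glm,
    mann_whitney,
    pca_traits,
    r2_measures,
    stepwise_aic,
)
from .tct import tct_class, tct_spectrum

__all__ = ["RunConfig", "run_pipeline", "default_model_suite",
           "prepare_model_frame"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | Path | None = None
    preset: str | None = None
    n_leaves: int = 1000          # per site, generated scenarios only
    n_per_site: int = 400         # Dataset 3 subsample size
    min_preserved_d2: float = 0.70
    min_group: int = 5
    seed: int = 0
    rarefaction_n: int = 400
    imputation: ImputationSpec | None = None
    models: list[str] = field(
        default_factory=lambda: ["M1", "M2", "M3", "M4", "M5"]
    )
    output_dir: str | Path = "ilta_out"

    def validate(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError(
                "exactly one of input_path or preset must be given"
            )
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input path {self.input_path} does not exist")


def default_model_suite() -> dict[str, ModelFormula]:
    """The five-model GLM suite on the modelling frame.

    M1 (LM_A) and M2 (leaf size) are trait models; M3 is the damage
    presence/absence model (binomial); M4 (damaged area) and M5 (herbivory
    index) describe the extent of damage on damaged leaves.  Each formula
    is the *full* model handed to stepwise selection.
    """
    return {
        "M1": ModelFormula(
            "lma_gm2",
            ("fossil_species", "leaf_area_mm2", "phenology_modern",
             "area_index", "site"),
            "gamma_identity",
        ),
        "M2": ModelFormula(
            "leaf_area_mm2",
            ("fossil_species", "area_index", "phenology_modern", "site"),
            "gamma_identity",
        ),
        "M3": ModelFormula(
            "damaged01",
            ("site", "lma_gm2", "tct_class", "leaf_area_mm2"),
            "binomial_logit",
        ),
        "M4": ModelFormula(
            "damaged_area_mm2",
            ("leaf_area_mm2", "phenology_modern", "site"),
            "gamma_identity",
        ),
        "M5": ModelFormula(
            "herbivory_index",
            ("phenology_modern", "lma_gm2", "site"),
            "gamma_identity",
        ),
    }


def prepare_model_frame(a: Assemblage) -> pd.DataFrame:
    """Flatten an assemblage into the modelling frame: adds the binary
    damage indicator, the herbivory index, and the 8-level TCT class."""
    frame = a.to_frame()
    frame["damaged01"] = frame["damaged"].astype(int)
    frame["tct_class"] = frame["tct_combined"].map(
        lambda lt: tct_class(lt) if isinstance(lt, str) and len(lt) == 1
        else None
    )
    frame["herbivory_index"] = np.where(
        frame["leaf_area_mm2"].notna() & frame["damaged_area_mm2"].notna(),
        frame["damaged_area_mm2"] / frame["leaf_area_mm2"],
        np.nan,
    )
    return frame


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary.

    Raises at the failing stage with the stage name in the message; a CLI
    wrapper converts that to a non-zero exit.
    """
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
    }

    def log(stage: str, n_in: int, n_out: int, **extra):
        manifest["stages"].append(
            {"stage": stage, "n_in": n_in, "n_out": n_out, **extra}
        )

    # --- stage 0: input -----------------------------------------------
    if cfg.input_path is not None:
        path = Path(cfg.input_path)
        d1 = read_assemblage(path, name=path.stem)
        manifest["input"] = {"path": str(path), "sha256": _sha256(path)}
        truth = None
    else:
        from .synthetic_data import generate_assemblage, scenario_presets

        presets = scenario_presets()
        if cfg.preset not in presets:
            raise ValueError(
                f"unknown preset {cfg.preset!r}; available: "
                f"{sorted(presets)}"
            )
        species, taph = presets[cfg.preset]
        d1, truth = generate_assemblage(
            species, taph, n_leaves=cfg.n_leaves, seed=cfg.seed,
            name=cfg.preset,
        )
        truth.to_csv(out_dir / "truth.csv", index=False)
        manifest["input"] = {"preset": cfg.preset, "n_leaves": cfg.n_leaves}
    log("dataset1", len(d1), len(d1))

    # --- cascade -------------------------------------------------------
    d2 = filter_dataset2(d1, cfg.min_preserved_d2)
    log("dataset2", len(d1), len(d2))
    d3 = sample_dataset3(d2, cfg.n_per_site, seed=cfg.seed + 1)
    log("dataset3", len(d2), len(d3))

    # --- TCT spectra ---------------------------------------------------
    spectra = []
    for site, sub in d1.by_site().items():
        spec = tct_spectrum(s.tct_combined for s in sub)
        spec = spec.reset_index()
        spec.insert(0, "site", site)
        spectra.append(spec)
    tct_frame = pd.concat(spectra, ignore_index=True)
    tct_frame.to_csv(out_dir / "tct_spectrum.csv", index=False)
    log("tct_spectrum", len(d1), len(tct_frame))

    # --- quantitative traits ------------------------------------------
    summaries = []
    for site, sub in d3.by_site().items():
        summary = species_summary(sub, min_n=cfg.min_group)
        summary.insert(0, "site", site)
        summaries.append(summary)
    trait_frame = pd.concat(summaries, ignore_index=True)
    trait_frame.to_csv(out_dir / "species_traits.csv", index=False)
    log("species_traits", len(d3), len(trait_frame))

    # --- herbivory metrics --------------------------------------------
    catalog = default_dt_catalog()
    herb_rows = []
    for site, sub in d1.by_site().items():
        matrix = write_incidence_matrix(
            sub, out_dir / f"incidence_{site}.csv"
        )
        row = {
            "site": site,
            "n_leaves": len(sub),
            "dam_percent": dam_percent(sub, catalog=catalog),
            "dto": dto(sub, catalog=catalog),
            "dtr_observed": dtr_observed(matrix),
        }
        n_rare = min(cfg.rarefaction_n, len(sub))
        try:
            rare = rarefy_analytic(matrix, n_rare)
            row["rarefied_n"] = n_rare
            row["dtr_rarefied"] = rare["expected_richness"]
            row["dtr_rarefied_sd"] = rare["sd"]
        except BelowCutoffError:
            row["rarefied_n"] = None
        herb_rows.append(row)
    herb_frame = pd.DataFrame(herb_rows)
    herb_frame.to_csv(out_dir / "herbivory_metrics.csv", index=False)
    log("herbivory", len(d1), len(herb_frame))

    # --- Dataset 4 + imputation (Dataset 5) ---------------------------
    d4, ledger = build_dataset4(d3, min_group=cfg.min_group)
    log("dataset4", len(d3), len(d4), removed=ledger)
    imp_spec = cfg.imputation or ImputationSpec(seed=cfg.seed + 2)
    imputed, diag = impute_lma(d3, imp_spec)
    d5, ledger5 = build_dataset4(imputed, min_group=cfg.min_group)
    log("dataset5", len(imputed), len(d5), removed=ledger5,
        imputed=diag.n_imputed, range_removed=diag.n_removed_range)
    (out_dir / "imputation_report.txt").write_text(
        imputation_report(diag) + "\n"
    )
    write_assemblage(d5, out_dir / "dataset5.csv")

    # --- dataset summary (cascade table) ------------------------------
    summary_rows = []
    for label, ds in [("D1", d1), ("D2", d2), ("D3", d3), ("D4", d4),
                      ("D5", d5)]:
        frame = ds.to_frame()
        row = {"dataset": label, "n": len(ds)}
        for site, grp in frame.groupby("site"):
            row[f"n_{site}"] = len(grp)
            sizes = grp["leaf_area_mm2"].dropna()
            lmas = grp["lma_gm2"].dropna()
            if len(sizes):
                row[f"mean_size_{site}"] = sizes.mean()
            if len(lmas):
                row[f"mean_lma_{site}"] = lmas.mean()
        summary_rows.append(row)
    cascade = pd.DataFrame(summary_rows)
    # between-site Mann-Whitney on the measurement sample
    d3_frame = d3.to_frame()
    sites = sorted(d3_frame["site"].unique())
    if len(sites) == 2:
        first, second = sites
        tests = {}
        for col, label in [("leaf_area_mm2", "size"), ("lma_gm2", "lma")]:
            x = d3_frame.loc[d3_frame["site"] == first, col].dropna()
            y = d3_frame.loc[d3_frame["site"] == second, col].dropna()
            if len(x) and len(y):
                tests[label] = mann_whitney(x, y)
        manifest["mann_whitney_d3"] = tests
    cascade.to_csv(out_dir / "dataset_summary.csv", index=False)

    # --- multivariate stage -------------------------------------------
    model_frame = prepare_model_frame(d5)
    complete = model_frame.dropna(
        subset=["lma_gm2", "leaf_area_mm2", "leaf_width_mm",
                "leaf_length_mm", "length_width_ratio"]
    )
    pca = pca_traits(complete)
    pd.DataFrame(
        {
            "axis": [f"PC{k+1}" for k in range(len(pca.eigenvalues))],
            "eigenvalue": pca.eigenvalues,
            "variance_explained": pca.variance_explained,
        }
    ).to_csv(out_dir / "pca_axes.csv", index=False)
    pca.contributions.to_csv(out_dir / "pca_contributions.csv")
    manifest["pca"] = {
        "n": int(len(complete)),
        "pc1_pc2_percent": float(pca.variance_explained[:2].sum()),
    }
    log("pca", len(d5), len(complete))

    glm_rows = []
    suite = default_model_suite()
    for key in cfg.models:
        formula = suite[key]
        frame = complete
        if key in ("M4", "M5"):
            frame = complete[
                (complete["damaged01"] == 1)
                & (complete["herbivory_index"] > 0)
            ]
        frame = frame.dropna(
            subset=[formula.response, *[
                t for t in formula.terms if t in frame.columns
            ]]
        )
        entry: dict = {"model": key, "family": formula.family,
                       "n": len(frame)}
        if len(frame) < 10:
            entry["error"] = "too few observations"
            glm_rows.append(entry)
            continue
        try:
            selected = stepwise_aic(formula, frame)
            anova = anova_type2(selected, frame)
            r2 = r2_measures(selected, frame)
            entry.update(
                formula=selected.formula.formula,
                aic=selected.aic,
                terms="+".join(selected.formula.terms),
                **{f"r2_{k}": v for k, v in r2.items()},
            )
            anova.to_csv(out_dir / f"anova_{key}.csv")
        except (ValueError, RuntimeError) as exc:
            entry["error"] = str(exc)
        glm_rows.append(entry)
    pd.DataFrame(glm_rows).to_csv(out_dir / "glm_summary.csv", index=False)
    log("glm", len(complete), len(glm_rows))

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str)
                             + "\n")
    return manifest
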