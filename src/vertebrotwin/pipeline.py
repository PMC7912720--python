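"""End-to-end pipeline: simulate -> measure -> model.

Stages are file-backed and individually re-runnable: the cohort stage
writes a subject CSV with the simulated geometric phenotypes, the
morphometry stage builds one synthetic vessel network per subject from
those phenotypes (optionally perturbed), measures it and writes the
morphometry CSV, and the heritability stage fits the twin models to the
measured indices and writes the report tables.  Every number in a report
is a function of (config, master seed) only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .cohort import (
    RISK_FACTORS, CohortSpec, PhenotypeSpec, default_phenotype_specs,
    simulate_cohort, simulate_ace_phenotype,
)
from .synthesis import (
    GeometryTargets, build_vessel_network, perturb_network,
    minimum_ba_tortuosity, maximum_va_tortuosity,
)
from .morphometry import network_morphometry
from . import io as net_io
from .ace import (
    ACEModel, fit_variance_components, fit_saturated,
    intrapair_correlation, lrt_vs_saturated, covariate_lrt, select_model, profile_ci,
    MODELS,
)

#: phenotypes that parameterise the synthetic geometry directly
GEOMETRY_PHENOTYPES = (
    "ba_length", "ba_diameter", "ba_bend", "ba_tortuosity",
    "left_va_diameter", "right_va_diameter",
    "left_va_curvature", "right_va_curvature",
    "left_va_torsion", "right_va_torsion",
    "left_va_tortuosity", "right_va_tortuosity",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "vertebrotwin_out"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    phenotypes: list = field(default_factory=default_phenotype_specs)
    noise_sd_point: float = 0.0
    noise_sd_radius: float = 0.0
    spur_probability: float = 0.0
    spacing: float = 0.5
    smooth_iters: int = 20
    min_branch_mm: float = 3.0
    models: tuple = MODELS
    covariates_model1: tuple = ("age", "sex")
    covariates_model2: tuple = ("age", "sex", "exercise", "alcohol", "smoking",
                                "diabetes", "hypertension", "dyslipidemia",
                                "height_cm", "weight_kg", "bmi")
    network_format: str = "vtp"
    write_networks: bool = True
    profile_cis: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "cohort" in raw:
            cfg.cohort = CohortSpec(**raw.pop("cohort"))
        if "phenotypes" in raw:
            cfg.phenotypes = [PhenotypeSpec(**p) for p in raw.pop("phenotypes")]
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        cfg.models = tuple(cfg.models)
        cfg.covariates_model1 = tuple(cfg.covariates_model1)
        cfg.covariates_model2 = tuple(cfg.covariates_model2)
        return cfg

    def resolved(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["covariates_model1"] = list(self.covariates_model1)
        d["covariates_model2"] = list(self.covariates_model2)
        return d


@dataclass
class ReportBundle:
    descriptives: pd.DataFrame
    heritability: pd.DataFrame
    covariate_lrt: pd.DataFrame
    covariate_effects: pd.DataFrame
    spearman: pd.DataFrame
    run_log: dict


# ------------------------------------------------------------ stage 1

def simulate_stage(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    try:
        cohort_spec = config.cohort
        if cohort_spec.seed != config.seed:
            cohort_spec = CohortSpec(**{**asdict(cohort_spec), "seed": config.seed})
        df = simulate_cohort(cohort_spec)
        for k, pheno in enumerate(config.phenotypes):
            df[pheno.name] = simulate_ace_phenotype(df, pheno, config.seed, stream_index=k)
        df.to_csv(outdir / "cohort.csv", index=False)
        return df
    except Exception as exc:  # re-tag with the stage name
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("simulate", str(exc)) from exc


def _clip_targets(row: pd.Series) -> GeometryTargets:
    """Map simulated phenotypes to feasible geometry targets."""
    g = lambda k, lo, hi: float(np.clip(row[k], lo, hi)) if k in row else None
    ba_length = g("ba_length", 12.0, 40.0)
    # a bend much above ~15% of the length would force an extreme bow
    ba_bend = min(g("ba_bend", 0.0, 6.0), 0.15 * ba_length)
    ba_tort = g("ba_tortuosity", 0.3, 35.0)
    min_tort = minimum_ba_tortuosity(ba_length, ba_bend)
    ba_tort = max(ba_tort, min_tort * 1.12 + 0.25)

    def va(side):
        kappa = g(f"{side}_va_curvature", 1.5, 25.0)
        tau = g(f"{side}_va_torsion", 0.0, 40.0)
        tort = g(f"{side}_va_tortuosity", 1.0, 30.0)
        tort = min(tort, 0.85 * maximum_va_tortuosity(kappa, tau))
        tort = max(tort, 0.5)
        return kappa, tau, tort

    lk, lt, ltt = va("left")
    rk, rt, rtt = va("right")
    return GeometryTargets(
        ba_length=ba_length,
        ba_mean_diameter=g("ba_diameter", 1.5, 6.0),
        ba_bend=ba_bend,
        ba_tortuosity=ba_tort,
        left_va_diameter=g("left_va_diameter", 0.8, 5.0),
        right_va_diameter=g("right_va_diameter", 0.8, 5.0),
        left_va_curvature=lk,
        right_va_curvature=rk,
        left_va_torsion=lt,
        right_va_torsion=rt,
        left_va_tortuosity=ltt,
        right_va_tortuosity=rtt,
    )


# ------------------------------------------------------------ stage 2

def morphometry_stage(config: PipelineConfig, outdir: Path, cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    try:
        if cohort is None:
            cohort = pd.read_csv(outdir / "cohort.csv")
        net_dir = outdir / "networks"
        if config.write_networks:
            net_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for i, (_, row) in enumerate(cohort.iterrows()):
            targets = _clip_targets(row)
            net = build_vessel_network(targets, seed=config.seed * 100003 + i)
            if config.noise_sd_point or config.noise_sd_radius or config.spur_probability:
                net = perturb_network(
                    net, config.noise_sd_point, config.noise_sd_radius,
                    config.spur_probability, seed=config.seed * 100003 + i,
                )
            if config.write_networks:
                net_io.write_network(net, net_dir / f"{row['subject_id']}.{config.network_format}",
                                     config.network_format)
            rec = network_morphometry(net, spacing=config.spacing, smooth_iters=config.smooth_iters)
            flat = rec.to_dict()
            flat["subject_id"] = row["subject_id"]
            records.append(flat)
        morpho = pd.DataFrame(records)
        morpho.to_csv(outdir / "morphometry.csv", index=False)
        return morpho
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("morphometry", str(exc)) from exc


#: measured columns entering the heritability table, in report order
MEASURED_INDICES = (
    "ba_length", "ba_diameter", "ba_area", "ba_volume", "ba_bend",
    "ba_tortuosity", "ba_torsion",
    "left_va_diameter", "right_va_diameter", "va_difference",
    "left_va_curvature", "right_va_curvature",
    "left_va_tortuosity", "right_va_tortuosity",
    "left_va_torsion", "right_va_torsion",
)


# ------------------------------------------------------------ stage 3

def heritability_stage(config: PipelineConfig, outdir: Path,
                       cohort: pd.DataFrame | None = None,
                       morpho: pd.DataFrame | None = None) -> dict:
    try:
        if cohort is None:
            cohort = pd.read_csv(outdir / "cohort.csv")
        if morpho is None:
            morpho = pd.read_csv(outdir / "morphometry.csv")
        merged = cohort.drop(columns=[c for c in cohort.columns if c in MEASURED_INDICES]) \
                       .merge(morpho, on="subject_id", validate="one_to_one")
        herit_rows, lrt_rows, eff_rows = [], [], []
        for pheno in MEASURED_INDICES:
            if pheno not in merged:
                continue
            fits = {}
            for m in config.models:
                fits[m] = fit_variance_components(merged, pheno, m, config.covariates_model1)
            sat = fit_saturated(merged, pheno, config.covariates_model1)
            best = select_model(fits.values())
            sat_lrt = lrt_vs_saturated(best, sat)
            r_mz = intrapair_correlation(merged, pheno, "MZ", config.covariates_model1)
            r_dz = intrapair_correlation(merged, pheno, "DZ", config.covariates_model1)
            for m, f in fits.items():
                st = f.standardized
                row = {
                    "phenotype": pheno, "model": m, "selected": f is best,
                    "aic": f.aic, "bic": f.bic, "minus2ll": f.deviance,
                    "A": st["A"], "C": st["C"], "E": st["E"],
                    "r_mz": r_mz.r, "r_mz_low": r_mz.ci_low, "r_mz_high": r_mz.ci_high,
                    "r_dz": r_dz.r, "r_dz_low": r_dz.ci_low, "r_dz_high": r_dz.ci_high,
                    "saturated_lrt_p": sat_lrt.p_value if f is best else np.nan,
                }
                if config.profile_cis and f is best and m != "E":
                    model_obj = ACEModel.from_dataframe(merged, pheno, config.covariates_model1, m)
                    for comp in ("A", "C", "E"):
                        if comp in m:
                            lo, hi = profile_ci(model_obj, f, comp)
                            row[f"{comp}_ci_low"], row[f"{comp}_ci_high"] = lo, hi
                herit_rows.append(row)
            # Model 2: add the configured risk factors to the best model
            extra = [c for c in config.covariates_model2 if c not in config.covariates_model1]
            if extra:
                full = fit_variance_components(merged, pheno, best.model_label, config.covariates_model2)
                test = covariate_lrt(full, best)
                lrt_rows.append({
                    "phenotype": pheno,
                    "minus2ll_base": test.deviance_base,
                    "minus2ll_reduced": test.deviance_reduced,
                    "chi_square": test.chi_square, "df": test.df, "p": test.p_value,
                })
                for _, eff in full.covariate_effects(extra).iterrows():
                    eff_rows.append({"phenotype": pheno, **eff.to_dict()})
        herit = pd.DataFrame(herit_rows)
        lrt = pd.DataFrame(lrt_rows)
        effects = pd.DataFrame(eff_rows)
        herit.to_csv(outdir / "heritability.csv", index=False)
        lrt.to_csv(outdir / "covariate_lrt.csv", index=False)
        effects.to_csv(outdir / "covariate_effects.csv", index=False)
        return {"heritability": herit, "covariate_lrt": lrt,
                "covariate_effects": effects, "merged": merged}
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("heritability", str(exc)) from exc


# ------------------------------------------------------------ reports

def descriptives_compare(cohort: pd.DataFrame, extra_continuous=()) -> pd.DataFrame:
    """Zygosity-group descriptives with MZ-vs-DZ tests.

    Continuous variables use Welch's two-sample t-test, binary variables a
    chi-square test on the 2x2 table.  Pair-level variables (age, sex) are
    counted once per pair; subject-level variables use all subjects.
    Constant columns are reported with a flag instead of a p-value.
    """
    mz = cohort[cohort["zygosity"] == "MZ"]
    dz = cohort[cohort["zygosity"] == "DZ"]
    if len(mz) == 0 or len(dz) == 0:
        raise ValueError("both zygosity groups must be non-empty")
    rows = []

    def cont(name, a, b, pair_level=False):
        if pair_level:
            a = a.groupby(cohort.loc[a.index, "pair_id"]).first()
            b = b.groupby(cohort.loc[b.index, "pair_id"]).first()
        flag = ""
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = np.nan
            flag = "constant"
        else:
            _, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({
            "variable": name, "kind": "continuous",
            "mz_mean": a.mean(), "mz_sd": a.std(ddof=1),
            "dz_mean": b.mean(), "dz_sd": b.std(ddof=1),
            "p": p, "flag": flag,
        })

    def binary(name, a, b):
        tbl = np.array([[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]], dtype=float)
        flag = ""
        if np.any(tbl.sum(axis=0) == 0):
            p = np.nan
            flag = "constant"
        else:
            _, p, *_ = sps.chi2_contingency(tbl, correction=False)
        rows.append({
            "variable": name, "kind": "binary",
            "mz_mean": a.mean(), "mz_sd": np.nan,
            "dz_mean": b.mean(), "dz_sd": np.nan,
            "p": p, "flag": flag,
        })

    cont("age", mz["age"], dz["age"], pair_level=True)
    binary("female", (mz["sex"] == "F").astype(int), (dz["sex"] == "F").astype(int))
    for rf in RISK_FACTORS:
        if rf in cohort:
            binary(rf, mz[rf], dz[rf])
    for var in ("height_cm", "weight_kg", "bmi", *extra_continuous):
        if var in cohort:
            cont(var, mz[var], dz[var])
    for var in MEASURED_INDICES:
        if var in cohort:
            cont(var, mz[var], dz[var])
    return pd.DataFrame(rows)


def spearman_matrix(table: pd.DataFrame, variables) -> pd.DataFrame:
    """Symmetric Spearman rank-correlation matrix with average-rank ties."""
    variables = list(variables)
    sub = table[variables].apply(pd.to_numeric, errors="coerce")
    if len(sub.dropna()) < 3:
        raise ValueError("need at least 3 complete rows")
    mat = np.full((len(variables), len(variables)), np.nan)
    for i in range(len(variables)):
        for j in range(i, len(variables)):
            xi, xj = sub.iloc[:, i], sub.iloc[:, j]
            ok = xi.notna() & xj.notna()
            if i == j:
                mat[i, j] = 1.0 if xi[ok].nunique() > 1 else np.nan
                continue
            if xi[ok].nunique() < 2 or xj[ok].nunique() < 2:
                continue  # constant variable: undefined, left missing
            rho = sps.spearmanr(xi[ok], xj[ok]).statistic
            mat[i, j] = mat[j, i] = rho
    # a constant variable still correlates perfectly with itself by
    # convention only when defined; keep the unit diagonal where possible
    np.fill_diagonal(mat, np.where(np.isnan(np.diag(mat)), np.nan, 1.0))
    return pd.DataFrame(mat, index=variables, columns=variables)


def correlation_heatmap(matrix: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * len(matrix) + 2,) * 2)
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run simulate -> morphometry -> heritability and write the bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_stage(config, outdir)
    morpho = morphometry_stage(config, outdir, cohort)
    herit = heritability_stage(config, outdir, cohort, morpho)
    merged = herit["merged"]
    desc = descriptives_compare(merged)
    desc.to_csv(outdir / "descriptives.csv", index=False)
    corr_vars = ["age", "height_cm", "weight_kg", "bmi", *RISK_FACTORS,
                 *[v for v in MEASURED_INDICES if v in merged]]
    spear = spearman_matrix(merged.assign(female=(merged["sex"] == "F").astype(int)), corr_vars)
    spear.to_csv(outdir / "spearman.csv")
    correlation_heatmap(spear, outdir / "spearman.png")
    run_log = {
        "config": config.resolved(),
        "seed": config.seed,
        "versions": {
            "vertebrotwin": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    return ReportBundle(
        descriptives=desc, heritability=herit["heritability"],
        covariate_lrt=herit["covariate_lrt"],
        covariate_effects=herit["covariate_effects"],
        spearman=spear, run_log=run_log,
    )
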