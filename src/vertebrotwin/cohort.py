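"""Synthetic twin cohorts with ACE-structured phenotypes.

The generator emulates a same-sex twin registry sample at the scale of a
typical vertebrobasilar imaging study: ~100 pairs (2:1 MZ:DZ), adult ages
with the MZ group a few years younger, two-thirds female, and binary
cardiovascular risk factors at registry prevalences.  Phenotypes follow the
classical twin model: for subject *j* of pair *i*

    y_ij = mu + sum_k beta_k x_ijk + A_ij + C_i + E_ij

where C is shared within a pair, E is independent, and the additive genetic
deviate A correlates 1 within MZ pairs and 0.5 within DZ pairs (random
mating, no dominance).  The DZ value is built as
sqrt(0.5)*shared + sqrt(0.5)*own so the correlation is exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

RISK_FACTORS = ("smoking", "hypertension", "diabetes", "dyslipidemia", "exercise", "alcohol")


class CohortSpecError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level parameters; defaults reproduce the study-scale sample."""

    n_mz_pairs: int = 67
    n_dz_pairs: int = 33
    age_mean_by_zygosity: dict = field(default_factory=lambda: {"MZ": 49.57, "DZ": 56.0})
    age_sd_by_zygosity: dict = field(default_factory=lambda: {"MZ": 14.42, "DZ": 15.23})
    prop_female: float = 0.66
    risk_factor_prevalences: dict = field(
        default_factory=lambda: {
            "smoking": 0.27,
            "hypertension": 0.305,
            "diabetes": 0.085,
            "dyslipidemia": 0.245,
            "exercise": 0.63,
            "alcohol": 0.54,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_mz_pairs) < 1 or int(self.n_dz_pairs) < 1:
            raise CohortSpecError("pair counts must be >= 1")
        for z in ("MZ", "DZ"):
            if z not in self.age_mean_by_zygosity or z not in self.age_sd_by_zygosity:
                raise CohortSpecError(f"age parameters missing for {z}")
            if not np.isfinite(self.age_mean_by_zygosity[z]):
                raise CohortSpecError("age means must be finite")
            if not (np.isfinite(self.age_sd_by_zygosity[z]) and self.age_sd_by_zygosity[z] > 0):
                raise CohortSpecError("age SDs must be positive")
        if not (0.0 <= self.prop_female <= 1.0):
            raise CohortSpecError("prop_female must be in [0, 1]")
        for name, p in self.risk_factor_prevalences.items():
            if name not in RISK_FACTORS:
                raise CohortSpecError(f"unknown risk factor {name!r}")
            if not (0.0 <= p <= 1.0 and np.isfinite(p)):
                raise CohortSpecError(f"prevalence of {name!r} must be in [0, 1]")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One phenotype's mean model and raw ACE variance components."""

    name: str
    mean: float
    var_a: float
    var_c: float
    var_e: float
    covariate_betas: dict = field(default_factory=dict)
    covariate_refs: dict = field(default_factory=dict)  # centring values

    def __post_init__(self) -> None:
        for nm in ("var_a", "var_c", "var_e"):
            v = getattr(self, nm)
            if not np.isfinite(v) or v < 0:
                raise CohortSpecError(f"{self.name}: {nm} must be finite and >= 0")
        if self.var_a + self.var_c + self.var_e <= 0:
            raise CohortSpecError(f"{self.name}: total variance must be positive")
        if not np.isfinite(self.mean):
            raise CohortSpecError(f"{self.name}: mean must be finite")

    @property
    def total_variance(self) -> float:
        return self.var_a + self.var_c + self.var_e


def _pair_correlated_normal(rng, is_mz: np.ndarray, dz_correlation: float = 0.5) -> np.ndarray:
    """(n_pairs, 2) standard-normal deviates with twin-pair correlation.

    MZ pairs share one deviate; DZ pairs get sqrt(rho)*shared +
    sqrt(1-rho)*own with rho = ``dz_correlation``.
    """
    n = len(is_mz)
    shared = rng.normal(size=n)
    own = rng.normal(size=(n, 2))
    out = np.empty((n, 2))
    out[is_mz] = shared[is_mz, None]
    r = np.sqrt(dz_correlation)
    q = np.sqrt(1.0 - dz_correlation)
    out[~is_mz] = r * shared[~is_mz, None] + q * own[~is_mz]
    return out


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the subject table: one row per subject, two per pair.

    Age and sex are pair-level (same-sex twin design); risk factors are
    subject-level Bernoulli draws; height carries a twin-correlated
    component (MZ 0.8, DZ 0.4 of its variance shared) around sex-specific
    means; weight is derived from a twin-correlated BMI so that
    BMI = weight / height^2 holds exactly.
    """
    rng = substream(spec.seed, "cohort")
    n_mz, n_dz = int(spec.n_mz_pairs), int(spec.n_dz_pairs)
    n_pairs = n_mz + n_dz
    is_mz = np.concatenate([np.ones(n_mz, bool), np.zeros(n_dz, bool)])
    zyg = np.where(is_mz, "MZ", "DZ")

    age_mean = np.where(is_mz, spec.age_mean_by_zygosity["MZ"], spec.age_mean_by_zygosity["DZ"])
    age_sd = np.where(is_mz, spec.age_sd_by_zygosity["MZ"], spec.age_sd_by_zygosity["DZ"])
    age = rng.normal(age_mean, age_sd)
    female = rng.uniform(size=n_pairs) < spec.prop_female

    # height: sex-specific mean, twin-correlated deviation (heritable trait)
    h_mean = np.where(female, 162.9, 177.7)
    h_g = _pair_correlated_normal(rng, is_mz)         # genetic-like, rDZ = 0.5
    h_e = rng.normal(size=(n_pairs, 2))
    height = h_mean[:, None] + 6.5 * (np.sqrt(0.8) * h_g + np.sqrt(0.2) * h_e)
    # BMI: twin-correlated around the adult mean
    b_g = _pair_correlated_normal(rng, is_mz)
    b_e = rng.normal(size=(n_pairs, 2))
    bmi = 25.74 + 4.59 * (np.sqrt(0.6) * b_g + np.sqrt(0.4) * b_e)
    bmi = np.maximum(bmi, 15.0)
    weight = bmi * (height / 100.0) ** 2

    rows = []
    sid = 1
    for i in range(n_pairs):
        for j in range(2):
            row = {
                "subject_id": f"S{sid:04d}",
                "pair_id": f"P{i + 1:03d}",
                "zygosity": zyg[i],
                "age": float(age[i]),
                "sex": "F" if female[i] else "M",
            }
            rows.append(row)
            sid += 1
    df = pd.DataFrame(rows)
    for name in RISK_FACTORS:
        p = spec.risk_factor_prevalences.get(name, 0.0)
        df[name] = (rng.uniform(size=2 * n_pairs) < p).astype(int)
    df["height_cm"] = height.ravel()
    df["weight_kg"] = weight.ravel()
    df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    return df


class MissingCovariateError(KeyError):
    pass


def covariate_design(cohort: pd.DataFrame, names) -> np.ndarray:
    """Numeric covariate matrix; 'sex' is encoded as male = 1, female = 0."""
    cols = []
    for nm in names:
        if nm == "sex":
            if "sex" not in cohort:
                raise MissingCovariateError("sex")
            cols.append((cohort["sex"].to_numpy() == "M").astype(float))
        else:
            if nm not in cohort:
                raise MissingCovariateError(nm)
            cols.append(pd.to_numeric(cohort[nm]).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def simulate_ace_phenotype(cohort: pd.DataFrame, pheno: PhenotypeSpec, seed: int, stream_index: int = 0) -> pd.Series:
    """Simulate one ACE-structured phenotype column for a cohort table."""
    if not {"pair_id", "zygosity"}.issubset(cohort.columns):
        raise CohortSpecError("cohort table lacks pair structure (pair_id / zygosity)")
    pair_ids = cohort["pair_id"].to_numpy()
    uniq, pair_index = np.unique(pair_ids, return_inverse=True)
    n_pairs = len(uniq)
    if len(cohort) != 2 * n_pairs:
        raise CohortSpecError("cohort must contain exactly two subjects per pair")
    # subject slot within pair (0/1) in table order
    slot = np.zeros(len(cohort), dtype=int)
    seen: dict = {}
    for k, pid in enumerate(pair_ids):
        slot[k] = seen.get(pid, 0)
        seen[pid] = slot[k] + 1
    is_mz_pair = np.zeros(n_pairs, dtype=bool)
    is_mz_pair[pair_index] = cohort["zygosity"].to_numpy() == "MZ"

    rng = substream(seed, "phenotype", stream_index)
    a = _pair_correlated_normal(rng, is_mz_pair) * np.sqrt(pheno.var_a)
    c = rng.normal(size=n_pairs)[:, None] * np.sqrt(pheno.var_c) * np.ones((1, 2))
    e = rng.normal(size=(n_pairs, 2)) * np.sqrt(pheno.var_e)

    names = list(pheno.covariate_betas)
    X = covariate_design(cohort, names)
    refs = np.array([pheno.covariate_refs.get(nm, 0.0) for nm in names])
    betas = np.array([pheno.covariate_betas[nm] for nm in names])
    fixed = (X - refs) @ betas if names else np.zeros(len(cohort))

    y = pheno.mean + fixed + (a + c + e)[pair_index, slot]
    return pd.Series(y, index=cohort.index, name=pheno.name)


# ------------------------------------------------------- default phenotypes

def default_phenotype_specs() -> list[PhenotypeSpec]:
    """The 16 vertebrobasilar indices with study-scale means, variances and
    best-model variance shares; smoking/height slopes on the basilar and
    left-VA dimensions are the only non-zero covariate effects."""
    height_ref = {"height_cm": 167.95}

    def spec(name, mean, sd, A, C, betas=None, refs=None):
        var = sd * sd
        E = 1.0 - A - C
        return PhenotypeSpec(
            name=name, mean=mean,
            var_a=A * var, var_c=C * var, var_e=E * var,
            covariate_betas=betas or {}, covariate_refs=refs or {},
        )

    return [
        spec("ba_length", 24.08, 4.41, 0.63, 0.0),
        spec("ba_diameter", 3.42, 0.57, 0.0, 0.354,
             {"smoking": 0.212, "height_cm": 0.025}, height_ref),
        spec("ba_area", 9.43, 3.02, 0.0, 0.354,
             {"smoking": 0.188, "height_cm": 0.022}, height_ref),
        spec("ba_volume", 218.28, 81.32, 0.601, 0.0,
             {"height_cm": 0.03}, height_ref),
        spec("ba_bend", 2.57, 2.29, 0.0, 0.164),
        spec("ba_tortuosity", 6.37, 3.0, 0.0, 0.475),
        spec("ba_torsion", 11.29, 4.0, 0.0, 0.0),
        spec("left_va_diameter", 2.44, 0.72, 0.0, 0.232, {"smoking": 0.22}),
        spec("right_va_diameter", 2.36, 0.61, 0.0, 0.41),
        spec("va_difference", 0.75, 0.62, 0.23, 0.0),
        spec("left_va_curvature", 7.79, 2.0, 0.0, 0.329),
        spec("right_va_curvature", 8.10, 2.0, 0.216, 0.0),
        spec("left_va_tortuosity", 11.77, 5.0, 0.476, 0.0),
        spec("right_va_tortuosity", 11.57, 5.0, 0.557, 0.0),
        spec("left_va_torsion", 12.34, 4.0, 0.0, 0.0),
        spec("right_va_torsion", 12.62, 4.0, 0.0, 0.0),
    ]
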