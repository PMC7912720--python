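"""Classical twin-design variance-component models (ACE family).

Maximum-likelihood structural models for paired phenotype data: the
phenotypic variance is decomposed into additive genetic (A), shared
environmental (C) and unique environmental (E) parts using the different
within-pair covariance of monozygotic (genetic correlation 1) and dizygotic
(0.5) twin pairs,

    Sigma_MZ = [[v, a2 + c2], [a2 + c2, v]],
    Sigma_DZ = [[v, a2/2 + c2], [a2/2 + c2, v]],   v = a2 + c2 + e2,

with a per-subject linear mean model (intercept + covariates, shared across
twin order and zygosity).  Non-negativity of the components is enforced by
optimising unconstrained path coefficients whose squares are the
components.  The module follows the statsmodels idiom: build an
:class:`ACEModel` (or :class:`SaturatedModel`) from data, call ``fit()``,
interrogate the returned results object.

Conventions: AIC = -2LL + 2k, BIC = -2LL + k ln(N) with k the number of
free parameters and N the number of subjects (twice the pair count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import covariate_design

MODELS = ("ACE", "AE", "CE", "E")
_COMPONENTS = {"ACE": ("A", "C", "E"), "AE": ("A", "E"), "CE": ("C", "E"), "E": ("E",)}
_E_FLOOR_FRACTION = 1e-8  # e2 floor relative to total variance


class ConvergenceError(RuntimeError):
    pass


class CollinearityError(ValueError):
    pass


class NestingError(ValueError):
    pass


# ===================================================================== data

@dataclass(frozen=True)
class TwinPairData:
    """Complete twin pairs: phenotype values and per-subject covariates.

    ``y`` is (n_pairs, 2); ``x`` is (n_pairs, 2, p) including the leading
    intercept column; ``is_mz`` is boolean per pair.
    """

    y: np.ndarray
    x: np.ndarray
    is_mz: np.ndarray
    exog_names: tuple
    n_dropped_pairs: int = 0

    @property
    def n_pairs(self) -> int:
        return self.y.shape[0]

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_pairs

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phenotype: str, covariates=("age", "sex")) -> "TwinPairData":
        """Assemble pairs from a one-row-per-subject table.

        Pairs with a missing member, a non-finite phenotype or missing
        covariates are dropped and counted in ``n_dropped_pairs``.
        """
        if phenotype not in df:
            raise KeyError(f"phenotype column {phenotype!r} not found")
        covariates = tuple(covariates)
        X = covariate_design(df, covariates)
        y = pd.to_numeric(df[phenotype]).to_numpy(dtype=float)
        zyg = df["zygosity"].to_numpy()
        pid = df["pair_id"].to_numpy()

        order = np.argsort(pid, kind="stable")
        pid_s, y_s, X_s, zyg_s = pid[order], y[order], X[order], zyg[order]
        uniq, starts, counts = np.unique(pid_s, return_index=True, return_counts=True)
        complete = counts == 2
        dropped = int(np.sum(~complete))
        idx0 = starts[complete]
        yy = np.column_stack([y_s[idx0], y_s[idx0 + 1]])
        xx = np.stack([X_s[idx0], X_s[idx0 + 1]], axis=1)
        finite = np.all(np.isfinite(yy), axis=1) & np.all(np.isfinite(xx), axis=(1, 2))
        dropped += int(np.sum(~finite))
        yy, xx = yy[finite], xx[finite]
        mz = (zyg_s[idx0] == "MZ")[finite]
        if len(yy) == 0:
            raise ValueError("no complete pairs")
        xx = np.concatenate([np.ones((xx.shape[0], 2, 1)), xx], axis=2)
        names = ("intercept",) + covariates
        data = cls(yy, xx, mz, names, dropped)
        data._check_collinearity()
        return data

    def _check_collinearity(self) -> None:
        flat = self.x.reshape(-1, self.x.shape[2])
        if flat.shape[0] >= flat.shape[1]:
            s = np.linalg.svd(flat, compute_uv=False)
            if s[-1] < 1e-10 * s[0]:
                raise CollinearityError(
                    "covariate design is rank deficient (duplicated or "
                    "linearly dependent covariates)"
                )

    def phenotype_variance(self) -> float:
        return float(np.var(self.y))


# ------------------------------------------------------------ likelihoods

def _pair_loglike(y, x, is_mz, beta, cov_mz, cov_dz, var):
    """Sum of bivariate-normal log densities over pairs."""
    resid = y - x @ beta
    d1, d2 = resid[:, 0], resid[:, 1]
    cov = np.where(is_mz, cov_mz, cov_dz)
    with np.errstate(over="ignore", invalid="ignore"):
        det = var * var - cov * cov
        if not np.all(np.isfinite(det)) or np.any(det <= 0) or var <= 0:
            return -np.inf
        quad = (var * (d1 * d1 + d2 * d2) - 2.0 * cov * d1 * d2) / det
        out = float(-len(d1) * np.log(2.0 * np.pi) - 0.5 * np.sum(np.log(det)) - 0.5 * np.sum(quad))
    return out if np.isfinite(out) else -np.inf


def _gls_beta(y, x, is_mz, cov_mz, cov_dz, var):
    """Closed-form GLS mean coefficients for fixed covariance structure."""
    cov = np.where(is_mz, cov_mz, cov_dz)
    det = var * var - cov * cov
    # Sigma^-1 = [[var, -cov], [-cov, var]] / det
    w11 = var / det
    w12 = -cov / det
    x1, x2 = x[:, 0, :], x[:, 1, :]
    y1, y2 = y[:, 0], y[:, 1]
    XtWX = (
        np.einsum("i,ij,ik->jk", w11, x1, x1)
        + np.einsum("i,ij,ik->jk", w11, x2, x2)
        + np.einsum("i,ij,ik->jk", w12, x1, x2)
        + np.einsum("i,ij,ik->jk", w12, x2, x1)
    )
    XtWy = (
        np.einsum("i,ij,i->j", w11, x1, y1)
        + np.einsum("i,ij,i->j", w11, x2, y2)
        + np.einsum("i,ij,i->j", w12, x1, y2)
        + np.einsum("i,ij,i->j", w12, x2, y1)
    )
    return np.linalg.solve(XtWX, XtWy)


def _paths_to_components(paths, model):
    comps = dict.fromkeys(("A", "C", "E"), 0.0)
    for name, p in zip(_COMPONENTS[model], paths):
        comps[name] = float(p * p)
    return comps["A"], comps["C"], comps["E"]


# ===================================================================== fits

@dataclass
class VCFit:
    """A fitted variance-component (or saturated) model."""

    model_label: str
    data: TwinPairData
    params_beta: np.ndarray
    var_a: float
    var_c: float
    var_e: float
    log_likelihood: float
    k_params: int
    cov_structure: dict = field(default_factory=dict)  # saturated extras
    converged: bool = True
    _beta_cov: np.ndarray | None = None

    # -- scalar summaries ------------------------------------------------
    @property
    def total_variance(self) -> float:
        return self.var_a + self.var_c + self.var_e

    @property
    def standardized(self) -> dict:
        v = self.total_variance
        return {"A": self.var_a / v, "C": self.var_c / v, "E": self.var_e / v}

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return self.deviance + self.k_params * np.log(self.data.n_subjects)

    @property
    def implied_r_mz(self) -> float:
        return (self.var_a + self.var_c) / self.total_variance

    @property
    def implied_r_dz(self) -> float:
        return (0.5 * self.var_a + self.var_c) / self.total_variance

    def covariate_effects(self, names) -> pd.DataFrame:
        """Mean-model slopes with Wald 95% CIs (observed information)."""
        if self._beta_cov is None:
            raise ConvergenceError("no parameter covariance available")
        out = []
        for nm in names:
            if nm not in self.data.exog_names:
                raise KeyError(f"covariate {nm!r} not in the fitted mean model")
            j = self.data.exog_names.index(nm)
            b = self.params_beta[j]
            se = float(np.sqrt(self._beta_cov[j, j]))
            out.append({"covariate": nm, "beta": b, "se": se,
                        "ci_low": b - 1.959963984540054 * se,
                        "ci_high": b + 1.959963984540054 * se})
        return pd.DataFrame(out)

    def summary(self) -> str:
        lines = [
            f"{self.model_label} twin variance-component model",
            f"  pairs: {self.data.n_pairs} ({int(self.data.is_mz.sum())} MZ, "
            f"{int((~self.data.is_mz).sum())} DZ); subjects: {self.data.n_subjects}",
            f"  logLik {self.log_likelihood:.4f}  -2LL {self.deviance:.4f}  "
            f"AIC {self.aic:.4f}  BIC {self.bic:.4f}  k={self.k_params}",
        ]
        if self.model_label != "saturated":
            st = self.standardized
            lines.append(
                f"  raw: a2={self.var_a:.4f} c2={self.var_c:.4f} e2={self.var_e:.4f}"
            )
            lines.append(
                f"  standardized: A={st['A']:.3f} C={st['C']:.3f} E={st['E']:.3f}"
            )
        for nm, b in zip(self.data.exog_names, self.params_beta):
            lines.append(f"  beta[{nm}] = {b:.5f}")
        return "\n".join(lines)


class ACEModel:
    """Structured twin model with components chosen by ``model_label``."""

    def __init__(self, data: TwinPairData, model_label: str = "ACE"):
        if model_label not in MODELS:
            raise ValueError(f"model_label must be one of {MODELS}")
        self.data = data
        self.model_label = model_label

    @classmethod
    def from_dataframe(cls, df, phenotype, covariates=("age", "sex"), model_label="ACE"):
        return cls(TwinPairData.from_dataframe(df, phenotype, covariates), model_label)

    # -- likelihood in terms of free parameters -------------------------
    def _unpack(self, theta):
        p = self.data.x.shape[2]
        beta = theta[:p]
        a2, c2, e2 = _paths_to_components(theta[p:], self.model_label)
        return beta, a2, c2, e2

    def loglike(self, theta) -> float:
        beta, a2, c2, e2 = self._unpack(theta)
        v = a2 + c2 + e2
        floor = _E_FLOOR_FRACTION * max(v, self.data.phenotype_variance())
        e2 = max(e2, floor)
        v = a2 + c2 + e2
        return _pair_loglike(
            self.data.y, self.data.x, self.data.is_mz, beta,
            a2 + c2, 0.5 * a2 + c2, v,
        )

    def _share_starts(self, n_starts: int):
        """Falconer method-of-moments start plus jittered alternatives."""
        d = self.data
        flat_x = d.x.reshape(-1, d.x.shape[2])
        beta0, *_ = np.linalg.lstsq(flat_x, d.y.reshape(-1), rcond=None)
        resid = d.y - d.x @ beta0

        def _r(group):
            r1, r2 = resid[group, 0], resid[group, 1]
            both = np.concatenate([np.column_stack([r1, r2]), np.column_stack([r2, r1])])
            if len(both) < 3 or np.std(both[:, 0]) == 0:
                return 0.0
            return float(np.corrcoef(both[:, 0], both[:, 1])[0, 1])

        r_mz, r_dz = _r(d.is_mz), _r(~d.is_mz)
        A0 = float(np.clip(2.0 * (r_mz - r_dz), 0.0, 0.9))
        C0 = float(np.clip(2.0 * r_dz - r_mz, 0.0, 0.9))
        base = {"A": A0, "C": C0}
        starts = [base]
        rng = np.random.Generator(np.random.PCG64(12345))
        for _ in range(n_starts - 1):
            starts.append({
                "A": float(np.clip(A0 + rng.uniform(-0.25, 0.25), 0.0, 0.95)),
                "C": float(np.clip(C0 + rng.uniform(-0.25, 0.25), 0.0, 0.95)),
            })
        return starts

    def fit(self, n_starts: int = 5, gtol: float = 1e-8) -> VCFit:
        """Maximum-likelihood fit.

        The mean coefficients and the total variance are concentrated out in
        closed form, leaving at most two free standardized shares, which are
        optimised quasi-Newton under box constraints from multiple starts
        (a Falconer-type moment start plus jittered restarts).
        """
        comps = _COMPONENTS[self.model_label]
        free = [c for c in comps if c != "E"]
        cap = 1.0 - 1e-8

        def shares_ll(vec):
            shares = dict(zip(free, vec))
            a = shares.get("A", 0.0)
            c = shares.get("C", 0.0)
            if a + c > cap:  # keep e2 strictly positive
                over = (a + c) / cap
                a, c = a / over, c / over
            return self._correlation_profile_ll(a + c, 0.5 * a + c)

        if not free:
            best_vec = np.zeros(0)
        else:
            best = None
            for start in self._share_starts(n_starts):
                x0 = np.array([min(start.get(c, 0.1), 0.9) for c in free])
                res = optimize.minimize(
                    lambda v: -shares_ll(v), x0, method="L-BFGS-B",
                    bounds=[(0.0, cap)] * len(free),
                    options={"maxiter": 500, "gtol": gtol, "ftol": 1e-14},
                )
                if best is None or res.fun < best.fun:
                    best = res
            if best is None or not np.isfinite(best.fun):
                raise ConvergenceError(f"{self.model_label} fit failed: no finite optimum")
            best_vec = best.x

        shares = dict(zip(free, best_vec))
        tA, tC = shares.get("A", 0.0), shares.get("C", 0.0)
        if tA + tC > cap:
            over = (tA + tC) / cap
            tA, tC = tA / over, tC / over
        # recover the scale and mean at the optimum
        d = self.data
        r_mz, r_dz = tA + tC, 0.5 * tA + tC
        beta = _gls_beta(d.y, d.x, d.is_mz, r_mz, r_dz, 1.0)
        resid = d.y - d.x @ beta
        r = np.where(d.is_mz, r_mz, r_dz)
        q = (resid[:, 0] ** 2 + resid[:, 1] ** 2 - 2.0 * r * resid[:, 0] * resid[:, 1]) / (1.0 - r * r)
        sigma2 = float(np.sum(q)) / (2.0 * d.n_pairs)
        a2, c2 = tA * sigma2, tC * sigma2
        e2 = max((1.0 - tA - tC) * sigma2,
                 _E_FLOOR_FRACTION * max(sigma2, self.data.phenotype_variance()))
        ll = _pair_loglike(d.y, d.x, d.is_mz, beta, a2 + c2, 0.5 * a2 + c2, a2 + c2 + e2)
        p = d.x.shape[2]
        k = p + len(comps)
        fit = VCFit(
            model_label=self.model_label, data=self.data, params_beta=beta,
            var_a=a2, var_c=c2, var_e=e2, log_likelihood=ll, k_params=k,
        )
        fit._beta_cov = self._beta_covariance(a2, c2, e2)
        return fit

    def _beta_covariance(self, a2, c2, e2):
        """Exact GLS covariance of the mean coefficients."""
        d = self.data
        v = a2 + c2 + e2
        cov = np.where(d.is_mz, a2 + c2, 0.5 * a2 + c2)
        det = v * v - cov * cov
        w11 = v / det
        w12 = -cov / det
        x1, x2 = d.x[:, 0, :], d.x[:, 1, :]
        XtWX = (
            np.einsum("i,ij,ik->jk", w11, x1, x1)
            + np.einsum("i,ij,ik->jk", w11, x2, x2)
            + np.einsum("i,ij,ik->jk", w12, x1, x2)
            + np.einsum("i,ij,ik->jk", w12, x2, x1)
        )
        return np.linalg.inv(XtWX)

    # -- profile likelihood on the standardized scale --------------------
    def _correlation_profile_ll(self, r_mz: float, r_dz: float) -> float:
        """Max LL for fixed implied correlations (closed form).

        With the within-pair correlations fixed, the GLS mean coefficients
        do not depend on the overall scale and the total-variance MLE is the
        average Mahalanobis quadratic form, so no iteration is needed.
        """
        d = self.data
        r_mz = min(r_mz, 1.0 - 1e-10)
        r_dz = min(r_dz, 1.0 - 1e-10)
        beta = _gls_beta(d.y, d.x, d.is_mz, r_mz, r_dz, 1.0)
        resid = d.y - d.x @ beta
        d1, d2 = resid[:, 0], resid[:, 1]
        r = np.where(d.is_mz, r_mz, r_dz)
        q = (d1 * d1 + d2 * d2 - 2.0 * r * d1 * d2) / (1.0 - r * r)
        n = d.n_pairs
        sigma2 = float(np.sum(q)) / (2.0 * n)
        if sigma2 <= 0:
            return -np.inf
        return float(
            -n * np.log(2.0 * np.pi) - n * np.log(sigma2)
            - 0.5 * np.sum(np.log(1.0 - r * r)) - n
        )

    def _profile_loglike(self, component: str, share: float) -> float:
        """Max LL with the standardized share of ``component`` fixed.

        The mean and total variance are concentrated out in closed form;
        for three-component models the split of the remaining share between
        the two free components is optimised by a bounded 1-D search.
        """
        comps = _COMPONENTS[self.model_label]
        if component not in comps:
            raise ValueError(f"{component} is not free in the {self.model_label} model")
        others = [c for c in comps if c != component]

        def ll_of_shares(shares: dict) -> float:
            a = shares.get("A", 0.0)
            c = shares.get("C", 0.0)
            return self._correlation_profile_ll(a + c, 0.5 * a + c)

        if len(others) == 0:
            return ll_of_shares({component: share})
        if len(others) == 1:
            return ll_of_shares({component: share, others[0]: 1.0 - share})

        def neg(f):
            return -ll_of_shares({
                component: share,
                others[0]: (1.0 - share) * f,
                others[1]: (1.0 - share) * (1.0 - f),
            })

        res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-8})
        return -res.fun


def profile_ci(model: ACEModel, fit: VCFit, component: str, level: float = 0.95):
    """Likelihood-profile CI for a standardized component, truncated to [0, 1].

    Bounds solve 2*(LLmax - LLprofile(t)) = chi2_1(level); a bound that the
    profile cannot bracket is returned at the search edge with a flag.
    """
    if model.model_label == "E":
        # E is the only component: its standardized share is identically 1.
        return (1.0, 1.0) if component == "E" else (0.0, 0.0)
    crit = stats.chi2.ppf(level, 1)
    t_hat = fit.standardized[component]
    eps = 1e-6
    # the closed-form profile concentrates the mean and scale exactly, so it
    # can sit a hair above the iterative optimum; reference the larger
    ll_max = max(fit.log_likelihood, model._profile_loglike(component, t_hat))

    def drop(t):
        return 2.0 * (ll_max - model._profile_loglike(component, float(np.clip(t, 0.0, 1.0 - 1e-9))))

    def search(side):
        edge = 0.0 if side == "lower" else 1.0
        if drop(edge if side == "lower" else 1.0 - 1e-6) <= crit:
            return edge
        lo, hi = (edge, t_hat) if side == "lower" else (t_hat, 1.0 - 1e-6)
        try:
            return float(optimize.brentq(lambda t: drop(t) - crit, lo, hi,
                                         xtol=1e-4, rtol=1e-6, maxiter=100))
        except ValueError:
            # no sign change inside the bracket (flat profile): report the
            # searched edge rather than failing
            return edge

    lower = float(np.clip(search("lower"), 0.0, 1.0))
    upper = float(np.clip(search("upper"), 0.0, 1.0))
    if t_hat <= eps:
        lower = 0.0
    return lower, upper


# ================================================================ saturated

class SaturatedModel:
    """Unstructured reference model: per-zygosity variances for each twin
    position and a free within-pair covariance (6 covariance parameters),
    with the covariate-adjusted mean shared across twin order and groups."""

    def __init__(self, data: TwinPairData):
        self.data = data

    @classmethod
    def from_dataframe(cls, df, phenotype, covariates=("age", "sex")):
        return cls(TwinPairData.from_dataframe(df, phenotype, covariates))

    def _covariances(self, theta):
        """Cholesky-parameterised 2x2 covariances per zygosity group."""
        out = []
        for g in range(2):
            l11, l21, l22 = theta[3 * g: 3 * g + 3]
            out.append((l11 * l11, l11 * l21, l21 * l21 + l22 * l22))
        return out

    def _concentrated_nll(self, theta) -> float:
        """-LL over the 6 covariance parameters, mean concentrated by GLS."""
        d = self.data
        covs = self._covariances(theta)
        w = np.empty((d.n_pairs, 3))  # w11, w12, w22 of Sigma^-1
        logdet = 0.0
        for (s11, s12, s22), grp in zip(covs, (d.is_mz, ~d.is_mz)):
            det = s11 * s22 - s12 * s12
            if det <= 0 or s11 <= 0 or s22 <= 0:
                return 1e12
            w[grp, 0] = s22 / det
            w[grp, 1] = -s12 / det
            w[grp, 2] = s11 / det
            logdet += np.sum(grp) * np.log(det)
        x1, x2 = d.x[:, 0, :], d.x[:, 1, :]
        y1, y2 = d.y[:, 0], d.y[:, 1]
        XtWX = (
            np.einsum("i,ij,ik->jk", w[:, 0], x1, x1)
            + np.einsum("i,ij,ik->jk", w[:, 2], x2, x2)
            + np.einsum("i,ij,ik->jk", w[:, 1], x1, x2)
            + np.einsum("i,ij,ik->jk", w[:, 1], x2, x1)
        )
        XtWy = (
            np.einsum("i,ij,i->j", w[:, 0], x1, y1)
            + np.einsum("i,ij,i->j", w[:, 2], x2, y2)
            + np.einsum("i,ij,i->j", w[:, 1], x1, y2)
            + np.einsum("i,ij,i->j", w[:, 1], x2, y1)
        )
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return 1e12
        d1 = y1 - x1 @ beta
        d2 = y2 - x2 @ beta
        quad = np.sum(w[:, 0] * d1 * d1 + 2.0 * w[:, 1] * d1 * d2 + w[:, 2] * d2 * d2)
        ll = -d.n_pairs * np.log(2.0 * np.pi) - 0.5 * logdet - 0.5 * quad
        self._last_beta = beta
        return -float(ll)

    def fit(self) -> VCFit:
        d = self.data
        p = d.x.shape[2]
        flat_x = d.x.reshape(-1, p)
        beta0, *_ = np.linalg.lstsq(flat_x, d.y.reshape(-1), rcond=None)
        resid = d.y - d.x @ beta0
        theta0 = []
        for grp in (d.is_mz, ~d.is_mz):
            r = resid[grp]
            S = np.cov(r.T) if len(r) > 1 else np.eye(2)
            S = S + 1e-8 * np.eye(2)
            L = np.linalg.cholesky(S)
            theta0 += [L[0, 0], L[1, 0], L[1, 1]]
        res = optimize.minimize(
            self._concentrated_nll, np.asarray(theta0), method="L-BFGS-B",
            options={"maxiter": 4000, "gtol": 1e-9, "ftol": 1e-14},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            raise ConvergenceError("saturated fit failed")
        self._concentrated_nll(res.x)  # refresh _last_beta at the optimum
        beta = self._last_beta
        cov_structure = {}
        for (s11, s12, s22), name in zip(self._covariances(res.x), ("MZ", "DZ")):
            cov_structure[name] = {"var1": s11, "var2": s22, "cov": s12}
        v = float(np.mean([cov_structure[g]["var1"] + cov_structure[g]["var2"]
                           for g in ("MZ", "DZ")])) / 2.0
        return VCFit(
            model_label="saturated", data=d, params_beta=beta,
            var_a=0.0, var_c=0.0, var_e=v,
            log_likelihood=-res.fun, k_params=p + 6,
            cov_structure=cov_structure,
        )


# ============================================================== comparisons

@dataclass(frozen=True)
class CorrelationResult:
    zygosity: str
    r: float
    ci_low: float
    ci_high: float
    n_pairs: int
    defined: bool = True


def intrapair_correlation(df: pd.DataFrame, phenotype: str, zygosity: str,
                          adjust=("age", "sex")) -> CorrelationResult:
    """One-way ANOVA intraclass correlation of a zygosity group.

    The phenotype is first adjusted for the listed covariates by OLS over
    the full sample; the ICC of the pair structure is then
    (MSB - MSW) / (MSB + MSW) with pairs as groups of size two, and the CI
    comes from the Fisher z transform with the pair count as effective n.
    """
    data = TwinPairData.from_dataframe(df, phenotype, tuple(adjust))
    flat_x = data.x.reshape(-1, data.x.shape[2])
    beta, *_ = np.linalg.lstsq(flat_x, data.y.reshape(-1), rcond=None)
    resid = data.y - data.x @ beta
    grp = data.is_mz if zygosity == "MZ" else ~data.is_mz
    r = resid[grp]
    n = len(r)
    if n < 3:
        raise ValueError("need at least 3 pairs for an intraclass correlation")
    pair_means = r.mean(axis=1)
    grand = r.mean()
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((r - pair_means[:, None]) ** 2) / n
    if msb + msw <= 1e-300:
        return CorrelationResult(zygosity, np.nan, np.nan, np.nan, n, defined=False)
    icc = float((msb - msw) / (msb + msw))
    icc_c = np.clip(icc, -0.999999, 0.999999)
    z = np.arctanh(icc_c)
    se = 1.0 / np.sqrt(n - 3) if n > 3 else np.inf
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return CorrelationResult(zygosity, icc, float(lo), float(hi), n)


@dataclass(frozen=True)
class LRTResult:
    deviance_base: float
    deviance_reduced: float
    chi_square: float
    df: int
    p_value: float


def lrt_from_deviances(deviance_base: float, deviance_reduced: float, df: int) -> LRTResult:
    """Likelihood-ratio test from two printed/stored deviances (-2LL)."""
    chi2 = deviance_reduced - deviance_base
    if chi2 < -1e-6:
        raise NestingError("reduced model fits better than the base model")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(deviance_base, deviance_reduced, chi2, df, p)


def lrt_vs_saturated(structured: VCFit, saturated: VCFit) -> LRTResult:
    df = saturated.k_params - structured.k_params
    return lrt_from_deviances(saturated.deviance, structured.deviance, df)


def covariate_lrt(fit_full: VCFit, fit_reduced: VCFit) -> LRTResult:
    """Mean-model likelihood-ratio test of nested covariate sets."""
    full = set(fit_full.data.exog_names)
    red = set(fit_reduced.data.exog_names)
    if not red.issubset(full):
        raise NestingError("reduced covariates are not a subset of the full model")
    df = len(full) - len(red)
    return lrt_from_deviances(fit_full.deviance, fit_reduced.deviance, df)


def select_model(fits) -> VCFit:
    """Minimum-AIC choice; ties resolved by BIC, then by fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fitted models to select from")

    def key(f):
        k = getattr(f, "k_params", getattr(f, "k", 0))
        return (round(f.aic, 10), round(f.bic, 10), k)

    return min(fits, key=key)


def fit_variance_components(df, phenotype, model_label="ACE", covariates=("age", "sex"), **kw) -> VCFit:
    """Convenience wrapper: build the model from a subject table and fit."""
    return ACEModel.from_dataframe(df, phenotype, covariates, model_label).fit(**kw)


def fit_saturated(df, phenotype, covariates=("age", "sex")) -> VCFit:
    return SaturatedModel.from_dataframe(df, phenotype, covariates).fit()
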