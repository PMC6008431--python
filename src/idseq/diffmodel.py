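"""Per-antibody negative-binomial differential model with likelihood-ratio test.

Distinct-UMI counts are overdispersed relative to Poisson, so each antibody's
counts across wells are modelled as NB2:

    y_w ~ NB(mu_w, alpha),   mu_w = s_w * exp(x_w' beta),   Var = mu + alpha*mu^2

with the well size factor s_w entering as a log offset, treatment as the
contrast of interest and replicate/batch as fixed blocking covariates.  The
treatment effect is tested by a likelihood-ratio test of the full design
against the design without the treatment term; the per-antibody score fed to
the screen layer is the signed p-value, sign(estimate) * (-log10 p).

Fitting alternates an IRLS step for the regression coefficients (at fixed
dispersion) with a bounded one-dimensional maximum-likelihood step for the
dispersion, starting from a Poisson fit.  The dispersion is bounded below at
1e-8, where the model degenerates to Poisson regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 1e4
P_FLOOR = 1e-300


def nb_loglike(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood of counts ``y`` at means ``mu`` and dispersion ``alpha``."""
    r = 1.0 / alpha
    mu = np.clip(mu, 1e-12, None)
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


@dataclass
class ModelSpec:
    """Design description for the differential model.

    Parameters
    ----------
    treatment : str
        Column of the plate map holding the treatment factor.
    reference : str, optional
        Treatment level used as baseline; defaults to the lexicographically
        first level.
    blocking : tuple of str
        Plate-map columns treated as fixed blocking covariates (levels that
        appear only once are constant-in-design and are dropped).
    dispersion : {"ml", "shared"}
        Per-antibody maximum-likelihood dispersion, or a single dispersion
        shared across the panel (the median of per-antibody ML estimates).
    """

    treatment: str = "treatment"
    reference: str | None = None
    blocking: tuple[str, ...] = ("replicate", "batch")
    dispersion: str = "ml"

    def __post_init__(self) -> None:
        if self.dispersion not in ("ml", "shared"):
            raise ValueError("dispersion mode must be 'ml' or 'shared'")

    def design_matrices(self, plate_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (full, reduced) design matrices for the given wells; the
        reduced design omits the treatment columns."""
        if self.treatment not in plate_df.columns:
            raise ValueError(f"plate map lacks treatment column {self.treatment!r}")
        parts = [pd.Series(1.0, index=plate_df.index, name="Intercept")]
        for col in self.blocking:
            if col not in plate_df.columns:
                continue
            levels = plate_df[col].astype(str)
            if levels.nunique() < 2:
                continue
            dummies = pd.get_dummies(levels, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        reduced = pd.concat(parts, axis=1)

        tr = plate_df[self.treatment].astype(str)
        levels = sorted(tr.unique())
        ref = self.reference if self.reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among treatment levels {levels}")
        tr_dummies = pd.get_dummies(tr, prefix=self.treatment, dtype=float)
        tr_dummies = tr_dummies.drop(columns=f"{self.treatment}_{ref}")
        full = pd.concat([reduced, tr_dummies], axis=1)

        for name, X in (("full", full), ("reduced", reduced)):
            rank = np.linalg.matrix_rank(X.to_numpy())
            if rank < X.shape[1]:
                raise ValueError(
                    f"{name} design matrix is rank deficient "
                    f"({rank} < {X.shape[1]}); check confounded covariates"
                )
        return full, reduced

    @property
    def treatment_prefix(self) -> str:
        return f"{self.treatment}_"


class NBRegression:
    """Negative-binomial regression for one antibody's counts across wells.

    Parameters
    ----------
    endog : array-like
        Non-negative integer counts, one per well.
    exog : DataFrame or ndarray
        Design matrix (include the intercept explicitly).
    offset : array-like, optional
        Log size factors; zeros if omitted.
    dispersion : float, optional
        Fix the NB dispersion instead of estimating it by ML.
    """

    def __init__(self, endog, exog, offset=None, dispersion: float | None = None):
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=float)
        else:
            self.exog = np.asarray(exog, dtype=float)
            if self.exog.ndim == 1:
                self.exog = self.exog[:, None]
            self.exog_names = [f"x{i}" for i in range(self.exog.shape[1])]
        if np.any(self.endog < 0) or np.any(self.endog != np.floor(self.endog)):
            raise ValueError("endog must be non-negative integer counts")
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        self.offset = (
            np.zeros_like(self.endog) if offset is None else np.asarray(offset, dtype=float)
        )
        if self.offset.shape != self.endog.shape:
            raise ValueError("offset must have one value per well")
        self.fixed_dispersion = dispersion
        if dispersion is not None and dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @classmethod
    def from_dataframe(
        cls,
        counts_row: pd.Series,
        plate_df: pd.DataFrame,
        spec: ModelSpec | None = None,
        log_size_factors: pd.Series | None = None,
        reduced: bool = False,
        dispersion: float | None = None,
    ) -> "NBRegression":
        """Build the model for one antibody from a plate map, aligning wells."""
        spec = spec or ModelSpec()
        plate_df = plate_df.loc[counts_row.index]
        full, red = spec.design_matrices(plate_df)
        offset = None
        if log_size_factors is not None:
            offset = log_size_factors.loc[counts_row.index].to_numpy(dtype=float)
        return cls(
            counts_row.to_numpy(dtype=float),
            red if reduced else full,
            offset=offset,
            dispersion=dispersion,
        )

    # -- likelihood machinery -------------------------------------------------

    def predict(self, params: np.ndarray) -> np.ndarray:
        return np.exp(self.exog @ params + self.offset)

    def loglike(self, params: np.ndarray, alpha: float) -> float:
        return nb_loglike(self.endog, self.predict(params), alpha)

    def score_beta(self, params: np.ndarray, alpha: float) -> np.ndarray:
        """Gradient of the log-likelihood in the regression coefficients."""
        mu = self.predict(params)
        return self.exog.T @ ((self.endog - mu) / (1.0 + alpha * mu))

    def _beta_step(self, alpha: float, start: np.ndarray | None):
        family = sm.families.NegativeBinomial(alpha=max(alpha, MIN_DISPERSION))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(self.endog, self.exog, family=family, offset=self.offset)
            res = glm.fit(start_params=start, maxiter=200)
        return res

    def _alpha_step(self, mu: np.ndarray) -> float:
        y = self.endog

        def neg_ll(log_alpha: float) -> float:
            return -nb_loglike(y, mu, np.exp(log_alpha))

        res = optimize.minimize_scalar(
            neg_ll,
            bounds=(np.log(MIN_DISPERSION), np.log(MAX_DISPERSION)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(np.exp(res.x))

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "NBRegressionResults":
        """Maximise the NB log-likelihood; never raises on non-convergence
        (the result carries ``converged`` and degeneracy flags instead)."""
        y = self.endog
        if np.all(y == 0):
            params = np.full(self.exog.shape[1], np.nan)
            return NBRegressionResults(
                self, params, np.nan, np.nan, converged=False, degenerate=True,
                n_iter=0, grad_norm=np.nan, cov_params=None,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            poisson = sm.GLM(
                y, self.exog, family=sm.families.Poisson(), offset=self.offset
            ).fit(maxiter=200)
        beta = np.asarray(poisson.params, dtype=float)
        mu = self.predict(beta)
        if self.fixed_dispersion is not None:
            alpha = self.fixed_dispersion
        else:
            # method-of-moments start from Poisson residuals
            mom = np.sum((y - mu) ** 2 - mu) / max(np.sum(mu**2), 1e-12)
            alpha = float(np.clip(mom, MIN_DISPERSION, MAX_DISPERSION))
        ll = nb_loglike(y, mu, alpha)
        converged = False
        n_iter = 0
        glm_res = None
        for n_iter in range(1, maxiter + 1):
            beta_old = beta
            try:
                glm_res = self._beta_step(alpha, beta)
                beta = np.asarray(glm_res.params, dtype=float)
            except Exception:
                break
            mu = self.predict(beta)
            if self.fixed_dispersion is None:
                alpha = self._alpha_step(mu)
            ll_new = nb_loglike(y, mu, alpha)
            # the likelihood is flat in the dispersion near the Poisson
            # boundary, so coefficient stability also counts as convergence
            beta_stable = np.max(np.abs(beta - beta_old)) <= 1e-8 * (
                1.0 + np.max(np.abs(beta))
            )
            if abs(ll_new - ll) <= tol * (abs(ll) + 1.0) or beta_stable:
                ll = ll_new
                converged = True
                break
            ll = ll_new
            if self.fixed_dispersion is not None and n_iter >= 1:
                # single IRLS solve is the exact MLE at fixed dispersion once
                # the inner GLM converges; one refinement pass suffices
                if glm_res.converged:
                    converged = True
                    break
        grad = self.score_beta(beta, alpha)
        cov = None
        if glm_res is not None:
            try:
                cov = np.asarray(glm_res.cov_params())
            except Exception:
                cov = None
        return NBRegressionResults(
            self,
            beta,
            float(alpha),
            float(ll),
            converged=converged,
            degenerate=False,
            n_iter=n_iter,
            grad_norm=float(np.linalg.norm(grad)),
            cov_params=cov,
        )


@dataclass
class NBRegressionResults:
    """Fitted NB regression: coefficient estimates, dispersion and likelihood."""

    model: NBRegression
    params_array: np.ndarray
    dispersion: float
    llf: float
    converged: bool
    degenerate: bool
    n_iter: int
    grad_norm: float
    cov_params: np.ndarray | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.params_array, index=self.model.exog_names, name="coef")

    @property
    def bse(self) -> pd.Series:
        if self.cov_params is None:
            vals = np.full(len(self.model.exog_names), np.nan)
        else:
            vals = np.sqrt(np.diag(self.cov_params))
        return pd.Series(vals, index=self.model.exog_names, name="std err")

    @property
    def df_model(self) -> int:
        return len(self.model.exog_names)

    def predict(self) -> np.ndarray:
        return self.model.predict(self.params_array)

    def summary(self) -> str:
        header = (
            "Negative-binomial regression results\n"
            f"  observations: {len(self.model.endog)}\n"
            f"  dispersion:   {self.dispersion:.6g}"
            f"{' (fixed)' if self.model.fixed_dispersion is not None else ' (ML)'}\n"
            f"  log-likelihood: {self.llf:.4f}\n"
            f"  converged: {self.converged} (iter {self.n_iter}, "
            f"|score| {self.grad_norm:.3g})\n"
        )
        table = pd.DataFrame({"coef": self.params, "std err": self.bse})
        return header + table.to_string(float_format=lambda v: f"{v: .4f}")


def lrt(full: NBRegressionResults, reduced: NBRegressionResults) -> tuple[float, float]:
    """Likelihood-ratio test of nested NB fits on the same data.

    Returns (statistic, p) with the statistic clipped at zero and the p-value
    from the chi-square with df equal to the difference in coefficient count.
    """
    if not np.array_equal(full.model.endog, reduced.model.endog):
        raise ValueError("models were fitted to different data")
    if not set(reduced.model.exog_names) <= set(full.model.exog_names):
        raise ValueError("reduced model is not nested in the full model")
    df = full.df_model - reduced.df_model
    if df < 0:
        raise ValueError("full model must have at least as many coefficients")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    if df == 0:  # identical designs: nothing to test
        return stat, 1.0
    p = float(stats.chi2.sf(stat, df))
    if stat == 0.0:
        p = 1.0
    return stat, p


def signed_logp(estimate: float, p: float) -> float:
    """sign(estimate) * (-log10 p), with p floored at 1e-300; 0 when p == 1."""
    if not np.isfinite(estimate) or not np.isfinite(p):
        return np.nan
    if p >= 1.0:
        return 0.0
    return float(np.sign(estimate) * -np.log10(max(p, P_FLOOR)))


@dataclass
class DifferentialResults:
    """Panel-wide differential analysis with a statsmodels-flavoured summary."""

    table: pd.DataFrame
    spec: ModelSpec
    fits: dict[str, NBRegressionResults] = field(default_factory=dict, repr=False)

    def summary(self, alpha: float = 0.01) -> str:
        t = self.table
        n_up = int(((t["q_value"] < alpha) & (t["estimate"] > 0)).sum())
        n_down = int(((t["q_value"] < alpha) & (t["estimate"] < 0)).sum())
        lines = [
            "Differential NB analysis",
            f"  antibodies: {len(t)}    treatment: {self.spec.treatment}",
            f"  significant at q<{alpha:g}: {n_up} up, {n_down} down",
            "",
        ]
        show = t.sort_values("p_value").head(10)
        return "\n".join(lines) + show.to_string(float_format=lambda v: f"{v: .4g}")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def differential_table(
    counts,
    spec: ModelSpec,
    factors=None,
    plate_df: pd.DataFrame | None = None,
    keep_fits: bool = False,
) -> DifferentialResults:
    """Fit the NB model and run the treatment LRT for every antibody.

    The dispersion is estimated by ML under the reduced (no-treatment) model
    and held fixed in both fits, so the likelihood-ratio test concerns the
    treatment coefficients only.  Estimating the nuisance dispersion under
    the null avoids the small-sample downward bias of a full-model estimate
    that would otherwise inflate the test.  Benjamini-Hochberg q-values are
    appended.

    Parameters
    ----------
    counts : UMICountMatrix or DataFrame
        Antibodies × wells distinct-UMI counts.
    spec : ModelSpec
    factors : SizeFactors, optional
        Per-well depth factors; their log enters the model as offset.
    plate_df : DataFrame
        Well covariates indexed by well id (required; carried by the plate map).
    """
    from .demux import UMICountMatrix  # local import to avoid cycle at module load

    if isinstance(counts, UMICountMatrix):
        counts = counts.counts
    counts = pd.DataFrame(counts)
    if plate_df is None:
        raise ValueError("plate_df with well covariates is required")
    missing = [w for w in counts.columns if w not in plate_df.index]
    if missing:
        raise ValueError(f"wells missing from plate map: {missing}")
    plate_df = plate_df.loc[counts.columns]
    full_X, red_X = spec.design_matrices(plate_df)
    log_sf = None
    if factors is not None:
        log_sf = factors.log.loc[counts.columns].to_numpy(dtype=float)

    tr_cols = [c for c in full_X.columns if c.startswith(spec.treatment_prefix)]

    rows = []
    fits: dict[str, NBRegressionResults] = {}
    fitted = []
    for ab, row in counts.iterrows():
        y = row.to_numpy(dtype=float)
        # nuisance dispersion by ML under the null (reduced) model
        reduced_ml = NBRegression(y, red_X, offset=log_sf).fit()
        fitted.append((ab, y, reduced_ml))
    alphas = [r.dispersion for _, _, r in fitted if not r.degenerate]
    shared = float(np.median(alphas)) if alphas else np.nan

    for ab, y, reduced_fit in fitted:
        if reduced_fit.degenerate:
            rows.append(
                dict(
                    antibody_id=ab, estimate=np.nan, dispersion=np.nan,
                    lrt_stat=np.nan, p_value=np.nan, signed_logp=np.nan,
                    converged=False, degenerate=True,
                )
            )
            continue
        alpha = shared if spec.dispersion == "shared" else reduced_fit.dispersion
        if spec.dispersion == "shared":
            reduced_fit = NBRegression(y, red_X, offset=log_sf, dispersion=alpha).fit()
        full_fit = NBRegression(y, full_X, offset=log_sf, dispersion=alpha).fit()
        stat, p = lrt(full_fit, reduced_fit)
        est = float(full_fit.params[tr_cols[0]]) if len(tr_cols) == 1 else float(
            full_fit.params[tr_cols].mean()
        )
        rows.append(
            dict(
                antibody_id=ab,
                estimate=est,
                dispersion=full_fit.dispersion,
                lrt_stat=stat,
                p_value=p,
                signed_logp=signed_logp(est, p),
                converged=full_fit.converged and reduced_fit.converged,
                degenerate=False,
            )
        )
        if keep_fits:
            fits[str(ab)] = full_fit

    table = pd.DataFrame(rows)
    ok = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(table.loc[ok, "p_value"], method="fdr_bh")[1]
    table["q_value"] = q
    return DifferentialResults(table=table, spec=spec, fits=fits)
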