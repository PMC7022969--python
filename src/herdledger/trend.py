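"""Mixed-model trend analysis of herd-year traits.

The response (a herd-year trait value, log-transformed for the incidence
traits) is modelled with categorical fixed effects — agroecological zone,
predominant breed, herd-size class, calendar period, adoption level,
follow-up year, and the adoption-level x follow-up-year interaction — a
random between-herd intercept, and a within-herd AR(1) process across
follow-up years:

    y_hj = x_hj' beta + b_h + e_hj,
    b_h ~ N(0, sigma2_between),    Corr(e_hj, e_hk) = rho^|j-k|,
    Var(e_hj) = sigma2_within.

Gaps in a herd's years decay the serial correlation as rho^|Delta year|.
Estimation is by REML: the overall scale is profiled out and a
quasi-Newton search runs over (variance ratio, rho) on unconstrained
transforms. The API follows the statsmodels convention: a
:class:`HerdTrendModel` is built from a tidy DataFrame and its
:meth:`~HerdTrendModel.fit` returns a :class:`HerdTrendResults` carrying
estimates, Wald tests, and marginal (least-squares) means.

Marginal means average the linear predictor with equal weights over the
levels of the nuisance factors; for log-transformed responses they are
back-transformed by exponentiation and reported as geometric means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

LOGNORMAL_TRAITS = ("MAST", "LAM")

DEFAULT_FACTORS = ["zone", "breed_group", "herd_size_class",
                   "calendar_period", "adoption_level", "followup_year"]


@dataclass
class ModelSpec:
    """Response and design description for one trait's trend model."""

    trait: str
    family: str | None = None
    factors: list = field(default_factory=lambda: list(DEFAULT_FACTORS))
    interaction: tuple | None = ("adoption_level", "followup_year")
    log_offset: float = 0.5

    def __post_init__(self) -> None:
        expected = "LOGNORMAL" if self.trait in LOGNORMAL_TRAITS else "NORMAL"
        if self.family is None:
            self.family = expected
        if self.family != expected:
            raise ValueError(
                f"{self.trait} must use the {expected} family, got {self.family}")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")
        if self.interaction is not None:
            a, b = self.interaction
            if a not in self.factors or b not in self.factors:
                raise ValueError("interaction factors must be in `factors`")


def build_model_frame(traits: pd.DataFrame, meta: pd.DataFrame,
                      levels: dict[str, str], trait: str) -> pd.DataFrame:
    """Assemble the modelling frame for one trait: trait rows joined with
    herd metadata (zone, breed) and the herd's adoption level."""
    sub = traits[traits["trait"] == trait].copy()
    sub = sub.merge(meta[["herd_id", "zone", "breed_group"]], on="herd_id",
                    how="left")
    sub["adoption_level"] = sub["herd_id"].map(levels)
    return sub.dropna(subset=["value", "zone", "breed_group", "adoption_level"])


class HerdTrendModel:
    """Linear mixed model for one trait's herd-year panel.

    Parameters
    ----------
    frame : DataFrame with columns ``herd_id``, ``followup_year``,
        ``value``, and every factor named in ``spec.factors``.
    spec : ModelSpec
    """

    def __init__(self, frame: pd.DataFrame, spec: ModelSpec,
                 on_singular: str = "raise"):
        if frame.empty:
            raise ValueError("empty modelling frame")
        if on_singular not in ("raise", "drop"):
            raise ValueError("on_singular must be 'raise' or 'drop'")
        self.spec = spec
        frame = frame.sort_values(["herd_id", "followup_year"],
                                  kind="stable").reset_index(drop=True)
        self.frame = frame

        y = frame["value"].to_numpy(dtype=float)
        self.applied_offset = 0.0
        if spec.family == "LOGNORMAL":
            if (y <= 0).any():
                self.applied_offset = spec.log_offset
            y = np.log(y + self.applied_offset)
        self.y = y

        self.factor_levels: dict[str, list] = {}
        for f in spec.factors:
            lv = sorted(frame[f].unique().tolist())
            if len(lv) < 2:
                raise ValueError(f"factor {f!r} has a single observed level")
            self.factor_levels[f] = lv

        cols: list[np.ndarray] = [np.ones(len(frame))]
        names: list[str] = ["Intercept"]
        terms: list[list[tuple[str, object]]] = [[]]
        for f in spec.factors:
            for lv in self.factor_levels[f][1:]:
                cols.append((frame[f] == lv).to_numpy(float))
                names.append(f"{f}[{lv}]")
                terms.append([(f, lv)])
        if spec.interaction is not None:
            fa, fb = spec.interaction
            for la in self.factor_levels[fa][1:]:
                for lb in self.factor_levels[fb][1:]:
                    cols.append(((frame[fa] == la) & (frame[fb] == lb))
                                .to_numpy(float))
                    names.append(f"{fa}[{la}]:{fb}[{lb}]")
                    terms.append([(fa, la), (fb, lb)])
        self.exog = np.column_stack(cols)
        self.exog_names = names
        self.terms = terms
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            if on_singular == "raise":
                raise ValueError(
                    f"design matrix is rank deficient ({rank} < "
                    f"{self.exog.shape[1]}); some factor levels are aliased")
            # drop aliased columns (QR with pivoting), keeping the earliest
            # independent set so the intercept always survives
            _, _, piv = linalg.qr(self.exog, mode="economic", pivoting=True)
            keep = np.sort(piv[:rank])
            if 0 not in keep:  # safeguard; intercept is never aliased away
                keep = np.unique(np.r_[0, keep[: rank - 1]])
            self.exog = self.exog[:, keep]
            self.exog_names = [names[i] for i in keep]
            self.terms = [terms[i] for i in keep]
            warnings.warn(
                f"dropped {len(names) - len(keep)} aliased design columns",
                stacklevel=2)

        # group structure: herds, within-herd observation times
        self.herd_ids, herd_codes = np.unique(frame["herd_id"], return_inverse=True)
        times = frame["followup_year"].to_numpy(dtype=float)
        self._patterns: dict[tuple, list[np.ndarray]] = {}
        a_full = np.column_stack([self.exog, self.y])
        for h in range(len(self.herd_ids)):
            idx = np.where(herd_codes == h)[0]
            key = tuple(times[idx])
            self._patterns.setdefault(key, []).append(a_full[idx])
        self._stacked = {
            key: np.stack(mats) for key, mats in self._patterns.items()
        }
        self.n_obs = len(frame)
        self.n_herds = len(self.herd_ids)
        self.k_exog = self.exog.shape[1]

    # ------------------------------------------------------------------
    def _corr_stats(self, gamma: float, rho: float):
        """Sufficient statistics under unit-scale covariance
        C = gamma * J + R(rho): returns (G, logdet) with G the Gram matrix
        of [X y] in the C^-1 metric and logdet = sum_i log|C_i|."""
        m = self.k_exog + 1
        g_acc = np.zeros((m, m))
        logdet = 0.0
        for key, stacked in self._stacked.items():
            t = np.asarray(key)
            n = len(t)
            c = gamma + np.power(rho, np.abs(t[:, None] - t[None, :]))
            try:
                low = linalg.cholesky(c, lower=True)
            except linalg.LinAlgError:
                return None, None
            h = stacked.shape[0]
            a2 = stacked.transpose(1, 0, 2).reshape(n, h * m)
            b2 = linalg.solve_triangular(low, a2, lower=True)
            b3 = b2.reshape(n, h, m)
            g_acc += np.einsum("nhj,nhk->jk", b3, b3)
            logdet += h * 2.0 * np.log(np.diag(low)).sum()
        return g_acc, logdet

    def _profiled_crit(self, gamma: float, rho: float):
        """-2 REML log-likelihood minus constants, with the within-herd
        scale profiled out. Returns (crit, beta, sigma2, xtx, logdet)."""
        g_acc, logdet = self._corr_stats(gamma, rho)
        if g_acc is None:
            return np.inf, None, None, None, None
        p = self.k_exog
        xtx, xty, yty = g_acc[:p, :p], g_acc[:p, p], g_acc[p, p]
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf, None, None, None, None
        beta = np.linalg.solve(xtx, xty)
        rss = max(yty - xty @ beta, 1e-300)
        dof = self.n_obs - p
        sigma2 = rss / dof
        crit = dof * np.log(sigma2) + logdet + logdet_xtx
        return crit, beta, sigma2, xtx, logdet

    def _neg2_reml(self, theta: np.ndarray) -> float:
        gamma = np.exp(theta[0])
        rho = np.tanh(theta[1])
        crit, *_ = self._profiled_crit(gamma, rho)
        return crit

    def _neg2_reml_natural(self, s2b: float, s2w: float, rho: float) -> float:
        """Unprofiled -2 REML log-likelihood (up to the same constants),
        used for the numerical information matrix of the variance
        parameters."""
        if s2w <= 0 or s2b < 0 or not abs(rho) < 1:
            return np.inf
        g_acc, logdet = self._corr_stats(s2b / s2w, rho)
        if g_acc is None:
            return np.inf
        p = self.k_exog
        xtx, xty, yty = g_acc[:p, :p], g_acc[:p, p], g_acc[p, p]
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtx, xty)
        rss = max(yty - xty @ beta, 1e-300)
        dof = self.n_obs - p
        return dof * np.log(s2w) + logdet + logdet_xtx + rss / s2w

    # ------------------------------------------------------------------
    def fit(self, starts: tuple = ((0.0, 0.2), (-1.0, 0.0), (1.0, 0.6)),
            compute_vc_se: bool = True,
            fix_rho: float | None = None) -> "HerdTrendResults":
        """Maximize the restricted likelihood; never silent on failure —
        the results object carries a ``converged`` flag and optimizer
        diagnostics. ``fix_rho`` pins the AR(1) correlation (0 reduces
        the model to a plain random-intercept fit)."""
        best = None
        diagnostics = []
        for g0, r0 in starts:
            if fix_rho is not None:
                res = optimize.minimize(
                    lambda t: self._neg2_reml(np.array([t[0],
                                                        np.arctanh(fix_rho)])),
                    x0=np.array([g0]), method="L-BFGS-B",
                    options={"maxiter": 200},
                )
                res.x = np.array([res.x[0], np.arctanh(fix_rho)])
            else:
                res = optimize.minimize(
                    self._neg2_reml, x0=np.array([g0, np.arctanh(r0)]),
                    method="L-BFGS-B",
                    options={"maxiter": 200},
                )
            diagnostics.append(res.message)
            better = best is None or res.fun < best.fun
            # prefer cleanly terminated runs over abnormal ones
            if best is not None and best.success and not res.success:
                better = False
            if best is not None and res.success and not best.success:
                better = True
            if better:
                best = res
        gamma = float(np.exp(best.x[0]))
        rho = float(np.tanh(best.x[1]))
        crit, beta, sigma2, xtx, logdet = self._profiled_crit(gamma, rho)
        converged = bool(best.success and np.isfinite(crit))
        s2w = float(sigma2)
        s2b = float(gamma * s2w)
        cov_beta = s2w * np.linalg.inv(xtx)
        dof = self.n_obs - self.k_exog
        loglike = -0.5 * (crit + dof * (1.0 + np.log(2.0 * np.pi)))

        vc_se = {"sigma2_between": np.nan, "sigma2_within": np.nan, "rho": np.nan}
        if compute_vc_se and converged:
            vc_se = self._vc_standard_errors(s2b, s2w, rho)

        return HerdTrendResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names,
                                    columns=self.exog_names),
            sigma2_between=s2b, sigma2_within=s2w, rho=rho,
            sigma2_residual=s2w * (1.0 - rho**2),
            vc_se=vc_se, loglike=float(loglike), converged=converged,
            optimizer_messages=diagnostics,
        )

    def _vc_standard_errors(self, s2b: float, s2w: float, rho: float) -> dict:
        """Wald standard errors of the variance parameters from a central
        finite-difference Hessian of the unprofiled REML criterion."""
        theta = np.array([s2b, s2w, rho])
        steps = np.array([
            max(1e-4 * s2w, 1e-3 * abs(s2b)),
            max(1e-4 * s2w, 1e-3 * s2w),
            min(1e-3, (1 - abs(rho)) / 10 + 1e-6),
        ])

        def f(v):
            return self._neg2_reml_natural(max(v[0], 0.0), v[1],
                                           np.clip(v[2], -0.999, 0.999))

        k = 3
        hess = np.full((k, k), np.nan)
        f0 = f(theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(k):
                for j in range(i, k):
                    ei = np.zeros(k); ei[i] = steps[i]
                    ej = np.zeros(k); ej[j] = steps[j]
                    if i == j:
                        val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
                    else:
                        val = (f(theta + ei + ej) - f(theta + ei - ej)
                               - f(theta - ei + ej) + f(theta - ei - ej)) \
                              / (4 * steps[i] * steps[j])
                    hess[i, j] = hess[j, i] = val
        try:
            cov = 2.0 * np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        return {"sigma2_between": se[0], "sigma2_within": se[1], "rho": se[2]}


@dataclass
class HerdTrendResults:
    """Fitted trend model: estimates, uncertainties, and derived tables."""

    model: HerdTrendModel
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2_between: float
    sigma2_within: float
    rho: float
    sigma2_residual: float
    vc_se: dict
    loglike: float
    converged: bool
    optimizer_messages: list

    # ---------------- fixed and random effect tests -------------------
    def wald_fixed(self) -> pd.DataFrame:
        """Joint Wald chi-square test per fixed factor (and interaction)."""
        rows = []
        spec = self.model.spec
        groups: dict[str, list[int]] = {}
        for i, term in enumerate(self.model.terms):
            if not term:
                continue
            if len(term) == 2:
                name = f"{term[0][0]} x {term[1][0]}"
            else:
                name = term[0][0]
            groups.setdefault(name, []).append(i)
        for name, idx in groups.items():
            b = self.params.iloc[idx].to_numpy()
            cov = self.cov_params.iloc[idx, idx].to_numpy()
            try:
                w = float(b @ np.linalg.solve(cov, b))
            except np.linalg.LinAlgError:
                w = np.nan
            df = len(idx)
            rows.append((name, w, df, stats.chi2.sf(w, df)))
        out = pd.DataFrame(rows, columns=["effect", "wald_chi2", "df", "p_value"])
        return out.set_index("effect")

    def wald_random(self) -> pd.DataFrame:
        """Wald Z tests of the variance components (one-sided for the
        variances, two-sided for the AR(1) correlation)."""
        rows = []
        for name, est in (("sigma2_between", self.sigma2_between),
                          ("sigma2_within", self.sigma2_within)):
            se = self.vc_se.get(name, np.nan)
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            rows.append((name, est, se, z, stats.norm.sf(z) if np.isfinite(z) else np.nan))
        se = self.vc_se.get("rho", np.nan)
        z = self.rho / se if se and np.isfinite(se) and se > 0 else np.nan
        rows.append(("rho", self.rho, se, z,
                     2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan))
        return pd.DataFrame(
            rows, columns=["component", "estimate", "se", "z", "p_value"]
        ).set_index("component")

    # ---------------- marginal means ----------------------------------
    def marginal_means(self, by: tuple | None = None) -> pd.DataFrame:
        """Least-squares means over the cells of ``by`` (default: the
        interaction pair), averaging the linear predictor with equal
        weights across all other factors' levels.

        For the lognormal family the means are back-transformed by
        exponentiation (geometric means) with delta-method SEs.
        """
        if not self.converged:
            raise RuntimeError("cannot compute marginal means: fit did not converge")
        model = self.model
        spec = model.spec
        if by is None:
            by = spec.interaction if spec.interaction is not None \
                else (spec.factors[0],)
        by = tuple(by)
        from itertools import product

        cells = list(product(*[model.factor_levels[f] for f in by]))
        beta = self.params.to_numpy()
        cov = self.cov_params.to_numpy()
        rows = []
        for cell in cells:
            assign = dict(zip(by, cell))
            lvec = np.zeros(model.k_exog)
            for j, term in enumerate(model.terms):
                w = 1.0
                for f, lv in term:
                    if f in assign:
                        w *= 1.0 if assign[f] == lv else 0.0
                    else:
                        w *= 1.0 / len(model.factor_levels[f])
                lvec[j] = w
            m = float(lvec @ beta)
            se = float(np.sqrt(lvec @ cov @ lvec))
            if spec.family == "LOGNORMAL":
                mean = float(np.exp(m) - model.applied_offset)
                se = float(np.exp(m) * se)
                scale = "geometric"
            else:
                mean, scale = m, "arithmetic"
            rows.append((*cell, mean, se, scale))
        return pd.DataFrame(rows, columns=[*by, "mean", "se", "scale"])

    # ---------------- presentation ------------------------------------
    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Herd-year trend model: {spec.trait} ({spec.family})",
            f"observations: {self.model.n_obs}   herds: {self.model.n_herds}"
            f"   REML loglik: {self.loglike:.2f}   converged: {self.converged}",
            "",
            "Variance components:",
            f"  between-herd  {self.sigma2_between:10.4f}"
            f"  (se {self.vc_se['sigma2_between']:.4f})",
            f"  within-herd   {self.sigma2_within:10.4f}"
            f"  (se {self.vc_se['sigma2_within']:.4f})",
            f"  AR(1) rho     {self.rho:10.4f}"
            f"  (se {self.vc_se['rho']:.4f})",
            f"  innovation    {self.sigma2_residual:10.4f}",
            "",
            "Fixed effects (joint Wald):",
        ]
        wf = self.wald_fixed()
        for effect, row in wf.iterrows():
            lines.append(f"  {effect:<40s} chi2={row.wald_chi2:9.2f} "
                         f"df={int(row.df):3d}  p={row.p_value:.4g}")
        lines.append("")
        lines.append("Coefficients:")
        se = np.sqrt(np.diag(self.cov_params))
        for name, b, s in zip(self.params.index, self.params, se):
            lines.append(f"  {name:<45s} {b:12.4f}  (se {s:.4f})")
        return "\n".join(lines)

    def plot_marginal_means(self, ax=None):
        """Marginal-mean trajectories per adoption level over follow-up
        years (requires matplotlib)."""
        import matplotlib.pyplot as plt

        mm = self.marginal_means()
        a, b = mm.columns[:2]
        if ax is None:
            _, ax = plt.subplots()
        for lvl, grp in mm.groupby(a):
            ax.errorbar(grp[b], grp["mean"], yerr=grp["se"], label=str(lvl),
                        marker="o", capsize=2)
        ax.set_xlabel("follow-up year")
        ax.set_ylabel(f"{self.model.spec.trait} marginal mean")
        ax.legend(title="adoption level")
        return ax


EFFECT_ORDER = ["herd_size_class", "breed_group", "zone", "calendar_period",
                "adoption_level", "followup_year",
                "adoption_level x followup_year"]


def effect_table(fits: dict[str, HerdTrendResults]) -> pd.DataFrame:
    """Significance summary across traits: one row per fixed effect plus
    the two random components, one column per fitted trait."""
    cols = {}
    for trait, res in fits.items():
        pvals = res.wald_fixed()["p_value"]
        rnd = res.wald_random()["p_value"]
        col = {e: pvals.get(e, np.nan) for e in EFFECT_ORDER}
        col["between herds"] = rnd.get("sigma2_between", np.nan)
        col["within herds"] = rnd.get("sigma2_within", np.nan)
        cols[trait] = col
    return pd.DataFrame(cols)
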