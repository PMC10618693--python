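"""Group-level models linking tracking accuracy, acoustics, movement and
vocabulary.

Model families (long, tidy input; one row per dyad × condition × …):

- accuracy model: linear mixed model ``z_accuracy ~ song type * data type
  (* channel)`` with per-dyad random intercept and song-type/data-type
  slopes; Fisher-z accuracies are expected as input.
- acoustic models: ``z_accuracy ~ song type * (tempo + pitch + pulse clarity
  + RMS) + channel`` with random intercepts, once for the feature means and
  once for their SDs; features are z-scored within the fit.
- movement model: beta-family GLMM (logit link, per-dyad random intercept
  integrated by Gauss–Hermite quadrature) for the proportionate duration of
  rhythmic movement.
- vocabulary models: interaction models of tracking (linear mixed) and
  movement (beta GLMM) with the 20-month expressive vocabulary count.

Term χ² values come from likelihood-ratio tests of ML fits (interactions:
full vs additive; main effects: additive vs dropped). Post-hoc contrasts and
per-condition trends carry 95% confidence intervals; robustness is judged by
whether a CI excludes 0. Multiple comparisons are corrected with the
Benjamini–Hochberg false discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelReport",
    "BetaMixedModel",
    "fit_accuracy_model",
    "fit_acoustic_models",
    "fit_movement_model",
    "fit_vocabulary_models",
    "fdr_correct",
    "adjust_proportions",
]

_COND = "C(condition, Treatment('lullaby'))"
_DTYPE = "C(data_type, Treatment('shifted'))"
Z_CRIT = 1.959963984540054  # two-sided 95%


@dataclass
class ModelReport:
    """Fixed effects, likelihood-ratio χ² per term, and post-hoc contrasts."""

    formula: str
    params: pd.DataFrame  # index term: estimate, se, ci_low, ci_high
    lrt: pd.DataFrame  # term, chi2, df, p
    contrasts: pd.DataFrame  # name, estimate, se, ci_low, ci_high, p
    converged: bool
    family: str = "gaussian-lmm"
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Model ({self.family}): {self.formula}",
            f"converged: {self.converged}",
            "",
            "Fixed effects",
            self.params.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        if len(self.lrt):
            lines += ["", "Likelihood-ratio tests", self.lrt.to_string(index=False)]
        if len(self.contrasts):
            lines += ["", "Contrasts / trends", self.contrasts.to_string(index=False)]
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "formula": self.formula,
            "family": self.family,
            "converged": self.converged,
            "params": self.params.reset_index().to_dict(orient="records"),
            "lrt": self.lrt.to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "notes": list(self.notes),
        }


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_proportions(y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Pull boundary proportions into (0,1) via (y·(n−1)+0.5)/n."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if np.any((y <= 0) | (y >= 1)):
        n = y.size
        return (y * (n - 1) + 0.5) / n, True
    return y, False


# ---------------------------------------------------------------------------
# helpers


def _require_levels(table: pd.DataFrame, column: str, n: int = 2) -> None:
    if column not in table.columns or table[column].nunique() < n:
        raise ValueError(f"factor {column!r} needs at least {n} levels")


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    return (col - col.mean()) / (sd if sd > 0 else 1.0)


def _fit_mixedlm(formula: str, data: pd.DataFrame, re_formula: str | None = None):
    """ML mixed-model fit, retrying across optimizers; a boundary fit with a
    finite likelihood is accepted (random-effect variances may sit at 0)."""
    import statsmodels.formula.api as smf

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            model = smf.mixedlm(formula, data, groups=data["dyad_id"], re_formula=re_formula)
            try:
                res = model.fit(reml=False, method=method)
            except Exception:
                continue
            if not np.isfinite(res.llf) or not np.all(np.isfinite(res.fe_params)):
                continue
            if res.converged:
                return res
            if best is None or res.llf > best.llf:
                best = res
    if best is None:
        raise RuntimeError(
            f"mixed model {formula!r} failed to produce a finite fit "
            f"(n={len(data)}); check the input for degeneracies"
        )
    return best


def _mixedlm_with_fallback(formula, data, re_formula):
    notes = []
    res = None
    if re_formula is not None:
        try:
            res = _fit_mixedlm(formula, data, re_formula)
            if not res.converged:
                res = None
        except Exception:
            res = None
        if res is None:
            notes.append("random-slope fit did not converge; fell back to random intercepts")
    if res is None:
        res = _fit_mixedlm(formula, data, None)
        if not res.converged:
            notes.append("intercept-only fit stopped at a variance boundary")
    return res, notes


def _fixed_param_table(res) -> pd.DataFrame:
    fe = res.fe_params
    se = res.bse_fe
    return pd.DataFrame(
        {
            "estimate": fe,
            "se": se,
            "ci_low": fe - Z_CRIT * se,
            "ci_high": fe + Z_CRIT * se,
        }
    )


def _lrt(full_llf: float, reduced_llf: float, df: int) -> tuple[float, float]:
    chi2 = max(0.0, 2.0 * (full_llf - reduced_llf))
    return chi2, float(sp_stats.chi2.sf(chi2, df))


def _design_rows(res, grid: pd.DataFrame) -> np.ndarray:
    design_info = res.model.data.design_info
    return np.asarray(patsy.build_design_matrices([design_info], grid)[0])


def _cell_rows(res, data: pd.DataFrame, cells: Mapping[str, Sequence]) -> np.ndarray:
    """Average fixed-effect design rows per cell, marginalizing over the
    remaining factors present in the data (e.g. channel)."""
    base_cols = [c for c in data.columns]
    rows = []
    keys = list(cells)
    from itertools import product

    for combo in product(*(cells[k] for k in keys)):
        grid = data[base_cols].copy()
        for k, v in zip(keys, combo):
            grid[k] = v
        rows.append(_design_rows(res, grid).mean(axis=0))
    return np.asarray(rows)


def _linear_combo(res, L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: beta.size, : beta.size]
    est = L @ beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", L, cov, L), 0.0, None))
    return est, se


def _tukey_p(est: float, se: float, k: int, df: float) -> float:
    """Tukey-style adjusted p via the studentized range with k means."""
    if se <= 0:
        return float("nan")
    q = abs(est) / se * np.sqrt(2.0)
    return float(sp_stats.studentized_range.sf(q, k, max(df, 2.0)))


# ---------------------------------------------------------------------------
# accuracy model


def fit_accuracy_model(table: pd.DataFrame, channel_mode: str = "auto") -> ModelReport:
    """Linear mixed model of Fisher-z accuracy on song type × data type
    (× channel), with per-dyad random intercept and song/data-type slopes.

    ``channel_mode``: 'factor' enters channel as a fixed factor as printed;
    'mean' averages accuracies over channels first (the desk-scale variant);
    'auto' uses 'factor' when a channel column with >1 level is present.
    """
    data = table.copy()
    for col in ("dyad_id", "z_accuracy"):
        if col not in data.columns:
            raise ValueError(f"column {col!r} is required")
    _require_levels(data, "condition")
    _require_levels(data, "data_type")
    if not np.all(np.isfinite(data["z_accuracy"])):
        raise ValueError("z_accuracy must be finite")

    has_channel = "channel" in data.columns and data["channel"].nunique() > 1
    if channel_mode == "auto":
        channel_mode = "factor" if has_channel else "mean"
    if channel_mode == "mean" and has_channel:
        group_cols = ["dyad_id", "condition", "data_type"]
        data = data.groupby(group_cols, as_index=False)["z_accuracy"].mean()
        has_channel = False

    inter = f"{_COND}:{_DTYPE}"
    base = f"{_COND} + {_DTYPE}"
    chan = " + C(channel)" if (channel_mode == "factor" and has_channel) else ""
    if channel_mode == "factor" and has_channel:
        inter_full = f"{_COND} * {_DTYPE} * C(channel)"
        formula = f"z_accuracy ~ {inter_full}"
    else:
        formula = f"z_accuracy ~ {base} + {inter}{chan}"
    re_formula = f"~ {_COND} + {_DTYPE}"

    res, notes = _mixedlm_with_fallback(formula, data, re_formula)

    # LRTs on matched random structures (intercept-only, ML)
    lrt_rows = []
    f_add = f"z_accuracy ~ {base}{chan}"
    f_full = f"z_accuracy ~ {base} + {inter}{chan}"
    ll_full = _fit_mixedlm(f_full, data).llf
    ll_add = _fit_mixedlm(f_add, data).llf
    chi2, p = _lrt(ll_full, ll_add, 1)
    lrt_rows.append({"term": "condition:data_type", "chi2": chi2, "df": 1, "p": p})
    for term, label in ((_COND, "condition"), (_DTYPE, "data_type")):
        other = _DTYPE if term == _COND else _COND
        ll_red = _fit_mixedlm(f"z_accuracy ~ {other}{chan}", data).llf
        chi2, p = _lrt(ll_add, ll_red, 1)
        lrt_rows.append({"term": label, "chi2": chi2, "df": 1, "p": p})

    # post-hoc cell means and contrasts (marginal over channel)
    cells = {"condition": ["lullaby", "playsong"], "data_type": ["true", "shifted"]}
    L = _cell_rows(res, data, cells)
    order = [(c, d) for c in cells["condition"] for d in cells["data_type"]]
    mean_est, mean_se = _linear_combo(res, L)
    df_resid = max(float(len(data) - len(res.fe_params)), 2.0)
    rows = []
    for (c, d), est, se in zip(order, mean_est, mean_se):
        rows.append(
            {
                "name": f"mean[{c},{d}]",
                "estimate": est,
                "se": se,
                "ci_low": est - Z_CRIT * se,
                "ci_high": est + Z_CRIT * se,
                "p": np.nan,
            }
        )
    idx = {cd: i for i, cd in enumerate(order)}
    diff_defs = {
        "true-shifted": (
            (L[idx[("lullaby", "true")]] + L[idx[("playsong", "true")]]) / 2
            - (L[idx[("lullaby", "shifted")]] + L[idx[("playsong", "shifted")]]) / 2
        ),
        "lullaby-playsong|true": L[idx[("lullaby", "true")]] - L[idx[("playsong", "true")]],
        "lullaby-playsong|shifted": L[idx[("lullaby", "shifted")]]
        - L[idx[("playsong", "shifted")]],
    }
    for name, l_row in diff_defs.items():
        est, se = _linear_combo(res, l_row[None, :])
        rows.append(
            {
                "name": name,
                "estimate": float(est[0]),
                "se": float(se[0]),
                "ci_low": float(est[0] - Z_CRIT * se[0]),
                "ci_high": float(est[0] + Z_CRIT * se[0]),
                "p": _tukey_p(float(est[0]), float(se[0]), k=4, df=df_resid),
            }
        )

    return ModelReport(
        formula=formula + " + (1 + condition + data_type | dyad)",
        params=_fixed_param_table(res),
        lrt=pd.DataFrame(lrt_rows),
        contrasts=pd.DataFrame(rows),
        converged=bool(res.converged),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# acoustic models


def _fit_feature_model(table: pd.DataFrame, features: list[str]) -> ModelReport:
    data = table.copy()
    if "data_type" in data.columns:
        data = data[data["data_type"] == "true"].copy()
    _require_levels(data, "condition")
    notes = []
    kept = []
    for feat in features:
        if data[feat].std(ddof=0) == 0:
            notes.append(f"feature {feat} is constant; its terms were dropped")
        else:
            data[feat] = _zscore(data[feat])
            kept.append(feat)
    if kept:
        corr = data[kept].corr().to_numpy()
        off = corr[~np.eye(len(kept), dtype=bool)]
        if off.size and np.max(np.abs(off)) > 0.99:
            cond_num = np.linalg.cond(data[kept].to_numpy())
            notes.append(f"collinear features (|r|>0.99); design condition number {cond_num:.3g}")

    has_channel = "channel" in data.columns and data["channel"].nunique() > 1
    chan = " + C(channel)" if has_channel else ""
    if not kept:  # degenerate input: song-type-only model, no trends
        import warnings as _warnings

        _warnings.warn("all acoustic features are constant; interaction terms dropped")
        res, fb_notes = _mixedlm_with_fallback(f"z_accuracy ~ {_COND}{chan}", data, None)
        return ModelReport(
            formula=f"z_accuracy ~ {_COND}{chan} + (1 | dyad)",
            params=_fixed_param_table(res),
            lrt=pd.DataFrame(columns=["term", "chi2", "df", "p"]),
            contrasts=pd.DataFrame(columns=["name", "estimate", "se", "ci_low", "ci_high", "p"]),
            converged=bool(res.converged),
            notes=notes + fb_notes,
        )
    feats = " + ".join(kept)
    formula = f"z_accuracy ~ {_COND} * ({feats}){chan}"
    res, fb_notes = _mixedlm_with_fallback(formula, data, None)
    notes += fb_notes

    ll_full = res.llf
    lrt_rows = []
    f_no_inter = f"z_accuracy ~ {_COND} + {feats}{chan}"
    ll_add = _fit_mixedlm(f_no_inter, data).llf
    chi2, p = _lrt(ll_full, ll_add, len(kept))
    lrt_rows.append({"term": "condition:(features)", "chi2": chi2, "df": len(kept), "p": p})
    for feat in kept:
        # interaction of this feature only: full minus cond:feat
        other_inter = " + ".join(f"{_COND}:{f}" for f in kept if f != feat)
        f_red = f"z_accuracy ~ {_COND} + {feats}{chan}" + (
            f" + {other_inter}" if other_inter else ""
        )
        ll_red = _fit_mixedlm(f_red, data).llf
        chi2, p = _lrt(ll_full, ll_red, 1)
        lrt_rows.append({"term": f"condition:{feat}", "chi2": chi2, "df": 1, "p": p})
    ll_cond_red = _fit_mixedlm(f"z_accuracy ~ {feats}{chan}", data).llf
    chi2, p = _lrt(ll_add, ll_cond_red, 1)
    lrt_rows.append({"term": "condition", "chi2": chi2, "df": 1, "p": p})

    # per-condition simple slopes ("trends") via design-row differencing
    rows = []
    for cond in ("lullaby", "playsong"):
        for feat in kept:
            hi = data.copy()
            lo = data.copy()
            hi["condition"] = cond
            lo["condition"] = cond
            hi[feat] = 0.5
            lo[feat] = -0.5
            l_row = (_design_rows(res, hi).mean(axis=0) - _design_rows(res, lo).mean(axis=0))
            est, se = _linear_combo(res, l_row[None, :])
            rows.append(
                {
                    "name": f"trend[{feat}|{cond}]",
                    "estimate": float(est[0]),
                    "se": float(se[0]),
                    "ci_low": float(est[0] - Z_CRIT * se[0]),
                    "ci_high": float(est[0] + Z_CRIT * se[0]),
                    "p": float(2 * sp_stats.norm.sf(abs(est[0] / se[0]))) if se[0] > 0 else np.nan,
                }
            )

    return ModelReport(
        formula=formula + " + (1 | dyad)",
        params=_fixed_param_table(res),
        lrt=pd.DataFrame(lrt_rows),
        contrasts=pd.DataFrame(rows),
        converged=bool(res.converged),
        notes=notes,
    )


def fit_acoustic_models(table: pd.DataFrame) -> tuple[ModelReport, ModelReport]:
    """Accuracy on song type × acoustic features: one model for the feature
    means, one for their SDs (both with features z-scored within the fit)."""
    means = _fit_feature_model(table, ["tempo_bpm", "pitch_hz", "pulse_clarity", "rms_mean"])
    sds = _fit_feature_model(table, ["tempo_sd", "pitch_sd", "pulse_clarity_sd", "rms_sd"])
    return means, sds


# ---------------------------------------------------------------------------
# beta-family GLMM


class BetaMixedModel:
    """Beta regression (logit link) with a per-group random intercept.

    The marginal likelihood integrates the Gaussian random intercept with
    Gauss–Hermite quadrature; estimation is maximum likelihood. Parameters
    are the fixed effects, log precision φ, and log random-intercept SD.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        groups: np.ndarray,
        exog_names: Sequence[str] | None = None,
        n_quad: int = 20,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            raise ValueError("responses must lie strictly in (0,1); adjust boundaries first")
        codes, _ = pd.factorize(np.asarray(groups))
        self.groups = codes
        self.n_groups = codes.max() + 1
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        self._nodes = nodes
        self._logw = np.log(weights) - 0.5 * np.log(np.pi)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, groups: str = "dyad_id", **kw):
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        model = cls(
            y.to_numpy().ravel(),
            X.to_numpy(),
            data.loc[X.index, groups].to_numpy(),
            exog_names=list(X.columns),
            **kw,
        )
        model._design_info = X.design_info
        model.formula = formula
        return model

    @property
    def k_params(self) -> int:
        return self.exog.shape[1] + 2

    def loglike(self, params: np.ndarray) -> float:
        p = self.exog.shape[1]
        beta = params[:p]
        phi = np.exp(np.clip(params[p], -20, 20))
        sigma = np.exp(np.clip(params[p + 1], -20, 10))
        eta = self.exog @ beta
        b = np.sqrt(2.0) * sigma * self._nodes  # (K,)
        mu = special.expit(eta[:, None] + b[None, :])
        mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
        y = self.endog[:, None]
        logpdf = (
            special.gammaln(phi)
            - special.gammaln(mu * phi)
            - special.gammaln((1.0 - mu) * phi)
            + (mu * phi - 1.0) * np.log(y)
            + ((1.0 - mu) * phi - 1.0) * np.log1p(-y)
        )
        acc = np.zeros((self.n_groups, self._nodes.size))
        np.add.at(acc, self.groups, logpdf)
        return float(special.logsumexp(acc + self._logw[None, :], axis=1).sum())

    def _start(self) -> np.ndarray:
        z = special.logit(np.clip(self.endog, 1e-4, 1 - 1e-4))
        beta, *_ = np.linalg.lstsq(self.exog, z, rcond=None)
        return np.concatenate([beta, [np.log(20.0), np.log(0.3)]])

    def fit(self) -> "BetaMixedResults":
        nll = lambda p: -self.loglike(p)  # noqa: E731
        start = self._start()
        opt = optimize.minimize(nll, start, method="L-BFGS-B")
        if not opt.success:  # one retry from a calmer start
            opt2 = optimize.minimize(nll, start * 0.5, method="Nelder-Mead",
                                     options={"maxiter": 4000})
            if opt2.fun < opt.fun:
                opt = opt2
        from statsmodels.tools.numdiff import approx_hess3

        hess = approx_hess3(opt.x, nll)  # central differences for stable SEs
        try:
            cov = np.linalg.inv(hess)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return BetaMixedResults(self, opt.x, bse, cov, -opt.fun, bool(opt.success))


@dataclass
class BetaMixedResults:
    model: BetaMixedModel
    params_array: np.ndarray
    bse_array: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool

    @property
    def param_names(self) -> list[str]:
        return list(self.model.exog_names) + ["log_precision", "log_re_sd"]

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.params_array, index=self.param_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.bse_array, index=self.param_names)

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * sp_stats.norm.sf(np.abs(self.zvalues)), index=self.param_names
        )

    def conf_int(self) -> pd.DataFrame:
        lo = self.params - Z_CRIT * self.bse
        hi = self.params + Z_CRIT * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})


def _beta_param_table(res: BetaMixedResults) -> pd.DataFrame:
    ci = res.conf_int()
    return pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "ci_low": ci["ci_low"],
            "ci_high": ci["ci_high"],
        }
    )


def fit_movement_model(table: pd.DataFrame, by_study: bool = False) -> ModelReport:
    """Beta GLMM of rhythmic-movement proportion on song type (and study)."""
    data = table.copy()
    _require_levels(data, "condition")
    for col in ("dyad_id", "movement_prop"):
        if col not in data.columns:
            raise ValueError(f"column {col!r} is required")
    notes = []
    y, adjusted = adjust_proportions(data["movement_prop"].to_numpy())
    if adjusted:
        notes.append("boundary proportions adjusted by (y*(n-1)+0.5)/n")
    data["movement_prop"] = y

    has_study = (not by_study) and "study" in data.columns and data["study"].nunique() > 1
    rhs = f"{_COND} * C(study)" if has_study else _COND
    formula = f"movement_prop ~ {rhs}"
    model = BetaMixedModel.from_formula(formula, data)
    res = model.fit()

    reduced_rhs = f"C(study) + {_COND}:C(study)" if has_study else "1"
    red = BetaMixedModel.from_formula(f"movement_prop ~ {reduced_rhs}", data).fit() if not has_study else None
    lrt_rows = []
    if red is not None:
        chi2, p = _lrt(res.llf, red.llf, 1)
        lrt_rows.append({"term": "condition", "chi2": chi2, "df": 1, "p": p})
    else:
        red_add = BetaMixedModel.from_formula(f"movement_prop ~ {_COND} + C(study)", data).fit()
        chi2, p = _lrt(res.llf, red_add.llf, 1)
        lrt_rows.append({"term": "condition:study", "chi2": chi2, "df": 1, "p": p})
        red_cond = BetaMixedModel.from_formula("movement_prop ~ C(study)", data).fit()
        chi2, p = _lrt(red_add.llf, red_cond.llf, 1)
        lrt_rows.append({"term": "condition", "chi2": chi2, "df": 1, "p": p})

    cond_name = next(n for n in res.param_names if "playsong" in n)
    est = float(res.params[cond_name])
    se = float(res.bse[cond_name])
    contrasts = pd.DataFrame(
        [
            {
                "name": "playsong-lullaby (logit)",
                "estimate": est,
                "se": se,
                "ci_low": est - Z_CRIT * se,
                "ci_high": est + Z_CRIT * se,
                "p": float(res.pvalues[cond_name]),
            }
        ]
    )
    return ModelReport(
        formula=formula + " + (1 | dyad)",
        params=_beta_param_table(res),
        lrt=pd.DataFrame(lrt_rows),
        contrasts=contrasts,
        converged=res.converged,
        family="beta-glmm",
        notes=notes,
    )


# ---------------------------------------------------------------------------
# vocabulary models


def fit_vocabulary_models(
    table: pd.DataFrame, which: str = "both"
) -> tuple[ModelReport | None, ModelReport | None]:
    """Interaction models of vocabulary with tracking and with movement.

    Returns (tracking model, movement model); rows with missing vocabulary
    are dropped and counted; fewer than 5 complete dyads refuses to fit.
    ``which`` restricts fitting to 'tracking' or 'movement' (the other slot
    is None).
    """
    data = table.copy()
    if "vocabulary" not in data.columns or data["vocabulary"].isna().all():
        raise ValueError("no vocabulary scores available; refusing to fit")
    complete = data.dropna(subset=["vocabulary"])
    n_dropped = data["dyad_id"].nunique() - complete["dyad_id"].nunique()
    if complete["dyad_id"].nunique() < 5:
        raise ValueError("fewer than 5 dyads with vocabulary; refusing to fit")
    notes = []
    if n_dropped:
        notes.append(f"dropped {n_dropped} dyads with missing vocabulary")
    coverage = complete["dyad_id"].nunique() / data["dyad_id"].nunique()
    if coverage < 0.8:
        notes.append(f"vocabulary coverage only {coverage:.0%}")
    complete = complete.copy()
    complete["vocabulary_z"] = _zscore(complete["vocabulary"].astype(float))

    def _trend_rows(res, data_, predictor):
        rows = []
        for cond in ("lullaby", "playsong"):
            hi = data_.copy()
            lo = data_.copy()
            hi["condition"] = cond
            lo["condition"] = cond
            hi[predictor] = 0.5
            lo[predictor] = -0.5
            l_row = _design_rows(res, hi).mean(axis=0) - _design_rows(res, lo).mean(axis=0)
            est, se = _linear_combo(res, l_row[None, :])
            rows.append(
                {
                    "name": f"trend[vocabulary|{cond}]",
                    "estimate": float(est[0]),
                    "se": float(se[0]),
                    "ci_low": float(est[0] - Z_CRIT * se[0]),
                    "ci_high": float(est[0] + Z_CRIT * se[0]),
                    "p": float(2 * sp_stats.norm.sf(abs(est[0] / se[0]))) if se[0] > 0 else np.nan,
                }
            )
        return rows

    # tracking model
    report_tracking = None
    if which in ("both", "tracking"):
        acc = complete
        if "data_type" in acc.columns:
            acc = acc[acc["data_type"] == "true"]
        acc = acc.dropna(subset=["z_accuracy"]) if "z_accuracy" in acc.columns else acc
        if "z_accuracy" not in acc.columns or not len(acc):
            raise ValueError("no accuracy values available for the vocabulary model")
        has_channel = "channel" in acc.columns and acc["channel"].nunique() > 1
        chan = " + C(channel)" if has_channel else ""
        f_track = f"z_accuracy ~ {_COND} * vocabulary_z{chan}"
        res_t, fb_notes = _mixedlm_with_fallback(f_track, acc, None)
        ll_add = _fit_mixedlm(f"z_accuracy ~ {_COND} + vocabulary_z{chan}", acc).llf
        chi2, p = _lrt(res_t.llf, ll_add, 1)
        report_tracking = ModelReport(
            formula=f_track + " + (1 | dyad)",
            params=_fixed_param_table(res_t),
            lrt=pd.DataFrame([{"term": "condition:vocabulary", "chi2": chi2, "df": 1, "p": p}]),
            contrasts=pd.DataFrame(_trend_rows(res_t, acc, "vocabulary_z")),
            converged=bool(res_t.converged),
            notes=notes + fb_notes,
        )
    if which == "tracking":
        return report_tracking, None

    # movement model
    mv = complete.drop_duplicates(subset=["dyad_id", "condition"]).copy()
    y, adjusted = adjust_proportions(mv["movement_prop"].to_numpy())
    mv["movement_prop"] = y
    mv_notes = ["boundary proportions adjusted by (y*(n-1)+0.5)/n"] if adjusted else []
    f_move = f"movement_prop ~ {_COND} * vocabulary_z"
    res_m = BetaMixedModel.from_formula(f_move, mv).fit()
    red_m = BetaMixedModel.from_formula(f"movement_prop ~ {_COND} + vocabulary_z", mv).fit()
    chi2_m, p_m = _lrt(res_m.llf, red_m.llf, 1)

    def _beta_trends(res, data_):
        rows = []
        di = res.model._design_info
        for cond in ("lullaby", "playsong"):
            hi = data_.copy()
            lo = data_.copy()
            hi["condition"] = cond
            lo["condition"] = cond
            hi["vocabulary_z"] = 0.5
            lo["vocabulary_z"] = -0.5
            Xh = np.asarray(patsy.build_design_matrices([di], hi)[0]).mean(axis=0)
            Xl = np.asarray(patsy.build_design_matrices([di], lo)[0]).mean(axis=0)
            l_row = Xh - Xl
            p_fix = len(res.model.exog_names)
            beta = res.params_array[:p_fix]
            cov = res.cov[:p_fix, :p_fix]
            est = float(l_row @ beta)
            se = float(np.sqrt(max(l_row @ cov @ l_row, 0.0)))
            rows.append(
                {
                    "name": f"trend[vocabulary|{cond}] (logit)",
                    "estimate": est,
                    "se": se,
                    "ci_low": est - Z_CRIT * se,
                    "ci_high": est + Z_CRIT * se,
                    "p": float(2 * sp_stats.norm.sf(abs(est / se))) if se > 0 else np.nan,
                }
            )
        return rows

    report_movement = ModelReport(
        formula=f_move + " + (1 | dyad)",
        params=_beta_param_table(res_m),
        lrt=pd.DataFrame([{"term": "condition:vocabulary", "chi2": chi2_m, "df": 1, "p": p_m}]),
        contrasts=pd.DataFrame(_beta_trends(res_m, mv)),
        converged=res_m.converged,
        family="beta-glmm",
        notes=notes + mv_notes,
    )
    return report_tracking, report_movement
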