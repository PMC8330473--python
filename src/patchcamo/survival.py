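"""Detection-risk survival modelling.

The response is not time but *relative approach*: a detection at distance
d, at a position first visible from d_max, becomes u = 1 - d/d_max, so
larger u means the observer walked further towards the target before
spotting it (better camouflage).  A missed target is censored at
u = 1 - d_min/d_max, the closest the path ever came.  Online trials use
search time in seconds with censoring at the timeout instead.

Hazards on this transformed scale are modelled with a Cox proportional
hazards model, optionally with normal random effects ("frailties") on the
log-hazard scale for subject and position.  Fixed effects are estimated
by maximising the partial likelihood (Efron tie handling); random effects
by penalised partial likelihood, with the frailty variances estimated by
profiling a Laplace approximation of the integrated likelihood — the
standard mixed-effects Cox recipe.  Model comparison uses likelihood
ratio tests and an AIC ladder; proportional hazards are checked with a
Schoenfeld-residual score test.

The public surface follows the Model/Results convention:
``CoxFrailtyModel.from_dataframe(df, ...).fit()`` returns a
:class:`CoxFrailtyResults` carrying estimates, standard errors, hazard
ratios with Wald intervals, log-likelihoods, AIC and a ``summary()``
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "field_response",
    "online_response",
    "centre_distance_quartiles",
    "CoxFrailtyModel",
    "CoxFrailtyResults",
    "lr_test",
    "aic_ladder",
]


# ---------------------------------------------------------------------------
# response transforms

def field_response(d_detect, d_min, d_max):
    """Transform field detection distances to (response, event).

    Detected: response = 1 - d_detect/d_max, event 1.  Missed (d_detect
    NaN/None): response = 1 - d_min/d_max, event 0.  Vectorised.
    """
    d_detect = np.asarray(d_detect, dtype=float)
    d_min = np.asarray(d_min, dtype=float)
    d_max = np.asarray(d_max, dtype=float)
    if np.any(d_min >= d_max):
        raise ValueError("d_min must be strictly below d_max")
    detected = ~np.isnan(d_detect)
    if np.any(d_detect[detected] > d_max[detected] if d_max.ndim else d_detect[detected] > d_max):
        raise ValueError("d_detect exceeds d_max")
    response = np.where(detected, 1.0 - d_detect / d_max, 1.0 - d_min / d_max)
    return response, detected.astype(int)


def online_response(time_s, timeout_s: float = 10.0):
    """Transform online search times to (response, event); NaN = timed out."""
    t = np.asarray(time_s, dtype=float)
    found = ~np.isnan(t)
    if np.any(t[found] > timeout_s):
        raise ValueError("time_s exceeds the timeout")
    if np.any(t[found] <= 0):
        raise ValueError("time_s must be positive")
    return np.where(found, t, timeout_s), found.astype(int)


def centre_distance_quartiles(distances) -> np.ndarray:
    """Quartile index (0-3) of each centre distance, boundaries from the
    analysed dataset's empirical quartiles; boundary ties go to the lower
    quartile."""
    d = np.asarray(distances, dtype=float)
    q = np.quantile(d, [0.25, 0.5, 0.75])
    return np.digitize(d, q, right=True)


# ---------------------------------------------------------------------------
# partial likelihood machinery

def _group_sorted(y: np.ndarray):
    """Sort descending by y; return order and per-position group ids/ends of
    tied-y groups (groups ordered by decreasing y)."""
    order = np.argsort(-y, kind="stable")
    ys = y[order]
    new = np.r_[True, ys[1:] != ys[:-1]]
    gid = np.cumsum(new) - 1
    return order, gid


def _partial_loglik(y, e, X, eta, ties="efron", want_hess=True):
    """Cox partial log-likelihood, gradient and Hessian for one stratum.

    Fast vectorised path when no event time is tied with another event;
    a grouped Efron/Breslow loop otherwise.
    """
    n, p = X.shape
    order, gid = _group_sorted(y)
    Xs, es, etas = X[order], e[order], eta[order]
    w = np.exp(etas)
    ngroups = gid[-1] + 1
    # group-end cumulative sums (risk set = positions with group <= g)
    gw = np.bincount(gid, weights=w, minlength=ngroups)
    S0 = np.cumsum(gw)
    d_per_group = np.bincount(gid, weights=es, minlength=ngroups)

    if not np.any(es):
        raise ValueError("no events in the data")

    tied = np.any(d_per_group > 1)
    if not tied or ties == "breslow":
        Xw = Xs * w[:, None]
        S1 = np.empty((ngroups, p))
        cum = np.cumsum(Xw, axis=0)
        ends = np.searchsorted(gid, np.arange(ngroups), side="right") - 1
        S1 = cum[ends]
        ev = es.astype(bool)
        ge = gid[ev]
        mu = S1[ge] / S0[ge][:, None]
        ll = float(etas[ev].sum() - np.log(S0[ge]).sum())
        grad = Xs[ev].sum(axis=0) - mu.sum(axis=0)
        if not want_hess:
            return ll, grad, None
        # sum_k S2_k/S0_k = X' diag(w * A) X with A_j = cumhaz at y_j
        contrib = np.bincount(gid[ev], weights=1.0 / S0[ge], minlength=ngroups)
        A_group = np.cumsum(contrib[::-1])[::-1]
        a = A_group[gid] * w
        hess = -((Xs * a[:, None]).T @ Xs - mu.T @ mu)
        return ll, grad, hess

    # grouped Efron loop (tied event times)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if want_hess else None
    cumS0 = 0.0
    cumS1 = np.zeros(p)
    cumS2 = np.zeros((p, p)) if want_hess else None
    for g in range(ngroups):
        idx = np.nonzero(gid == g)[0]
        wg = w[idx]
        Xg = Xs[idx]
        cumS0 += wg.sum()
        cumS1 += Xg.T @ wg
        if want_hess:
            cumS2 += (Xg * wg[:, None]).T @ Xg
        ev = es[idx].astype(bool)
        d = int(ev.sum())
        if d == 0:
            continue
        Xe, we = Xg[ev], wg[ev]
        ll += float(etas[idx][ev].sum())
        grad += Xe.sum(axis=0)
        s0d = we.sum()
        s1d = Xe.T @ we
        s2d = (Xe * we[:, None]).T @ Xe if want_hess else None
        for l in range(d):
            f = l / d
            den = cumS0 - f * s0d
            num1 = cumS1 - f * s1d
            mu = num1 / den
            ll -= math.log(den)
            grad -= mu
            if want_hess:
                hess -= (cumS2 - f * s2d) / den - np.outer(mu, mu)
    return ll, grad, hess


def _loglik_all(y, e, X, eta, strata_ids, ties, want_hess=True):
    p = X.shape[1]
    ll, grad = 0.0, np.zeros(p)
    hess = np.zeros((p, p)) if want_hess else None
    for s in np.unique(strata_ids):
        m = strata_ids == s
        if not np.any(e[m]):
            continue  # stratum contributes nothing without events
        l, g, h = _partial_loglik(y[m], e[m], X[m], eta[m], ties, want_hess)
        ll += l
        grad += g
        if want_hess:
            hess += h
    return ll, grad, hess


# ---------------------------------------------------------------------------
# model / results

class CoxFrailtyModel:
    """Cox proportional hazards model with optional normal log-frailties.

    Parameters
    ----------
    response, event
        Transformed response (relative approach or seconds) and the
        detection indicator (1 = event, 0 = censored).
    exog
        (n, p) fixed-effect design matrix (may be empty for a null model).
    exog_names
        Column names for reporting.
    frailty
        Mapping name -> integer/str group labels, one array per random
        effect (e.g. ``{"subject": ..., "position": ...}``).
    strata
        Optional array of stratum keys; partial likelihoods are computed
        within strata and summed.
    ties
        "efron" (default) or "breslow".
    """

    def __init__(
        self,
        response,
        event,
        exog=None,
        exog_names=None,
        frailty: dict | None = None,
        strata=None,
        ties: str = "efron",
    ):
        self.y = np.asarray(response, dtype=float)
        self.e = np.asarray(event, dtype=int)
        n = len(self.y)
        if exog is None:
            exog = np.empty((n, 0))
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.X.shape[0] != n:
            self.X = self.X.T
        if self.X.shape[0] != n:
            raise ValueError("exog row count must match response length")
        p = self.X.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else [f"x{i}" for i in range(p)]
        if len(self.exog_names) != p:
            raise ValueError("exog_names length mismatch")
        if self.e.sum() < 1:
            raise ValueError("need at least one event")
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties

        if strata is None:
            self.strata_ids = np.zeros(n, dtype=int)
        else:
            _, self.strata_ids = np.unique(np.asarray(strata), return_inverse=True)

        self.frailty_names: list[str] = []
        self.frailty_levels: list[np.ndarray] = []
        blocks = []
        if frailty:
            for name, labels in frailty.items():
                levels, codes = np.unique(np.asarray(labels), return_inverse=True)
                Z = np.zeros((n, len(levels)))
                Z[np.arange(n), codes] = 1.0
                blocks.append(Z)
                self.frailty_names.append(name)
                self.frailty_levels.append(levels)
        self.Z = np.hstack(blocks) if blocks else np.empty((n, 0))
        self._block_sizes = [Z.shape[1] for Z in blocks]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates=(),
        response_col: str = "response",
        event_col: str = "event",
        frailty=(),
        strata_cols=(),
        ties: str = "efron",
    ) -> "CoxFrailtyModel":
        covariates = list(covariates)
        X = df[covariates].to_numpy(dtype=float) if covariates else None
        fr = {c: df[c].to_numpy() for c in frailty} or None
        strata = None
        strata_cols = list(strata_cols)
        if strata_cols:
            strata = pd.MultiIndex.from_frame(df[strata_cols]).to_numpy() if len(strata_cols) > 1 else df[strata_cols[0]].to_numpy()
        return cls(
            df[response_col].to_numpy(dtype=float),
            df[event_col].to_numpy(dtype=int),
            exog=X,
            exog_names=covariates,
            frailty=fr,
            strata=strata,
            ties=ties,
        )

    # -- penalised Newton for (beta, b) at fixed variances -----------------
    def _inner_fit(self, variances, start=None, tol=1e-12, max_iter=50):
        p = self.X.shape[1]
        q = self.Z.shape[1]
        XZ = np.hstack([self.X, self.Z]) if q else self.X
        pen = np.zeros(p + q)
        if q:
            inv_var = np.concatenate(
                [np.full(m, 1.0 / v) for m, v in zip(self._block_sizes, variances)]
            )
            pen[p:] = inv_var
        theta = np.zeros(p + q) if start is None else start.copy()

        def objective(th):
            eta = XZ @ th if p + q else np.zeros(len(self.y))
            ll, grad, hess = _loglik_all(self.y, self.e, XZ, eta, self.strata_ids, self.ties)
            llp = ll - 0.5 * float(pen @ th**2)
            grad = grad - pen * th
            hess = hess - np.diag(pen)
            return llp, grad, hess, ll

        llp, grad, hess, ll = objective(theta)
        converged = p + q == 0
        slack = 1e-9 * max(1.0, abs(llp))
        for _ in range(max_iter):
            if p + q == 0:
                break
            try:
                step = np.linalg.solve(-hess + 1e-12 * np.eye(p + q), grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            # Newton decrement: quadratic estimate of the remaining gap
            if 0.5 * float(grad @ step) < tol:
                converged = True
                break
            for _ in range(30):  # step halving
                cand = theta + step
                llp_new, grad_new, hess_new, ll_new = objective(cand)
                if llp_new >= llp - slack:
                    theta, llp, grad, hess, ll = cand, llp_new, grad_new, hess_new, ll_new
                    break
                step /= 2.0
            else:
                break
        if not converged and 0.5 * float(grad @ np.linalg.solve(-hess + 1e-12 * np.eye(p + q), grad)) > 1e-6:
            raise RuntimeError(
                f"penalised Newton did not converge (|grad|={np.max(np.abs(grad)):.2e})"
            )
        return theta, llp, ll, hess, pen

    def _laplace_loglik(self, log_variances, state):
        variances = np.exp(np.clip(log_variances, -12, 6))
        theta, llp, ll, hess, pen = self._inner_fit(variances, start=state.get("theta"))
        state["theta"] = theta
        p = self.X.shape[1]
        q = self.Z.shape[1]
        # l_int = llp - 0.5 log det(I + D H_bb)
        Hbb = -(hess[p:, p:] + np.diag(pen[p:]))  # unpenalised info, b-block
        D = np.concatenate([np.full(m, v) for m, v in zip(self._block_sizes, variances)])
        M = np.eye(q) + Hbb * D[None, :]
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf, theta, llp, ll, hess
        lint = llp - 0.5 * logdet
        return lint, theta, llp, ll, hess

    def fit(self, frailty_variances=None, tol: float = 1e-12) -> "CoxFrailtyResults":
        """Estimate the model.

        Without frailty terms this is a plain Newton fit of the partial
        likelihood.  With frailty terms, the variances are estimated by
        maximising the Laplace-approximate integrated likelihood over
        log-variances (Nelder-Mead), with a penalised Newton inner fit;
        pass ``frailty_variances`` to fix them instead.
        """
        p = self.X.shape[1]
        nblocks = len(self._block_sizes)
        if nblocks == 0:
            theta, llp, ll, hess, pen = self._inner_fit((), tol=tol)
            K = -hess
            cov = np.linalg.inv(K) if p else np.zeros((0, 0))
            return CoxFrailtyResults(
                self, theta[:p], cov, llf=ll, llf_integrated=ll,
                frailty_variances={}, random_effects={}, theta=theta,
            )

        state: dict = {}
        if frailty_variances is not None:
            variances = np.asarray(frailty_variances, dtype=float)
            lint, theta, llp, ll, hess = self._laplace_loglik(np.log(variances), state)
        else:
            def neg(lv):
                val = self._laplace_loglik(lv, state)[0]
                return -val if np.isfinite(val) else 1e10

            x0 = np.log(np.full(nblocks, 0.05))
            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                options={"xatol": 0.02, "fatol": 1e-4, "maxfev": 120},
            )
            lint, theta, llp, ll, hess = self._laplace_loglik(res.x, state)
            variances = np.exp(np.clip(res.x, -12, 6))

        K = -hess  # penalised information, full
        cov_full = np.linalg.inv(K)
        cov = cov_full[:p, :p]
        q_off = p
        re = {}
        for name, levels, m in zip(self.frailty_names, self.frailty_levels, self._block_sizes):
            re[name] = pd.Series(theta[q_off : q_off + m], index=levels)
            q_off += m
        return CoxFrailtyResults(
            self, theta[:p], cov, llf=ll, llf_integrated=lint,
            frailty_variances=dict(zip(self.frailty_names, variances.tolist())),
            random_effects=re, theta=theta,
        )


@dataclass
class CoxFrailtyResults:
    """Fitted detection-risk model: estimates, uncertainty, diagnostics."""

    model: CoxFrailtyModel
    params_: np.ndarray
    cov_params_: np.ndarray
    llf: float  # partial log-likelihood at the optimum
    llf_integrated: float  # Laplace integrated (== llf when no frailty)
    frailty_variances: dict
    random_effects: dict
    theta: np.ndarray  # (beta, b)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.params_, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params_)), index=self.model.exog_names)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.model.exog_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald CI for the hazard ratios, computed on the log-hazard scale."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params_ - z * np.sqrt(np.diag(self.cov_params_)))
        hi = np.exp(self.params_ + z * np.sqrt(np.diag(self.cov_params_)))
        return pd.DataFrame({"hr_lower": lo, "hr_upper": hi}, index=self.model.exog_names)

    @property
    def df_model(self) -> int:
        return self.model.X.shape[1]

    @property
    def df_aic(self) -> int:
        """Effective parameters for AIC: fixed effects + one variance per
        frailty term (integrated-likelihood convention)."""
        return self.df_model + len(self.frailty_variances)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf_integrated + 2.0 * self.df_aic

    def _data_signature(self):
        m = self.model
        return (
            len(m.y), float(m.y.sum()), int(m.e.sum()),
            tuple(sorted(m.frailty_names)), int(m.strata_ids.max()),
        )

    def summary(self) -> str:
        lines = [
            "Cox proportional hazards (detection risk)",
            f"n = {len(self.model.y)}, events = {int(self.model.e.sum())}, "
            f"ties = {self.model.ties}",
            f"partial loglik = {self.llf:.3f}, integrated loglik = "
            f"{self.llf_integrated:.3f}, AIC = {self.aic:.3f}",
        ]
        if self.frailty_variances:
            vs = ", ".join(f"{k}: {v:.4f}" for k, v in self.frailty_variances.items())
            lines.append(f"frailty variances (log-hazard scale): {vs}")
        if self.df_model:
            ci = self.conf_int()
            lines.append(f"{'term':<16}{'coef':>10}{'HR':>10}{'se':>10}{'z':>8}"
                         f"{'p':>10}{'CI95':>20}")
            for name in self.model.exog_names:
                lines.append(
                    f"{name:<16}{self.params[name]:>10.4f}{self.hazard_ratios[name]:>10.4f}"
                    f"{self.bse[name]:>10.4f}{self.zvalues[name]:>8.2f}"
                    f"{self.pvalues[name]:>10.3g}"
                    f"{ci.loc[name, 'hr_lower']:>10.3f}-{ci.loc[name, 'hr_upper']:<9.3f}"
                )
        return "\n".join(lines)

    # -- diagnostics -------------------------------------------------------
    def schoenfeld_residuals(self):
        """Schoenfeld residuals (one row per event, fixed covariates only)."""
        m = self.model
        p = m.X.shape[1]
        if p == 0:
            raise ValueError("no fixed covariates")
        XZ = np.hstack([m.X, m.Z]) if m.Z.shape[1] else m.X
        eta = XZ @ self.theta
        rows, times = [], []
        for s in np.unique(m.strata_ids):
            sel = m.strata_ids == s
            y, e, X, et = m.y[sel], m.e[sel], m.X[sel], eta[sel]
            order, gid = _group_sorted(y)
            ys, es, Xs, ets = y[order], e[order], X[order], et[order]
            w = np.exp(ets)
            ngroups = gid[-1] + 1
            gw = np.bincount(gid, weights=w, minlength=ngroups)
            S0 = np.cumsum(gw)
            cum = np.cumsum(Xs * w[:, None], axis=0)
            ends = np.searchsorted(gid, np.arange(ngroups), side="right") - 1
            S1 = cum[ends]
            for i in np.nonzero(es)[0]:
                g = gid[i]
                rows.append(Xs[i] - S1[g] / S0[g])
                times.append(ys[i])
        order = np.argsort(times)
        return np.asarray(times)[order], np.asarray(rows)[order]

    def ph_test(self, transform: str = "identity") -> pd.DataFrame:
        """Score test of proportional hazards per covariate.

        Correlates Schoenfeld residuals with a transform g of the event
        response (identity or rank), testing theta = 0 in
        beta(t) = beta + theta (g(t) - gbar).  Returns statistic and p
        per covariate plus the residual series in ``attrs``.
        """
        times, resid = self.schoenfeld_residuals()
        d = len(times)
        if d < 2:
            raise ValueError("need at least two events for the PH check")
        if transform == "identity":
            g = times.astype(float)
        elif transform == "rank":
            g = stats.rankdata(times).astype(float)
        else:
            raise ValueError("transform must be 'identity' or 'rank'")
        gc = g - g.mean()
        # average per-event covariance of the covariates in the risk set,
        # estimated from the residual scatter
        Vbar = resid.T @ resid / d
        U = resid.T @ gc
        denom = (gc**2).sum() * np.diag(Vbar)
        stat = U**2 / denom
        out = pd.DataFrame(
            {"chi2": stat, "df": 1, "p": stats.chi2.sf(stat, 1)},
            index=self.model.exog_names,
        )
        out.attrs["times"] = times
        out.attrs["residuals"] = resid
        return out

    def plot_survival(self, by=None, ax=None, labels=None):
        """Kaplan-Meier curves of the response, optionally split by a
        grouping array (e.g. strategy), in the style of the field plots."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        groups = np.zeros(len(m.y), dtype=int) if by is None else np.asarray(by)
        for gval in np.unique(groups):
            sel = groups == gval
            t, s = _kaplan_meier(m.y[sel], m.e[sel])
            lab = labels.get(gval, str(gval)) if labels else str(gval)
            ax.step(t, s, where="post", label=lab)
        ax.set_xlabel("relative approach (1 - d/d_max) or time")
        ax.set_ylabel("survival (undetected) probability")
        ax.legend()
        return ax


def _kaplan_meier(y, e):
    order = np.argsort(y)
    y, e = y[order], e[order]
    t_out, s_out = [0.0], [1.0]
    at_risk = len(y)
    s = 1.0
    for t in np.unique(y[e == 1]):
        d = int(((y == t) & (e == 1)).sum())
        n = int((y >= t).sum())
        s *= 1.0 - d / n
        t_out.append(t)
        s_out.append(s)
    return np.array(t_out), np.array(s_out)


def lr_test(full: CoxFrailtyResults, reduced: CoxFrailtyResults):
    """Likelihood ratio test of nested Cox fits on identical data.

    Uses integrated log-likelihoods when frailty terms are present
    (both fits must share the random-effect structure).
    """
    if full._data_signature() != reduced._data_signature():
        raise ValueError("fits are not on the same data / random-effect structure")
    if not set(reduced.model.exog_names) <= set(full.model.exog_names):
        raise ValueError("reduced model is not nested in the full model")
    df = full.df_model - reduced.df_model
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    lf = full.llf_integrated if full.frailty_variances else full.llf
    lr = reduced.llf_integrated if reduced.frailty_variances else reduced.llf
    chi2 = max(0.0, 2.0 * (lf - lr))
    p = stats.chi2.sf(chi2, df) if df > 0 else 1.0
    return chi2, df, p


def aic_ladder(fits, labels=None, substantial: float = 6.0) -> pd.DataFrame:
    """Rank fits by AIC with dAIC to the best; flag dAIC > ``substantial``.

    All fits must be on the same response data with the same
    random-effect structure.
    """
    fits = list(fits)
    if labels is None:
        labels = [f"model_{i}" for i in range(len(fits))]
    sig = fits[0]._data_signature()
    for f in fits[1:]:
        if f._data_signature() != sig:
            raise ValueError("AIC ladder requires fits on identical data")
    tab = pd.DataFrame(
        {
            "model": list(labels),
            "aic": [f.aic for f in fits],
            "loglik": [f.llf_integrated for f in fits],
            "df": [f.df_aic for f in fits],
        }
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    tab["substantial"] = tab["delta_aic"] > substantial
    return tab
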