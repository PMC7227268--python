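"""Conditional logistic regression for 1:m matched sets.

The model conditions on each matched set containing exactly one case,
eliminating the set-specific intercepts.  With covariate vectors x_k for
the members of set j and the case's vector x_case, the log likelihood is

    l(beta) = sum_j [ x_case' beta - log sum_{k in j} exp(x_k' beta) ]

Sets whose members all share an identical covariate vector contribute the
constant -log(set size) and are counted non-informative.  Fitting is
Newton–Raphson on the analytic gradient and Hessian with step-halving;
standard errors come from the inverse observed information, and 95%
confidence intervals are Wald intervals exp(beta ± 1.96 SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "ConditionalLogit",
    "ConditionalLogitResults",
    "fit_clogit",
    "odds_ratio_report",
    "format_report",
]


class ConditionalLogit:
    """Conditional logit model for matched sets with exactly one case each.

    Parameters
    ----------
    endog : array-like of bool/int
        Case indicator, one entry per matched-set member.
    exog : array-like, shape (n, k)
        Covariates (no intercept: it is absorbed by the conditioning).
    groups : array-like
        Matched-set label per member.
    param_names : sequence of str, optional
    """

    def __init__(self, endog, exog, groups, param_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        g = np.asarray(groups)
        if not (len(y) == len(X) == len(g)):
            raise ValueError("endog, exog and groups must have equal length")
        order = np.argsort(g, kind="stable")
        self.endog = y[order]
        self.exog = X[order]
        g = g[order]
        # contiguous group slices
        starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
        self._starts = starts
        self._sizes = np.diff(np.r_[starts, len(g)])
        self.group_labels = g[starts]
        case_counts = np.add.reduceat(self.endog, starts)
        bad = ~np.isclose(case_counts, 1.0)
        if bad.any():
            raise ValueError(
                "each matched set must contain exactly one case; offending "
                f"set(s): {self.group_labels[bad][:5].tolist()}"
            )
        self.n_sets = len(starts)
        self.k_params = self.exog.shape[1]
        if param_names is None:
            param_names = [f"x{i}" for i in range(self.k_params)]
        self.param_names = list(param_names)
        # a set is informative iff its members' covariate vectors differ
        informative = np.zeros(self.n_sets, dtype=bool)
        for j, (s, n) in enumerate(zip(starts, self._sizes)):
            block = self.exog[s : s + n]
            informative[j] = bool((block != block[0]).any())
        self._informative = informative
        self.n_informative_sets = int(informative.sum())

    # ---- likelihood machinery -------------------------------------------

    def _group_logsumexp(self, eta):
        starts = self._starts
        gmax = np.maximum.reduceat(eta, starts)
        centred = np.exp(eta - np.repeat(gmax, self._sizes))
        gsum = np.add.reduceat(centred, starts)
        return gmax + np.log(gsum), centred / np.repeat(gsum, self._sizes)

    def loglike(self, params) -> float:
        beta = np.asarray(params, dtype=float)
        eta = self.exog @ beta
        lse, _ = self._group_logsumexp(eta)
        return float(eta[self.endog == 1].sum() - lse.sum())

    def score(self, params) -> np.ndarray:
        beta = np.asarray(params, dtype=float)
        eta = self.exog @ beta
        _, p = self._group_logsumexp(eta)
        return self.exog[self.endog == 1].sum(axis=0) - p @ self.exog

    def hessian(self, params) -> np.ndarray:
        beta = np.asarray(params, dtype=float)
        eta = self.exog @ beta
        _, p = self._group_logsumexp(eta)
        w = p[:, None] * self.exog
        mu = np.add.reduceat(w, self._starts, axis=0)  # per-set E[x]
        return -(self.exog.T @ w - mu.T @ mu)

    # ---- fitting ---------------------------------------------------------

    def fit(
        self,
        start_params=None,
        maxiter: int = 100,
        gtol: float = 1e-8,
        ltol: float = 1e-10,
    ) -> "ConditionalLogitResults":
        """Newton–Raphson with step-halving from beta = 0.

        Raises ``ValueError("no discordant sets")`` when no set is
        informative.  When the MLE diverges (an exposure perfectly
        separating cases from controls), the result is returned flagged
        non-converged with the direction of divergence.
        """
        if self.n_informative_sets == 0:
            raise ValueError("no discordant sets")
        beta = (
            np.zeros(self.k_params)
            if start_params is None
            else np.asarray(start_params, dtype=float).copy()
        )
        ll = self.loglike(beta)
        converged = False
        separation = None
        it = 0
        for it in range(1, maxiter + 1):
            grad = self.score(beta)
            if np.abs(grad).max() < gtol:
                converged = True
                break
            H = self.hessian(beta)
            try:
                step = linalg.solve(H, -grad, assume_a="sym")
            except linalg.LinAlgError:
                step = -np.asarray(np.linalg.pinv(H) @ grad)
            # step-halving if the Newton step decreases the log likelihood
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
            if abs(ll_new - ll) < ltol * (abs(ll) + 1.0):
                ll = ll_new
                converged = True
                break
            ll = ll_new
            if np.abs(beta).max() > 15.0:
                i = int(np.abs(beta).argmax())
                separation = (
                    f"apparent separation: coefficient for "
                    f"{self.param_names[i]!r} diverging towards "
                    f"{'+inf' if beta[i] > 0 else '-inf'}"
                )
                break
        H = self.hessian(beta)
        try:
            cov = linalg.inv(-H)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except linalg.LinAlgError:
            cov = np.full((self.k_params, self.k_params), np.nan)
            bse = np.full(self.k_params, np.nan)
        return ConditionalLogitResults(
            model=self,
            params=beta,
            bse=bse,
            cov_params=cov,
            llf=self.loglike(beta),
            converged=bool(converged and separation is None),
            iterations=it,
            separation=separation,
        )


@dataclass
class ConditionalLogitResults:
    """Estimates from :meth:`ConditionalLogit.fit`.

    ``params`` are log odds ratios; ``odds_ratios()`` exponentiates them
    with Wald 95% bounds.
    """

    model: ConditionalLogit
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    iterations: int
    separation: str | None = None

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def n_sets(self) -> int:
        return self.model.n_sets

    @property
    def n_informative_sets(self) -> int:
        return self.model.n_informative_sets

    @property
    def n_cases(self) -> int:
        return int(self.model.endog.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.model.endog) - self.model.endog.sum())

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.exp(self.conf_int(alpha))
        return pd.DataFrame(
            {
                "odds_ratio": np.exp(self.params),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=pd.Index(self.param_names, name="term"),
        )

    def summary(self) -> str:
        lines = [
            "Conditional logistic regression (matched sets)",
            f"  sets: {self.n_sets} ({self.n_informative_sets} informative)",
            f"  cases: {self.n_cases}   controls: {self.n_controls}",
            f"  log-likelihood: {self.llf:.4f}   "
            f"converged: {self.converged} ({self.iterations} iterations)",
        ]
        if self.separation:
            lines.append(f"  WARNING: {self.separation}")
        lines.append(
            f"  {'term':<18}{'coef':>10}{'se':>10}{'OR':>10}"
            f"{'2.5%':>10}{'97.5%':>10}"
        )
        ors = self.odds_ratios()
        for i, name in enumerate(self.param_names):
            r = ors.iloc[i]
            lines.append(
                f"  {name:<18}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{r['odds_ratio']:>10.4f}{r['ci_low']:>10.4f}{r['ci_high']:>10.4f}"
            )
        return "\n".join(lines)


def _design_from_rows(
    rows: pd.DataFrame, exposure: str, adjust_for: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    cols = [rows[exposure].astype(float).to_numpy()]
    names = [exposure]
    for cov in adjust_for:
        if cov == "trial_arm":
            arm = rows["trial_arm"]
            if arm.isna().any():
                raise ValueError(
                    "cannot adjust for trial_arm: some subjects have no arm"
                )
            cols.append((arm == "early").astype(float).to_numpy())
            names.append("arm_early")
        else:
            cols.append(rows[cov].astype(float).to_numpy())
            names.append(cov)
    return np.column_stack(cols), names


def fit_clogit(
    rows: pd.DataFrame, exposure: str, adjust_for: tuple[str, ...] = ()
) -> ConditionalLogitResults:
    """Fit a conditional logit to an analysis table for one exposure.

    ``rows`` is the output of
    :func:`nestedcc.exposure.build_analysis_table`; ``adjust_for`` may
    name ``"trial_arm"`` (coded as an early-arm indicator) or any numeric
    column of the table.
    """
    X, names = _design_from_rows(rows, exposure, tuple(adjust_for))
    model = ConditionalLogit(
        rows["is_case"].to_numpy(), X, rows["set_id"].to_numpy(), param_names=names
    )
    return model.fit()


def odds_ratio_report(
    fits: dict[tuple[str, str], "ConditionalLogitResults | Exception"],
) -> pd.DataFrame:
    """Tabulate odds ratios per exposure x adjustment.

    Values of the mapping may be results objects or exceptions captured
    from failed fits; failures yield a row with a convergence flag of
    False and blank estimates.
    """
    if not fits:
        raise ValueError("no fits to report")
    rows = []
    for (exposure, adjustment), res in fits.items():
        if isinstance(res, Exception) or not res.converged:
            rows.append(
                {
                    "exposure": exposure,
                    "adjustment": adjustment,
                    "n_cases": getattr(res, "n_cases", np.nan),
                    "n_controls": getattr(res, "n_controls", np.nan),
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "converged": False,
                    "n_informative_sets": getattr(res, "n_informative_sets", np.nan),
                    "note": str(res) if isinstance(res, Exception) else res.separation or "did not converge",
                }
            )
            continue
        orr = res.odds_ratios().loc[exposure]
        rows.append(
            {
                "exposure": exposure,
                "adjustment": adjustment,
                "n_cases": res.n_cases,
                "n_controls": res.n_controls,
                "odds_ratio": orr["odds_ratio"],
                "ci_low": orr["ci_low"],
                "ci_high": orr["ci_high"],
                "converged": True,
                "n_informative_sets": res.n_informative_sets,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`odds_ratio_report` output."""
    lines = [
        f"{'exposure':<18}{'adjustment':<14}{'OR':>8}{'95% CI':>18}"
        f"{'cases':>7}{'ctrls':>7}{'conv':>6}"
    ]
    for _, r in report.iterrows():
        if r["converged"]:
            or_s = f"{r['odds_ratio']:.2f}"
            ci_s = f"({r['ci_low']:.2f}, {r['ci_high']:.2f})"
        else:
            or_s, ci_s = "-", "-"
        lines.append(
            f"{r['exposure']:<18}{r['adjustment']:<14}{or_s:>8}{ci_s:>18}"
            f"{r['n_cases']!s:>7}{r['n_controls']!s:>7}{str(bool(r['converged'])):>6}"
        )
    return "\n".join(lines)
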