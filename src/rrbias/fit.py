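"""Maximum-likelihood estimation, standard errors and model fit.

Estimation maximizes the multinomial kernel ``ln l(Phi | n) = n' ln pi*``
over an unconstrained parameterization: category probabilities through
the softmax map (one reference category fixed at zero) and the bias
parameters theta / theta_yy_yn on their natural scale, so that theta may
go negative.  A multi-start quasi-Newton search is followed by an exact
natural-scale polish (SLSQP on the probability simplex) because softmax
coordinates can only approach simplex-boundary optima asymptotically,
and boundary solutions do occur in practice for sparse profile tables.

Standard errors use the delta method: the observed information on the
unconstrained scale is inverted and propagated through the Jacobian of
the natural-parameter map (both by central finite differences).

Model fit is summarized by the deviance ``G2 = 2 n' ln(n / nhat)`` on
``df = (non-redundant cells) - (free parameters)`` degrees of freedom,
and models are ranked by ``AIC = 2k - 2 ln l`` (kernel log-likelihood;
only AIC differences between models on the same data are meaningful).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

from .design import DesignLayout, build_design_matrix, kronecker_chain
from .models import ProfileProbs, loglinear_design_matrix

__all__ = ["ProfileCounts", "FitResult", "loglik", "fit_ml", "deviance_g2", "aic", "lr_test"]

_NEG_PENALTY = 1e12
_BOUNDARY_EPS = 1e-7


@dataclass
class ProfileCounts:
    """Labelled non-negative frequencies of observed response profiles.

    Float values are accepted so that exact expected frequencies (or
    probability weights) can be fitted; real surveys use integers.
    """

    counts: np.ndarray
    labels: list[str]
    block_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.labels),):
            raise ValueError("counts and labels differ in length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.block_index is None:
            self.block_index = np.zeros(len(self.labels), dtype=int)
        else:
            self.block_index = np.asarray(self.block_index, dtype=int)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def block_totals(self) -> np.ndarray:
        nb = int(self.block_index.max()) + 1
        return np.array([self.counts[self.block_index == b].sum() for b in range(nb)])

    def check_layout(self, layout: DesignLayout) -> None:
        if self.labels != layout.obs_labels:
            raise ValueError(
                f"profile labels {self.labels} do not match the design's {layout.obs_labels}")

    def to_frame(self, layout: DesignLayout | None = None) -> pd.DataFrame:
        rows = []
        for lab, cnt, blk in zip(self.labels, self.counts, self.block_index):
            letters = lab.split("|")[0]
            row = {}
            if layout is not None:
                for qname, letter in zip(layout.question_names, letters):
                    row[qname] = letter
            else:
                for i, letter in enumerate(letters):
                    row[f"q{i + 1}"] = letter
            if "|" in lab or self.block_index.max() > 0:
                row["subsample"] = blk + 1
            row["count"] = int(cnt) if float(cnt).is_integer() else cnt
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class FitResult:
    """Everything a fitted model reports."""

    model: str
    layout: DesignLayout
    estimates: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    aic: float
    g2: float
    df: int
    p_value: float | None
    fitted_counts: np.ndarray
    observed: ProfileCounts
    n_params: int
    converged: bool
    n_starts_used: int
    best_start: int
    boundary: bool
    se_available: bool
    profile_probs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def summary(self) -> str:
        lines = [f"model: {self.model}"]
        width = max(len(k) for k in self.estimates)
        for k, v in self.estimates.items():
            se = self.std_errors.get(k)
            se_s = f"({se:.3f})" if se is not None and np.isfinite(se) else "(  na )"
            lines.append(f"  {k:<{width}s}  {v: .3f} {se_s}")
        p_s = f", p = {self.p_value:.3f}" if self.p_value is not None else " (saturated df)"
        lines.append(f"  G2({self.df}) = {self.g2:.2f}{p_s}")
        lines.append(f"  logLik = {self.loglik:.3f}, AIC = {self.aic:.1f}, k = {self.n_params}")
        if self.boundary:
            lines.append("  note: solution on the boundary of the parameter space")
        if not self.converged:
            lines.append("  WARNING: optimizer did not converge")
        return "\n".join(lines)


def loglik(probs: ProfileProbs, counts: ProfileCounts) -> float:
    """Multinomial kernel log-likelihood ``sum_r n_r ln pi*_r``.

    Returns ``-inf`` (with a warning) when a profile with positive count
    has zero probability.  For the sub-samples design this is the
    product-multinomial kernel: the per-block contributions simply add.
    """
    if probs.labels != counts.labels:
        raise ValueError("profile labels of probabilities and counts do not match")
    n = counts.counts
    p = probs.values
    bad = (n > 0) & (p <= 0)
    if np.any(bad):
        warnings.warn(f"zero probability at observed profiles {[counts.labels[i] for i in np.flatnonzero(bad)]}")
        return -np.inf
    nz = n > 0
    return float(n[nz] @ np.log(p[nz]))


# ---------------------------------------------------------------------------
# internal model parameterizations


def _softmax(beta_free: np.ndarray) -> np.ndarray:
    b = np.concatenate([[0.0], beta_free])
    b = b - b.max()
    w = np.exp(b)
    return w / w.sum()


class _Parameterization:
    """Unconstrained parameterization of one (layout, model) pair.

    Provides the map x -> pi*, the natural-parameter map, the free
    parameter count and the natural-scale polish problem.
    """

    def __init__(self, layout: DesignLayout, model: str):
        self.layout = layout
        self.model = model
        self.cat_labels = list(layout.true_labels)
        C = len(self.cat_labels)
        base = build_design_matrix(layout, bias_structure="none")
        self.T = base.values
        self.row_labels = list(base.row_labels)
        self.block_index = base.block_index
        self.e = base.allno_indicator()
        self.loglinear = False
        self.X = None

        if model == "null":
            self.n_free = C - 1
            self.names = self.cat_labels
        elif model == "cdm":
            self.n_free = C
            self.names = self.cat_labels + ["tau_c"]
        elif model == "sp_no":
            pure_mq = (not layout.subsamples and not layout.has_ely
                       and len(layout.blocks) >= 2)
            if pure_mq:
                # log-linear identification: independence for two questions,
                # no-three-way for three
                structure = "independence" if layout.n_questions == 2 else "no_threeway"
                if layout.n_questions > 3:
                    structure = "independence"
                self.X, cells, self.lam_names = loglinear_design_matrix(
                    layout.n_questions, structure)
                if cells != self.cat_labels:
                    raise AssertionError("log-linear cell order mismatch")
                self.loglinear = True
                self.n_free = self.X.shape[1] + 1
                self.names = self.cat_labels + ["theta"]
            else:
                if C - 1 + 1 > len(self.row_labels) - base.n_blocks:
                    raise ValueError("SP-no model not identified for this design")
                self.n_free = C
                self.names = self.cat_labels + ["theta"]
        elif model == "sp_last_year":
            if not layout.has_ely:
                raise ValueError("sp_last_year requires an ever/last-year block")
            self.n_free = C + 1
            self.names = self.cat_labels + ["theta", "theta_yy_yn"]
            self._setup_sply()
        elif model == "sp_no_by_category":
            raise ValueError("free per-category SP-no probabilities are not identified; "
                             "use the CDM/SP-no correspondence variants instead")
        else:
            raise ValueError(f"unknown model {model!r}")

        n_cells = len(self.row_labels) - base.n_blocks
        if self.n_free > n_cells:
            raise ValueError(
                f"model {model!r} has {self.n_free} free parameters but only "
                f"{n_cells} non-redundant cells: not identified")
        self.df = n_cells - self.n_free

    def _setup_sply(self) -> None:
        null_mats = [b.null_matrix() for b in self.layout.blocks]
        from .design import _ely_edit_operator  # local import of the row operator
        self.edit_terms = []  # (diff matrix, column mask) per ELY block
        comps = []
        for lab in self.cat_labels:
            pos, parts = 0, []
            for b in self.layout.blocks:
                w = 2 if b.kind == "ever_last_year" else 1
                parts.append(lab[pos:pos + w])
                pos += w
            comps.append(parts)
        for j, b in enumerate(self.layout.blocks):
            if b.kind != "ever_last_year":
                continue
            mats = list(null_mats)
            from .design import TransitionMatrix
            ed = _ely_edit_operator() @ null_mats[j].values
            mats[j] = TransitionMatrix(ed, null_mats[j].row_labels, null_mats[j].col_labels)
            edited = kronecker_chain(mats).values
            mask = np.array([parts[j] == "yy" for parts in comps], dtype=float)
            self.edit_terms.append((edited - self.T, mask))
        self.max_edit_blocks = int(max(sum(mask[t] for _, mask in self.edit_terms)
                                       for t in range(len(self.cat_labels))))

    # -- forward map ------------------------------------------------------

    def probs(self, x: np.ndarray) -> np.ndarray:
        m = self.model
        if m == "null":
            return self.T @ _softmax(x)
        if m == "cdm":
            tau = _softmax(x)
            return self.T @ tau[:-1] + self.e * tau[-1]
        if m == "sp_no":
            theta = x[-1]
            if self.loglinear:
                lp = self.X @ x[:-1]
                w = np.exp(lp - lp.max())
                pi = w / w.sum()
            else:
                pi = _softmax(x[:-1])
            return (1 - theta) * (self.T @ pi) + theta * self.e
        if m == "sp_last_year":
            theta, the = x[-2], x[-1]
            pi = _softmax(x[:-2])
            out = (1 - theta) * (self.T @ pi) + theta * self.e
            for diff, mask in self.edit_terms:
                out = out + the * (diff @ (mask * pi))
            return out
        raise AssertionError(m)

    # -- natural parameters ----------------------------------------------

    def natural(self, x: np.ndarray) -> np.ndarray:
        m = self.model
        if m == "null":
            return _softmax(x)
        if m == "cdm":
            return _softmax(x)
        if m == "sp_no":
            if self.loglinear:
                lp = self.X @ x[:-1]
                w = np.exp(lp - lp.max())
                pi = w / w.sum()
            else:
                pi = _softmax(x[:-1])
            return np.concatenate([pi, [x[-1]]])
        if m == "sp_last_year":
            return np.concatenate([_softmax(x[:-2]), x[-2:]])
        raise AssertionError(m)

    def from_natural(self, nat: np.ndarray) -> np.ndarray:
        """Map natural parameters back to the unconstrained scale (clipping zeros)."""
        m = self.model
        if m in ("null", "cdm"):
            pi = np.clip(nat, 1e-10, None)
            beta = np.log(pi / pi[0])
            return beta[1:]
        if m == "sp_no":
            pi = np.clip(nat[:-1], 1e-10, None)
            if self.loglinear:
                lam, *_ = np.linalg.lstsq(
                    self.X - self.X.mean(axis=0), np.log(pi) - np.log(pi).mean(), rcond=None)
                return np.concatenate([lam, [nat[-1]]])
            beta = np.log(pi / pi[0])
            return np.concatenate([beta[1:], [nat[-1]]])
        if m == "sp_last_year":
            pi = np.clip(nat[:-2], 1e-10, None)
            beta = np.log(pi / pi[0])
            return np.concatenate([beta[1:], nat[-2:]])
        raise AssertionError(m)

    def x_bounds(self) -> list[tuple[float, float]]:
        m = self.model
        if m == "null":
            return [(-30, 30)] * self.n_free
        if m == "cdm":
            return [(-30, 30)] * self.n_free
        if m == "sp_no":
            return [(-30, 30)] * (self.n_free - 1) + [(-0.5, 1.0)]
        if m == "sp_last_year":
            return [(-30, 30)] * (self.n_free - 2) + [(-0.5, 1.0), (0.0, 1.0)]
        raise AssertionError(m)

    # -- natural-scale polish problem -------------------------------------

    def polish_problem(self, nat0: np.ndarray):
        """Return (x0, objective-args) for SLSQP on the natural scale.

        Variables are the category probabilities (full simplex) plus the
        raw bias parameters; None is returned when the model has no
        useful natural-scale formulation (log-linear SP-no).
        """
        if self.loglinear:
            return None
        C = len(self.cat_labels)
        m = self.model
        if m == "null":
            nvar, split = C, C
        elif m == "cdm":
            nvar, split = C + 1, C + 1
        elif m == "sp_no":
            nvar, split = C + 1, C
        else:
            nvar, split = C + 2, C

        def nat_probs(v: np.ndarray) -> np.ndarray:
            if m == "null":
                return self.T @ v
            if m == "cdm":
                return self.T @ v[:-1] + self.e * v[-1]
            if m == "sp_no":
                pi, theta = v[:C], v[C]
                return (1 - theta) * (self.T @ pi) + theta * self.e
            pi, theta, the = v[:C], v[C], v[C + 1]
            out = (1 - theta) * (self.T @ pi) + theta * self.e
            for diff, mask in self.edit_terms:
                out = out + the * (diff @ (mask * pi))
            return out

        bounds = [(0.0, 1.0)] * split
        if m in ("sp_no", "sp_last_year"):
            bounds.append((-0.5, 1.0))
        if m == "sp_last_year":
            bounds.append((0.0, 1.0))
        cons = [{"type": "eq", "fun": lambda v: v[:split].sum() - 1.0}]
        if m in ("sp_no", "sp_last_year"):
            cons.append({"type": "ineq", "fun": lambda v: nat_probs(v)})
        if m == "sp_last_year":
            k = self.max_edit_blocks
            cons.append({"type": "ineq",
                         "fun": lambda v: 1.0 - v[C] - max(k, 1) * v[C + 1]})

        if m in ("null", "cdm"):
            v0 = nat0.copy()
        elif m == "sp_no":
            v0 = nat0.copy()
        else:
            v0 = nat0.copy()
        return v0, nat_probs, bounds, cons, split


# ---------------------------------------------------------------------------


def _nll_factory(par: _Parameterization, counts: np.ndarray):
    nz = counts > 0

    def nll(x: np.ndarray) -> float:
        p = par.probs(x)
        if np.any(p[nz] <= 0) or np.any(p < -1e-12):
            return _NEG_PENALTY + np.sum(np.minimum(p, 0.0) ** 2)
        return -float(counts[nz] @ np.log(p[nz]))

    return nll


def _hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi = np.zeros(n); xi[i] = h
            xj = np.zeros(n); xj[j] = h
            if i == j:
                H[i, i] = (f(x + xi) - 2 * f0 + f(x - xi)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + xi + xj) - f(x + xi - xj) - f(x - xi + xj) + f(x - xi - xj)
                ) / (4 * h ** 2)
    return H


def _jacobian(g, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g0 = np.asarray(g(x))
    J = np.empty((len(g0), len(x)))
    for i in range(len(x)):
        d = np.zeros(len(x)); d[i] = h
        J[:, i] = (np.asarray(g(x + d)) - np.asarray(g(x - d))) / (2 * h)
    return J


def fit_ml(layout: DesignLayout, model: str, counts: ProfileCounts, *,
           n_starts: int = 20, seed: int = 0, polish: bool = True,
           gtol: float = 1e-10, compute_se: bool = True) -> FitResult:
    """Fit a randomized-response model by maximum likelihood.

    Parameters
    ----------
    layout
        Question structure and randomization probabilities.
    model
        One of ``"null"``, ``"cdm"``, ``"sp_no"``, ``"sp_last_year"``.
        For a pure multiple-questions design ``"sp_no"`` uses the
        log-linear identification (independence for two questions,
        no-three-way interaction for three).
    counts
        Observed profile frequencies matching ``layout.obs_labels``.
    n_starts
        Number of random starts of the quasi-Newton stage (the first
        start is deterministic at the uniform distribution).
    seed
        Seeds the random starts; fits are reproducible given the seed.
    polish
        Run the natural-scale SLSQP polish able to reach simplex-
        boundary solutions exactly.
    compute_se
        Delta-method standard errors (skippable for speed in
        simulation loops).
    """
    counts.check_layout(layout)
    par = _Parameterization(layout, model)
    n = counts.counts
    nll = _nll_factory(par, n)
    rng = np.random.default_rng(seed)
    bounds = par.x_bounds()

    best_fun, best_x, best_start, n_conv = np.inf, None, -1, 0
    for s in range(max(n_starts, 1)):
        if s == 0:
            x0 = np.zeros(par.n_free)
            if model in ("sp_no", "sp_last_year"):
                x0[-1] = 0.02
            if model == "sp_last_year":
                x0[-2], x0[-1] = 0.02, 0.05
        else:
            x0 = rng.normal(0.0, 0.75, par.n_free)
            if model in ("sp_no", "sp_last_year"):
                x0[-1] = rng.uniform(-0.05, 0.3)
            if model == "sp_last_year":
                x0[-2] = rng.uniform(-0.05, 0.3)
                x0[-1] = rng.uniform(0.0, 0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                           options=dict(maxiter=2000, ftol=1e-14, gtol=gtol))
        if res.fun < best_fun - 1e-12:
            best_fun, best_x, best_start = res.fun, res.x, s
        n_conv += bool(res.success)

    if best_x is None:
        raise RuntimeError("no optimizer start produced a finite log-likelihood")

    converged = n_conv > 0
    nat = par.natural(best_x)

    # natural-scale polish: reaches boundary MLEs the softmax scale cannot
    if polish:
        prob = par.polish_problem(nat)
        if prob is not None:
            v0, nat_probs, nbounds, cons, split = prob
            nzmask = n > 0

            def nat_nll(v: np.ndarray) -> float:
                p = nat_probs(v)
                if np.any(p[nzmask] <= 0):
                    return _NEG_PENALTY
                return -float(n[nzmask] @ np.log(p[nzmask]))

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                resn = minimize(nat_nll, np.clip(v0, 0, None), method="SLSQP",
                                bounds=nbounds, constraints=cons,
                                options=dict(maxiter=2000, ftol=1e-14))
            if np.isfinite(resn.fun) and resn.fun < best_fun - 1e-10:
                best_fun = resn.fun
                v = resn.x
                v[:split] = np.clip(v[:split], 0.0, None)
                v[:split] /= v[:split].sum()
                nat = v
                best_x = par.from_natural(nat)
                converged = converged or resn.success
        else:
            # log-linear models: second, tighter quasi-Newton pass
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res2 = minimize(nll, best_x, method="Nelder-Mead",
                                options=dict(maxiter=20000, xatol=1e-12, fatol=1e-13))
            if res2.fun < best_fun:
                best_fun, best_x = res2.fun, res2.x
                nat = par.natural(best_x)

    ll = -best_fun
    pi_star = (par.probs(best_x) if not polish or par.polish_problem(nat) is None
               else _natural_probs(par, nat))
    pi_star = np.clip(pi_star, 0.0, None)

    # fitted counts per row block
    bt = counts.block_totals()
    fitted = pi_star * bt[par.block_index]

    g2, p_value = deviance_g2(counts, fitted, par.df)
    k = par.n_free
    aic_val = 2 * k - 2 * ll

    boundary = bool(np.any(nat[:len(par.cat_labels) + (model == "cdm")] < _BOUNDARY_EPS))

    names = list(par.names)
    estimates = dict(zip(names, [float(v) for v in nat]))

    std_errors: dict[str, float] = {}
    se_available = False
    if compute_se:
        try:
            x_se = par.from_natural(nat)
            H = _hessian(nll, x_se)
            cov = np.linalg.pinv(H)
            J = _jacobian(par.natural, x_se)
            var = np.clip(np.diag(J @ cov @ J.T), 0.0, None)
            std_errors = dict(zip(names, np.sqrt(var)))
            se_available = bool(np.all(np.isfinite(list(std_errors.values()))))
        except (np.linalg.LinAlgError, ValueError):
            std_errors = {k_: float("nan") for k_ in names}

    return FitResult(
        model=model, layout=layout, estimates=estimates, std_errors=std_errors,
        loglik=ll, aic=aic_val, g2=g2, df=par.df, p_value=p_value,
        fitted_counts=fitted, observed=counts, n_params=k, converged=converged,
        n_starts_used=max(n_starts, 1), best_start=best_start,
        boundary=boundary, se_available=se_available, profile_probs=pi_star)


def _natural_probs(par: _Parameterization, nat: np.ndarray) -> np.ndarray:
    prob = par.polish_problem(nat)
    if prob is None:
        return par.probs(par.from_natural(nat))
    _, nat_probs, *_ = prob
    return nat_probs(nat)


def deviance_g2(counts: ProfileCounts, fitted: np.ndarray, df: int) -> tuple[float, float | None]:
    """Deviance ``G2 = 2 n' ln(n/nhat)`` and its chi-squared p-value.

    Cells with zero observed count contribute zero (0 ln 0 = 0).  A
    fitted zero with a positive observed count makes the deviance
    infinite and is reported as an error.  With zero residual degrees
    of freedom the p-value is undefined (``None``).
    """
    n = counts.counts if isinstance(counts, ProfileCounts) else np.asarray(counts, float)
    fitted = np.asarray(fitted, dtype=float)
    nz = n > 0
    if np.any(fitted[nz] <= 0):
        raise ValueError("fitted frequency zero at an observed profile; deviance undefined")
    g2 = float(2.0 * n[nz] @ np.log(n[nz] / fitted[nz]))
    if df > 0:
        return g2, float(chi2_dist.sf(max(g2, 0.0), df))
    return g2, None


def aic(fit: FitResult) -> float:
    """AIC = 2k - 2 lnl with k the number of free identified parameters.

    The absolute value depends on the parameter-counting convention and
    on the kernel (no multinomial coefficient); only differences between
    models fitted to the same data are meaningful.
    """
    return fit.aic


def lr_test(fit_null: FitResult, fit_alt: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits on the same data.

    Returns ``(statistic, df, p_value)`` with
    ``statistic = 2 (lnl_alt - lnl_null) = G2_null - G2_alt``.
    """
    if fit_null.observed.labels != fit_alt.observed.labels:
        raise ValueError("fits are not on the same data")
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("models are not nested (df <= 0)")
    stat = max(2.0 * (fit_alt.loglik - fit_null.loglik), 0.0)
    return stat, df, float(chi2_dist.sf(stat, df))
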