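"""Monte-Carlo power analysis for detecting SP-no saying / cheating.

For each grid cell a large number of surveys is simulated under the
SP-no data-generating process, the null and SP-no models are fitted,
and the rejection rate of the test of theta = 0 is recorded.  The
default test is the likelihood-ratio statistic 2 (lnl_spno - lnl_null)
referred to chi-squared with one degree of freedom at alpha = .05; a
Wald test (theta_hat / se) is available behind a flag.  Negative theta
estimates are retained, making the test two-sided.

The study conditions mirror the power analysis of the ever/last-year
designs: the all-never category has prevalence pi_never and the
remaining true categories share (1 - pi_never)/k equally; every
question uses p = 5/6 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .design import DesignLayout, QuestionBlock, RandomizationSpec
from .fit import fit_ml, lr_test
from .models import TrueCategoryProbs
from .simulate import SimulationScenario, simulate_counts

__all__ = ["PowerCell", "design_variant", "equal_remainder_probs", "power_grid",
           "power_cell", "efficiency_compare"]

VARIANTS = ("ely1", "ely1+q", "ely2")


@dataclass
class PowerCell:
    """Result of one power-grid cell."""

    variant: str
    pi_never: float
    theta: float
    n: int
    p: float
    reps: int
    alpha: float
    rejection_rate: float
    mc_std_error: float


def design_variant(variant: str, p: float = 5 / 6) -> DesignLayout:
    """Layout of a named design variant.

    ``ely1``: one set of ever/last-year questions; ``ely1+q``: one set
    plus a third dichotomous question; ``ely2``: two sets.
    """
    rand = RandomizationSpec(p)
    ely = QuestionBlock("ever_last_year", rand)
    single = QuestionBlock("single", rand)
    if variant == "ely1":
        return DesignLayout([ely])
    if variant == "ely1+q":
        return DesignLayout([ely, single])
    if variant == "ely2":
        return DesignLayout([ely, ely])
    raise ValueError(f"unknown design variant {variant!r}; expected one of {VARIANTS}")


def equal_remainder_probs(layout: DesignLayout, pi_never: float) -> TrueCategoryProbs:
    """All-never category at pi_never, remaining mass split equally."""
    labels = layout.true_labels
    k = len(labels) - 1
    vals = np.full(len(labels), (1.0 - pi_never) / k)
    vals[labels.index("n" * layout.n_questions)] = pi_never
    return TrueCategoryProbs(vals, labels)


def power_cell(variant: str, pi_never: float, theta: float, n: int, *,
               p: float = 5 / 6, reps: int = 1000, alpha: float = 0.05,
               seed: int = 0, test: str = "lr", n_starts: int = 2) -> PowerCell:
    """Monte-Carlo rejection rate of the theta = 0 test in one condition."""
    if reps < 1:
        raise ValueError("reps must be positive")
    if test not in ("lr", "wald"):
        raise ValueError("test must be 'lr' or 'wald'")
    layout = design_variant(variant, p)
    probs = equal_remainder_probs(layout, pi_never)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * reps) % (2 ** 31)
    crit = float(chi2_dist.ppf(1 - alpha, 1))
    rejections = 0
    for r in range(reps):
        scen = SimulationScenario(layout=layout, true_probs=probs, theta=theta,
                                  n=n, seed=int(child_seeds[2 * r]))
        counts = simulate_counts(scen)
        fit0 = fit_ml(layout, "null", counts, n_starts=n_starts,
                      seed=int(child_seeds[2 * r + 1]), compute_se=False)
        fit1 = fit_ml(layout, "sp_no", counts, n_starts=n_starts,
                      seed=int(child_seeds[2 * r + 1]), compute_se=(test == "wald"))
        if test == "lr":
            stat, _, pval = lr_test(fit0, fit1)
            rejections += pval < alpha
        else:
            se = fit1.std_errors.get("theta", float("nan"))
            if np.isfinite(se) and se > 0:
                rejections += (fit1.estimates["theta"] / se) ** 2 > crit
    rate = rejections / reps
    return PowerCell(variant, pi_never, theta, n, p, reps, alpha, rate,
                     float(np.sqrt(rate * (1 - rate) / reps)))


def power_grid(variants: Sequence[str], pi_never_values: Sequence[float],
               theta_values: Sequence[float], n_values: Sequence[int], *,
               p: float = 5 / 6, reps: int = 1000, alpha: float = 0.05,
               seed: int = 0, test: str = "lr", n_starts: int = 2) -> pd.DataFrame:
    """Rejection rates over the full condition grid.

    Each cell gets an independent sub-seed derived deterministically
    from the master seed, so cells are reproducible individually.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    cells = [(v, pn, th, n) for v in variants for pn in pi_never_values
             for th in theta_values for n in n_values]
    cell_seeds = ss.generate_state(len(cells)) % (2 ** 31)
    for (v, pn, th, n), cs in zip(cells, cell_seeds):
        cell = power_cell(v, pn, th, n, p=p, reps=reps, alpha=alpha,
                          seed=int(cs), test=test, n_starts=n_starts)
        rows.append(vars(cell))
    return pd.DataFrame(rows)


def efficiency_compare(p_values: Sequence[float], pi: TrueCategoryProbs, n: int, *,
                       reps: int = 500, seed: int = 0, theta: float = 0.1,
                       pi_never: float = 0.8, alpha: float = 0.05,
                       n_starts: int = 2) -> pd.DataFrame:
    """Efficiency of the last-year estimate and power across p values.

    For each randomization probability ``p`` this reports (a) the
    empirical standard error of the last-year prevalence estimate under
    the ever/last-year design versus a design asking only the last-year
    question, at matched n, and (b) the power to detect ``theta`` of
    SP-no saying.  Lower p (closer to 1/2) costs precision on the
    prevalence but buys power for the bias parameter.
    """
    if pi.labels != ["nn", "yn", "yy"]:
        raise ValueError("pi must be ever/last-year category probabilities (nn, yn, yy)")
    rows = []
    ss = np.random.SeedSequence(seed)
    for ip, p in enumerate(p_values):
        rand = RandomizationSpec(p)
        ely_layout = DesignLayout([QuestionBlock("ever_last_year", rand)])
        child = np.random.SeedSequence([seed, ip]).generate_state(2 * reps) % (2 ** 31)
        est_ely, est_single = [], []
        for r in range(reps):
            scen = SimulationScenario(layout=ely_layout, true_probs=pi, n=n,
                                      seed=int(child[2 * r]))
            counts = simulate_counts(scen)
            fit = fit_ml(ely_layout, "null", counts, n_starts=n_starts,
                         seed=int(child[2 * r + 1]), compute_se=False)
            est_ely.append(fit.estimates["yy"])
            # single last-year question at the same p and n: the observed
            # yes-rate inverts linearly, the interior ML solution
            rng = np.random.default_rng(int(child[2 * r]) + 1)
            true_y = rng.random(n) < pi.values[2]
            flip = rng.random(n) < (1 - p)
            yes = np.sum(np.where(flip, ~true_y, true_y))
            est_single.append((yes / n - (1 - p)) / (2 * p - 1))
        cell = power_cell("ely1", pi_never, theta, n, p=p,
                          reps=reps, alpha=alpha,
                          seed=int(np.random.SeedSequence([seed, 1000 + ip]).generate_state(1)[0] % (2 ** 31)),
                          n_starts=n_starts)
        rows.append({
            "p": p, "n": n, "reps": reps,
            "se_lastyear_ely": float(np.std(est_ely, ddof=1)),
            "se_lastyear_single": float(np.std(est_single, ddof=1)),
            "power_theta": cell.rejection_rate,
            "power_mc_se": cell.mc_std_error,
        })
    return pd.DataFrame(rows)
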