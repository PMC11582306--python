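"""Forward probability maps and model algebra.

The statistical models all share the structure ``pi* = f(Phi)`` mapping
true-category probabilities (plus optional bias parameters) to observed
randomized-response profile probabilities.  This module provides the
forward maps, the log-linear identification used for the pure
multiple-questions design, the algebraic correspondence between the
cheater-detection model (CDM) and the SP-no model for the sub-samples
design, the exact CDM inversion for that design, and the misreport
fraction of a sample with SP-no sayers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (
    BiasParams,
    DesignLayout,
    RandomizationSpec,
    build_design_matrix,
    subsamples_matrix,
)

__all__ = [
    "TrueCategoryProbs",
    "ProfileProbs",
    "LoglinearParams",
    "forward",
    "loglinear_probs",
    "loglinear_design_matrix",
    "cdm_spno_correspondence",
    "spno_cdm_inverse",
    "invert_cdm_subsamples",
    "misreport_fraction",
]

PROB_TOL = 1e-10


@dataclass
class TrueCategoryProbs:
    """Labelled probability vector over adherent true categories.

    ``cheater_prob`` holds the CDM cheater prevalence tau_c when
    present; then ``sum(values) + cheater_prob = 1``.
    """

    values: np.ndarray
    labels: list[str]
    cheater_prob: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("values and labels differ in length")
        if np.any(self.values < -PROB_TOL):
            raise ValueError("category probabilities must be non-negative")
        total = self.values.sum() + (self.cheater_prob or 0.0)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"category probabilities sum to {total}, expected 1")

    def as_dict(self) -> dict[str, float]:
        d = {lab: float(v) for lab, v in zip(self.labels, self.values)}
        if self.cheater_prob is not None:
            d["c"] = float(self.cheater_prob)
        return d


@dataclass
class ProfileProbs:
    """Labelled observed-profile probabilities, one simplex per row block."""

    values: np.ndarray
    labels: list[str]
    block_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("values and labels differ in length")
        if self.block_index is None:
            self.block_index = np.zeros(len(self.labels), dtype=int)
        else:
            self.block_index = np.asarray(self.block_index, dtype=int)
        for b in np.unique(self.block_index):
            s = self.values[self.block_index == b].sum()
            if abs(s - 1.0) > 1e-8:
                raise ValueError(f"profile probabilities of block {b} sum to {s}")
        if np.any(self.values < -PROB_TOL):
            raise ValueError("profile probabilities must be non-negative")


def forward(layout: DesignLayout, probs: TrueCategoryProbs,
            bias: BiasParams | None = None,
            bias_structure: str | None = None) -> ProfileProbs:
    """Forward map pi* = P(Phi) pi for any supported design and bias model.

    For the CDM, ``probs`` must carry ``cheater_prob`` and the cheater
    column of the transition matrix is used; for SP-no and
    SP(last-year) the bias parameters live inside the matrix.  The
    result is an exact matrix-vector product (no renormalization).
    """
    structure = bias_structure if bias_structure is not None else layout.bias_structure
    T = build_design_matrix(layout, bias=bias, bias_structure=structure)
    if structure == "cdm":
        if probs.cheater_prob is None:
            raise ValueError("CDM forward needs cheater_prob in TrueCategoryProbs")
        vec = np.concatenate([probs.values, [probs.cheater_prob]])
        labels = probs.labels + ["c"]
    else:
        vec = probs.values
        labels = probs.labels
    if labels != T.col_labels:
        raise ValueError(f"category labels {labels} do not match design {T.col_labels}")
    out = T.values @ vec
    if np.any(out < -PROB_TOL):
        raise ValueError("bias parameters push a profile probability below zero")
    return ProfileProbs(np.clip(out, 0.0, None), list(T.row_labels), T.block_index.copy())


# ---------------------------------------------------------------------------
# log-linear identification for the pure multiple-questions design


@dataclass
class LoglinearParams:
    """Dummy-coded log-linear parameters with true response n as reference.

    For two questions the independence model (A, B) uses the two main
    effects; for three questions the no-three-way model (AB, AC, BC)
    adds the three pairwise interactions.  The normalizing constant is
    implicit (cell probabilities are normalized to sum to one).
    """

    main_effects: dict[str, float]
    pairwise: dict[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pairwise is None:
            self.pairwise = {}


def loglinear_design_matrix(n_questions: int, structure: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Cell-by-parameter design matrix of the log-linear model.

    Returns ``(X, cell_labels, param_names)`` such that the cell
    probabilities are ``softmax(X @ beta)``.  ``structure`` is
    ``"independence"`` (main effects only; the identifying assumption
    for two questions) or ``"no_threeway"`` (all pairwise interactions;
    requires three questions).
    """
    if structure not in ("independence", "no_threeway"):
        raise ValueError(f"unknown log-linear structure {structure!r}")
    if structure == "no_threeway" and n_questions != 3:
        raise ValueError("the no-three-way model is defined for three questions")
    letters = [chr(ord("A") + i) for i in range(n_questions)]
    cells = [""]
    for _ in range(n_questions):
        cells = [c + a for c in cells for a in "ny"]
    params = [f"{L}_y" for L in letters]
    if structure == "no_threeway":
        params += [f"{letters[i]}{letters[j]}_yy"
                   for i in range(n_questions) for j in range(i + 1, n_questions)]
    X = np.zeros((len(cells), len(params)))
    for r, cell in enumerate(cells):
        for i in range(n_questions):
            if cell[i] == "y":
                X[r, i] = 1.0
        if structure == "no_threeway":
            k = n_questions
            for i in range(n_questions):
                for j in range(i + 1, n_questions):
                    if cell[i] == "y" and cell[j] == "y":
                        X[r, k] = 1.0
                    k += 1
    return X, cells, params


def loglinear_probs(params: LoglinearParams, structure: str) -> TrueCategoryProbs:
    """Cell probabilities of the log-linear model, normalized to sum to one.

    Under the independence structure the joint yy probability factors
    into the product of the marginals.
    """
    n_questions = len(params.main_effects)
    X, cells, names = loglinear_design_matrix(
        n_questions, "independence" if structure in ("independence", "independence_2q") else "no_threeway")
    beta = []
    for name in names:
        if name.endswith("_y") and len(name) == 3:
            beta.append(params.main_effects[name[0]])
        else:
            beta.append(params.pairwise.get(name[:2], 0.0))
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite log-linear parameters")
    lp = X @ beta
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite log-linear predictor")
    w = np.exp(lp - lp.max())
    return TrueCategoryProbs(w / w.sum(), cells)


# ---------------------------------------------------------------------------
# CDM <-> SP-no correspondence (sub-samples design)


def cdm_spno_correspondence(tau: TrueCategoryProbs, variant: str) -> tuple[TrueCategoryProbs, float]:
    """Map CDM parameters (tau_n, tau_y, tau_c) to SP-no parameters (pi, theta).

    The three identifying variants fix the assumed true status of the
    cheaters: ``theta_equal`` (equal SP-no probability in both
    categories), ``theta_n_zero`` (only carriers say SP-no, so all
    cheaters are carriers: pi_y is the CDM upper bound), ``theta_y_zero``
    (only non-carriers say SP-no: pi_y is the CDM lower bound).
    """
    if tau.cheater_prob is None:
        raise ValueError("correspondence needs a CDM parameter vector with cheater_prob")
    if tau.labels != ["n", "y"]:
        raise ValueError("the correspondence is defined for the sub-samples design (labels n, y)")
    tau_n, tau_y = tau.values
    tau_c = tau.cheater_prob
    if variant == "theta_equal":
        if tau_c >= 1.0:
            raise ZeroDivisionError("tau_c = 1: no adherent respondents to renormalize")
        pi = np.array([tau_n, tau_y]) / (1.0 - tau_c)
        theta = tau_c
    elif variant == "theta_n_zero":
        pi = np.array([tau_n, tau_y + tau_c])
        theta = tau_c / (1.0 - tau_n)
    elif variant == "theta_y_zero":
        pi = np.array([tau_n + tau_c, tau_y])
        theta = tau_c / (1.0 - tau_y)
    else:
        raise ValueError(f"unknown correspondence variant {variant!r}")
    return TrueCategoryProbs(pi, ["n", "y"]), float(theta)


def spno_cdm_inverse(pi: TrueCategoryProbs, theta: float, variant: str) -> TrueCategoryProbs:
    """Closed-form inverse of :func:`cdm_spno_correspondence`."""
    if pi.labels != ["n", "y"]:
        raise ValueError("the correspondence is defined for the sub-samples design (labels n, y)")
    pi_n, pi_y = pi.values
    if variant == "theta_equal":
        tau_c = theta
        tau_n, tau_y = (1.0 - theta) * pi_n, (1.0 - theta) * pi_y
    elif variant == "theta_n_zero":
        # theta = tau_c / (1 - tau_n), tau_n = pi_n  =>  tau_c = theta (1 - pi_n)
        tau_n = pi_n
        tau_c = theta * (1.0 - pi_n)
        tau_y = pi_y - tau_c
    elif variant == "theta_y_zero":
        tau_y = pi_y
        tau_c = theta * (1.0 - pi_y)
        tau_n = pi_n - tau_c
    else:
        raise ValueError(f"unknown correspondence variant {variant!r}")
    return TrueCategoryProbs(np.array([tau_n, tau_y]), ["n", "y"], cheater_prob=float(tau_c))


def invert_cdm_subsamples(pi_star, p: float) -> tuple[TrueCategoryProbs, tuple[float, float]]:
    """Exact CDM solution for sub-sample conditional observed probabilities.

    Given ``pi_star = (pi*_{n|1}, pi*_{y|1}, pi*_{n|2}, pi*_{y|2})`` the
    "yes" rows are uncontaminated by cheaters, yielding a linear system
    for (tau_n, tau_y); the cheater prevalence is the remainder.
    Returns the CDM parameter vector and the (lower, upper) prevalence
    bounds ``(tau_y, tau_y + tau_c)``.
    """
    pi_star = np.asarray(pi_star, dtype=float)
    if pi_star.shape != (4,):
        raise ValueError("expected the 4-vector (n|1, y|1, n|2, y|2)")
    rand = RandomizationSpec(p)
    S = subsamples_matrix(rand)
    # rows y|1 and y|2 of the adherent 4x2 matrix
    A = S.values[[1, 3], :]
    tau_n, tau_y = np.linalg.solve(A, pi_star[[1, 3]])
    tau_c = 1.0 - tau_n - tau_y
    tau = TrueCategoryProbs(np.array([tau_n, tau_y]), ["n", "y"], cheater_prob=float(tau_c))
    return tau, (float(tau_y), float(tau_y + tau_c))


def misreport_fraction(pi_y: float, theta: float, p_nn: float) -> float:
    """Proportion of actually misreported responses in the whole sample.

    SP-no sayers answer "no" regardless of the randomizer, but only
    misreport when the randomizer required "yes": non-carriers with
    probability ``1 - p_nn`` and carriers with probability ``p_nn``.
    """
    for name, v in (("pi_y", pi_y), ("theta", theta), ("p_nn", p_nn)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return theta * (1.0 - pi_y) * (1.0 - p_nn) + theta * pi_y * p_nn
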