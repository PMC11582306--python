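"""Transition matrices for randomized-response designs.

A randomized-response (RR) design is described by a *transition matrix*
``P`` whose entry ``P[r, t]`` is the conditional probability of observing
randomized response profile ``r`` given true category ``t``; the forward
model for the observed profile probabilities is ``pi* = P @ pi``.

This module builds the transition matrices for

* a single dichotomous question with symmetric randomization
  (``p = p_{y|y} = p_{n|n}``),
* the two sub-samples design with complementary randomization
  probabilities,
* the ever/last-year design (two questions on the same attribute; the
  true profile "never, but used last year" is structurally impossible),
* Kronecker combinations of the above for multi-question designs,

and their bias-augmented variants: an extra "cheater" category (CDM), a
self-protective-no-saying (SP-no) mixture, and the SP(last-year) matrix
with an additional editing parameter for last-year carriers.

Profile labels are lexicographic with ``n`` before ``y`` and the
first-listed question varying slowest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RandomizationSpec",
    "QuestionBlock",
    "DesignLayout",
    "TransitionMatrix",
    "BiasParams",
    "symmetric_2x2",
    "asymmetric_2x2",
    "kronecker_chain",
    "identity_matrix",
    "subsamples_matrix",
    "everlastyear_matrix",
    "append_cheater_column",
    "splastyear_matrix",
    "build_design_matrix",
    "ALLNO_TOL",
]

#: numerical tolerance for column-sum checks
COLSUM_TOL = 1e-12
ALLNO_TOL = 1e-12

#: lower bound admitted for SP-no theta during estimation (the parameter
#: is estimated on its natural scale and may legitimately go negative).
THETA_LOWER = -0.5


@dataclass(frozen=True)
class RandomizationSpec:
    """Symmetric randomization probability of a single RR question.

    ``p`` is the probability that the recorded answer equals the true
    answer (``p = p_{y|y} = p_{n|n}``); ``q = 1 - p`` is the flip
    probability.  ``p = 1`` corresponds to direct questioning; at
    ``p = 0.5`` the design is uninformative (the observed distribution no
    longer depends on the true prevalence) which is exposed through
    :attr:`uninformative` rather than raised as an error.
    """

    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"randomization probability p must be in (0, 1], got {self.p}")

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def uninformative(self) -> bool:
        return self.p == 0.5


@dataclass(frozen=True)
class QuestionBlock:
    """One question block of a design.

    ``kind="single"`` is one dichotomous question (true categories
    ``n``/``y``); ``kind="ever_last_year"`` is a pair of questions on the
    same attribute (lifetime and last 12 months) sharing one
    randomization probability, with true categories ``nn`` (never),
    ``yn`` (former) and ``yy`` (last-year) — the profile ``ny`` is a
    structural zero and is omitted from the category space.
    """

    kind: str
    rand: RandomizationSpec
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("single", "ever_last_year"):
            raise ValueError(f"unknown question block kind {self.kind!r}")

    @property
    def n_questions(self) -> int:
        return 1 if self.kind == "single" else 2

    @property
    def n_true_categories(self) -> int:
        return 2 if self.kind == "single" else 3

    @property
    def true_labels(self) -> list[str]:
        return ["n", "y"] if self.kind == "single" else ["nn", "yn", "yy"]

    @property
    def obs_labels(self) -> list[str]:
        return ["n", "y"] if self.kind == "single" else ["nn", "ny", "yn", "yy"]

    def null_matrix(self) -> "TransitionMatrix":
        if self.kind == "single":
            return symmetric_2x2(self.rand)
        return everlastyear_matrix(self.rand)


@dataclass(frozen=True)
class DesignLayout:
    """Ordered question blocks plus optional two-sub-sample structure.

    The sub-samples design (two groups with complementary randomization
    probabilities) is only defined for a single one-question block.
    ``bias_structure`` records the default bias model attached to the
    design; it can be overridden at fit time.
    """

    blocks: tuple[QuestionBlock, ...]
    subsamples: bool = False
    bias_structure: str = "none"

    def __init__(self, blocks, subsamples: bool = False, bias_structure: str = "none"):
        object.__setattr__(self, "blocks", tuple(blocks))
        object.__setattr__(self, "subsamples", bool(subsamples))
        object.__setattr__(self, "bias_structure", bias_structure)
        self._validate()

    def _validate(self) -> None:
        if not self.blocks:
            raise ValueError("a design needs at least one question block")
        if self.bias_structure not in ("none", "cdm", "sp_no", "sp_last_year", "sp_no_by_category"):
            raise ValueError(f"unknown bias structure {self.bias_structure!r}")
        if self.subsamples:
            if len(self.blocks) != 1 or self.blocks[0].kind != "single":
                raise ValueError("the sub-samples design requires exactly one single-question block")
        if self.bias_structure == "sp_last_year" and not self.has_ely:
            raise ValueError("sp_last_year requires at least one ever/last-year block")
        if self.bias_structure == "sp_no_by_category" and not self.subsamples:
            raise ValueError("per-category SP-no probabilities are only identified "
                             "for the sub-samples design")

    @property
    def has_ely(self) -> bool:
        return any(b.kind == "ever_last_year" for b in self.blocks)

    @property
    def n_questions(self) -> int:
        return sum(b.n_questions for b in self.blocks)

    @property
    def question_names(self) -> list[str]:
        names = []
        for i, b in enumerate(self.blocks):
            base = b.name or f"q{i + 1}"
            if b.kind == "single":
                names.append(base)
            else:
                names.extend([f"{base}_ever", f"{base}_last"])
        return names

    @property
    def true_labels(self) -> list[str]:
        """Labels of the adherent true categories (no cheater class)."""
        labels = [""]
        for b in self.blocks:
            labels = [a + c for a in labels for c in b.true_labels]
        return labels

    @property
    def obs_labels(self) -> list[str]:
        if self.subsamples:
            return ["n|1", "y|1", "n|2", "y|2"]
        labels = [""]
        for b in self.blocks:
            labels = [a + c for a in labels for c in b.obs_labels]
        return labels

    @property
    def n_row_blocks(self) -> int:
        """Number of independent multinomial blocks among the observed rows."""
        return 2 if self.subsamples else 1

    @property
    def row_block_index(self) -> np.ndarray:
        if self.subsamples:
            return np.array([0, 0, 1, 1])
        return np.zeros(len(self.obs_labels), dtype=int)


@dataclass(frozen=True)
class BiasParams:
    """Evasive-response-bias parameters.

    ``theta`` is the SP-no / cheating prevalence (it may go slightly
    negative during estimation, hence the [-0.5, 1] validation window);
    ``theta_yy_yn`` is the SP(last-year) probability that a last-year
    carrier edits a randomized ``yy`` profile to ``yn``; ``theta_n`` /
    ``theta_y`` are the per-category SP-no probabilities of the
    sub-samples variant (only identified under constraints).
    """

    theta: float = 0.0
    theta_yy_yn: float = 0.0
    theta_n: float | None = None
    theta_y: float | None = None

    def __post_init__(self) -> None:
        for name in ("theta", "theta_yy_yn"):
            v = getattr(self, name)
            if not (THETA_LOWER <= v <= 1.0):
                raise ValueError(f"{name}={v} outside the admitted range [{THETA_LOWER}, 1]")
        if self.theta + self.theta_yy_yn > 1.0 + 1e-12:
            raise ValueError("theta + theta_yy_yn must not exceed 1")


@dataclass
class TransitionMatrix:
    """Labelled matrix of conditional probabilities P(observed | true).

    ``block_index`` partitions the rows into independent multinomial
    blocks (used by the sub-samples design); within each block every
    column sums to one.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    block_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: signed matrices arise from SP-no mixtures with negative theta; they
    #: keep unit column sums but individual entries may leave [0, 1]
    signed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if self.block_index is None:
            self.block_index = np.zeros(self.values.shape[0], dtype=int)
        else:
            self.block_index = np.asarray(self.block_index, dtype=int)
        self.validate()

    def validate(self) -> None:
        if not self.signed and (np.any(self.values < -COLSUM_TOL)
                                or np.any(self.values > 1 + COLSUM_TOL)):
            raise ValueError("transition probabilities must lie in [0, 1]")
        for b in np.unique(self.block_index):
            colsums = self.values[self.block_index == b].sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-10, rtol=0):
                raise ValueError(f"columns of row-block {b} do not sum to 1: {colsums}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_blocks(self) -> int:
        return int(self.block_index.max()) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="profile")

    def allno_indicator(self) -> np.ndarray:
        """Indicator of the all-'no' observed profile within each row block.

        This is the response column of a cheater / SP-no sayer: within
        each sub-sample block the single profile consisting solely of
        'n' answers gets probability one.
        """
        col = np.zeros(self.shape[0])
        for b in np.unique(self.block_index):
            rows = np.flatnonzero(self.block_index == b)
            allno = [r for r in rows if set(self.row_labels[r].split("|")[0]) == {"n"}]
            if len(allno) != 1:
                raise ValueError(f"row-block {b} has no unique all-no profile")
            col[allno[0]] = 1.0
        return col


# ---------------------------------------------------------------------------
# matrix builders


def symmetric_2x2(rand: RandomizationSpec) -> TransitionMatrix:
    """2x2 transition matrix [[p, q], [q, p]] of a symmetric design.

    Warner's design with answer probability .8 and the unrelated-question
    design with question probability .6 and innocuous prevalence .5 both
    yield p=.8, illustrating that designs sharing a transition matrix are
    statistically equivalent.
    """
    p, q = rand.p, rand.q
    return TransitionMatrix(np.array([[p, q], [q, p]]), ["n", "y"], ["n", "y"])


def asymmetric_2x2(p_n_given_n: float, p_n_given_y: float) -> TransitionMatrix:
    """General single-question matrix with unequal misclassification rates.

    Columns are (n, y): ``P[:, t] = (P(n|t), P(y|t))``.  Only supported
    for 2x2 single-question designs; the identifiability condition is
    ``p_n_given_n != p_n_given_y``.
    """
    for v in (p_n_given_n, p_n_given_y):
        if not (0.0 <= v <= 1.0):
            raise ValueError("conditional probabilities must lie in [0, 1]")
    if p_n_given_n == p_n_given_y:
        raise ValueError("p_{n|n} == p_{n|y}: the design is not identified")
    vals = np.array([[p_n_given_n, p_n_given_y],
                     [1 - p_n_given_n, 1 - p_n_given_y]])
    return TransitionMatrix(vals, ["n", "y"], ["n", "y"])


def identity_matrix(labels: list[str]) -> TransitionMatrix:
    """Identity transition matrix for a non-randomized variable."""
    n = len(labels)
    return TransitionMatrix(np.eye(n), list(labels), list(labels))


def kronecker_chain(mats: list[TransitionMatrix]) -> TransitionMatrix:
    """Kronecker product of per-question matrices with concatenated labels.

    The leftmost factor varies slowest, so for two questions with labels
    n < y the rows come out in the order (nn, ny, yn, yy).
    """
    if not mats:
        raise ValueError("kronecker_chain needs at least one matrix")
    for m in mats:
        if m.n_blocks != 1:
            raise ValueError("cannot Kronecker a sub-sample-blocked matrix")
    vals = mats[0].values
    rows = list(mats[0].row_labels)
    cols = list(mats[0].col_labels)
    for m in mats[1:]:
        vals = np.kron(vals, m.values)
        rows = [a + b for a in rows for b in m.row_labels]
        cols = [a + b for a in cols for b in m.col_labels]
    return TransitionMatrix(vals, rows, cols)


def subsamples_matrix(rand: RandomizationSpec) -> TransitionMatrix:
    """4x2 matrix of the two-sub-samples design with complementary p.

    Sub-sample 1 answers with probability ``p`` of matching the true
    response; sub-sample 2 with the complementary probability ``q``.
    Rows are (n|1, y|1, n|2, y|2); each sub-sample block's columns sum
    to one.  Under instruction adherence the conditional observed
    probabilities satisfy ``pi*_{n|1} + pi*_{n|2} = 1``.
    """
    p, q = rand.p, rand.q
    vals = np.array([[p, q], [q, p], [q, p], [p, q]])
    return TransitionMatrix(vals, ["n|1", "y|1", "n|2", "y|2"], ["n", "y"],
                            block_index=[0, 0, 1, 1])


def everlastyear_matrix(rand: RandomizationSpec) -> TransitionMatrix:
    """4x3 matrix of the ever/last-year design.

    Rows are observed profiles (nn, ny, yn, yy) of the (ever, last-year)
    answers, columns are the true categories nn=never, yn=former,
    yy=last-year.  Both questions share one randomization probability
    and are randomized independently, e.g. the last-year column is
    (q^2, qp, pq, p^2).
    """
    p, q = rand.p, rand.q
    vals = np.array([
        [p * p, q * p, q * q],
        [p * q, q * q, q * p],
        [q * p, p * p, p * q],
        [q * q, p * q, p * p],
    ])
    return TransitionMatrix(vals, ["nn", "ny", "yn", "yy"], ["nn", "yn", "yy"])


def append_cheater_column(T: TransitionMatrix) -> TransitionMatrix:
    """Augment a transition matrix with the cheater category (CDM).

    Cheaters answer "no" to every question irrespective of the
    randomizer, so their response column is the indicator of the all-no
    observed profile within each sub-sample block: (1,0,1,0)' for the
    sub-samples design and (1,0,...,0)' otherwise.
    """
    col = T.allno_indicator()
    vals = np.hstack([T.values, col[:, None]])
    return TransitionMatrix(vals, list(T.row_labels), list(T.col_labels) + ["c"],
                            block_index=T.block_index.copy())


def _ely_edit_operator() -> np.ndarray:
    """Row operator moving a randomized yy profile to yn (rows nn,ny,yn,yy)."""
    E = np.eye(4)
    E[3, 3] = 0.0
    E[2, 3] = 1.0
    return E


def splastyear_matrix(rand: RandomizationSpec, theta: float, theta_yy_yn: float) -> TransitionMatrix:
    """4x3 SP(last-year) matrix with theta and theta_yy_yn built in.

    Three mutually exclusive respondent classes: SP-no sayers (weight
    ``theta``) answer nn regardless of the randomizer; last-year editors
    (weight ``theta_yy_yn``, last-year carriers only) follow the
    randomizer but report yn whenever the randomized profile is yy;
    the rest adhere.  With both parameters zero this reduces to the
    null ever/last-year matrix, and with ``theta_yy_yn = 0`` it equals
    the SP-no mixture ``(1-theta) P + theta e_allno``.
    """
    _check_sply(theta, theta_yy_yn)
    K = everlastyear_matrix(rand)
    e = K.allno_indicator()
    edited = _ely_edit_operator() @ K.values
    vals = np.empty_like(K.values)
    for t, lab in enumerate(K.col_labels):
        et = theta_yy_yn if lab == "yy" else 0.0
        vals[:, t] = (1 - theta - et) * K.values[:, t] + theta * e + et * edited[:, t]
    return TransitionMatrix(vals, list(K.row_labels), list(K.col_labels), signed=theta < 0)


def _check_sply(theta: float, theta_yy_yn: float, n_edit_blocks: int = 1) -> None:
    if not (THETA_LOWER <= theta <= 1.0):
        raise ValueError(f"theta={theta} outside [{THETA_LOWER}, 1]")
    if not (0.0 <= theta_yy_yn <= 1.0):
        raise ValueError(f"theta_yy_yn={theta_yy_yn} outside [0, 1]")
    if theta + n_edit_blocks * theta_yy_yn > 1.0 + 1e-12:
        raise ValueError("theta + theta_yy_yn exceeds 1: class weights are not a distribution")


def build_design_matrix(layout: DesignLayout, bias: BiasParams | None = None,
                        bias_structure: str | None = None) -> TransitionMatrix:
    """Transition matrix of a full design, with optional bias structure.

    Dispatches to the per-block builders: Kronecker product over blocks
    for multi-question designs, the 4x2 blocked matrix for sub-samples,
    then the CDM cheater column, SP-no mixture or SP(last-year) editing.
    ``bias_structure`` defaults to the layout's; numeric values come
    from ``bias``.
    """
    structure = bias_structure if bias_structure is not None else layout.bias_structure
    bias = bias or BiasParams()

    if layout.subsamples:
        base = subsamples_matrix(layout.blocks[0].rand)
    else:
        base = kronecker_chain([b.null_matrix() for b in layout.blocks])

    if structure == "none":
        return base

    if structure == "cdm":
        return append_cheater_column(base)

    if structure == "sp_no":
        e = base.allno_indicator()
        vals = (1 - bias.theta) * base.values + bias.theta * e[:, None]
        return TransitionMatrix(vals, list(base.row_labels), list(base.col_labels),
                                block_index=base.block_index.copy(),
                                signed=bias.theta < 0)

    if structure == "sp_no_by_category":
        # Eq-1.8-style per-category SP-no for the sub-samples design.
        th = {"n": bias.theta_n if bias.theta_n is not None else bias.theta,
              "y": bias.theta_y if bias.theta_y is not None else bias.theta}
        e = base.allno_indicator()
        vals = base.values.copy()
        for t, lab in enumerate(base.col_labels):
            vals[:, t] = (1 - th[lab]) * base.values[:, t] + th[lab] * e
        return TransitionMatrix(vals, list(base.row_labels), list(base.col_labels),
                                block_index=base.block_index.copy())

    if structure == "sp_last_year":
        if not layout.has_ely:
            raise ValueError("sp_last_year requires an ever/last-year block")
        # Edited Kronecker: apply the yy->yn edit operator inside every
        # ever/last-year block; elsewhere an editor behaves adherently.
        null_mats = [b.null_matrix() for b in layout.blocks]
        K = kronecker_chain(null_mats)
        e = K.allno_indicator()
        # per-block edited matrices (shared parameter, mutually exclusive classes)
        edited_chains = []
        qualifies = []  # per column of K, number of blocks whose component is yy
        for j, b in enumerate(layout.blocks):
            if b.kind != "ever_last_year":
                continue
            mats = list(null_mats)
            ed = _ely_edit_operator() @ null_mats[j].values
            mats[j] = TransitionMatrix(ed, null_mats[j].row_labels, null_mats[j].col_labels)
            edited_chains.append((j, kronecker_chain(mats).values))
        # decompose each joint column label into block components
        comps = []
        for lab in K.col_labels:
            pos, parts = 0, []
            for b in layout.blocks:
                w = 2 if b.kind == "ever_last_year" else 1
                parts.append(lab[pos:pos + w])
                pos += w
            comps.append(parts)
        theta, the = bias.theta, bias.theta_yy_yn
        max_edit = max((sum(1 for bb, bl in zip(layout.blocks, c)
                            if bb.kind == "ever_last_year" and bl == "yy")
                        for c in comps), default=0)
        _check_sply(theta, the, n_edit_blocks=max(max_edit, 1))
        vals = np.empty_like(K.values)
        for t, parts in enumerate(comps):
            total_edit = 0.0
            col = np.zeros(K.shape[0])
            for j, edited in edited_chains:
                if parts[j] == "yy":
                    col += the * edited[:, t]
                    total_edit += the
            vals[:, t] = (1 - theta - total_edit) * K.values[:, t] + theta * e + col
        return TransitionMatrix(vals, list(K.row_labels), list(K.col_labels), signed=theta < 0)

    raise ValueError(f"unknown bias structure {structure!r}")
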