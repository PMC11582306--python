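"""Respondent-level simulation of randomized-response surveys.

Each simulated respondent gets a true category, possibly a latent
evasive class (SP-no sayer / cheater, and for the SP(last-year) model a
last-year editor), then answers every question through the randomizer.
An optional item-specific evasion mechanism makes carriers of a flagged
question answer it evasively — by default at the true-response stage
(they answer the item as non-carriers, before randomization), which is
the mechanism behind the sensitivity analysis showing that excess
evasion on an add-on question is absorbed by that item's prevalence
estimate without biasing the ever/last-year categories or theta.  A
recorded-response variant (a randomizer-required "yes" replaced by
"no") is available; it can depress an item's yes-rate below the
randomization floor q, which no prevalence value can mimic.

Draw order (one seeded generator, bit-stable): categories, class
uniforms (SP-no / editor slots), true-response evasion draws,
per-question randomizer flips, recorded-response evasion draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignLayout
from .fit import ProfileCounts, fit_ml
from .models import TrueCategoryProbs

__all__ = ["SimulationScenario", "simulate_counts", "sensitivity_item_evasion"]


@dataclass
class SimulationScenario:
    """Data-generating configuration for one simulated survey."""

    layout: DesignLayout
    true_probs: TrueCategoryProbs
    theta: float = 0.0
    theta_yy_yn: float = 0.0
    item_evasion: dict[int, float] = field(default_factory=dict)
    #: "true_response": a carrier of the flagged item answers it as a
    #: non-carrier (evasion before randomization; equivalent to a lower
    #: item prevalence).  "recorded_response": a randomizer-required
    #: "yes" is replaced by "no" after randomization (can push the
    #: item's yes-rate below the randomization floor q).
    item_evasion_stage: str = "true_response"
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.item_evasion_stage not in ("true_response", "recorded_response"):
            raise ValueError(f"unknown item_evasion_stage {self.item_evasion_stage!r}")
        if self.n < 1:
            raise ValueError("sample size must be at least 1")
        if self.true_probs.labels != self.layout.true_labels:
            raise ValueError("true-category labels do not match the layout")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("the simulator draws latent classes; theta must be in [0, 1]")
        n_ely = sum(b.kind == "ever_last_year" for b in self.layout.blocks)
        if (not (0.0 <= self.theta_yy_yn <= 1.0)
                or self.theta + max(n_ely, 1) * self.theta_yy_yn > 1.0):
            raise ValueError("inadmissible theta_yy_yn: class weights exceed 1")
        for qi, ev in self.item_evasion.items():
            if not (0 <= qi < self.layout.n_questions):
                raise ValueError(f"item_evasion refers to unknown question index {qi}")
            if not (0.0 <= ev <= 1.0):
                raise ValueError("evasion probabilities must lie in [0, 1]")


def _true_answer_matrix(layout: DesignLayout) -> np.ndarray:
    """(categories x questions) matrix of true yes-answers (1 = yes)."""
    rows = []
    for lab in layout.true_labels:
        rows.append([1 if ch == "y" else 0 for ch in lab])
    return np.array(rows, dtype=np.int8)


def _ely_question_slices(layout: DesignLayout) -> list[tuple[int, int]]:
    """(ever_index, last_index) question positions of each ELY block."""
    out, pos = [], 0
    for b in layout.blocks:
        if b.kind == "ever_last_year":
            out.append((pos, pos + 1))
        pos += b.n_questions
    return out


def simulate_counts(scenario: SimulationScenario,
                    rng: np.random.Generator | None = None) -> ProfileCounts:
    """Draw profile counts for one simulated survey.

    True categories are multinomial draws from ``true_probs``; with
    probability ``theta`` (independent of category) a respondent is an
    SP-no sayer and answers "no" to everything; last-year carriers are
    editors with probability ``theta_yy_yn`` and replace a randomized
    yy pair by yn; everyone else answers each question truthfully with
    probability ``p`` per question.  Item evasion acts on flagged
    questions at the stage set by ``item_evasion_stage``.
    """
    layout = scenario.layout
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    n = scenario.n
    n_q = layout.n_questions
    truth = _true_answer_matrix(layout)

    cat = rng.choice(len(layout.true_labels), size=n, p=scenario.true_probs.values)
    # one class draw: [0, theta) -> SP-no; then one theta_yy_yn-wide slot per
    # ELY block for the mutually exclusive last-year editor classes
    class_u = rng.random(n)
    spno = class_u < scenario.theta
    edit_pairs = _ely_question_slices(layout)

    # per-question p (shared within an ELY block)
    p_q = np.concatenate([[b.rand.p] * b.n_questions for b in layout.blocks])

    answers = truth[cat].astype(np.int8)  # n x Q true answers

    # evasion at the true-response stage: flagged-item carriers answer as
    # non-carriers with the stated probability, before the randomizer
    if scenario.item_evasion and scenario.item_evasion_stage == "true_response":
        ev_draws = rng.random((n, n_q))
        for qi, ev in scenario.item_evasion.items():
            mask = (answers[:, qi] == 1) & (ev_draws[:, qi] < ev)
            answers = answers.copy()
            answers[mask, qi] = 0

    flips = rng.random((n, n_q)) < (1.0 - p_q)[None, :]
    recorded = np.where(flips, 1 - answers, answers)

    # last-year editors: a randomized yy on their qualifying ELY pair becomes yn
    if scenario.theta_yy_yn > 0:
        for k, (ei, li) in enumerate(edit_pairs):
            lo = scenario.theta + k * scenario.theta_yy_yn
            editor_k = (class_u >= lo) & (class_u < lo + scenario.theta_yy_yn)
            qual = editor_k & (answers[:, ei] == 1) & (answers[:, li] == 1)
            hit = qual & (recorded[:, ei] == 1) & (recorded[:, li] == 1)
            recorded[hit, li] = 0

    # SP-no sayers: all-"no" regardless of the randomizer
    recorded[spno] = 0

    # evasion at the recorded-response stage: a randomizer-required "yes"
    # on a flagged question is replaced by "no"
    if scenario.item_evasion and scenario.item_evasion_stage == "recorded_response":
        ev_draws = rng.random((n, n_q))
        for qi, ev in scenario.item_evasion.items():
            mask = (recorded[:, qi] == 1) & (ev_draws[:, qi] < ev)
            recorded[mask, qi] = 0

    if layout.subsamples:
        # first half answers with p, second half with the complementary q
        half = n // 2
        sub2 = np.zeros(n, dtype=bool)
        sub2[half:] = True
        rec = recorded[:, 0].copy()
        # complementary probabilities: a flip of the block-1 recording rule;
        # SP-no sayers still answer no
        rec_c = np.where(flips[:, 0], answers[:, 0], 1 - answers[:, 0])
        rec_c[spno] = 0
        rec = np.where(sub2, rec_c, rec)
        counts = np.zeros(4)
        counts[0] = np.sum(~sub2 & (rec == 0))
        counts[1] = np.sum(~sub2 & (rec == 1))
        counts[2] = np.sum(sub2 & (rec == 0))
        counts[3] = np.sum(sub2 & (rec == 1))
        return ProfileCounts(counts, layout.obs_labels, block_index=[0, 0, 1, 1])

    idx = np.zeros(n, dtype=int)
    for j in range(n_q):
        idx = idx * 2 + recorded[:, j]
    counts = np.bincount(idx, minlength=2 ** n_q).astype(float)
    return ProfileCounts(counts, layout.obs_labels)


def sensitivity_item_evasion(base: SimulationScenario, evasion_on_extra_question: float,
                             reps: int = 100, seed: int = 0, *,
                             fit_model: str = "sp_no", n_starts: int = 3) -> pd.DataFrame:
    """Bias of SP-no estimates under excess evasion on the add-on question.

    Repeatedly simulates the base scenario with the stated extra
    item-evasion probability on the single (non-ever/last-year)
    question, fits the SP-no model, and summarizes the mean bias of
    every parameter estimate with its Monte-Carlo standard error.

    The expected pattern: the ever/last-year *marginal* category
    prevalences stay unbiased and theta is not systematically inflated,
    while the add-on question's prevalence absorbs the excess evasion
    and is underestimated.
    """
    layout = base.layout
    single_idx = [i for i, b in enumerate(layout.blocks) if b.kind == "single"]
    if len(single_idx) != 1 or not layout.has_ely:
        raise ValueError("the sensitivity design is one ever/last-year block plus one single question")
    qpos = sum(layout.blocks[i].n_questions for i in range(single_idx[0]))

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(reps):
        scen = SimulationScenario(
            layout=layout, true_probs=base.true_probs, theta=base.theta,
            theta_yy_yn=base.theta_yy_yn,
            item_evasion={**base.item_evasion, qpos: evasion_on_extra_question},
            item_evasion_stage=base.item_evasion_stage,
            n=base.n, seed=int(rng.integers(2 ** 31)))
        counts = simulate_counts(scen)
        fit = fit_ml(layout, fit_model, counts, n_starts=n_starts,
                     seed=int(rng.integers(2 ** 31)), compute_se=False)
        rows.append(fit.estimates)
    est = pd.DataFrame(rows)

    truth = dict(zip(base.true_probs.labels, base.true_probs.values))
    truth["theta"] = base.theta

    # derived marginals: ELY-block category prevalences and the single
    # question's "ever" prevalence, aggregated from the joint categories
    ely_pos = [i for i, b in enumerate(layout.blocks) if b.kind == "ever_last_year"][0]
    start = sum(2 if layout.blocks[i].kind == "ever_last_year" else 1 for i in range(ely_pos))
    for cat in ("nn", "yn", "yy"):
        cols = [lab for lab in base.true_probs.labels if lab[start:start + 2] == cat]
        est[f"ely_{cat}"] = est[cols].sum(axis=1)
        truth[f"ely_{cat}"] = sum(truth[c] for c in cols)
    ycols = [lab for lab in base.true_probs.labels if lab[qpos] == "y"]
    est["extra_y"] = est[ycols].sum(axis=1)
    truth["extra_y"] = sum(truth[c] for c in ycols)

    out = []
    for name in est.columns:
        if name not in truth:
            continue
        bias = est[name] - truth[name]
        out.append({"parameter": name, "truth": truth[name],
                    "mean_estimate": est[name].mean(), "mean_bias": bias.mean(),
                    "mc_std_error": bias.std(ddof=1) / np.sqrt(reps)})
    return pd.DataFrame(out).set_index("parameter")
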