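"""Readers/writers, design configuration and the bundled survey fixtures.

Counts travel as CSV with one column per question (values ``n``/``y``),
an optional ``subsample`` column for the two-sub-samples design, and an
integer ``count`` column.  Designs are YAML/JSON mappings with a
``blocks`` list (``{kind, p, name}``), a ``subsamples`` flag and an
optional ``bias_structure``.

Two doping surveys are bundled as fixtures: Study I (2,269 male gym
users; ever/last-year anabolic-steroid questions plus an ever question
on SARMs) and Study II (1,050 Dutch elite athletes; ever/last-year
questions on both anabolics and blood manipulations).  Both used
p = 5/6 for every question.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignLayout, QuestionBlock, RandomizationSpec
from .fit import FitResult, ProfileCounts

__all__ = ["StudyFixture", "load_fixture", "FIXTURE_NAMES", "read_counts",
           "write_counts", "read_design", "write_design", "write_report"]

FIXTURE_NAMES = ("study1", "study1_anabolics_collapsed", "study2")

_P_FIXTURE = 5.0 / 6.0

# Observed profile frequencies of the two surveys, in lexicographic
# profile order (n < y, first question slowest).
_STUDY1_COUNTS = [1220, 248, 226, 61, 290, 78, 114, 32]          # (everA, lastA, SARMs)
_STUDY2_COUNTS = [521, 89, 93, 21, 86, 23, 22, 10,
                  93, 18, 19, 10, 22, 7, 8, 8]                   # (everA, lastA, everB, lastB)


@dataclass(frozen=True)
class StudyFixture:
    name: str
    layout: DesignLayout
    counts: ProfileCounts
    note: str

    @property
    def total(self) -> int:
        return int(self.counts.total)


def load_fixture(name: str) -> StudyFixture:
    """Bundled survey data by name.

    ``study1``: 8 profiles of (ever anabolics, last-year anabolics,
    ever SARMs), n = 2,269.  ``study1_anabolics_collapsed``: the four
    ever/last-year anabolics profiles obtained by summing over the
    SARMs index.  ``study2``: 16 profiles of two ever/last-year sets
    (anabolics, blood manipulations), n = 1,050.
    """
    rand = RandomizationSpec(_P_FIXTURE)
    if name == "study1":
        layout = DesignLayout([QuestionBlock("ever_last_year", rand, name="anabolics"),
                               QuestionBlock("single", rand, name="sarms")])
        counts = ProfileCounts(np.array(_STUDY1_COUNTS, float), layout.obs_labels)
        note = "male gym users survey; ever/last-year anabolics + ever SARMs; p = 5/6"
    elif name == "study1_anabolics_collapsed":
        layout = DesignLayout([QuestionBlock("ever_last_year", rand, name="anabolics")])
        c = np.array(_STUDY1_COUNTS, float).reshape(4, 2).sum(axis=1)
        counts = ProfileCounts(c, layout.obs_labels)
        note = "study1 collapsed over the SARMs index"
    elif name == "study2":
        layout = DesignLayout([QuestionBlock("ever_last_year", rand, name="anabolics"),
                               QuestionBlock("ever_last_year", rand, name="blood")])
        counts = ProfileCounts(np.array(_STUDY2_COUNTS, float), layout.obs_labels)
        note = ("Dutch elite athletes survey; ever/last-year anabolics and blood "
                "manipulations; two pooled answer formats, both p = 5/6")
    else:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    expected_total = {"study1": 2269, "study1_anabolics_collapsed": 2269, "study2": 1050}[name]
    assert counts.total == expected_total
    return StudyFixture(name, layout, counts, note)


# ---------------------------------------------------------------------------
# counts CSV


def write_counts(counts: ProfileCounts, path, layout: DesignLayout | None = None) -> None:
    counts.to_frame(layout).to_csv(path, index=False)


def read_counts(path, layout: DesignLayout) -> ProfileCounts:
    """Read a profile-counts CSV and validate it against a design.

    Every profile of the design must appear exactly once; letters other
    than ``n``/``y``, negative counts, duplicates and missing profiles
    are rejected by name.
    """
    df = pd.read_csv(path, dtype=str)
    if "count" not in df.columns:
        raise ValueError("counts file needs a 'count' column")
    qcols = [c for c in df.columns if c not in ("count", "subsample")]
    if len(qcols) != layout.n_questions:
        raise ValueError(f"expected {layout.n_questions} question columns, found {qcols}")
    has_sub = "subsample" in df.columns
    if layout.subsamples != has_sub:
        raise ValueError("subsample column " + ("missing" if layout.subsamples else "unexpected"))

    values = {}
    for _, row in df.iterrows():
        letters = "".join(str(row[c]).strip().lower() for c in qcols)
        if set(letters) - {"n", "y"}:
            raise ValueError(f"answers must be n/y, got {letters!r}")
        label = letters + (f"|{int(row['subsample'])}" if has_sub else "")
        if label in values:
            raise ValueError(f"duplicate profile row {label!r}")
        cnt = float(row["count"])
        if cnt < 0:
            raise ValueError(f"negative count at profile {label!r}")
        values[label] = cnt

    missing = [lab for lab in layout.obs_labels if lab not in values]
    if missing:
        raise ValueError(f"missing profile rows: {missing}")
    extra = [lab for lab in values if lab not in layout.obs_labels]
    if extra:
        raise ValueError(f"unknown profile rows: {extra}")
    arr = np.array([values[lab] for lab in layout.obs_labels])
    return ProfileCounts(arr, layout.obs_labels, block_index=layout.row_block_index)


# ---------------------------------------------------------------------------
# design configuration


def design_to_dict(layout: DesignLayout) -> dict:
    return {
        "blocks": [{"kind": b.kind, "p": b.rand.p, **({"name": b.name} if b.name else {})}
                   for b in layout.blocks],
        "subsamples": layout.subsamples,
        "bias_structure": layout.bias_structure,
    }


def design_from_dict(cfg: dict) -> DesignLayout:
    blocks = [QuestionBlock(b["kind"], RandomizationSpec(float(b["p"])), name=b.get("name", ""))
              for b in cfg["blocks"]]
    return DesignLayout(blocks, subsamples=cfg.get("subsamples", False),
                        bias_structure=cfg.get("bias_structure", "none"))


def write_design(layout: DesignLayout, path) -> None:
    path = Path(path)
    cfg = design_to_dict(layout)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_design(path) -> DesignLayout:
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return design_from_dict(cfg)


# ---------------------------------------------------------------------------
# fit reports


def fit_to_dict(fit: FitResult) -> dict:
    return {
        "model": fit.model,
        "estimates": fit.estimates,
        "std_errors": {k: (None if not np.isfinite(v) else float(v))
                       for k, v in fit.std_errors.items()},
        "loglik": fit.loglik,
        "aic": fit.aic,
        "g2": fit.g2,
        "df": fit.df,
        "p_value": fit.p_value,
        "n_params": fit.n_params,
        "observed": dict(zip(fit.observed.labels, fit.observed.counts.tolist())),
        "fitted_counts": dict(zip(fit.observed.labels, fit.fitted_counts.tolist())),
        "converged": fit.converged,
        "boundary": fit.boundary,
        "n_starts_used": fit.n_starts_used,
        "best_start": fit.best_start,
    }


def write_report(fit: FitResult, path) -> None:
    """Structured JSON report of a fit (estimates, SEs, fit statistics)."""
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2))
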