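"""Per-symptom genotype differences, thresholded weights and variant scores.

For each variant v and symptom s the members are split into a
symptom-present and a symptom-absent group and the difference of mean
numeric genotype codes

    d[s][v] = mean(codes | s = yes) - mean(codes | s = no)

is taken.  A positive d means carriers of the mutated allele lean toward
showing the symptom (putative causative direction), a negative d toward
not showing it (putative protective direction).  |d| is discretized into
a weight p in {0, 1, 2} at cut points 0.5 and 1, and a variant's
relevance score SC is the column sum of weights over all scored
symptoms.  Variants are then banded by where SC falls relative to the
median and standard deviation of the score distribution.

Contrast population
-------------------
With ``contrast="family"`` (default) the symptom-absent group is
augmented with the disease-free members of the pedigree, who exhibit
none of the clinical symptoms; a symptom must still vary among the
examined (affected) members to be scored at all — rows uniform across
the patients stay "white" (masked).  ``contrast="affected"`` restricts
both groups to the examined members.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

import numpy as np
import pandas as pd

from .family_data import Pedigree, Status, SymptomMatrix
from .genotype_models import EncodedMatrix

__all__ = [
    "group_difference",
    "weight",
    "heatmap_category",
    "band_classification",
    "score_matrix",
    "ScoreResult",
]

#: |d| cut points of the weight rule: p = 0 below 0.5, 1 in [0.5, 1), 2 at >= 1.
WEIGHT_CUTPOINTS = (0.5, 1.0)

BAND_BELOW = "below"
BAND_ONE_SD = "one_sd"
BAND_TWO_SD = "two_sd"


def _is_defined(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def group_difference(codes: Sequence[Optional[float]],
                     symptom_row: Sequence[str]) -> Optional[float]:
    """Difference of mean codes, symptom-present minus symptom-absent.

    ``codes`` and ``symptom_row`` are indexed by the same subjects;
    entries with an absent code or an ``unknown`` symptom value are
    dropped pairwise.  Returns None (undefined, a "white" cell) when
    either group is empty.
    """
    if len(codes) != len(symptom_row):
        raise ValueError(
            f"length mismatch: {len(codes)} codes vs {len(symptom_row)} symptom values"
        )
    yes, no = [], []
    for code, val in zip(codes, symptom_row):
        if not _is_defined(code) or val == "unknown":
            continue
        if val == "yes":
            yes.append(float(code))
        elif val == "no":
            no.append(float(code))
        else:
            raise ValueError(f"symptom value {val!r} not in {{yes,no,unknown}}")
    if not yes or not no:
        return None
    return float(np.mean(yes) - np.mean(no))


def weight(d: Optional[float]) -> int:
    """Discretized magnitude of a difference: 0 if |d| < 0.5, 1 if
    0.5 <= |d| < 1, 2 if |d| >= 1; an undefined d contributes 0."""
    if not _is_defined(d):
        return 0
    a = abs(d)
    if a < WEIGHT_CUTPOINTS[0]:
        return 0
    if a < WEIGHT_CUTPOINTS[1]:
        return 1
    return 2


def heatmap_category(d: Optional[float]) -> str:
    """Display category of a difference for heatmap export.

    Intervals: irrelevant -0.05 <= d < 0.05; low_causative 0.05 <= d < 1;
    low_protective -1 < d <= -0.05; strong_causative d >= 1;
    strong_protective d <= -1; undefined -> white.  The printed interval
    ends overlap at d = -0.05; the protective label wins there, mirroring
    the half-open convention on the causative side.
    """
    if not _is_defined(d):
        return "white"
    if d >= 1:
        return "strong_causative"
    if d <= -1:
        return "strong_protective"
    if d <= -0.05:
        return "low_protective"
    if d < 0.05:
        return "irrelevant"
    return "low_causative"


def band_classification(sc: pd.Series, sd_estimator: str = "population"
                        ) -> tuple[pd.Series, float, float]:
    """Label each variant by where its score sits in the score distribution.

    two_sd: sc >= median + 2*sd; one_sd: median + sd <= sc < median + 2*sd;
    below otherwise.  With a degenerate distribution (sd = 0) a score is
    one_sd only if strictly above the median, else below.
    """
    if len(sc) < 2:
        raise ValueError("band classification needs at least 2 variants")
    if sd_estimator not in ("population", "sample"):
        raise ValueError("sd_estimator must be 'population' or 'sample'")
    values = sc.astype(float)
    med = float(values.median())
    sd = float(values.std(ddof=0 if sd_estimator == "population" else 1))

    def _band(x: float) -> str:
        if sd == 0.0:
            return BAND_ONE_SD if x > med else BAND_BELOW
        if x >= med + 2 * sd:
            return BAND_TWO_SD
        if x >= med + sd:
            return BAND_ONE_SD
        return BAND_BELOW

    return values.map(_band), med, sd


@dataclass
class ScoreResult:
    scores: pd.Series              # SC per variant (column sums of weights)
    median: float
    sd: float
    bands: pd.Series               # below / one_sd / two_sd per variant
    sd_estimator: str
    model: str
    contrast: str
    difference: pd.DataFrame       # d, symptom x variant (NaN where masked)
    weights: pd.DataFrame          # p in {0,1,2}, masked cells 0
    defined: pd.DataFrame          # mask: True where d is defined
    scored_symptoms: list[str]     # symptoms that entered the sums
    absent_group_extras: list[str]  # disease-free members added to "no" groups

    def summary(self) -> dict:
        return {
            "model": self.model,
            "contrast": self.contrast,
            "sd_estimator": self.sd_estimator,
            "median": self.median,
            "sd": self.sd,
            "n_variants": int(len(self.scores)),
            "scored_symptoms": self.scored_symptoms,
            "white_symptoms": [s for s in self.difference.index
                               if not self.defined.loc[s].any()],
            "absent_group_extras": self.absent_group_extras,
            "masked_cells": int((~self.defined).to_numpy().sum()),
            "bands": {b: [str(k) for k in self.bands.index[self.bands == b]]
                      for b in (BAND_TWO_SD, BAND_ONE_SD, BAND_BELOW)},
        }


def score_matrix(encoded: EncodedMatrix, symptoms: SymptomMatrix,
                 pedigree: Optional[Pedigree] = None,
                 contrast: str = "family",
                 include_uncertain: bool = False,
                 sd_estimator: str = "population") -> ScoreResult:
    """Compute the difference matrix D, weight matrix P and score vector SC.

    The symptom matrix covers the examined (affected) members.  Under the
    default ``family`` contrast every other genotyped subject that the
    pedigree marks healthy joins the symptom-absent group (uncertain
    members are left out unless ``include_uncertain``); without a
    pedigree, all extra genotyped subjects join it.  A symptom enters the
    score only if informative among the examined members.
    """
    if contrast not in ("family", "affected"):
        raise ValueError("contrast must be 'family' or 'affected'")
    patients = [s for s in symptoms.subjects if s in encoded.subjects]
    if len(patients) != len(symptoms.subjects):
        missing = sorted(set(symptoms.subjects) - set(encoded.subjects))
        raise ValueError(f"symptom subjects absent from genotype matrix: {missing}")

    extras: list[str] = []
    if contrast == "family":
        rest = [s for s in encoded.subjects if s not in patients]
        if pedigree is None:
            extras = rest
        else:
            allowed = {Status.HEALTHY}
            if include_uncertain:
                allowed.add(Status.UNCERTAIN)
            extras = [s for s in rest
                      if s in pedigree and pedigree.subject(s).status in allowed]

    informative = symptoms.informative
    if not informative.any():
        raise ValueError("no informative symptoms: every row is uniform")

    keys = encoded.variant_keys
    d_rows, w_rows, m_rows = [], [], []
    for s in symptoms.symptoms:
        row = symptoms.present.loc[s]
        d_row, w_row, m_row = {}, {}, {}
        for key in keys:
            codes = encoded.codes.loc[key]
            if not informative[s]:
                d = None  # white row: uniform among the examined members
            else:
                subj = patients + extras
                vals = ([row[p] for p in patients] + ["no"] * len(extras))
                d = group_difference([codes[x] for x in subj], vals)
            d_row[key] = np.nan if d is None else d
            w_row[key] = weight(d)
            m_row[key] = d is not None
        d_rows.append(d_row)
        w_rows.append(w_row)
        m_rows.append(m_row)

    D = pd.DataFrame(d_rows, index=symptoms.symptoms, columns=keys, dtype=float)
    P = pd.DataFrame(w_rows, index=symptoms.symptoms, columns=keys, dtype=int)
    defined = pd.DataFrame(m_rows, index=symptoms.symptoms, columns=keys, dtype=bool)
    sc = P.sum(axis=0)
    bands, med, sd = band_classification(sc, sd_estimator=sd_estimator)
    scored = [s for s in symptoms.symptoms if defined.loc[s].any()]
    return ScoreResult(
        scores=sc, median=med, sd=sd, bands=bands, sd_estimator=sd_estimator,
        model=encoded.model.value, contrast=contrast, difference=D, weights=P,
        defined=defined, scored_symptoms=scored, absent_group_extras=extras,
    )
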