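"""Synthetic family-cohort generator with planted causative and modifier
variants, for end-to-end testing and parameter-recovery studies.

The generator emulates the structure of the study data: a small set of
affected members with binary symptoms, disease-free relatives, one fully
penetrant dominant causative variant (heterozygous in every affected
member, wild-type in every healthy one), a few modifier variants whose
mutant-allele dosage shifts the probability of their linked symptoms,
and neutral variants.  Genotypes at non-causative sites follow
Hardy-Weinberg proportions at the configured allele frequencies; each
affected member's symptom s is Bernoulli with

    logit P(s) = logit(baseline_prob)
                 + sum over modifiers linked to s of effect_size * (code - 1)

where code is the additive genotype code (1, 2, 3).  Relatedness is not
modeled (status labels only): the downstream statistics use only status
and symptoms, never transmission.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from .family_data import (
    GenotypeCall, GenotypeMatrix, Pedigree, Sex, Status, Subject, SymptomMatrix,
    VariantRecord,
)
from .symptom_scoring import ScoreResult

__all__ = ["SimulationConfig", "SyntheticTruth", "SimulatedCohort",
           "simulate_cohort", "recovery_rate", "score_cohort", "mean_recovery"]


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 4 affected + 4 healthy members, 32 candidate
    variants of which 3 are modifiers, 11 binary symptoms, a 100-subject
    control cohort; effect_size is the log-odds increment per additive
    genotype step on a linked symptom."""
    n_affected: int = 4
    n_healthy: int = 4
    n_variants: int = 32
    n_modifiers: int = 3
    n_symptoms: int = 11
    effect_size: float = 2.0
    baseline_prob: float = 0.5
    modifier_allele_freq: float = 0.3
    neutral_allele_freq: float = 0.3
    control_cohort_size: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_affected < 1:
            raise ValueError("need at least one affected member")
        if self.n_modifiers > self.n_variants:
            raise ValueError("n_modifiers cannot exceed n_variants")
        if self.n_symptoms < 1:
            raise ValueError("need at least one symptom")
        for name in ("baseline_prob", "modifier_allele_freq", "neutral_allele_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if not 0.0 < self.baseline_prob < 1.0:
            raise ValueError("baseline_prob must be strictly inside (0, 1)")


@dataclass
class SyntheticTruth:
    causative: str                       # variant key
    modifiers: dict[str, dict] = field(default_factory=dict)
    # key -> {"symptoms": [...], "effect_size": float}

    def to_json(self) -> dict:
        return asdict(self)


class SimulatedCohort(NamedTuple):
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    symptoms: SymptomMatrix
    controls: GenotypeMatrix
    truth: SyntheticTruth


_CODE_TO_CALL = {0: GenotypeCall.WILD, 1: GenotypeCall.HET, 2: GenotypeCall.HOM_MUT}


def _hwe_calls(rng: np.random.Generator, freq: float, n: int) -> list[GenotypeCall]:
    dosage = rng.binomial(2, freq, size=n)
    return [_CODE_TO_CALL[int(d)] for d in dosage]


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Deterministic under a fixed config (including seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    affected = [f"A{i+1}" for i in range(cfg.n_affected)]
    healthy = [f"H{i+1}" for i in range(cfg.n_healthy)]
    subjects = affected + healthy
    pedigree = Pedigree(
        [Subject(id=s, sex=Sex.UNKNOWN, status=Status.AFFECTED, family="SIM")
         for s in affected]
        + [Subject(id=s, sex=Sex.UNKNOWN, status=Status.HEALTHY, family="SIM")
           for s in healthy]
    )

    symptoms = [f"S{i+1:02d}" for i in range(cfg.n_symptoms)]

    variants = [VariantRecord(gene="CAUS1", variant_id="simC", hgvs="c.1A>T",
                              consequence="missense", role="causative")]
    for i in range(cfg.n_variants):
        variants.append(VariantRecord(
            gene=f"GENE{i+1:02d}", variant_id=f"sim{i+1:03d}",
            hgvs=f"c.{100+i}A>T", consequence="missense",
            role="modifier-candidate",
        ))
    candidate_keys = [v.key for v in variants[1:]]
    modifier_keys = candidate_keys[:cfg.n_modifiers]

    # causative: dominant, fully penetrant — het in all affected, wild elsewhere
    calls = {}
    calls[variants[0].key] = ([GenotypeCall.HET] * cfg.n_affected
                              + [GenotypeCall.WILD] * cfg.n_healthy)
    for v in variants[1:]:
        freq = (cfg.modifier_allele_freq if v.key in modifier_keys
                else cfg.neutral_allele_freq)
        calls[v.key] = _hwe_calls(rng, freq, len(subjects))
    g = GenotypeMatrix(variants, subjects,
                       pd.DataFrame.from_dict(calls, orient="index",
                                              columns=subjects)
                       .loc[[v.key for v in variants]])

    truth = SyntheticTruth(causative=variants[0].key)
    for key in modifier_keys:
        n_links = int(rng.integers(1, min(3, cfg.n_symptoms) + 1))
        linked = sorted(rng.choice(cfg.n_symptoms, size=n_links, replace=False))
        truth.modifiers[key] = {
            "symptoms": [symptoms[i] for i in linked],
            "effect_size": cfg.effect_size,
        }

    # symptoms for affected members only (the examined patients)
    base_logit = float(np.log(cfg.baseline_prob / (1 - cfg.baseline_prob)))
    additive = {GenotypeCall.WILD: 1, GenotypeCall.HET: 2, GenotypeCall.HOM_MUT: 3}
    present = pd.DataFrame("no", index=symptoms, columns=affected)
    for s_idx, s in enumerate(symptoms):
        for subj in affected:
            logit = base_logit
            for key, info in truth.modifiers.items():
                if s in info["symptoms"]:
                    code = additive[g.call(key, subj)]
                    logit += info["effect_size"] * (code - 1)
            p = 1.0 / (1.0 + np.exp(-logit))
            if rng.random() < p:
                present.at[s, subj] = "yes"
    sym = SymptomMatrix(symptoms, affected, present)

    control_ids = [f"C{i+1:03d}" for i in range(cfg.control_cohort_size)]
    ctrl_calls = {variants[0].key: [GenotypeCall.WILD] * len(control_ids)}
    for v in variants[1:]:
        freq = (cfg.modifier_allele_freq if v.key in modifier_keys
                else cfg.neutral_allele_freq)
        ctrl_calls[v.key] = _hwe_calls(rng, freq, len(control_ids))
    controls = GenotypeMatrix(
        variants, control_ids,
        pd.DataFrame.from_dict(ctrl_calls, orient="index", columns=control_ids)
        .loc[[v.key for v in variants]])

    return SimulatedCohort(pedigree, g, sym, controls, truth)


def score_cohort(cohort: SimulatedCohort, sd_estimator: str = "population"
                 ) -> ScoreResult:
    """Run the standard scoring chain (additive encoding, family contrast)
    on a simulated cohort's candidate variants."""
    from .genotype_models import InheritanceModel, encode_matrix
    from .symptom_scoring import score_matrix

    candidates = cohort.genotypes.select_role("modifier-candidate")
    enc = encode_matrix(candidates, InheritanceModel.ADDITIVE)
    return score_matrix(enc, cohort.symptoms, pedigree=cohort.pedigree,
                        sd_estimator=sd_estimator)


def mean_recovery(cfg: SimulationConfig, n_replicates: int, seed0: int,
                  k: int | None = None) -> float:
    """Mean top-k recovery of planted modifiers over seeded replicates
    (seed0, seed0+1, ...); k defaults to the number of modifiers."""
    if k is None:
        k = cfg.n_modifiers
    rates = []
    for i in range(n_replicates):
        cohort = simulate_cohort(
            SimulationConfig(**{**asdict(cfg), "seed": seed0 + i}))
        rates.append(recovery_rate(cohort.truth, score_cohort(cohort), k))
    return float(np.mean(rates))


def recovery_rate(truth: SyntheticTruth, result: ScoreResult, k: int) -> float:
    """Fraction of planted modifiers ranked in the top k by score
    (ties broken by variant key for determinism)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(result.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = {key for key, _ in ranked[:k]}
    planted = set(truth.modifiers)
    if not planted:
        return 0.0
    return len(planted & top) / len(planted)
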