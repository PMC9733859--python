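"""Pipeline orchestration: load inputs, encode, score, associate, cluster,
and write a deterministic report bundle."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import family_data as fd
from .genotype_models import InheritanceModel, encode_matrix
from .symptom_scoring import score_matrix, heatmap_category
from .association import (contingency_table, fisher_exact, fisher_exact_rxc,
                          perfect_separation, control_frequencies)
from .similarity import (similarity_matrix, threshold_clusters,
                         genotype_vectors, symptom_vectors)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


@dataclass
class RunConfig:
    pedigree: str
    genotypes: str
    symptoms: str
    controls: Optional[str] = None
    outdir: str = "cordmod_out"
    model: str = "additive"
    contrast: str = "family"
    sd_estimator: str = "population"
    scheme: str = "carrier_2x2"
    include_uncertain_as_healthy: bool = False
    genotype_cutoff: float = 0.7
    symptom_cutoff: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for cut in (self.genotype_cutoff, self.symptom_cutoff):
            if not 0.0 <= cut <= 1.0:
                raise ValueError("cutoffs must lie in [0, 1]")
        InheritanceModel(self.model)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.outdir``.

    Emits: inputs manifest, encoded matrices for all three inheritance
    models, difference/weight/score tables with bands and heatmap
    categories, the per-variant association table, similarity matrices
    and clusters on both bases, a control-frequency report when controls
    are given, and a JSON summary naming every configuration choice.
    Returns the summary dict.  Two runs with an identical config produce
    byte-identical bundles.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pedigree, genotypes, symptoms, controls = _load_inputs(cfg)
    manifest = fd.study_manifest(pedigree, genotypes, symptoms)
    _write_json(outdir / "manifest.json", manifest)

    encoded = _encode_all(genotypes, outdir)

    candidates = genotypes.select_role("modifier-candidate")
    enc_candidates = encode_matrix(candidates, InheritanceModel(cfg.model))
    result = _score(enc_candidates, symptoms, pedigree, cfg, outdir)

    assoc = _associate(genotypes, pedigree, cfg, outdir)

    clusters = _cluster(genotypes, symptoms, pedigree, cfg, outdir)

    freq_summary = None
    if controls is not None:
        freq_summary = _control_report(controls, candidates, outdir)

    summary = {
        "config": asdict(cfg),
        "manifest": manifest,
        "score": result.summary(),
        "association": assoc,
        "clusters": clusters,
        "control_frequencies": freq_summary
        if freq_summary is not None else "not run (no control cohort given)",
    }
    two_sd = summary["score"]["bands"]["two_sd"]
    summary["headline"] = {
        "n_two_sd": len(two_sd),
        "two_sd_genes": sorted({candidates.variant(k).gene for k in two_sd}),
        "n_one_sd": len(summary["score"]["bands"]["one_sd"]),
        "surviving_variants": sorted(two_sd + summary["score"]["bands"]["one_sd"]),
    }
    summary["headline"]["surviving_genes"] = sorted(
        {candidates.variant(k).gene for k in summary["headline"]["surviving_variants"]}
    )
    _write_json(outdir / "summary.json", summary)
    return summary


@_stage("load_inputs")
def _load_inputs(cfg: RunConfig):
    pedigree = fd.read_pedigree(cfg.pedigree)
    genotypes = fd.read_genotype_table(cfg.genotypes)
    symptoms = fd.read_symptom_table(cfg.symptoms)
    controls = fd.read_genotype_table(cfg.controls) if cfg.controls else None
    return pedigree, genotypes, symptoms, controls


@_stage("encode")
def _encode_all(genotypes, outdir: Path):
    encoded = {}
    for model in InheritanceModel:
        enc = encode_matrix(genotypes, model)
        enc.to_tsv(outdir / f"encoded_{model.value}.tsv")
        encoded[model] = enc
    return encoded


@_stage("score")
def _score(enc, symptoms, pedigree, cfg: RunConfig, outdir: Path):
    result = score_matrix(enc, symptoms, pedigree=pedigree,
                          contrast=cfg.contrast,
                          sd_estimator=cfg.sd_estimator)
    result.difference.rename_axis("symptom").to_csv(
        outdir / "difference_matrix.tsv", sep="\t", float_format="%.6g")
    result.weights.rename_axis("symptom").to_csv(
        outdir / "weight_matrix.tsv", sep="\t")
    scores = pd.DataFrame({"score": result.scores, "band": result.bands})
    scores.rename_axis("variant").to_csv(outdir / "scores.tsv", sep="\t")
    # long-format heatmap export
    rows = []
    for s in result.difference.index:
        for v in result.difference.columns:
            d = result.difference.at[s, v]
            rows.append({
                "symptom": s, "variant": v,
                "d": "" if np.isnan(d) else round(float(d), 6),
                "weight": int(result.weights.at[s, v]),
                "category": heatmap_category(None if np.isnan(d) else float(d)),
            })
    pd.DataFrame(rows).to_csv(outdir / "heatmap_long.tsv", sep="\t", index=False)
    return result


@_stage("associate")
def _associate(genotypes, pedigree, cfg: RunConfig, outdir: Path):
    separated = set(perfect_separation(
        genotypes, pedigree,
        include_uncertain_as_healthy=cfg.include_uncertain_as_healthy))
    rows = []
    for key in genotypes.variant_keys:
        t = contingency_table(
            genotypes, pedigree, key, scheme=cfg.scheme,
            include_uncertain_as_healthy=cfg.include_uncertain_as_healthy)
        p = fisher_exact(t) if t.counts.shape == (2, 2) else fisher_exact_rxc(t)
        rows.append({
            "variant": key,
            "scheme": cfg.scheme,
            "counts": "|".join(",".join(map(str, r)) for r in t.counts),
            "p_value": round(p, 10),
            "perfect_separation": key in separated,
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "association.tsv", sep="\t", index=False)
    best = df.loc[df["p_value"].idxmin()]
    return {
        "scheme": cfg.scheme,
        "include_uncertain_as_healthy": cfg.include_uncertain_as_healthy,
        "perfectly_separated": sorted(separated),
        "min_p_variant": best["variant"],
        "min_p": float(best["p_value"]),
        "note": ("exact two-sided Fisher p on the stated scheme; the table "
                 "construction is stamped here because different poolings of "
                 "the same pedigree counts give different printed p-values"),
    }


@_stage("cluster")
def _cluster(genotypes, symptoms, pedigree, cfg: RunConfig, outdir: Path):
    gv = genotype_vectors(genotypes)
    sim_g = similarity_matrix(gv, basis="genotype")
    extras = [s for s in genotypes.subjects if s not in symptoms.subjects]
    sv = symptom_vectors(symptoms, extras)[genotypes.subjects]
    sim_s = similarity_matrix(sv, basis="symptom")

    out = {}
    member_rows = []
    for sim, cutoff in ((sim_g, cfg.genotype_cutoff), (sim_s, cfg.symptom_cutoff)):
        sim.values.rename_axis("subject").to_csv(
            outdir / f"similarity_{sim.basis}.tsv", sep="\t", float_format="%.6g")
        assignment = threshold_clusters(sim, cutoff)
        out[sim.basis] = {"cutoff": cutoff, "clusters": assignment.clusters}
        for cid, members in enumerate(assignment.clusters, start=1):
            for m in members:
                member_rows.append({"subject": m, "basis": sim.basis,
                                    "cutoff": cutoff, "cluster": cid})
    pd.DataFrame(member_rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    return out


@_stage("control_frequencies")
def _control_report(controls, candidates, outdir: Path):
    report = control_frequencies(controls, candidates.variant_keys)
    report.table.to_csv(outdir / "control_frequencies.tsv", sep="\t",
                        float_format="%.6g")
    typed = report.table[report.table["typed"]]
    return {
        "cohort_size": len(controls.subjects),
        "n_variants": int(len(report.table)),
        "n_untyped": int((~report.table["typed"]).sum()),
        "min_freq_variant": str(typed["allele_freq"].idxmin()),
        "min_freq": float(typed["allele_freq"].min()),
    }


def _write_json(path: Path, obj: dict) -> None:
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
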