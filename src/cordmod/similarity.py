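"""Pairwise subject similarity and cutoff clustering.

Similarity is the simple matching coefficient between two categorical
vectors: the fraction of positions where they agree, positions with a
missing value in either subject excluded pairwise.  Clusters at a cutoff
are the connected components of the graph whose edges join subject pairs
with similarity >= cutoff (the "pixels that persist" after thresholding
a similarity heatmap).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .family_data import GenotypeCall, GenotypeMatrix, SymptomMatrix

__all__ = [
    "SimilarityMatrix",
    "ClusterAssignment",
    "similarity_matrix",
    "threshold_clusters",
    "genotype_vectors",
    "symptom_vectors",
]


@dataclass
class SimilarityMatrix:
    values: pd.DataFrame  # symmetric, unit diagonal, in [0,1]; NaN = undefined pair
    basis: str            # genotype | symptom

    @property
    def subjects(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterAssignment:
    cutoff: float
    clusters: list[list[str]]  # partition; singletons allowed

    def cluster_of(self, subject: str) -> list[str]:
        for c in self.clusters:
            if subject in c:
                return c
        raise KeyError(subject)

    def together(self, *subjects: str) -> bool:
        first = self.cluster_of(subjects[0])
        return all(s in first for s in subjects[1:])


def similarity_matrix(vectors: pd.DataFrame, basis: str) -> SimilarityMatrix:
    """Simple-matching similarity between subject columns of a
    feature-by-subject frame.  NaN cells are missing and excluded
    pairwise; a pair with zero comparable positions gets NaN."""
    if vectors.shape[0] < 1:
        raise ValueError("vectors must have at least one position")
    subjects = list(vectors.columns)
    vals = vectors.to_numpy(dtype=object)
    defined = ~pd.isna(vectors).to_numpy()
    n = len(subjects)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            both = defined[:, i] & defined[:, j]
            if not both.any():
                continue
            agree = np.mean(vals[both, i] == vals[both, j])
            out[i, j] = out[j, i] = float(agree)
    return SimilarityMatrix(pd.DataFrame(out, index=subjects, columns=subjects),
                            basis=basis)


def threshold_clusters(m: SimilarityMatrix, cutoff: float) -> ClusterAssignment:
    """Connected components of the graph with an edge wherever
    similarity >= cutoff.  Undefined (NaN) pairs never contribute edges."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    graph = nx.Graph()
    subjects = m.subjects
    graph.add_nodes_from(subjects)
    vals = m.values
    for i, a in enumerate(subjects):
        for b in subjects[i + 1:]:
            v = vals.at[a, b]
            if not np.isnan(v) and v >= cutoff:
                graph.add_edge(a, b)
    order = {s: k for k, s in enumerate(subjects)}
    clusters = [sorted(c, key=order.__getitem__)
                for c in nx.connected_components(graph)]
    clusters.sort(key=lambda c: order[c[0]])
    return ClusterAssignment(cutoff=cutoff, clusters=clusters)


def genotype_vectors(g: GenotypeMatrix) -> pd.DataFrame:
    """Raw genotype call strings per subject, missing as NaN."""
    return g.calls.map(
        lambda c: np.nan if c is GenotypeCall.MISSING else c.value
    )


def symptom_vectors(s: SymptomMatrix,
                    extra_subjects: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Symptom vectors per subject; members outside the examined set (the
    disease-free relatives) exhibit none of the clinical symptoms and get
    all-"no" columns.  Unknown entries become NaN."""
    df = s.present.replace("unknown", np.nan).copy()
    for extra in extra_subjects or []:
        if extra in df.columns:
            raise ValueError(f"{extra!r} already has a symptom column")
        df[extra] = "no"
    return df
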