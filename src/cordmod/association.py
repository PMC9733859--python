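"""Disease association per variant: Fisher exact tests on genotype-by-status
contingency tables, perfect-separation screening, and control-cohort
frequency reports.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, exp
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .family_data import GenotypeCall, GenotypeMatrix, Pedigree

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "fisher_exact",
    "fisher_exact_rxc",
    "perfect_separation",
    "FrequencyReport",
    "control_frequencies",
]

SCHEMES = ("carrier_2x2", "recessive_2x2", "genotype_2x3")


@dataclass
class ContingencyTable:
    counts: np.ndarray  # rows: affected, healthy; columns per scheme
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    scheme: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be nonnegative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")


def _status_groups(g: GenotypeMatrix, pedigree: Pedigree,
                   include_uncertain_as_healthy: bool) -> tuple[list[str], list[str]]:
    affected = [s for s in g.subjects if s in pedigree and
                pedigree.subject(s).status.value == "affected"]
    healthy_status = {"healthy", "uncertain"} if include_uncertain_as_healthy \
        else {"healthy"}
    healthy = [s for s in g.subjects if s in pedigree and
               pedigree.subject(s).status.value in healthy_status]
    if not affected or not healthy:
        raise ValueError("both an affected and a healthy group are required")
    return affected, healthy


def contingency_table(g: GenotypeMatrix, pedigree: Pedigree, variant_key: str,
                      scheme: str = "carrier_2x2",
                      include_uncertain_as_healthy: bool = False
                      ) -> ContingencyTable:
    """Genotype-by-status counts for one variant.

    carrier_2x2 pools heterozygous and homozygous-mutated calls as
    carriers; recessive_2x2 contrasts homozygous-mutated vs the rest;
    genotype_2x3 keeps the three genotype classes.  Missing calls are
    dropped.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    affected, healthy = _status_groups(g, pedigree, include_uncertain_as_healthy)

    def tally(ids: list[str]) -> dict[GenotypeCall, int]:
        out = {c: 0 for c in GenotypeCall}
        for s in ids:
            out[g.call(variant_key, s)] += 1
        return out

    a, h = tally(affected), tally(healthy)
    W, H, M = GenotypeCall.WILD, GenotypeCall.HET, GenotypeCall.HOM_MUT
    if scheme == "carrier_2x2":
        counts = [[a[H] + a[M], a[W]], [h[H] + h[M], h[W]]]
        cols = ("carrier", "wild")
    elif scheme == "recessive_2x2":
        counts = [[a[M], a[W] + a[H]], [h[M], h[W] + h[H]]]
        cols = ("hom_mut", "not_hom_mut")
    else:
        counts = [[a[W], a[H], a[M]], [h[W], h[H], h[M]]]
        cols = ("wild", "het", "hom_mut")
    return ContingencyTable(np.array(counts), ("affected", "healthy"), cols, scheme)


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-ordering
    convention: sum of hypergeometric probabilities <= that of the
    observed table)."""
    if t.counts.shape != (2, 2):
        raise ValueError("fisher_exact needs a 2x2 table; use fisher_exact_rxc")
    return float(stats.fisher_exact(t.counts, alternative="two-sided")[1])


def _log_table_prob(counts: np.ndarray) -> float:
    # P(table | margins) = prod(r_i!) prod(c_j!) / (N! prod(n_ij!))
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    lp = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
    lp -= lgamma(n + 1) + sum(lgamma(x + 1) for x in counts.ravel())
    return lp


def _enumerate_tables(rows: Sequence[int], cols: Sequence[int]):
    """All nonnegative integer tables with the given margins (2 rows)."""
    assert len(rows) == 2
    c = len(cols)

    def rec(j: int, remaining: list[int], first_row: list[int]):
        if j == c:
            yield first_row[:]
            return
        col_total = cols[j]
        lo = max(0, col_total - remaining[1])
        hi = min(col_total, remaining[0])
        for x in range(lo, hi + 1):
            first_row.append(x)
            remaining[0] -= x
            remaining[1] -= (col_total - x)
            yield from rec(j + 1, remaining, first_row)
            first_row.pop()
            remaining[0] += x
            remaining[1] += (col_total - x)

    for fr in rec(0, list(rows), []):
        table = np.array([fr, [cj - x for cj, x in zip(cols, fr)]])
        yield table


def fisher_exact_rxc(t: ContingencyTable, max_total: int = 30) -> float:
    """Exact two-sided p for a 2-row table by full enumeration over tables
    with the observed margins (Freeman-Halton ordering: sum probabilities
    not exceeding the observed table's, with 1e-12 relative slack at ties).
    """
    counts = t.counts
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("fisher_exact_rxc expects a table with 2 rows")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if (rows == 0).any() or (cols == 0).all():
        raise ValueError("untestable table: empty row or column margin")
    if counts.sum() > max_total:
        raise ValueError(
            f"table total {counts.sum()} exceeds enumeration limit {max_total}; "
            "collapse to a 2x2 scheme"
        )
    lp_obs = _log_table_prob(counts)
    p = 0.0
    for table in _enumerate_tables(rows, cols):
        lp = _log_table_prob(table)
        if lp <= lp_obs + 1e-12:
            p += exp(lp)
    return min(1.0, p)


def perfect_separation(g: GenotypeMatrix, pedigree: Pedigree,
                       include_uncertain_as_healthy: bool = False) -> list[str]:
    """Variants whose non-missing genotype values in the affected and
    healthy groups are disjoint sets."""
    affected, healthy = _status_groups(g, pedigree, include_uncertain_as_healthy)
    flagged = []
    for key in g.variant_keys:
        calls_a = {g.call(key, s) for s in affected} - {GenotypeCall.MISSING}
        calls_h = {g.call(key, s) for s in healthy} - {GenotypeCall.MISSING}
        if calls_a and calls_h and not (calls_a & calls_h):
            flagged.append(key)
    return flagged


@dataclass
class FrequencyReport:
    """Per-variant genotype counts and alternate-allele frequency in a
    control cohort; variants absent from the cohort are reported untyped
    (NaN frequency), never as zero."""
    table: pd.DataFrame  # index variant key; columns n_wild n_het n_hom_mut n_missing allele_freq typed

    def frequency(self, variant_key: str) -> float:
        return float(self.table.at[variant_key, "allele_freq"])


def control_frequencies(controls: GenotypeMatrix,
                        variant_keys: Optional[Sequence[str]] = None
                        ) -> FrequencyReport:
    keys = list(variant_keys) if variant_keys is not None else controls.variant_keys
    if not controls.subjects:
        raise ValueError("control cohort is empty")
    rows = []
    for key in keys:
        if key not in controls.variant_keys:
            rows.append({"variant": key, "n_wild": 0, "n_het": 0, "n_hom_mut": 0,
                         "n_missing": 0, "allele_freq": np.nan, "typed": False})
            continue
        counts = {c: 0 for c in GenotypeCall}
        for s in controls.subjects:
            counts[controls.call(key, s)] += 1
        called = (counts[GenotypeCall.WILD] + counts[GenotypeCall.HET]
                  + counts[GenotypeCall.HOM_MUT])
        alt = counts[GenotypeCall.HET] + 2 * counts[GenotypeCall.HOM_MUT]
        freq = alt / (2 * called) if called else np.nan
        rows.append({
            "variant": key,
            "n_wild": counts[GenotypeCall.WILD],
            "n_het": counts[GenotypeCall.HET],
            "n_hom_mut": counts[GenotypeCall.HOM_MUT],
            "n_missing": counts[GenotypeCall.MISSING],
            "allele_freq": freq,
            "typed": True,
        })
    return FrequencyReport(pd.DataFrame(rows).set_index("variant"))
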