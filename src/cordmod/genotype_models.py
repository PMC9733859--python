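"""Numeric genotype encodings under additive, dominant and recessive models.

The additive code is mutant-allele dosage shifted to 1..3 (1 = wild-type,
2 = heterozygous, 3 = homozygous mutated), i.e. risk grows 1r-fold per
heterozygous and 2r-fold per homozygous step.  Dominant and recessive
codes are mutated-class indicators in {0,1}.  Missing calls propagate as
NaN and are dropped pairwise downstream.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import math

import pandas as pd

from .family_data import GenotypeCall, GenotypeMatrix, VariantRecord

__all__ = ["InheritanceModel", "EncodedMatrix", "encode", "encode_matrix"]


class InheritanceModel(str, Enum):
    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


_ENCODINGS = {
    InheritanceModel.ADDITIVE: {
        GenotypeCall.WILD: 1, GenotypeCall.HET: 2, GenotypeCall.HOM_MUT: 3,
    },
    InheritanceModel.DOMINANT: {
        GenotypeCall.WILD: 0, GenotypeCall.HET: 1, GenotypeCall.HOM_MUT: 1,
    },
    InheritanceModel.RECESSIVE: {
        GenotypeCall.WILD: 0, GenotypeCall.HET: 0, GenotypeCall.HOM_MUT: 1,
    },
}


def encode(call: GenotypeCall, model: InheritanceModel) -> Optional[int]:
    """Numeric code for one call, or None for a missing call."""
    if call is GenotypeCall.MISSING:
        return None
    return _ENCODINGS[InheritanceModel(model)][call]


@dataclass
class EncodedMatrix:
    variants: list[VariantRecord]
    subjects: list[str]
    codes: pd.DataFrame  # float grid, NaN where the call was missing
    model: InheritanceModel

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def row(self, variant_key: str) -> pd.Series:
        return self.codes.loc[variant_key]

    def select(self, variant_keys: Sequence[str]) -> "EncodedMatrix":
        keep = [v for v in self.variants if v.key in set(variant_keys)]
        return EncodedMatrix(keep, self.subjects,
                             self.codes.loc[[v.key for v in keep]], self.model)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# model: {self.model.value}\n")
            out = self.codes.map(
                lambda x: "." if (isinstance(x, float) and math.isnan(x)) else str(int(x))
            )
            out.rename_axis("variant").to_csv(fh, sep="\t")


def encode_matrix(g: GenotypeMatrix, model: InheritanceModel) -> EncodedMatrix:
    model = InheritanceModel(model)
    table = {call: float(code) for call, code in _ENCODINGS[model].items()}
    table[GenotypeCall.MISSING] = float("nan")
    codes = g.calls.map(table.__getitem__).astype(float)
    return EncodedMatrix(list(g.variants), list(g.subjects), codes, model)
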