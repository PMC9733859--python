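import pandas as pd
import pytest

import cordmod as cm
from cordmod.family_data import GenotypeCall, Subject, Pedigree, Sex, Status, VariantRecord


@pytest.fixture(scope="session")
def pedigree():
    return cm.load_fixture("pedigree")


@pytest.fixture(scope="session")
def table1():
    return cm.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return cm.load_fixture("table2")


@pytest.fixture(scope="session")
def candidates(table2):
    return table2.select_role("modifier-candidate")


@pytest.fixture(scope="session")
def encoded_candidates(candidates):
    return cm.encode_matrix(candidates, cm.InheritanceModel.ADDITIVE)


TOKENS = {"wild": GenotypeCall.WILD, "het": GenotypeCall.HET,
          "hom": GenotypeCall.HOM_MUT, "missing": GenotypeCall.MISSING}


def make_genotype_matrix(rows: dict[str, str], subjects: list[str],
                         role: str = "modifier-candidate") -> cm.GenotypeMatrix:
    """Build a matrix from {'GENE:c.1A>T': 'het wild hom missing'} shorthand."""
    variants, calls = [], {}
    for key, tokens in rows.items():
        gene, hgvs = key.split(":", 1)
        variants.append(VariantRecord(gene=gene, variant_id=".", hgvs=hgvs,
                                      consequence="missense", role=role))
        calls[key] = [TOKENS[t] for t in tokens.split()]
    frame = pd.DataFrame.from_dict(calls, orient="index", columns=subjects)
    return cm.GenotypeMatrix(variants, subjects, frame.loc[list(rows)])


def make_pedigree(affected: list[str], healthy: list[str],
                  uncertain: list[str] = ()) -> Pedigree:
    subs = [Subject(id=s, sex=Sex.UNKNOWN, status=Status.AFFECTED) for s in affected]
    subs += [Subject(id=s, sex=Sex.UNKNOWN, status=Status.HEALTHY) for s in healthy]
    subs += [Subject(id=s, sex=Sex.UNKNOWN, status=Status.UNCERTAIN) for s in uncertain]
    return Pedigree(subs)


def make_symptom_matrix(rows: dict[str, str], subjects: list[str]) -> cm.SymptomMatrix:
    frame = pd.DataFrame.from_dict(
        {k: v.split() for k, v in rows.items()}, orient="index", columns=subjects)
    return cm.SymptomMatrix(list(rows), subjects, frame)
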