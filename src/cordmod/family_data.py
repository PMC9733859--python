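"""Pedigree, genotype and symptom data model with readers/writers.

The study design this package targets is a small autosomal-dominant
cone-rod dystrophy pedigree: a handful of affected members with
per-symptom clinical annotations, a diallelic genotype table over one
causative variant plus a panel of candidate modifier variants, and an
optional unrelated control cohort.  Everything here is deliberately
plain: TSV/PED text dialects, VCF through pysam, and pandas frames as
the in-memory containers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "Sex",
    "Status",
    "Subject",
    "Pedigree",
    "GenotypeCall",
    "VariantRecord",
    "GenotypeMatrix",
    "SymptomMatrix",
    "read_pedigree",
    "write_pedigree",
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf_genotypes",
    "write_vcf",
    "read_symptom_table",
    "write_symptom_table",
    "classify_variant_group",
    "load_fixture",
    "study_manifest",
]


class FormatError(ValueError):
    """An input file violates the expected dialect."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Status(str, Enum):
    AFFECTED = "affected"
    HEALTHY = "healthy"
    UNCERTAIN = "uncertain"


class GenotypeCall(str, Enum):
    WILD = "wild"
    HET = "het"
    HOM_MUT = "hom_mut"
    MISSING = "missing"


#: TSV cell vocabulary <-> call states ("+/+" wild type, "+/-" heterozygous,
#: "-/-" homozygous mutated, "./." missing).
TOKEN_TO_CALL = {
    "+/+": GenotypeCall.WILD,
    "+/-": GenotypeCall.HET,
    "-/-": GenotypeCall.HOM_MUT,
    "./.": GenotypeCall.MISSING,
}
CALL_TO_TOKEN = {v: k for k, v in TOKEN_TO_CALL.items()}

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PHENO_CODES = {"1": Status.HEALTHY, "2": Status.AFFECTED, "0": Status.UNCERTAIN}
_SEX_TO_CODE = {v: k for k, v in _SEX_CODES.items()}
_PHENO_TO_CODE = {v: k for k, v in _PHENO_CODES.items()}


@dataclass(frozen=True)
class Subject:
    id: str
    sex: Sex = Sex.UNKNOWN
    status: Status = Status.UNCERTAIN
    father: Optional[str] = None
    mother: Optional[str] = None
    family: str = "FAM"
    generation: Optional[str] = None


class Pedigree:
    """Ordered collection of subjects with unique ids."""

    def __init__(self, subjects: Iterable[Subject]):
        self.subjects: list[Subject] = list(subjects)
        ids = [s.id for s in self.subjects]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise FormatError(f"duplicate subject id(s): {sorted(dupes)}")
        self._by_id = {s.id: s for s in self.subjects}
        for s in self.subjects:
            for parent in (s.father, s.mother):
                if parent is not None and parent not in self._by_id:
                    raise FormatError(
                        f"subject {s.id!r} references unknown parent {parent!r}"
                    )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._by_id

    def subject(self, subject_id: str) -> Subject:
        return self._by_id[subject_id]

    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def with_status(self, status: Status) -> list[str]:
        return [s.id for s in self.subjects if s.status is status]

    @property
    def affected(self) -> list[str]:
        return self.with_status(Status.AFFECTED)

    @property
    def healthy(self) -> list[str]:
        return self.with_status(Status.HEALTHY)

    @property
    def uncertain(self) -> list[str]:
        return self.with_status(Status.UNCERTAIN)


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    variant_id: str  # dbSNP id or "NEW"
    hgvs: str  # printed coding-level HGVS string, treated as opaque
    consequence: str
    role: str = "modifier-candidate"  # causative | associated | modifier-candidate
    protein: Optional[str] = None
    group: Optional[int] = None
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.hgvs}"

    @property
    def is_novel(self) -> bool:
        return self.variant_id.upper() == "NEW"


class GenotypeMatrix:
    """Variant-by-subject grid of diallelic calls.

    ``calls`` is a pandas DataFrame indexed by ``gene:hgvs`` keys with one
    column per subject id; cell values are :class:`GenotypeCall` members.
    """

    def __init__(self, variants: Sequence[VariantRecord], subjects: Sequence[str],
                 calls: pd.DataFrame):
        self.variants = list(variants)
        self.subjects = list(subjects)
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (gene, hgvs) variant keys")
        if list(calls.index) != keys or list(calls.columns) != self.subjects:
            raise FormatError("calls grid does not match variant/subject lists")
        bad = calls.map(lambda c: not isinstance(c, GenotypeCall))
        if bad.any().any():
            r, c = next(zip(*bad.values.nonzero()))
            raise FormatError(
                f"non-call cell at row {calls.index[r]!r}, column {calls.columns[c]!r}"
            )
        self.calls = calls
        self._by_key = {v.key: v for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)

    def variant(self, key: str) -> VariantRecord:
        return self._by_key[key]

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def call(self, variant_key: str, subject: str) -> GenotypeCall:
        return self.calls.at[variant_key, subject]

    def select_role(self, *roles: str) -> "GenotypeMatrix":
        keep = [v for v in self.variants if v.role in roles]
        keys = [v.key for v in keep]
        return GenotypeMatrix(keep, self.subjects, self.calls.loc[keys])

    def select_subjects(self, subjects: Sequence[str]) -> "GenotypeMatrix":
        missing = [s for s in subjects if s not in self.subjects]
        if missing:
            raise KeyError(f"subjects absent from matrix: {missing}")
        return GenotypeMatrix(self.variants, list(subjects),
                              self.calls[list(subjects)])


class SymptomMatrix:
    """Symptom-by-subject grid of {yes,no,unknown} with informativeness flags.

    A row is *informative* when its non-unknown entries take at least two
    distinct values; rows shared by every examined member (or by none)
    cannot discriminate genotype groups and are the "white rows" of the
    score heatmap.
    """

    VOCAB = ("yes", "no", "unknown")

    def __init__(self, symptoms: Sequence[str], subjects: Sequence[str],
                 present: pd.DataFrame):
        self.symptoms = list(symptoms)
        self.subjects = list(subjects)
        if list(present.index) != self.symptoms or list(present.columns) != self.subjects:
            raise FormatError("present grid does not match symptom/subject lists")
        bad = ~present.isin(self.VOCAB)
        if bad.any().any():
            r, c = next(zip(*bad.values.nonzero()))
            raise FormatError(
                f"cell {present.iat[r, c]!r} outside vocabulary at row "
                f"{present.index[r]!r}, column {present.columns[c]!r}"
            )
        self.present = present

    @property
    def informative(self) -> pd.Series:
        def _row(row: pd.Series) -> bool:
            vals = {v for v in row if v != "unknown"}
            return len(vals) >= 2

        return self.present.apply(_row, axis=1)

    def subset(self, symptoms: Sequence[str]) -> "SymptomMatrix":
        return SymptomMatrix(list(symptoms), self.subjects,
                             self.present.loc[list(symptoms)])


# ---------------------------------------------------------------------------
# PED-like pedigree dialect: family, id, father, mother, sex, phenotype
# (sex 1=male 2=female 0=unknown; phenotype 1=healthy 2=affected 0=uncertain)


def read_pedigree(path: str | Path) -> Pedigree:
    path = Path(path)
    subjects: list[Subject] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 6 whitespace-separated "
                    f"columns, got {len(fields)}"
                )
            fam, sid, father, mother, sex, pheno = fields
            if sex not in _SEX_CODES:
                raise FormatError(f"{path.name}:{lineno}: unknown sex code {sex!r}")
            if pheno not in _PHENO_CODES:
                raise FormatError(
                    f"{path.name}:{lineno}: unknown phenotype code {pheno!r}"
                )
            subjects.append(Subject(
                id=sid,
                sex=_SEX_CODES[sex],
                status=_PHENO_CODES[pheno],
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                family=fam,
            ))
    if not subjects:
        log.warning("pedigree file %s is empty", path)
    return Pedigree(subjects)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in pedigree:
            fh.write("\t".join([
                s.family, s.id, s.father or "0", s.mother or "0",
                _SEX_TO_CODE[s.sex], _PHENO_TO_CODE[s.status],
            ]) + "\n")


# ---------------------------------------------------------------------------
# Genotype TSV dialect: metadata columns then one column per subject id,
# cells in {+/+, +/-, -/-, ./.}

_META_COLUMNS = ("role", "gene", "variant_id", "consequence", "hgvs",
                 "protein", "gnomad_af", "clinvar")


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    meta_cols = [c for c in df.columns if c in _META_COLUMNS]
    subj_cols = [c for c in df.columns if c not in _META_COLUMNS]
    for required in ("gene", "hgvs"):
        if required not in meta_cols:
            raise FormatError(f"{path.name}: missing required column {required!r}")
    if not subj_cols:
        raise FormatError(f"{path.name}: no subject columns found")

    variants = []
    for _, row in df.iterrows():
        meta = {c: row[c] for c in ("gnomad_af", "clinvar") if c in meta_cols
                and row[c] != "."}
        variants.append(VariantRecord(
            gene=row["gene"],
            variant_id=row.get("variant_id", "."),
            hgvs=row["hgvs"],
            consequence=row.get("consequence", "."),
            role=row.get("role", "modifier-candidate"),
            protein=None if row.get("protein", ".") == "." else row["protein"],
            meta=meta,
        ))
    calls = df[subj_cols].copy()
    calls.index = [v.key for v in variants]
    for r, key in enumerate(calls.index):
        for c in subj_cols:
            token = calls.at[key, c]
            if token not in TOKEN_TO_CALL:
                raise FormatError(
                    f"{path.name}: cell {token!r} outside vocabulary at "
                    f"variant {key!r}, subject {c!r}"
                )
    calls = calls.map(TOKEN_TO_CALL.__getitem__)
    return GenotypeMatrix(variants, subj_cols, calls)


def write_genotype_table(g: GenotypeMatrix, path: str | Path) -> None:
    rows = []
    for v in g.variants:
        row = {
            "role": v.role,
            "gene": v.gene,
            "variant_id": v.variant_id,
            "consequence": v.consequence,
            "hgvs": v.hgvs,
            "protein": v.protein or ".",
            "gnomad_af": v.meta.get("gnomad_af", "."),
            "clinvar": v.meta.get("clinvar", "."),
        }
        for s in g.subjects:
            row[s] = CALL_TO_TOKEN[g.call(v.key, s)]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF genotypes (diallelic sites; GT field)


def read_vcf_genotypes(path: str | Path, subject_ids: Sequence[str],
                       multiallelic: str = "reject") -> GenotypeMatrix:
    """Read GT fields for the named samples from a VCF.

    0/0 -> wild, 0/1 or 1/0 -> het, 1/1 -> hom_mut, ./. -> missing.
    Multi-allelic sites are rejected (default) or split into one record
    per alternate allele with all other alternates folded into wild.
    """
    import pysam

    if multiallelic not in ("reject", "split"):
        raise ValueError("multiallelic must be 'reject' or 'split'")
    vf = pysam.VariantFile(str(path))
    absent = [s for s in subject_ids if s not in vf.header.samples]
    if absent:
        raise FormatError(f"samples absent from VCF: {absent}")

    variants: list[VariantRecord] = []
    rows: list[dict] = []
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 and multiallelic == "reject":
            raise FormatError(
                f"multi-allelic site {rec.chrom}:{rec.pos} "
                f"(ALT {','.join(alts)}) under reject policy"
            )
        def _info(record, key, default):
            try:
                return record.info[key]
            except (KeyError, ValueError):
                return default

        for alt_index, alt in enumerate(alts, start=1):
            gene = _info(rec, "GENE", rec.chrom)
            hgvs = _info(rec, "HGVS", f"g.{rec.pos}{rec.ref}>{alt}")
            role = _info(rec, "ROLE", "modifier-candidate")
            consequence = _info(rec, "CSQ", ".")
            variants.append(VariantRecord(
                gene=str(gene), variant_id=rec.id or ".", hgvs=str(hgvs),
                consequence=str(consequence), role=str(role),
            ))
            row = {}
            for s in subject_ids:
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    row[s] = GenotypeCall.MISSING
                else:
                    dosage = sum(1 for a in alleles if a == alt_index)
                    row[s] = (GenotypeCall.WILD, GenotypeCall.HET,
                              GenotypeCall.HOM_MUT)[dosage]
            rows.append(row)
    calls = pd.DataFrame(rows, index=[v.key for v in variants],
                         columns=list(subject_ids))
    return GenotypeMatrix(variants, list(subject_ids), calls)


_VCF_CALL_TO_GT = {
    GenotypeCall.WILD: "0/0",
    GenotypeCall.HET: "0/1",
    GenotypeCall.HOM_MUT: "1/1",
    GenotypeCall.MISSING: "./.",
}


def write_vcf(g: GenotypeMatrix, path: str | Path, contig: str = "1") -> None:
    """Serialize a genotype matrix as a minimal diallelic VCF.

    Synthetic coordinates (1, 2, 3, ...) are assigned along the variant
    order; gene/HGVS/role travel in INFO so a read round-trips to an
    identical matrix.
    """
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=HGVS,Number=1,Type=String,Description="Coding HGVS">\n')
        fh.write('##INFO=<ID=ROLE,Number=1,Type=String,Description="Variant role">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.subjects) + "\n")
        for pos, v in enumerate(g.variants, start=1):
            info = (f"GENE={v.gene};HGVS={v.hgvs};ROLE={v.role};"
                    f"CSQ={v.consequence}")
            gts = [_VCF_CALL_TO_GT[g.call(v.key, s)] for s in g.subjects]
            fh.write("\t".join([
                contig, str(pos), v.variant_id, "A", "T", ".", "PASS",
                info, "GT", *gts,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Symptom TSV dialect: first column "symptom", then subject ids; cells
# in {yes, no, unknown}


def read_symptom_table(path: str | Path) -> SymptomMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "symptom":
        raise FormatError(f"{path.name}: first column must be 'symptom'")
    df = df.set_index("symptom")
    return SymptomMatrix(list(df.index), list(df.columns), df)


def write_symptom_table(s: SymptomMatrix, path: str | Path) -> None:
    s.present.rename_axis("symptom").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Variant group classification

_GROUP1_NOVEL = {"missense", "utr3", "utr5", "utr3-regulatory", "utr5-regulatory"}
_GROUP2_KNOWN = {"missense", "stop-gained", "nonsense", "inframe-insertion"}
_GROUP3_KNOWN = {"splice-region", "utr3-regulatory", "utr5-regulatory",
                 "regulatory", "utr3", "utr5"}


def classify_variant_group(v: VariantRecord, is_novel: Optional[bool] = None) -> int:
    """Assign the candidate class: 1 = novel missense/UTR, 2 = known
    missense/nonsense/inframe, 3 = known splice-region/UTR-regulatory,
    4 = synonymous.

    Raises ``ValueError`` for a consequence outside the scheme so an
    unclassifiable variant is never silently binned.
    """
    novel = v.is_novel if is_novel is None else is_novel
    csq = v.consequence.strip().lower()
    # compound annotations like "synonymous, regulatory" classify by the
    # coding-level term
    terms = [t.strip() for t in csq.split(",")]
    if "synonymous" in terms:
        return 4
    if novel and any(t in _GROUP1_NOVEL for t in terms):
        return 1
    if any(t in _GROUP2_KNOWN for t in terms):
        return 2
    if any(t in _GROUP3_KNOWN for t in terms):
        return 3
    raise ValueError(f"unclassified consequence {v.consequence!r} for {v.key}")


# ---------------------------------------------------------------------------
# Packaged fixtures (the published family tables, transcribed)

_FIXTURES = {
    "table1": ("table1.tsv", read_symptom_table),
    "table2": ("table2.tsv", read_genotype_table),
    "pedigree": ("pedigree.ped", read_pedigree),
}


def load_fixture(name: str):
    """Load a packaged study fixture: ``table1`` (symptom matrix of the
    four affected members), ``table2`` (genotypes of 2 causative/associated
    + 32 candidate variants across 8 members) or ``pedigree``."""
    if name not in _FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    fname, reader = _FIXTURES[name]
    with resources.as_file(resources.files("cordmod.data") / fname) as p:
        return reader(p)


def study_manifest(pedigree: Pedigree, genotypes: GenotypeMatrix,
                   symptoms: SymptomMatrix) -> dict:
    """JSON-serializable census of a loaded study."""
    roles: dict[str, int] = {}
    for v in genotypes.variants:
        roles[v.role] = roles.get(v.role, 0) + 1
    n_missing = int((genotypes.calls == GenotypeCall.MISSING).sum().sum())
    return {
        "subjects": {
            "total": len(pedigree),
            "affected": len(pedigree.affected),
            "healthy": len(pedigree.healthy),
            "uncertain": len(pedigree.uncertain),
            "roster": pedigree.ids(),
        },
        "variants": {
            "total": len(genotypes),
            "by_role": roles,
            "genes": sorted({v.gene for v in genotypes.variants}),
            "missing_calls": n_missing,
        },
        "symptoms": {
            "total": len(symptoms.symptoms),
            "informative": int(symptoms.informative.sum()),
            "roster": symptoms.symptoms,
        },
    }
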