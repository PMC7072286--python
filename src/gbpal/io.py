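"""Domain types and tab-separated file I/O shared by every pipeline stage.

All matrices are stored genes-(or pathways-, drugs-)by-samples in a pandas
DataFrame; estimator classes elsewhere work on the transposed
samples-by-features orientation, and the wrapper functions translate.

Containers validate their invariants at construction time so that a loaded
object is always safe to hand to the scoring stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gbpal")

STAGES = {"ndGB", "recGB", "secondary-recGB", "normal"}
MATERIALS = {"tissue", "GSC"}
#: valid activator/repressor role weights: -1 repressor, -0.5 likely
#: repressor, 0 ambivalent/neutral, 0.5 likely activator, 1 activator
ARR_VALUES = (-1.0, -0.5, 0.0, 0.5, 1.0)

METADATA_COLUMNS = [
    "sample_id", "patient_id", "tumor_id", "region_id",
    "stage", "material", "pfs_days", "event",
]


class LoadError(ValueError):
    """Raised when an input file violates a container invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes x samples, raw counts or normalized."""

    data: pd.DataFrame
    is_normalized: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate gene ids: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise LoadError(f"duplicate sample ids: {dupes[:5]}")
        values = df.to_numpy(dtype=float, copy=False)
        if np.isnan(values).any():
            raise LoadError("missing expression values (impute at load time)")
        if not np.isfinite(values).all():
            raise LoadError("non-finite expression values")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise LoadError(
                f"negative expression value at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleMetadata:
    """Per-sample study-design annotations (patient/tumor/region/stage/material).

    ``df`` is indexed by sample_id. ``pfs_days``/``event`` may be missing
    (NaN), but a sample with a PFS time must also carry an event flag.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate sample_id in metadata: {dupes[:5]}")
        bad_stage = set(df["stage"]) - STAGES
        if bad_stage:
            raise LoadError(f"unknown stage values: {sorted(bad_stage)}")
        bad_mat = set(df["material"]) - MATERIALS
        if bad_mat:
            raise LoadError(f"unknown material values: {sorted(bad_mat)}")
        for material, grp in df.groupby("material"):
            pairs = grp[["tumor_id", "region_id"]]
            if pairs.duplicated().any():
                dup = pairs[pairs.duplicated()].iloc[0]
                raise LoadError(
                    f"duplicate (tumor_id, region_id)=({dup.tumor_id}, "
                    f"{dup.region_id}) within material {material!r}"
                )
        if "pfs_days" in df:
            pfs = df["pfs_days"]
            has_pfs = pfs.notna()
            if (pfs[has_pfs] <= 0).any():
                raise LoadError("pfs_days must be positive")
            if "event" not in df or df.loc[has_pfs, "event"].isna().any():
                raise LoadError("pfs_days present without event flag")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(sample_ids)].copy())

    def stage_labels(self, sample_ids, positive_stage: str = "recGB") -> np.ndarray:
        """Boolean labels (True = positive_stage) aligned to sample_ids."""
        return (self.df.loc[list(sample_ids), "stage"] == positive_stage).to_numpy()


@dataclass
class PathwayDefinition:
    """A named pathway mapping member genes to signed activator/repressor roles."""

    pathway_id: str
    display_name: str
    members: dict[str, float]

    def __post_init__(self) -> None:
        bad = {g: a for g, a in self.members.items() if a not in ARR_VALUES}
        if bad:
            raise LoadError(
                f"pathway {self.pathway_id!r}: ARR values outside "
                f"{{-1,-0.5,0,0.5,1}}: {bad}"
            )
        if not any(a != 0 for a in self.members.values()):
            raise LoadError(
                f"pathway {self.pathway_id!r} has no member with nonzero ARR; "
                "activation level undefined"
            )


@dataclass
class PathwayDB:
    """A collection of pathways; the gene universe is always recomputed."""

    pathways: list[PathwayDefinition]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise LoadError("duplicate pathway ids in database")

    @property
    def gene_universe(self) -> set[str]:
        universe: set[str] = set()
        for p in self.pathways:
            universe.update(p.members)
        return universe

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)


@dataclass
class DrugDefinition:
    """A drug and its signed target genes.

    Weight +1 marks a molecular target / sensitizer whose high expression
    favors response; -1 marks a resistance factor (e.g. MGMT for
    temozolomide) whose high expression opposes it.
    """

    drug_name: str
    targets: dict[str, int]
    drug_class: str = ""

    def __post_init__(self) -> None:
        if not self.targets:
            raise LoadError(f"drug {self.drug_name!r} has no targets")
        bad = {g: w for g, w in self.targets.items() if w not in (1, -1)}
        if bad:
            raise LoadError(
                f"drug {self.drug_name!r}: target weights must be +1/-1: {bad}"
            )


@dataclass
class SubtypeSignature:
    """A transcriptomic subtype signature (e.g. Proneural, Mesenchymal)."""

    subtype_name: str
    signature_genes: list[str]
    centroid: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.signature_genes:
            raise LoadError(f"signature {self.subtype_name!r} is empty")
        if len(set(self.signature_genes)) != len(self.signature_genes):
            raise LoadError(f"signature {self.subtype_name!r} has duplicate genes")


@dataclass
class CNRMatrix:
    """Per-gene case-to-normal expression ratios, genes x samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            raise LoadError("CNR matrix contains non-finite values")
        if (values <= 0).any():
            raise LoadError("CNR values must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class PALMatrix:
    """Pathway activation levels, pathways x samples, plus coverage report."""

    data: pd.DataFrame
    coverage: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float, copy=False)).all():
            raise LoadError("PAL matrix contains non-finite values")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class BESMatrix:
    """Balanced drug efficiency scores, drugs x samples, with raw components."""

    data: pd.DataFrame
    gene_component: pd.DataFrame
    pathway_component: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float, copy=False)).all():
            raise LoadError("BES matrix contains non-finite values")

    @property
    def drug_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# readers


def _check_unique_header(path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(samples) != len(set(samples)):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise LoadError(f"{path}: duplicate sample ids in header: {dupes}")
    return samples


def read_expression_tsv(path, is_normalized: bool = False) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene symbols).

    Duplicate gene rows are collapsed by summation (transcript-to-gene
    convention) with a warning; missing cells are imputed to 0 and logged;
    a negative value is a load error naming the offending cell.
    """
    _check_unique_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise LoadError(f"{path}: non-numeric expression value: {exc}") from exc
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        logger.warning("%s: imputed %d missing entries to 0", path, n_missing)
        df = df.fillna(0.0)
    neg = np.argwhere(df.to_numpy() < 0)
    if neg.size:
        g, s = neg[0]
        raise LoadError(
            f"{path}: negative value at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "%s: collapsed %d duplicate gene rows by summation", path, n_dup
        )
        df = df.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(df, is_normalized=is_normalized)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a plain features-x-samples TSV (PAL, CNR, BES output files)."""
    _check_unique_header(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: metadata missing columns {missing}")
    df = df[METADATA_COLUMNS].set_index("sample_id")
    for col in ("patient_id", "tumor_id", "region_id", "stage", "material"):
        df[col] = df[col].astype(str)
    df["pfs_days"] = pd.to_numeric(df["pfs_days"], errors="coerce")
    event = df["event"]
    df["event"] = event.map(
        {True: True, False: False, "True": True, "False": False,
         "1": True, "0": False, 1: True, 0: False}
    )
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.to_csv(path, sep="\t", index_label="sample_id")


def _parse_weighted_token(token: str, line_no: int, path) -> tuple[str, float]:
    if ":" not in token:
        raise LoadError(f"{path} line {line_no}: malformed token {token!r}")
    gene, _, raw = token.rpartition(":")
    try:
        value = float(raw)
    except ValueError as exc:
        raise LoadError(
            f"{path} line {line_no}: non-numeric weight in {token!r}"
        ) from exc
    return gene, value


def read_pathway_db(path) -> PathwayDB:
    """Parse an extended GMT ("GMTX") pathway file.

    One pathway per line: ``pathway_id<TAB>name<TAB>GENE:ARR<TAB>...`` with
    ARR restricted to {-1, -0.5, 0, 0.5, 1}.
    """
    pathways = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LoadError(
                    f"{path} line {line_no}: expected id, name and >=1 member"
                )
            pid, name, *tokens = parts
            members: dict[str, float] = {}
            for token in tokens:
                gene, arr = _parse_weighted_token(token, line_no, path)
                if arr not in ARR_VALUES:
                    raise LoadError(
                        f"{path} line {line_no}: ARR {arr} for gene {gene!r} "
                        "not in {-1,-0.5,0,0.5,1}"
                    )
                members[gene] = arr
            try:
                pathways.append(PathwayDefinition(pid, name, members))
            except LoadError as exc:
                raise LoadError(f"{path} line {line_no}: {exc}") from exc
    return PathwayDB(pathways)


def write_pathway_db(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for p in db:
            tokens = [f"{g}:{_fmt_weight(a)}" for g, a in p.members.items()]
            fh.write("\t".join([p.pathway_id, p.display_name, *tokens]) + "\n")


def _fmt_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else str(w)


def read_drug_table(path) -> list[DrugDefinition]:
    """Parse a drug table: ``drug_name<TAB>GENE:+1<TAB>GENE:-1...``.

    An optional trailing ``class=...`` token carries the drug class.
    """
    drugs = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, *tokens = line.split("\t")
            if name in seen:
                raise LoadError(f"{path} line {line_no}: duplicate drug {name!r}")
            seen.add(name)
            drug_class = ""
            targets: dict[str, int] = {}
            for token in tokens:
                if token.startswith("class="):
                    drug_class = token[len("class="):]
                    continue
                gene, w = _parse_weighted_token(token, line_no, path)
                if w not in (1, -1):
                    raise LoadError(
                        f"{path} line {line_no}: weight for {gene!r} must be +1/-1"
                    )
                targets[gene] = int(w)
            try:
                drugs.append(DrugDefinition(name, targets, drug_class))
            except LoadError as exc:
                raise LoadError(f"{path} line {line_no}: {exc}") from exc
    return drugs


def write_drug_table(drugs: list[DrugDefinition], path) -> None:
    with open(path, "w") as fh:
        for d in drugs:
            tokens = [f"{g}:{'+1' if w > 0 else '-1'}" for g, w in d.targets.items()]
            if d.drug_class:
                tokens.append(f"class={d.drug_class}")
            fh.write("\t".join([d.drug_name, *tokens]) + "\n")


def read_signatures(path) -> list[SubtypeSignature]:
    """Parse subtype signatures, GMT-style: ``name<TAB>GENE<TAB>GENE...``."""
    sigs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, *genes = line.split("\t")
            if not genes:
                raise LoadError(f"{path} line {line_no}: signature with no genes")
            sigs.append(SubtypeSignature(name, genes))
    return sigs


def write_signatures(sigs: list[SubtypeSignature], path) -> None:
    with open(path, "w") as fh:
        for s in sigs:
            fh.write("\t".join([s.subtype_name, *s.signature_genes]) + "\n")
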