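"""Seeded synthetic glioblastoma cohorts for exercising the pipeline.

The generator emulates the structure of a longitudinal multi-region
glioblastoma RNA-seq study: a normal-brain control group, patients sampled
at the newly diagnosed (ndGB) and/or recurrent (recGB) stage with several
regions per tumor, and stem-cell cultures (GSCs) grown from a subset of
tumors. Gene counts are negative-binomial around a lognormal latent mean
built from nested random effects (patient, tumor, region or culture) on the
natural-log scale, scaled by a per-sample library size. Recurrence-
associated signal is *planted*: a planted pathway shifts each member gene
of recGB samples by ``delta * sign(ARR)``, so the induced pathway
activation change has the closed-form expectation ``+delta`` (recGB-up) or
``-delta`` (recGB-down); planted single genes shift additively. GSC samples
inherit their tumor's effects — including the planted stage effects — plus
an independent culture shift, which is what gives tissue/GSC concordance a
true signal to find. Every planted effect is recorded in truth tables.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DrugDefinition,
    ExpressionMatrix,
    PathwayDB,
    PathwayDefinition,
    SampleMetadata,
    SubtypeSignature,
    write_drug_table,
    write_matrix,
    write_metadata,
    write_pathway_db,
    write_signatures,
)

#: gene symbols always present in the universe so that drug definitions and
#: planted-signal scenarios can refer to them
ANCHOR_GENES = ("MGMT", "CTLA4", "CD274", "EGFR", "TGFB1", "FOXM1")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a desk-scale cohort with the study's design features:
    paired multi-region tumors, matched GSC cultures and a normal control
    group, with variance components on the ln scale chosen so that
    between-patient spread dominates within-tumor spread.
    """

    seed: int = 0
    n_genes: int = 5000
    n_pathways: int = 300
    pathway_size_range: tuple[int, int] = (5, 30)
    activator_fraction: float = 0.7
    neutral_fraction: float = 0.1  # probability a member is ARR = 0
    n_normals: int = 10
    n_patients: int = 20
    regions_per_tumor: int = 2
    paired_fraction: float = 0.5
    gsc_fraction: float = 0.5
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    sigma_patient: float = 0.3
    sigma_tumor: float = 0.2
    sigma_region: float = 0.1
    sigma_gsc: float = 0.3
    planted_pathways: list[tuple[str, str, float]] = field(default_factory=list)
    planted_genes: list[tuple[str, str, float]] = field(default_factory=list)
    subtype_delta: float = 0.0
    signature_size: int = 30
    library_size_range: tuple[float, float] = (0.7, 1.3)
    nb_dispersion: float = 0.1

    def __post_init__(self) -> None:
        for name in ("baseline_log_sd", "sigma_patient", "sigma_tumor",
                     "sigma_region", "sigma_gsc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for _, group, delta in list(self.planted_pathways) + list(self.planted_genes):
            if group not in ("recGB-up", "recGB-down"):
                raise ValueError(f"unknown planting group {group!r}")
            if not np.isfinite(delta):
                raise ValueError("planting delta must be finite")


@dataclass
class SyntheticCohort:
    counts: ExpressionMatrix           # tumor + GSC raw counts
    normals: ExpressionMatrix          # control raw counts
    metadata: SampleMetadata           # tumor, GSC and normal samples
    pathway_db: PathwayDB
    drugs: list[DrugDefinition]
    signatures: list[SubtypeSignature]
    truth: dict[str, pd.DataFrame]
    config: SyntheticConfig


def _make_genes(cfg: SyntheticConfig) -> list[str]:
    n_anchor = min(len(ANCHOR_GENES), cfg.n_genes)
    generic = [f"G{i:05d}" for i in range(cfg.n_genes - n_anchor)]
    return list(ANCHOR_GENES[:n_anchor]) + generic


def _make_pathways(cfg: SyntheticConfig, genes: list[str], rng) -> PathwayDB:
    lo, hi = cfg.pathway_size_range
    pathways = []
    for i in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members_idx = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        members: dict[str, float] = {}
        for gi in members_idx:
            if rng.random() < cfg.neutral_fraction:
                arr = 0.0
            else:
                sign = 1.0 if rng.random() < cfg.activator_fraction else -1.0
                arr = sign * (1.0 if rng.random() < 0.5 else 0.5)
            members[genes[gi]] = arr
        if not any(a != 0 for a in members.values()):
            members[genes[members_idx[0]]] = 1.0
        pathways.append(PathwayDefinition(f"P{i:03d}", f"Synthetic pathway {i}", members))
    # anchor genes get a guaranteed activator slot so drug scenarios always
    # have a pathway route: MGMT in P000, CTLA4 in P001 (when they exist)
    if pathways and "MGMT" in genes:
        pathways[0].members["MGMT"] = 1.0
    if len(pathways) > 1 and "CTLA4" in genes:
        pathways[1].members["CTLA4"] = 1.0
    return PathwayDB(pathways)


def _default_drugs(genes: list[str], rng) -> list[DrugDefinition]:
    drugs = []
    if "MGMT" in genes:
        drugs.append(DrugDefinition("Temozolomide", {"MGMT": -1}, "alkylating"))
        drugs.append(DrugDefinition("Lomustine", {"MGMT": -1}, "alkylating"))
    if "CTLA4" in genes:
        drugs.append(DrugDefinition("Ipilimumab", {"CTLA4": 1}, "immune checkpoint"))
    if "CD274" in genes:
        drugs.append(DrugDefinition("Durvalumab", {"CD274": 1}, "immune checkpoint"))
    pool = [g for g in genes if g not in ANCHOR_GENES]
    for i in range(6):
        k = int(rng.integers(1, 4))
        targets_idx = rng.choice(len(pool), size=k, replace=False)
        drugs.append(
            DrugDefinition(
                f"TargetedDrug{i:02d}",
                {pool[t]: 1 for t in targets_idx},
                "synthetic targeted",
            )
        )
    return drugs


def _make_signatures(cfg: SyntheticConfig, genes: list[str], rng) -> list[SubtypeSignature]:
    pool = [g for g in genes if g not in ANCHOR_GENES]
    size = min(cfg.signature_size, len(pool) // 2)
    chosen = rng.choice(len(pool), size=2 * size, replace=False)
    return [
        SubtypeSignature("Proneural", [pool[i] for i in chosen[:size]]),
        SubtypeSignature("Mesenchymal", [pool[i] for i in chosen[size:]]),
    ]


def _stage_shift(cfg, db, genes_index, truth_rows) -> np.ndarray:
    """Additive ln-scale shift applied to recGB samples (planted signal)."""
    shift = np.zeros(len(genes_index))
    members_of = {p.pathway_id: p.members for p in db}
    for pid, group, delta in cfg.planted_pathways:
        if pid not in members_of:
            raise ValueError(f"planted pathway {pid!r} not in generated database")
        direction = 1.0 if group == "recGB-up" else -1.0
        for gene, arr in members_of[pid].items():
            if arr != 0:
                shift[genes_index[gene]] += direction * delta * np.sign(arr)
        truth_rows["pathways"].append(
            {"pathway_id": pid, "group": group, "delta": delta,
             "expected_pal_shift": direction * delta}
        )
    for gene, group, delta in cfg.planted_genes:
        if gene not in genes_index:
            raise ValueError(f"planted gene {gene!r} not in generated universe")
        direction = 1.0 if group == "recGB-up" else -1.0
        shift[genes_index[gene]] += direction * delta
        truth_rows["genes"].append(
            {"gene_id": gene, "group": group, "delta": delta,
             "expected_lncnr_shift": direction * delta}
        )
    return shift


def _draw_counts(latent: np.ndarray, lib: float, cfg, rng) -> np.ndarray:
    mu = np.exp(latent) * lib
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        return rng.negative_binomial(r, r / (r + mu))
    return rng.poisson(mu)


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a complete seeded cohort plus truth tables."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _make_genes(cfg)
    genes_index = {g: i for i, g in enumerate(genes)}
    db = _make_pathways(cfg, genes, rng)
    drugs = _default_drugs(genes, rng)
    signatures = _make_signatures(cfg, genes, rng)

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, len(genes))

    truth_rows = {"pathways": [], "genes": []}
    rec_shift = _stage_shift(cfg, db, genes_index, truth_rows)

    # study design: which patients carry which stages
    n_paired = int(round(cfg.paired_fraction * cfg.n_patients))
    stages_of: dict[str, list[str]] = {}
    for i in range(cfg.n_patients):
        pid = f"PT{i:03d}"
        if i < n_paired:
            stages_of[pid] = ["ndGB", "recGB"]
        else:
            stages_of[pid] = ["ndGB"] if (i - n_paired) % 2 == 0 else ["recGB"]

    sig_genes = {s.subtype_name: [genes_index[g] for g in s.signature_genes]
                 for s in signatures}
    subtype_names = [s.subtype_name for s in signatures]

    lo, hi = cfg.library_size_range
    sample_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    sample_truth = []

    for pid in sorted(stages_of):
        patient_eff = rng.normal(0, cfg.sigma_patient, len(genes))
        for stage in stages_of[pid]:
            tumor_id = f"{pid}-{stage}"
            tumor_eff = rng.normal(0, cfg.sigma_tumor, len(genes))
            tumor_latent = baseline + patient_eff + tumor_eff
            if stage == "recGB":
                tumor_latent = tumor_latent + rec_shift
            subtype = ""
            if cfg.subtype_delta > 0:
                subtype = subtype_names[int(rng.integers(len(subtype_names)))]
                tumor_latent = tumor_latent.copy()
                tumor_latent[sig_genes[subtype]] += cfg.subtype_delta
            for r in range(cfg.regions_per_tumor):
                sid = f"{tumor_id}-R{r + 1}"
                latent = tumor_latent + rng.normal(0, cfg.sigma_region, len(genes))
                lib = rng.uniform(lo, hi)
                sample_cols[sid] = _draw_counts(latent, lib, cfg, rng)
                meta_rows.append((sid, pid, tumor_id, f"R{r + 1}", stage, "tissue"))
                sample_truth.append((sid, stage, "tissue", subtype, lib))
            if rng.random() < cfg.gsc_fraction:
                sid = f"{tumor_id}-GSC"
                latent = tumor_latent + rng.normal(0, cfg.sigma_gsc, len(genes))
                lib = rng.uniform(lo, hi)
                sample_cols[sid] = _draw_counts(latent, lib, cfg, rng)
                meta_rows.append((sid, pid, tumor_id, "C1", stage, "GSC"))
                sample_truth.append((sid, stage, "GSC", subtype, lib))

    normal_cols: dict[str, np.ndarray] = {}
    for i in range(cfg.n_normals):
        sid = f"NORM{i:02d}"
        latent = baseline + rng.normal(0, cfg.sigma_region, len(genes))
        lib = rng.uniform(lo, hi)
        normal_cols[sid] = _draw_counts(latent, lib, cfg, rng)
        meta_rows.append((sid, f"CTRL{i:02d}", f"N{i:02d}", "R1", "normal", "tissue"))

    counts = ExpressionMatrix(
        pd.DataFrame(sample_cols, index=genes, dtype=float), is_normalized=False
    )
    normals = ExpressionMatrix(
        pd.DataFrame(normal_cols, index=genes, dtype=float), is_normalized=False
    )
    meta_df = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "patient_id", "tumor_id", "region_id", "stage", "material"],
    ).set_index("sample_id")
    meta_df["pfs_days"] = np.nan
    meta_df["event"] = pd.Series([pd.NA] * len(meta_df), index=meta_df.index)
    metadata = SampleMetadata(meta_df)

    truth = {
        "planted_pathways": pd.DataFrame(
            truth_rows["pathways"],
            columns=["pathway_id", "group", "delta", "expected_pal_shift"],
        ),
        "planted_genes": pd.DataFrame(
            truth_rows["genes"],
            columns=["gene_id", "group", "delta", "expected_lncnr_shift"],
        ),
        "samples": pd.DataFrame(
            sample_truth,
            columns=["sample_id", "stage", "material", "planted_subtype", "library_size"],
        ).set_index("sample_id"),
    }
    return SyntheticCohort(counts, normals, metadata, db, drugs, signatures, truth, cfg)


# ---------------------------------------------------------------------------
# fixtures on disk


def write_cohort(cohort: SyntheticCohort, out_dir) -> list[Path]:
    """Write a cohort as the standard-format file bundle the CLIs consume."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.counts.data, out / "expression.tsv", index_label="gene_id")
    write_matrix(cohort.normals.data, out / "normals.tsv", index_label="gene_id")
    write_metadata(cohort.metadata, out / "metadata.tsv")
    write_pathway_db(cohort.pathway_db, out / "pathways.gmtx")
    write_drug_table(cohort.drugs, out / "drugs.tsv")
    write_signatures(cohort.signatures, out / "signatures.tsv")
    for name, df in cohort.truth.items():
        df.to_csv(out / "truth" / f"{name}.tsv", sep="\t")
    return sorted(p for p in out.rglob("*") if p.is_file())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixture(size: str, out_dir, seed: int = 0) -> SyntheticCohort:
    """Write a complete worked-example bundle (inputs + expected outputs).

    ``tiny`` is 50 genes / 5 pathways / 12 tumor-side samples; ``small`` is
    5000 genes / 300 pathways / ~100 samples. Expected CNR/PAL outputs are
    produced by the pipeline itself, and a MANIFEST of SHA-256 checksums
    allows corruption checks via :func:`verify_fixture`.
    """
    from .pipeline import run_pal_pipeline

    if size == "tiny":
        cfg = SyntheticConfig(
            seed=seed, n_genes=50, n_pathways=5, pathway_size_range=(3, 8),
            n_normals=4, n_patients=4, regions_per_tumor=1, paired_fraction=1.0,
            gsc_fraction=0.5,
        )
    elif size == "small":
        cfg = SyntheticConfig(
            seed=seed, n_genes=5000, n_pathways=300, n_normals=10,
            n_patients=25, regions_per_tumor=2, paired_fraction=1.0,
            gsc_fraction=0.3,
        )
    else:
        raise ValueError("size must be 'tiny' or 'small'")
    cohort = simulate_cohort(cfg)
    out = Path(out_dir)
    write_cohort(cohort, out)
    cnr, pal = run_pal_pipeline(
        cohort.counts, cohort.normals, cohort.pathway_db
    )
    (out / "expected").mkdir(exist_ok=True)
    write_matrix(cnr.data, out / "expected" / "cnr.tsv", index_label="gene_id")
    write_matrix(pal.data, out / "expected" / "pal.tsv", index_label="pathway_id")
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "MANIFEST.sha256")
    with open(out / "MANIFEST.sha256", "w") as fh:
        for p in files:
            fh.write(f"{_sha256(p)}  {p.relative_to(out).as_posix()}\n")
    return cohort


def verify_fixture(bundle_dir) -> None:
    """Raise ValueError if any bundle file fails its recorded checksum."""
    out = Path(bundle_dir)
    manifest = out / "MANIFEST.sha256"
    if not manifest.exists():
        raise ValueError(f"{out}: no MANIFEST.sha256")
    for line in manifest.read_text().splitlines():
        digest, rel = line.split(None, 1)
        target = out / rel.strip()
        if not target.exists():
            raise ValueError(f"fixture file missing: {rel}")
        if _sha256(target) != digest:
            raise ValueError(f"fixture file corrupted: {rel}")
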