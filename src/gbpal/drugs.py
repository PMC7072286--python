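"""Balanced efficiency scores (BES) for anticancer target drugs.

A drug's predicted response in a sample combines the two transcriptomic
readouts relevant to targeted action: expression of its target genes and
activation of the pathways those targets sit in.

For drug d with measured targets T (signed weights w_t, +1 for a
target/sensitizer, -1 for a resistance factor such as MGMT for
temozolomide) in sample j:

    G_dj = (1/|T|) sum_{t in T} w_t * ln(CNR_tj)            gene component
    P_dj = (1/|Q|) sum_{p in Q} s_dp * PAL_pj               pathway component

where Q is the set of scored pathways containing at least one target of d
with nonzero ARR, and s_dp = sign(sum over d's targets in p of w_t*ARR_tp);
pathways with s_dp = 0 are excluded. Within every sample the two components
are standardized across the drug panel (z-scores; a zero-variance component
contributes 0) and averaged:

    BES_dj = (z(G_dj) + z(P_dj)) / 2

(z(G) alone when a drug touches no scorable pathway). The balancing makes
the gene- and pathway-level evidence commensurate, but it also makes BES a
panel-relative quantity: scores are only comparable across samples for the
same drug panel. This scoring rule is a reconstruction: published uses of
pathway-plus-target drug scoring describe the two inputs without printing a
formula, so the rule is isolated here behind ``compute_bes`` so an
alternative can be swapped in.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import BESMatrix, CNRMatrix, DrugDefinition, PALMatrix, PathwayDB, SampleMetadata
from .differential import rank_auc
from .pal import PathwayActivationScorer

logger = logging.getLogger("gbpal")


def _zscore_panel(component: pd.DataFrame, defined: pd.DataFrame) -> pd.DataFrame:
    """Standardize a drugs-x-samples component across the panel, per sample.

    Only drugs for which the component is defined enter the panel mean/sd;
    undefined entries stay NaN. A zero-sd panel yields 0 for every drug.
    """
    z = pd.DataFrame(np.nan, index=component.index, columns=component.columns)
    values = component.to_numpy(dtype=float)
    mask = defined.to_numpy(dtype=bool)
    for j in range(values.shape[1]):
        col = values[mask[:, j], j]
        if col.size == 0:
            continue
        sd = col.std(ddof=0)
        if sd == 0:
            z.iloc[mask[:, j], j] = 0.0
        else:
            z.iloc[mask[:, j], j] = (values[mask[:, j], j] - col.mean()) / sd
    return z


class DrugEfficiencyScorer(BaseEstimator, TransformerMixin):
    """Transform samples-x-genes CNRs into samples-x-drugs balanced scores.

    Pathway activations are computed internally from ``pathway_db``; the
    spec-shaped :func:`compute_bes` accepts a precomputed PAL matrix
    instead.
    """

    def __init__(
        self,
        drugs: list[DrugDefinition] = None,
        pathway_db: PathwayDB = None,
        min_coverage: int = 1,
    ):
        self.drugs = drugs
        self.pathway_db = pathway_db
        self.min_coverage = min_coverage

    def fit(self, X: pd.DataFrame, y=None):
        if not self.drugs:
            raise ValueError("a drug panel is required")
        self._pal_scorer = PathwayActivationScorer(
            self.pathway_db, min_coverage=self.min_coverage
        ).fit(X)
        self._prepare(set(X.columns), self._pal_scorer.pathway_ids_)
        return self

    def _prepare(self, genes: set[str], pathway_ids: list[str]) -> None:
        members = {
            pw.pathway_id: pw.members
            for pw in (self.pathway_db or [])
            if pw.pathway_id in set(pathway_ids)
        }
        kept, target_maps, pathway_signs = [], [], []
        for drug in self.drugs:
            measured = {g: w for g, w in drug.targets.items() if g in genes}
            if not measured:
                logger.info("BES: dropping drug %s (no measured targets)", drug.drug_name)
                continue
            signs = {}
            for pid, mem in members.items():
                s = sum(
                    w * mem[g] for g, w in drug.targets.items()
                    if g in mem and mem[g] != 0
                )
                touched = any(g in mem and mem[g] != 0 for g in drug.targets)
                if touched and s != 0:
                    signs[pid] = float(np.sign(s))
            kept.append(drug)
            target_maps.append(measured)
            pathway_signs.append(signs)
        if len(kept) < 2:
            raise ValueError(
                "drug panel has fewer than 2 scorable drugs; balancing undefined"
            )
        self.drugs_ = kept
        self.drug_names_ = [d.drug_name for d in kept]
        self.target_maps_ = target_maps
        self.pathway_signs_ = pathway_signs

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        pal = self._pal_scorer.transform(X)
        return self._score(X, pal).data.T

    def score_matrix(self, X: pd.DataFrame) -> BESMatrix:
        pal = self._pal_scorer.transform(X)
        return self._score(X, pal)

    def _score(self, cnr: pd.DataFrame, pal: pd.DataFrame) -> BESMatrix:
        samples = cnr.index
        log_cnr = np.log(cnr.to_numpy(dtype=float))
        gene_pos = {g: i for i, g in enumerate(cnr.columns)}
        G = pd.DataFrame(np.nan, index=self.drug_names_, columns=samples)
        P = pd.DataFrame(np.nan, index=self.drug_names_, columns=samples)
        for name, targets, signs in zip(
            self.drug_names_, self.target_maps_, self.pathway_signs_
        ):
            idx = [gene_pos[g] for g in targets]
            w = np.array([targets[g] for g in targets], dtype=float)
            G.loc[name] = (log_cnr[:, idx] * w).mean(axis=1)
            usable = [p for p in signs if p in pal.columns]
            if usable:
                s = np.array([signs[p] for p in usable])
                P.loc[name] = (pal[usable].to_numpy() * s).mean(axis=1)
        g_defined = G.notna()
        p_defined = P.notna()
        zG = _zscore_panel(G, g_defined)
        zP = _zscore_panel(P, p_defined)
        bes = zG.where(~p_defined, (zG + zP) / 2)
        return BESMatrix(bes, gene_component=G.fillna(np.nan), pathway_component=P)


# ---------------------------------------------------------------------------
# spec-shaped functions (drugs x samples orientation)


def compute_bes(
    cnr: CNRMatrix,
    pal: PALMatrix,
    drugs: list[DrugDefinition],
    db: PathwayDB,
) -> BESMatrix:
    """Balanced efficiency scores from precomputed CNR and PAL matrices."""
    scorer = DrugEfficiencyScorer(drugs, db)
    scorer._prepare(set(cnr.gene_ids), pal.pathway_ids)
    return scorer._score(cnr.data.T, pal.data.T)


def compare_bes_groups(bes: BESMatrix, labels) -> pd.DataFrame:
    """Per-drug two-group comparison: medians, Mann-Whitney p, AUC."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both groups must be nonempty")
    auc = rank_auc(bes.data, labels, threshold=0.7)
    mat = bes.data.to_numpy(dtype=float)
    res = stats.mannwhitneyu(
        mat[:, labels], mat[:, ~labels], axis=1, alternative="two-sided"
    )
    return pd.DataFrame(
        {
            "median_pos": auc["median_pos"],
            "median_neg": auc["median_neg"],
            "wilcoxon_p": np.atleast_1d(res.pvalue),
            "auc": auc["auc"],
        },
        index=bes.data.index,
    )


def rank_differential_drugs(
    bes_tissue: BESMatrix,
    bes_gsc: BESMatrix,
    labels_tissue,
    labels_gsc,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Drugs differentially scored in BOTH the tissue and the GSC comparison.

    Output mirrors a differential-drug table: per drug, median BES in each
    stage for each material, and the two AUCs.
    """
    cmp_t = compare_bes_groups(bes_tissue, labels_tissue)
    cmp_g = compare_bes_groups(bes_gsc, labels_gsc)
    shared = cmp_t.index.intersection(cmp_g.index)
    rows = []
    for drug in shared:
        auc_t, auc_g = cmp_t.loc[drug, "auc"], cmp_g.loc[drug, "auc"]
        if max(auc_t, 1 - auc_t) >= threshold and max(auc_g, 1 - auc_g) >= threshold:
            rows.append(
                {
                    "drug": drug,
                    "median_bes_ndGB_tissue": cmp_t.loc[drug, "median_neg"],
                    "median_bes_recGB_tissue": cmp_t.loc[drug, "median_pos"],
                    "median_bes_ndGB_gsc": cmp_g.loc[drug, "median_neg"],
                    "median_bes_recGB_gsc": cmp_g.loc[drug, "median_pos"],
                    "auc_tissue": auc_t,
                    "auc_gsc": auc_g,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "median_bes_ndGB_tissue", "median_bes_recGB_tissue",
            "median_bes_ndGB_gsc", "median_bes_recGB_gsc",
            "auc_tissue", "auc_gsc",
        ],
    ).set_index("drug")


def stratify_by_bes(
    bes: BESMatrix, drug: str, metadata: SampleMetadata, cutoff: float = 0.0
) -> pd.Series:
    """Patient-level positive/negative stratum for one drug's score.

    Majority vote over the patient's samples of (BES > cutoff); a tied vote
    falls back to the sign of the patient's mean BES, with mean == cutoff
    counted as negative. Patients with no scored samples are excluded and
    logged.
    """
    if drug not in bes.data.index:
        raise ValueError(f"drug {drug!r} not in the scored panel")
    scores = bes.data.loc[drug]
    patient_of = metadata.df["patient_id"]
    strata: dict[str, bool] = {}
    for patient in pd.unique(patient_of):
        sample_ids = patient_of.index[patient_of == patient]
        vals = scores.reindex(sample_ids).dropna()
        if vals.empty:
            logger.info("stratify: patient %s has no scored samples", patient)
            continue
        above = int((vals > cutoff).sum())
        below = len(vals) - above
        if above != below:
            strata[patient] = above > below
        else:
            strata[patient] = bool(vals.mean() > cutoff)
    return pd.Series(strata, name=f"bes_{drug}_above_{cutoff}", dtype=bool)
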