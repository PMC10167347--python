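"""End-to-end orchestration of the landmark-GWAS pipeline.

Stage order: pose/trait QC -> object-symmetric GPA and ILD construction ->
genotype PCA and kinship filtering -> per-trait OLS GWAS -> effective-test
FDR, clumping and conditional classification -> archaic admixture mapping
(skipped with a logged reason when no tracts are supplied).  Every filter
logs the records it drops, and a provenance record (config hash + seed)
accompanies the outputs so a rerun with the same configuration is
hash-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import archaic as arch
from . import association as assoc
from . import io as mio
from . import morphometrics as morpho

log = logging.getLogger("morphgwas.pipeline")


class PipelineError(RuntimeError):
    """Raised with the failing stage's name; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    landmarks: str
    covariates: str
    vcf: str
    output_dir: str
    symmetry_map: str | None = None
    local_ancestry: str | None = None
    tracts: str | None = None
    seed: int = 0
    genomewide_p: float = 5e-8
    suggestive_p: float = 1e-5
    clump_r2: float = 0.1
    clump_window_bp: int = 1_000_000
    tract_min_conf: float = 0.99
    tract_min_len_bp: int = 10_000
    segment_max_change: float = 0.01
    segment_min_freq: float = 0.01
    n_pcs: int = 6
    kinship_threshold: float = 0.1
    fdr_alpha: float = 0.05
    max_traits: int | None = None

    def __post_init__(self):
        if not (0 < self.genomewide_p < 1 and 0 < self.suggestive_p < 1):
            raise ValueError("significance thresholds must be in (0,1)")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in [0,1]")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"filters": {}, "stages": []}

    def stage(name):
        report["stages"].append(name)
        log.info("stage: %s", name)

    try:
        stage("load")
        landmarks = mio.read_landmarks_tsv(config.landmarks)
        covariates = mio.read_covariates_tsv(config.covariates)
        panel = mio.read_vcf(config.vcf)
        sym = (
            mio.read_symmetry_map(config.symmetry_map)
            if config.symmetry_map
            else morpho.SymmetryMap.default_face()
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load", e) from e

    try:
        stage("qc_pose")
        keep_pose = morpho.qc_head_pose(covariates)
        report["filters"]["pose_excluded"] = int((~keep_pose).sum())
        ids_kept = [i for i, k in zip(landmarks.ids, keep_pose.to_numpy()) if k]
        landmarks = morpho.LandmarkSet(ids_kept, landmarks.coords[keep_pose.to_numpy()])
        covariates = covariates.loc[keep_pose]
        panel = panel.subset_individuals(keep_pose.to_numpy())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("qc_pose", e) from e

    try:
        stage("gpa_ilds")
        fit = morpho.gpa_object_symmetry(landmarks, sym)
        catalog = morpho.ild_catalog(sym)
        ilds = morpho.compute_ilds(fit, catalog)
        keep_traits = morpho.qc_trait_outliers(ilds, covariates["sex"])
        report["filters"]["trait_outlier_cells"] = int((~keep_traits).to_numpy().sum())
        values = ilds.values.where(keep_traits)
        # mean-impute the few outlier cells so the design stays complete-case
        values = values.fillna(values.mean())
        ilds = morpho.ILDMatrix(values=values, catalog=catalog)
        mio.write_ild_matrix(out_dir / "ilds.tsv", out_dir / "ild_catalog.json", ilds)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("gpa_ilds", e) from e

    try:
        stage("pca_kinship")
        phi, keep_kin = assoc.kinship_king(panel, config.kinship_threshold)
        report["filters"]["kinship_excluded"] = int((~keep_kin).sum())
        panel = panel.subset_individuals(keep_kin)
        ild_vals = ilds.values.iloc[keep_kin]
        covariates = covariates.iloc[keep_kin]
        pcs = assoc.genotype_pca(panel, config.n_pcs)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("pca_kinship", e) from e

    try:
        stage("gwas")
        cov_cols = ["sex", "age", "bmi", "yaw", "pitch", "roll"]
        cov = covariates[[c for c in cov_cols if c in covariates.columns]]
        traits = list(ild_vals.columns[: config.max_traits])
        results = []
        for trait in traits:
            res = assoc.gwas_ols(ild_vals[trait], panel, cov, pcs=pcs, model_tag="pc")
            res.insert(0, "trait", trait)
            results.append(res)
        gwas = pd.concat(results, ignore_index=True)
        lam = {t: assoc.lambda_gc(gwas.loc[gwas["trait"] == t, "p"].to_numpy()) for t in traits}
        gwas.to_csv(out_dir / "gwas.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("gwas", e) from e

    try:
        stage("multiple_testing")
        meff_t = assoc.meff_traits(ild_vals[traits]) if len(traits) > 1 else 1.0
        meff_s = assoc.meff_snps(panel, config.clump_r2, config.clump_window_bp)
        bh_thr, _ = assoc.bh_fdr(gwas["p"].dropna().to_numpy(), config.fdr_alpha)
        clumps = assoc.ld_clump(gwas, panel, config.genomewide_p, config.clump_r2, config.clump_window_bp)
        conditional = []
        for c in clumps.itertuples():
            others = [s for cl in clumps.itertuples() if cl.clump != c.clump for s in [cl.index_snp]]
            if not others:
                continue
            trait = gwas.loc[gwas["p"].idxmin(), "trait"]
            cond = assoc.conditional_scan(
                ild_vals[trait], panel, cov, others, test_snps=[c.index_snp], suggestive=config.suggestive_p, pcs=pcs
            )
            cond.insert(0, "clump", c.clump)
            conditional.append(cond)
        conditional = pd.concat(conditional, ignore_index=True) if conditional else pd.DataFrame()
        clumps.to_csv(out_dir / "clumps.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("multiple_testing", e) from e

    admix = None
    admix_thr = None
    if config.tracts:
        try:
            stage("admixmap")
            tracts = mio.read_tracts_bed(config.tracts)
            n0 = len(tracts)
            if n0 == 0:
                log.info("admixture mapping skipped: empty tract file")
                report["filters"]["tracts_retained"] = 0
            else:
                tracts = arch.filter_tracts(tracts, config.tract_min_conf, config.tract_min_len_bp)
                report["filters"]["tracts_dropped"] = n0 - len(tracts)
                report["filters"]["tracts_retained"] = len(tracts)
                if len(tracts):
                    hap_ids_kept = {f"hap{h}" for i in np.flatnonzero(keep_kin) for h in (2 * i, 2 * i + 1)}
                    remap = {}
                    for new_i, old_i in enumerate(np.flatnonzero(keep_kin)):
                        remap[f"hap{2 * old_i}"] = new_i
                        remap[f"hap{2 * old_i + 1}"] = new_i
                    tracts = tracts[tracts["haplotype"].isin(hap_ids_kept)]
                    dosage = arch.tracts_to_dosage(
                        tracts, panel.snp_table["pos"].to_numpy(), remap, n_individuals=panel.n
                    )
                    segments = arch.merge_segments(
                        dosage, panel.snp_table["pos"].to_numpy(), config.segment_max_change
                    )
                    segments = arch.filter_segment_frequency(segments, config.segment_min_freq)
                    report["filters"]["segments_retained"] = len(segments.table)
                    if len(segments.table):
                        admix, admix_thr = arch.admixmap_scan(
                            segments, ild_vals[traits], cov, alpha=config.fdr_alpha, pcs=pcs
                        )
                        admix.to_csv(out_dir / "admixmap.tsv", sep="\t", index=False)
                    else:
                        log.info("admixture mapping skipped: no segments after frequency filter")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("admixmap", e) from e
    else:
        log.info("admixture mapping skipped: no tract file supplied")

    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_individuals": int(panel.n),
        "n_snps": int(panel.m),
        "n_traits": len(traits),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, sort_keys=True, indent=2))

    return {
        "ilds": ilds,
        "gwas": gwas,
        "lambda": lam,
        "meff_traits": meff_t,
        "meff_snps": meff_s,
        "bh_threshold": bh_thr,
        "clumps": clumps,
        "conditional": conditional,
        "admixmap": admix,
        "admixmap_bh_threshold": admix_thr,
        "report": report,
        "provenance": provenance,
    }
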