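"""Readers and writers for the pipeline's on-disk formats.

Conventions: VCF positions are 1-based; tract BED files are 0-based
half-open; conversion happens only at this I/O boundary.  Landmark tables
are TSV with an ``id`` column followed by x1,y1[,z1],...; covariates and
local ancestry are plain TSV; the GRM is stored as a small binary
lower-triangle (float64) with a text ID sidecar.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .association import DosagePanel
from .heritability import GRM
from .morphometrics import ILDCatalog, ILDMatrix, LandmarkSet, SymmetryMap

# ---------------------------------------------------------------------------
# landmarks / covariates
# ---------------------------------------------------------------------------


def write_landmarks_tsv(path, landmarks: LandmarkSet) -> None:
    n, k, d = landmarks.coords.shape
    axes = "xyz"[:d]
    cols = [f"{ax}{j + 1}" for j in range(k) for ax in axes]
    df = pd.DataFrame(landmarks.coords.reshape(n, k * d), columns=cols)
    df.insert(0, "id", landmarks.ids)
    df.to_csv(path, sep="\t", index=False)


def read_landmarks_tsv(path, d: int | None = None) -> LandmarkSet:
    df = pd.read_csv(path, sep="\t")
    ids = df["id"].astype(str).tolist()
    mat = df.drop(columns="id").to_numpy(float)
    if d is None:
        d = 3 if df.columns[-1].startswith("z") else 2
    k = mat.shape[1] // d
    return LandmarkSet(ids, mat.reshape(len(ids), k, d))


def write_covariates_tsv(path, covariates: pd.DataFrame) -> None:
    covariates.rename_axis("id").to_csv(path, sep="\t")


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_vcf(path, panel: DosagePanel) -> None:
    """Minimal VCF v4.2 with phased GT from the panel haplotypes."""
    if panel.haplotypes is None:
        raise ValueError("panel has no phased haplotypes to write")
    hap = panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = panel.snp_table["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.ids) + "\n")
        for j, rec in enumerate(panel.snp_table.itertuples()):
            gts = "\t".join(f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(panel.n))
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> DosagePanel:
    """Read a (possibly phased) VCF into a dosage panel via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    chroms, poss, rsids, refs, alts = [], [], [], [], []
    haps = []
    phased_all = True
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rsids.append(var.ID or f"{var.CHROM}:{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        gt = np.array(var.genotypes)  # n x 3 (a, b, phased)
        phased_all &= bool(np.all(gt[:, 2]))
        haps.append(gt[:, :2])
    hap = np.stack(haps, axis=2) if haps else np.empty((len(ids), 2, 0))
    # interleave: rows 2i, 2i+1 are individual i's haplotypes
    hap_mat = np.empty((2 * len(ids), len(poss)), dtype=np.int16)
    hap_mat[0::2] = hap[:, 0, :]
    hap_mat[1::2] = hap[:, 1, :]
    dos = np.where(hap_mat[0::2] < 0, np.nan, hap_mat[0::2].astype(float)) + np.where(
        hap_mat[1::2] < 0, np.nan, hap_mat[1::2].astype(float)
    )
    snp_table = pd.DataFrame({"chrom": chroms, "pos": poss, "id": rsids, "ref": refs, "alt": alts})
    return DosagePanel(
        dosages=dos,
        snp_table=snp_table,
        ids=ids,
        haplotypes=hap_mat if phased_all and hap_mat.size and hap_mat.min() >= 0 else None,
    )


def write_local_ancestry_tsv(path, panel: DosagePanel) -> None:
    """Long-format per-haplotype local ancestry (haplotype_id, chrom, pos, ancestry)."""
    if panel.ancestry is None:
        raise ValueError("panel has no local ancestry")
    n_hap, m = panel.ancestry.shape
    df = pd.DataFrame(
        {
            "haplotype_id": np.repeat([f"hap{h}" for h in range(n_hap)], m),
            "chrom": np.tile(panel.snp_table["chrom"].to_numpy(), n_hap),
            "pos": np.tile(panel.snp_table["pos"].to_numpy(), n_hap),
            "ancestry": panel.ancestry.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_local_ancestry_tsv(path, snp_table: pd.DataFrame) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    hap_ids = df["haplotype_id"].unique()
    m = len(snp_table)
    anc = np.empty((len(hap_ids), m), dtype=np.uint8)
    order = {h: i for i, h in enumerate(hap_ids)}
    for h, grp in df.groupby("haplotype_id", sort=False):
        if len(grp) != m:
            raise ValueError("local ancestry rows do not match SNP table")
        anc[order[h]] = grp["ancestry"].to_numpy()
    return anc


# ---------------------------------------------------------------------------
# tracts / ILDs / GRM
# ---------------------------------------------------------------------------

TRACT_HEADER = ["chrom", "start", "end", "haplotype", "confidence"]


def write_tracts_bed(path, tracts: pd.DataFrame) -> None:
    tracts[TRACT_HEADER].to_csv(path, sep="\t", index=False)


def read_tracts_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[TRACT_HEADER + [c for c in df.columns if c not in TRACT_HEADER]]


def write_ild_matrix(path_values, path_catalog, ilds: ILDMatrix) -> None:
    ilds.values.rename_axis("id").to_csv(path_values, sep="\t")
    Path(path_catalog).write_text(ilds.catalog.to_json())


def read_ild_matrix(path_values, path_catalog) -> ILDMatrix:
    values = pd.read_csv(path_values, sep="\t", index_col="id")
    catalog = ILDCatalog.from_json(Path(path_catalog).read_text())
    return ILDMatrix(values=values, catalog=catalog)


def write_symmetry_map(path, sym: SymmetryMap) -> None:
    Path(path).write_text(sym.to_json())


def read_symmetry_map(path) -> SymmetryMap:
    return SymmetryMap.from_json(Path(path).read_text())


def write_grm_binary(path_bin, path_ids, grm: GRM) -> None:
    """n, then the row-major lower triangle (incl. diagonal) as float64."""
    n = grm.matrix.shape[0]
    tri = grm.matrix[np.tril_indices(n)]
    with open(path_bin, "wb") as fh:
        fh.write(struct.pack("<ii", n, grm.n_snps_used))
        fh.write(tri.astype("<f8").tobytes())
    Path(path_ids).write_text("\n".join(grm.ids) + "\n")


def read_grm_binary(path_bin, path_ids) -> GRM:
    with open(path_bin, "rb") as fh:
        n, n_snps = struct.unpack("<ii", fh.read(8))
        tri = np.frombuffer(fh.read(), dtype="<f8")
    mat = np.zeros((n, n))
    mat[np.tril_indices(n)] = tri
    mat = mat + np.tril(mat, -1).T
    ids = Path(path_ids).read_text().splitlines()
    return GRM(matrix=mat, n_snps_used=n_snps, ids=ids)
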