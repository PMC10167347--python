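"""Archaic-introgression admixture mapping.

Association testing on archaic (e.g. Neanderthal) haplotype dosage rather
than allelic genotype: reference-site filtering, introgression-tract
filtering, recoding of individuals by the number of archaic haplotypes
covering each site (0/1/2), merging of consecutive sites with nearly
identical dosage columns into segments, frequency filtering, linear-model
association of traits on segment dosage with a Benjamini-Hochberg
threshold, and cross-tabulation of tracts by the local-ancestry background
they ride on.

Tract coordinates follow BED conventions (0-based, half-open); SNP
positions are 1-based, so a site at position p is covered by a tract
[start, end) iff start < p <= end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import bh_fdr, gwas_ols, DosagePanel
from .morphometrics import SchemaError

TRACT_COLUMNS = ["haplotype", "chrom", "start", "end", "confidence"]

SITE_COLUMNS = [
    "chrom",
    "pos",
    "archaic_depth",
    "archaic_pass",
    "modern_pass",
    "archaic_anc",
    "archaic_der",
    "modern_anc",
    "modern_der",
    "ancestral_in_cohort",
]


@dataclass
class SegmentTable:
    """Merged-SNP segments with representative dosage columns.

    table: one row per segment (first/last SNP index, positions, bp span,
    archaic allele frequency); genotypes: individuals x segments
    representative dosage matrix.
    """

    table: pd.DataFrame
    genotypes: np.ndarray


def filter_archaic_sites(sites: pd.DataFrame, min_depth: int = 20) -> tuple[pd.Series, dict]:
    """Keep-mask for archaic reference sites.

    Retains a site iff (i) archaic read depth >= min_depth (inclusive),
    (ii) it passes the variant filters of both the archaic and the modern
    reference call sets, (iii) both report the same ancestral/derived
    alleles, and (iv) the ancestral allele is present in the study cohort.
    Also returns per-rule drop counts.
    """
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            raise SchemaError(f"missing site column {col!r}")
    depth_ok = sites["archaic_depth"] >= min_depth
    pass_ok = sites["archaic_pass"].astype(bool) & sites["modern_pass"].astype(bool)
    allele_ok = (sites["archaic_anc"] == sites["modern_anc"]) & (sites["archaic_der"] == sites["modern_der"])
    anc_ok = sites["ancestral_in_cohort"].astype(bool)
    keep = depth_ok & pass_ok & allele_ok & anc_ok
    counts = {
        "low_depth": int((~depth_ok).sum()),
        "fail_pass": int((~pass_ok).sum()),
        "allele_mismatch": int((~allele_ok).sum()),
        "ancestral_absent": int((~anc_ok).sum()),
        "retained": int(keep.sum()),
    }
    return keep, counts


def filter_tracts(
    tracts: pd.DataFrame,
    min_conf: float = 0.99,
    min_len_bp: int = 10_000,
) -> pd.DataFrame:
    """Retain tracts called with confidence strictly above ``min_conf`` and
    length strictly above ``min_len_bp`` (both strict inequalities)."""
    import logging

    length = tracts["end"] - tracts["start"]
    out = tracts[(tracts["confidence"] > min_conf) & (length > min_len_bp)].reset_index(drop=True)
    kept_len = (out["end"] - out["start"]).mean() if len(out) else float("nan")
    logging.getLogger(__name__).info(
        "filter_tracts: %d of %d tracts retained (mean length %.0f bp)",
        len(out),
        len(tracts),
        kept_len,
    )
    return out


def tracts_to_dosage(
    tracts: pd.DataFrame,
    snp_positions: np.ndarray,
    haplotype_map: dict,
    n_individuals: int | None = None,
) -> np.ndarray:
    """Archaic dosage matrix: per individual, the number of its haplotypes
    with a tract covering each site (0, 1 or 2).

    haplotype_map maps haplotype id -> individual row index.
    """
    pos = np.asarray(snp_positions)
    if n_individuals is None:
        n_individuals = max(haplotype_map.values()) + 1 if haplotype_map else 0
    dosage = np.zeros((n_individuals, pos.size), dtype=np.int16)
    for t in tracts.itertuples():
        if t.haplotype not in haplotype_map:
            raise KeyError(f"haplotype {t.haplotype!r} not in haplotype map")
        i = haplotype_map[t.haplotype]
        lo = np.searchsorted(pos, t.start, side="right")  # first pos > start
        hi = np.searchsorted(pos, t.end, side="right")  # last pos <= end
        dosage[i, lo:hi] += 1
    if dosage.max(initial=0) > 2:
        raise ValueError("overlapping tracts on one haplotype produce dosage > 2")
    return dosage


def tract_frequency_profile(
    tracts: pd.DataFrame,
    grid_positions: np.ndarray,
    n_haplotypes: int,
) -> np.ndarray:
    """Fraction of haplotypes covered by a tract at each grid position
    (tract stacking)."""
    grid = np.asarray(grid_positions)
    cover = np.zeros(grid.size)
    for t in tracts.itertuples():
        cover += (grid > t.start) & (grid <= t.end)
    return cover / n_haplotypes


def merge_segments(
    dosage: np.ndarray,
    positions: np.ndarray,
    max_change: float = 0.01,
) -> SegmentTable:
    """Merge consecutive sites with nearly identical dosage columns.

    Greedy left-to-right: the current segment is extended to the next site
    iff the fraction of individuals whose dosage differs between the two
    adjacent sites is <= max_change.  The representative genotype of a
    segment is its first site's column; the archaic allele frequency is
    mean(representative)/2.  Segments partition the ordered site list.
    """
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    if m < 1:
        raise ValueError("need at least one site")
    pos = np.asarray(positions)
    change = (dosage[:, 1:] != dosage[:, :-1]).mean(axis=0) if m > 1 else np.empty(0)
    breaks = np.flatnonzero(change > max_change) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [m]])  # half-open index ranges
    rows = []
    reps = []
    for s, e in zip(starts, ends):
        rep = dosage[:, s]
        reps.append(rep)
        rows.append(
            {
                "first_idx": int(s),
                "last_idx": int(e - 1),
                "start_pos": int(pos[s]),
                "end_pos": int(pos[e - 1]),
                "span_bp": int(pos[e - 1] - pos[s]),
                "n_sites": int(e - s),
                "frequency": float(rep.mean() / 2.0),
            }
        )
    table = pd.DataFrame(rows)
    table.insert(0, "segment", np.arange(1, len(rows) + 1))
    return SegmentTable(table=table, genotypes=np.stack(reps, axis=1))


def filter_segment_frequency(segments: SegmentTable, min_freq: float = 0.01) -> SegmentTable:
    """Retain segments with archaic allele frequency >= min_freq (inclusive)."""
    keep = segments.table["frequency"].to_numpy() >= min_freq
    return SegmentTable(
        table=segments.table[keep].reset_index(drop=True),
        genotypes=segments.genotypes[:, keep],
    )


def admixmap_scan(
    segments: SegmentTable,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | np.ndarray | None = None,
    alpha: float = 0.05,
    pcs: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Admixture mapping: OLS of each trait on each segment's representative
    archaic dosage plus covariates (same linear model as the SNP GWAS).

    Returns the per-(segment, trait) results and the Benjamini-Hochberg
    threshold computed over all segment x trait tests.  Constant segment
    dosages yield NA with a flag.
    """
    if len(segments.table) == 0:
        raise ValueError("no segments to test")
    tab = segments.table
    panel = DosagePanel(
        dosages=segments.genotypes.astype(float),
        snp_table=pd.DataFrame(
            {
                "chrom": ["seg"] * len(tab),
                "pos": tab["start_pos"].to_numpy(),
                "id": [f"seg{j}" for j in tab["segment"]],
                "ref": ["N"] * len(tab),
                "alt": ["A"] * len(tab),
            }
        ),
    )
    const = segments.genotypes.std(axis=0) == 0
    frames = []
    for trait in traits.columns:
        res = gwas_ols(traits[trait], panel, covariates, pcs=pcs, model_tag="admixmap")
        res = res.rename(columns={"id": "segment_id"})
        res["trait"] = trait
        res["segment"] = tab["segment"].to_numpy()
        res["constant_dosage"] = const
        res.loc[const, ["beta", "se", "p"]] = np.nan
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    pvals = out["p"].dropna().to_numpy()
    thr, _ = bh_fdr(pvals, alpha) if pvals.size else (0.0, None)
    return out, thr


def tract_ancestry_background(
    tracts: pd.DataFrame,
    ancestry: np.ndarray,
    snp_positions: np.ndarray,
    hap_index: dict,
    ancestry_labels: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Cross-tabulate tracts by the local-ancestry background at their
    midpoint.

    ancestry: (n_haplotypes x M) local-ancestry codes at each SNP;
    hap_index maps tract haplotype ids to ancestry rows.
    """
    pos = np.asarray(snp_positions)
    codes = np.unique(ancestry)
    counts = {c: 0 for c in codes}
    for t in tracts.itertuples():
        mid = 0.5 * (t.start + t.end)
        lo = int(np.searchsorted(pos, t.start, side="right"))
        hi = int(np.searchsorted(pos, t.end, side="right"))
        if hi > lo:  # SNPs inside the tract: take the one nearest the midpoint
            inside = pos[lo:hi]
            j = lo + int(np.argmin(np.abs(inside - mid)))
        else:  # no genotyped site inside; fall back to the nearest SNP
            j = int(np.clip(np.searchsorted(pos, mid), 0, pos.size - 1))
        code = ancestry[hap_index[t.haplotype], j]
        counts[code] = counts.get(code, 0) + 1
    total = sum(counts.values())
    rows = []
    for c in sorted(counts):
        label = ancestry_labels[c] if c < len(ancestry_labels) else str(c)
        rows.append(
            {
                "ancestry": label,
                "code": int(c),
                "n_tracts": counts[c],
                "fraction": counts[c] / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
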