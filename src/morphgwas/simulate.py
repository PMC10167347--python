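"""Synthetic admixed-cohort generator.

Generates cohorts with the statistical structure the pipeline assumes, so
every stage is testable without access-restricted data:

* three-way admixed genotypes: per-population allele frequencies from a
  Balding-Nichols construction, local-ancestry tracts from a Markov switch
  process (Poisson breakpoints at ``generations x genetic distance``,
  constant recombination of 1 cM/Mb), alleles drawn from the frequency of
  the local ancestry at each SNP;
* archaic introgression tracts of exponential length placed on haplotypes
  carrying a designated target ancestry at a focal region, with
  archaic-diagnostic alleles painted inside tracts;
* 2D frontal-face landmark configurations built from a symmetric mean
  shape plus sex/age/BMI effects on chosen inter-landmark distances,
  additive causal-SNP displacements, symmetric individual variation, small
  fluctuating asymmetry, and nuisance pose (yaw/pitch/roll foreshortening
  and rotation, bounded so Procrustes alignment converges);
* 3D mirror-symmetric skull-like configurations whose symmetric-component
  scores carry GRM-structured genetic covariance.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import DosagePanel
from .morphometrics import LandmarkSet, SymmetryMap, ild_catalog


class InvalidConfigurationError(ValueError):
    """Simulation configuration is degenerate or inconsistent."""


RECOMB_PER_BP = 1e-8  # 1 cM/Mb


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Ancestry proportions default to a typical three-way admixed Latin
    American cohort (European, Native American, African); the archaic
    preset places tracts of mean length 127 kb on 31% of target-background
    haplotypes around the chromosome midpoint.  Causal effects are
    (snp_index, ild_index, beta) triples with beta in phenotype-SD units.
    """

    seed: int = 0
    n_individuals: int = 600
    n_snps: int = 2000
    chrom_length_bp: int = 50_000_000
    ancestry_proportions: tuple[float, float, float] = (0.48, 0.46, 0.06)
    fst_divergence: float = 0.12
    generations_since_admixture: int = 12
    archaic_target_ancestry: int = 1
    archaic_haplotype_frequency: float = 0.31
    archaic_mean_tract_bp: float = 127_000.0
    causal_effects: tuple[tuple[int, int, float], ...] = ()
    ancestry_labels: tuple[str, ...] = ("EUR", "NAM", "AFR")

    def __post_init__(self):
        if self.n_individuals < 2 or self.n_snps < 1:
            raise InvalidConfigurationError("need n_individuals >= 2 and n_snps >= 1")
        props = np.asarray(self.ancestry_proportions, float)
        if abs(props.sum() - 1.0) > 1e-12 or np.any(props < 0):
            raise InvalidConfigurationError("ancestry_proportions must be a simplex vector")
        if not 0 < self.fst_divergence < 1:
            raise InvalidConfigurationError("fst_divergence must be in (0, 1)")
        if not 0 <= self.archaic_haplotype_frequency <= 1:
            raise InvalidConfigurationError("archaic_haplotype_frequency must be in [0, 1]")
        if self.generations_since_admixture < 1 or self.chrom_length_bp < 1:
            raise InvalidConfigurationError("counts must be positive")
        for snp, ild, beta in self.causal_effects:
            if not 0 <= snp < self.n_snps:
                raise InvalidConfigurationError(f"causal SNP index {snp} out of range")


@dataclass
class CohortBundle:
    """Everything downstream stages consume, mutually consistent."""

    panel: DosagePanel
    tracts: pd.DataFrame
    landmarks: LandmarkSet
    covariates: pd.DataFrame
    true_effects: pd.DataFrame
    template: SymmetryMap
    config: SimConfig


# ---------------------------------------------------------------------------
# genotypes and local ancestry
# ---------------------------------------------------------------------------


def _distinct_sorted_positions(rng: np.random.Generator, length: int, m: int) -> np.ndarray:
    """m distinct sorted 1-based positions without materializing the range."""
    if m > length:
        raise InvalidConfigurationError("more SNPs than base pairs")
    pos = np.unique(rng.integers(1, length + 1, size=int(m * 1.5) + 16))
    while pos.size < m:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=m)]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def simulate_admixed_genotypes(config: SimConfig):
    """Phased haplotypes, SNP table, and per-haplotype local ancestry.

    Returns (haplotypes (2n x M) uint8, snp_table, local_ancestry (2n x M)
    uint8).  Per-population allele frequencies follow Balding-Nichols:
    ancestral frequency p0 ~ U(0.05, 0.95), population frequency ~
    Beta(p0 (1-F)/F, (1-p0)(1-F)/F).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    n_hap = 2 * n
    pos = _distinct_sorted_positions(rng, config.chrom_length_bp, m)
    p0 = rng.uniform(0.05, 0.95, size=m)
    f = config.fst_divergence
    a, b = p0 * (1 - f) / f, (1 - p0) * (1 - f) / f
    n_anc = len(config.ancestry_proportions)
    freqs = np.stack([rng.beta(a, b) for _ in range(n_anc)], axis=0)  # n_anc x M

    props = np.asarray(config.ancestry_proportions, float)
    rate = config.generations_since_admixture * RECOMB_PER_BP
    ancestry = np.empty((n_hap, m), dtype=np.uint8)
    for h in range(n_hap):
        anc_here = rng.choice(n_anc, p=props)
        cursor = 0.0
        start_idx = 0
        while start_idx < m:
            seg_len = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            cursor += seg_len
            end_idx = int(np.searchsorted(pos, cursor, side="right"))
            ancestry[h, start_idx:end_idx] = anc_here
            start_idx = end_idx
            anc_here = rng.choice(n_anc, p=props)

    haplotypes = (rng.random((n_hap, m)) < freqs[ancestry, np.arange(m)]).astype(np.uint8)
    snp_table = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "id": [f"rs{i + 1}" for i in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    for i in range(n_anc):
        label = config.ancestry_labels[i] if i < len(config.ancestry_labels) else f"anc{i}"
        snp_table[f"freq_{label}"] = freqs[i]
    return haplotypes, snp_table, ancestry


def simulate_archaic_tracts(
    haplotypes: np.ndarray,
    local_ancestry: np.ndarray,
    snp_table: pd.DataFrame,
    config: SimConfig,
    n_decoys: int = 0,
):
    """Place archaic tracts on target-ancestry haplotypes at a focal region.

    Each haplotype carrying the target ancestry at the chromosome midpoint
    receives a tract with probability ``archaic_haplotype_frequency``; the
    tract has exponential length (mean ``archaic_mean_tract_bp``), spans
    the focal point, and is clipped to the haplotype's contiguous
    target-ancestry run so it lies entirely on the target background.
    Archaic-diagnostic SNPs (flagged in the returned SNP table) inside a
    tract carry the archaic (alternative) allele.  Decoy tracts with low
    confidence or short length can be added to exercise downstream
    filters.  Tract coordinates are BED-style (0-based half-open).
    """
    rng = np.random.default_rng(config.seed + 101)
    hap = haplotypes.copy()
    pos = snp_table["pos"].to_numpy()
    m = pos.size
    snp_table = snp_table.copy()
    focal = config.chrom_length_bp // 2
    target = config.archaic_target_ancestry
    diagnostic = (np.abs(pos - focal) < 2 * config.archaic_mean_tract_bp) & (np.arange(m) % 3 == 0)
    snp_table["archaic_diagnostic"] = diagnostic

    rows = []
    if not np.any(local_ancestry == target):
        import warnings

        warnings.warn("archaic target ancestry absent from cohort; no tracts placed")
    elif config.archaic_haplotype_frequency > 0:
        j_focal = int(np.clip(np.searchsorted(pos, focal), 0, m - 1))
        for h in range(hap.shape[0]):
            if local_ancestry[h, j_focal] != target:
                continue
            if rng.random() >= config.archaic_haplotype_frequency:
                continue
            length = rng.exponential(config.archaic_mean_tract_bp)
            u = rng.random()
            start = focal - u * length
            end = start + length
            # clip to the contiguous target-ancestry run around the focal SNP
            left = j_focal
            while left > 0 and local_ancestry[h, left - 1] == target:
                left -= 1
            right = j_focal
            while right < m - 1 and local_ancestry[h, right + 1] == target:
                right += 1
            lo_bound = 0 if left == 0 else pos[left - 1]  # pos > start excludes pos[left-1]
            hi_bound = config.chrom_length_bp if right == m - 1 else pos[right + 1] - 1
            start = max(start, lo_bound, 0)
            end = min(end, hi_bound, config.chrom_length_bp)
            if end - start < 1:
                continue
            start, end = int(start), int(end)
            rows.append({"haplotype": f"hap{h}", "chrom": "1", "start": start, "end": end, "confidence": 1.0})
            inside = diagnostic & (pos > start) & (pos <= end)
            hap[h, inside] = 1

    for _ in range(n_decoys):
        if rng.random() < 0.5:
            conf, length = 0.9, rng.exponential(config.archaic_mean_tract_bp)
        else:
            conf, length = 1.0, 5_000.0
        start = rng.integers(0, max(config.chrom_length_bp - int(length) - 1, 1))
        h = int(rng.integers(0, hap.shape[0]))
        rows.append(
            {
                "haplotype": f"hap{h}",
                "chrom": "1",
                "start": int(start),
                "end": int(start + length),
                "confidence": conf,
            }
        )
    tracts = pd.DataFrame(rows, columns=["haplotype", "chrom", "start", "end", "confidence"])
    return hap, tracts, snp_table


# ---------------------------------------------------------------------------
# face cohort
# ---------------------------------------------------------------------------


def mean_symmetric_shape(sym: SymmetryMap, d: int = 2, seed: int = 12345) -> np.ndarray:
    """Deterministic non-degenerate mirror-symmetric template configuration.

    Bilateral pairs get mirrored +-x positions; midline landmarks sit on
    x = 0.  The same seed always yields the same template.
    """
    rng = np.random.default_rng(seed)
    coords = np.zeros((sym.n_landmarks, d))
    for a, b in sym.pairs:
        p = rng.uniform(0.25, 1.0, size=d)
        p[1:] = rng.uniform(-1.0, 1.0, size=d - 1)
        coords[a] = p
        coords[b] = p.copy()
        coords[b, 0] = -p[0]
    for mld in sym.midline:
        p = np.zeros(d)
        p[1:] = rng.uniform(-1.0, 1.0, size=d - 1)
        coords[mld] = p
    coords -= coords.mean(axis=0)
    coords /= np.sqrt((coords**2).sum())
    return coords


def _mirror_field(field_arr: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    out = field_arr[sym.mirror_permutation(), :].copy()
    out[:, 0] = -out[:, 0]
    return out


def _ild_displacement_field(sym: SymmetryMap, catalog_entry, mean_shape: np.ndarray) -> np.ndarray:
    """Unit displacement field that increases one catalogued ILD by 1 per
    unit amplitude, applied symmetrically (the mirror ILD moves equally)."""
    a, b = catalog_entry.pair
    axis = mean_shape[a] - mean_shape[b]
    axis = axis / np.linalg.norm(axis)
    disp = np.zeros_like(mean_shape)
    disp[a] += 0.5 * axis
    disp[b] -= 0.5 * axis
    if len(catalog_entry.orbit) > 1:
        disp = disp + _mirror_field(disp, sym)
    else:
        sym_disp = 0.5 * (disp + _mirror_field(disp, sym))
        # self-dual pairs already have a symmetric field; keep unit gain
        if np.linalg.norm(sym_disp) > 1e-12:
            disp = sym_disp * (np.linalg.norm(disp) / np.linalg.norm(sym_disp))
    return disp


def simulate_face_cohort(
    panel_or_dosages,
    config: SimConfig,
    template: SymmetryMap | None = None,
    sex_effects: dict[int, float] | None = None,
    age_effect_sd: float = 0.15,
    bmi_effect_sd: float = 0.15,
    sym_noise_sd: float = 0.01,
    asym_noise_sd: float = 0.002,
    pose_sd_deg: float = 3.0,
    pose_cap_deg: float = 10.0,
):
    """2D face landmark cohort with covariate, SNP and pose structure.

    Each individual's configuration is the symmetric mean shape plus
    sex/age/BMI displacements on selected ILD axes, additive causal-SNP
    displacements (``config.causal_effects``), symmetric individual noise,
    a smaller fluctuating-asymmetry noise, then a nuisance pose (in-plane
    roll rotation, yaw/pitch foreshortening, translation and scale).
    Returns (LandmarkSet, covariate table, true-effect table); effect
    sizes are in approximate phenotype-SD units of the target ILD.
    """
    sym = template or SymmetryMap.default_face()
    dosages = panel_or_dosages.dosages if isinstance(panel_or_dosages, DosagePanel) else np.asarray(panel_or_dosages, float)
    n = dosages.shape[0] if dosages.ndim == 2 else config.n_individuals
    rng = np.random.default_rng(config.seed + 202)
    catalog = ild_catalog(sym)
    entries = list(catalog.entries.itertuples())
    mean_shape = mean_symmetric_shape(sym, d=2)
    # one phenotype-SD of an ILD is dominated by symmetric noise on its two
    # endpoints along the pair axis: sd(ILD) ~= sqrt(2) * sym_noise_sd
    ild_sd = np.sqrt(2.0) * sym_noise_sd

    if sex_effects is None:
        sex_effects = {0: 1.0, 1: 0.6}  # a few dimorphic distances
    sex = rng.integers(0, 2, size=n)
    age = rng.normal(45.0, 12.0, size=n)
    bmi = rng.normal(26.0, 4.0, size=n)
    age_z = (age - age.mean()) / age.std()
    bmi_z = (bmi - bmi.mean()) / bmi.std()

    effect_rows = []
    fields = np.zeros((n, sym.n_landmarks, 2))
    for ild_idx, beta in sex_effects.items():
        disp = _ild_displacement_field(sym, entries[ild_idx], mean_shape)
        fields += (sex * beta * ild_sd)[:, None, None] * disp
        effect_rows.append({"source": "sex", "ild_index": ild_idx, "ild_id": entries[ild_idx].ild_id, "beta_sd": beta})
    disp_age = _ild_displacement_field(sym, entries[2 % len(entries)], mean_shape)
    fields += (age_z * age_effect_sd * ild_sd)[:, None, None] * disp_age
    effect_rows.append({"source": "age", "ild_index": 2 % len(entries), "ild_id": entries[2 % len(entries)].ild_id, "beta_sd": age_effect_sd})
    disp_bmi = _ild_displacement_field(sym, entries[3 % len(entries)], mean_shape)
    fields += (bmi_z * bmi_effect_sd * ild_sd)[:, None, None] * disp_bmi
    effect_rows.append({"source": "bmi", "ild_index": 3 % len(entries), "ild_id": entries[3 % len(entries)].ild_id, "beta_sd": bmi_effect_sd})

    for snp_idx, ild_idx, beta in config.causal_effects:
        if ild_idx >= len(entries):
            raise InvalidConfigurationError(f"ILD index {ild_idx} out of catalog range")
        disp = _ild_displacement_field(sym, entries[ild_idx], mean_shape)
        g = dosages[:, snp_idx]
        fields += ((g - g.mean()) * beta * ild_sd)[:, None, None] * disp
        effect_rows.append(
            {"source": f"snp{snp_idx}", "ild_index": ild_idx, "ild_id": entries[ild_idx].ild_id, "beta_sd": beta}
        )

    # symmetric individual variation: noise on one side + midline, mirrored
    raw = rng.normal(0.0, sym_noise_sd, size=(n, sym.n_landmarks, 2))
    sym_noise = 0.5 * (raw + np.stack([_mirror_field(r, sym) for r in raw]))
    sym_noise *= np.sqrt(2.0)  # restore per-coordinate variance after averaging
    asym_noise = rng.normal(0.0, asym_noise_sd, size=(n, sym.n_landmarks, 2))

    coords = mean_shape[None] + fields + sym_noise + asym_noise

    def truncnorm(sd, size):
        x = rng.normal(0.0, sd, size=size)
        return np.clip(x, -pose_cap_deg, pose_cap_deg)

    yaw = truncnorm(pose_sd_deg, n)
    pitch = truncnorm(pose_sd_deg, n)
    roll = truncnorm(pose_sd_deg, n)
    rad = np.deg2rad
    out = np.empty_like(coords)
    scale = np.exp(rng.normal(0.0, 0.05, size=n))
    shift = rng.normal(0.0, 0.1, size=(n, 2))
    for i in range(n):
        c = coords[i].copy()
        c[:, 0] *= np.cos(rad(yaw[i]))  # yaw foreshortens width
        c[:, 1] *= np.cos(rad(pitch[i]))  # pitch foreshortens height
        th = rad(roll[i])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        out[i] = scale[i] * (c @ rot.T) + shift[i]

    ids = [f"ind{i}" for i in range(n)]
    landmarks = LandmarkSet(ids, out)
    covariates = pd.DataFrame(
        {"sex": sex, "age": age, "bmi": bmi, "yaw": yaw, "pitch": pitch, "roll": roll},
        index=ids,
    )
    return landmarks, covariates, pd.DataFrame(effect_rows)


# ---------------------------------------------------------------------------
# 3D symmetric cohort
# ---------------------------------------------------------------------------


def _symmetric_basis(sym: SymmetryMap, d: int) -> np.ndarray:
    """Orthonormal basis (rows) of the mirror-symmetric perturbation space
    in flattened (k*d) coordinates: free coordinates are one member of each
    pair (the other mirrors it) and the in-plane coordinates of midline
    landmarks."""
    k = sym.n_landmarks
    vecs = []
    for a, b in sym.pairs:
        for ax in range(d):
            v = np.zeros((k, d))
            v[a, ax] = 1.0
            vm = _mirror_field(v, sym)
            u = (v + vm) / np.sqrt(2.0)
            vecs.append(u.ravel())
    for mld in sym.midline:
        for ax in range(1, d):
            v = np.zeros((k, d))
            v[mld, ax] = 1.0
            vecs.append(v.ravel())
    return np.asarray(vecs)


def simulate_symmetric_3d_cohort(
    n: int,
    pairs: int = 17,
    midline: int = 10,
    grm: np.ndarray | None = None,
    genetic_cov: np.ndarray | None = None,
    snp_effect: np.ndarray | None = None,
    snp_dosage: np.ndarray | None = None,
    noise_sd: float = 0.01,
    pose_cap_deg: float = 10.0,
    seed: int = 0,
) -> tuple[LandmarkSet, SymmetryMap]:
    """3D mirror-symmetric configurations with GRM-structured variation.

    Symmetric perturbations are drawn in the mirror-symmetric subspace;
    the first ``r`` directions (r = genetic_cov size) receive a genetic
    component with covariance genetic_cov x GRM plus independent residual
    noise, remaining directions independent noise only.  An optional SNP
    effect vector (length r) displaces those directions by
    ``dosage x effect``.  Nuisance rotation/translation/scale is applied
    afterwards.
    """
    sym = SymmetryMap.template(pairs, midline)
    rng = np.random.default_rng(seed)
    basis = _symmetric_basis(sym, 3)
    n_dim = basis.shape[0]
    mean_shape = mean_symmetric_shape(sym, d=3, seed=777)

    theta = rng.normal(0.0, noise_sd, size=(n, n_dim))
    if genetic_cov is not None:
        genetic_cov = np.atleast_2d(np.asarray(genetic_cov, float))
        r = genetic_cov.shape[0]
        if grm is None:
            raise InvalidConfigurationError("genetic_cov requires a GRM")
        w, v = np.linalg.eigh(np.asarray(grm, float))
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise InvalidConfigurationError("GRM must be positive semidefinite")
        l_grm = v * np.sqrt(np.clip(w, 0.0, None))
        wg, vg_ = np.linalg.eigh(genetic_cov)
        if wg.min() < -1e-10:
            raise InvalidConfigurationError("genetic_cov must be positive semidefinite")
        l_cov = vg_ * np.sqrt(np.clip(wg, 0.0, None))
        theta[:, :r] += l_grm @ rng.standard_normal((n, r)) @ l_cov.T
    if snp_effect is not None:
        snp_effect = np.asarray(snp_effect, float)
        if snp_dosage is None:
            raise InvalidConfigurationError("snp_effect requires snp_dosage")
        theta[:, : snp_effect.size] += np.outer(np.asarray(snp_dosage, float), snp_effect)

    coords = mean_shape[None] + (theta @ basis).reshape(n, sym.n_landmarks, 3)

    out = np.empty_like(coords)
    scale = np.exp(rng.normal(0.0, 0.05, size=n))
    shift = rng.normal(0.0, 0.1, size=(n, 3))
    for i in range(n):
        angles = np.deg2rad(np.clip(rng.normal(0, 3, size=3), -pose_cap_deg, pose_cap_deg))
        rx, ry, rz = angles
        rotx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
        roty = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
        rotz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
        out[i] = scale[i] * coords[i] @ (rotx @ roty @ rotz).T + shift[i]
    return LandmarkSet([f"m{i}" for i in range(n)], out), sym


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig, template: SymmetryMap | None = None, n_decoy_tracts: int = 0) -> CohortBundle:
    """Generate a complete, mutually consistent cohort bundle."""
    haplotypes, snp_table, ancestry = simulate_admixed_genotypes(config)
    haplotypes, tracts, snp_table = simulate_archaic_tracts(
        haplotypes, ancestry, snp_table, config, n_decoys=n_decoy_tracts
    )
    panel = DosagePanel(
        dosages=haplotypes[0::2].astype(float) + haplotypes[1::2].astype(float),
        snp_table=snp_table,
        ids=[f"ind{i}" for i in range(config.n_individuals)],
        haplotypes=haplotypes,
        ancestry=ancestry,
        ancestry_labels=config.ancestry_labels,
    )
    template = template or SymmetryMap.default_face()
    landmarks, covariates, effects = simulate_face_cohort(panel, config, template)
    return CohortBundle(
        panel=panel,
        tracts=tracts,
        landmarks=landmarks,
        covariates=covariates,
        true_effects=effects,
        template=template,
        config=config,
    )
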