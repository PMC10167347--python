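"""Landmark morphometrics with object symmetry.

This module covers the phenotyping side of a landmark-based morphology GWAS:

* quality control of head pose and per-trait outliers,
* generalized Procrustes analysis (GPA), plain or with *object symmetry*
  (the bilateral symmetry of a single structure, handled by reflecting each
  configuration, relabeling paired landmarks, and superimposing originals
  and mirror copies jointly),
* decomposition of each aligned shape into a symmetric component (average
  of original and aligned mirror copy) and an asymmetric component
  (half-difference),
* construction of the deduplicated inter-landmark distance (ILD) phenotype
  matrix: because distances are measured on symmetrized shapes, the
  distance for a landmark pair equals the distance for its mirror-image
  pair, and only one representative per reflection orbit is retained.

Distances are in Procrustes units (configurations scaled to unit centroid
size).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateConfigurationError(ValueError):
    """A landmark configuration has zero centroid size or non-finite values."""


class SchemaError(KeyError):
    """A required column is missing from an input table."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymmetryMap:
    """Bilateral pair / midline structure of a landmark template.

    Parameters
    ----------
    n_landmarks:
        Total number of landmarks ``k``.
    pairs:
        ``(left, right)`` index pairs of bilaterally homologous landmarks.
    midline:
        Indices of landmarks on the midsagittal plane (mapped to themselves
        by the mirror relabeling).
    """

    n_landmarks: int
    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs))
        object.__setattr__(self, "midline", tuple(int(i) for i in self.midline))
        used = [i for p in self.pairs for i in p] + list(self.midline)
        if sorted(used) != list(range(self.n_landmarks)):
            raise ValueError(
                "pairs and midline must partition 0..k-1 with no repeats "
                f"(k={self.n_landmarks}, got indices {sorted(used)})"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_midline(self) -> int:
        return len(self.midline)

    def mirror_permutation(self) -> np.ndarray:
        """Permutation sigma with sigma[left]=right, sigma[right]=left,
        sigma[m]=m on the midline."""
        sigma = np.arange(self.n_landmarks)
        for a, b in self.pairs:
            sigma[a], sigma[b] = b, a
        return sigma

    @classmethod
    def template(cls, n_pairs: int, n_midline: int) -> "SymmetryMap":
        """Canonical template: pairs (0,1),(2,3),... then midline indices."""
        pairs = tuple((2 * i, 2 * i + 1) for i in range(n_pairs))
        midline = tuple(range(2 * n_pairs, 2 * n_pairs + n_midline))
        return cls(2 * n_pairs + n_midline, pairs, midline)

    @classmethod
    def default_face(cls) -> "SymmetryMap":
        """34-landmark frontal-face template: 13 bilateral pairs + 8 midline."""
        return cls.template(13, 8)

    @classmethod
    def default_skull(cls) -> "SymmetryMap":
        """44-landmark 3D skull template: 17 bilateral pairs + 10 midline."""
        return cls.template(17, 10)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_landmarks": self.n_landmarks,
                "pairs": [list(p) for p in self.pairs],
                "midline": list(self.midline),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SymmetryMap":
        d = json.loads(text)
        return cls(d["n_landmarks"], tuple(map(tuple, d["pairs"])), tuple(d["midline"]))


@dataclass
class LandmarkSet:
    """Per-individual landmark configurations.

    coords has shape (n_individuals, k, d) with d in {2, 3};
    centroid_size is filled by GPA (sizes before unit scaling).
    """

    ids: list[str]
    coords: np.ndarray
    centroid_size: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be (n, k, d)")
        if not np.all(np.isfinite(self.coords)):
            raise DegenerateConfigurationError("non-finite landmark coordinates")
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("ids length must match coords")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def d(self) -> int:
        return self.coords.shape[2]


@dataclass
class ProcrustesFit:
    """Result of (object-symmetric) generalized Procrustes analysis."""

    aligned: LandmarkSet
    mean_shape: np.ndarray
    iterations: int
    converged: bool
    symmetric: LandmarkSet | None = None
    asymmetric: np.ndarray | None = None
    sym: SymmetryMap | None = None


@dataclass
class ILDCatalog:
    """Catalog of deduplicated inter-landmark distances.

    entries: one row per retained ILD with its D-label, canonical landmark
    pair, and the members of its reflection orbit (the duplicate class).
    """

    entries: pd.DataFrame
    n_total_pairs: int
    n_duplicates_removed: int
    n_retained: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "entries": self.entries.to_dict(orient="records"),
                "n_total_pairs": self.n_total_pairs,
                "n_duplicates_removed": self.n_duplicates_removed,
                "n_retained": self.n_retained,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ILDCatalog":
        d = json.loads(text)
        ent = pd.DataFrame(d["entries"])
        ent["pair"] = ent["pair"].apply(tuple)
        ent["orbit"] = ent["orbit"].apply(lambda o: [tuple(p) for p in o])
        return cls(ent, d["n_total_pairs"], d["n_duplicates_removed"], d["n_retained"])


@dataclass
class ILDMatrix:
    """Individuals x retained-ILD distance matrix (Procrustes units)."""

    values: pd.DataFrame  # index = individual ids, columns = D-labels
    catalog: ILDCatalog


# ---------------------------------------------------------------------------
# Procrustes machinery
# ---------------------------------------------------------------------------


def centroid_size(coords: np.ndarray) -> np.ndarray:
    """Square root of summed squared distances of landmarks to their centroid.

    Works on a single (k, d) configuration or a stack (n, k, d).
    """
    x = np.asarray(coords, float)
    single = x.ndim == 2
    if single:
        x = x[None]
    c = x - x.mean(axis=1, keepdims=True)
    cs = np.sqrt((c**2).sum(axis=(1, 2)))
    return cs[0] if single else cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimizing ||x @ R - target||_F."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _mirror(coords: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    """Reflect the first coordinate axis and swap paired landmark labels.

    An involution: applying it twice returns the input.
    """
    out = coords[..., sym.mirror_permutation(), :].copy()
    out[..., 0] = -out[..., 0]
    return out


def gpa(
    landmarks: LandmarkSet,
    tol: float = 1e-10,
    max_iter: int = 100,
    _sym_mean: SymmetryMap | None = None,
) -> ProcrustesFit:
    """Generalized Procrustes analysis.

    Each configuration is centered, scaled to unit centroid size, and
    rotated to the current mean shape (optimal rotation from the SVD of the
    cross-covariance, with the determinant corrected so reflections are
    never used); the mean is re-estimated until it changes by less than
    ``tol`` or ``max_iter`` is reached.  Original centroid sizes are kept.

    ``_sym_mean`` is used internally by :func:`gpa_object_symmetry`: the
    mean shape is symmetrized each iteration, which makes the alignment
    commute exactly with the reflect-and-relabel operation.
    """
    x = np.asarray(landmarks.coords, float)
    if x.shape[0] < 1:
        raise ValueError("need at least one configuration")
    x = x - x.mean(axis=1, keepdims=True)
    cs = np.sqrt((x**2).sum(axis=(1, 2)))
    if np.any(cs <= 0):
        raise DegenerateConfigurationError("configuration with zero centroid size")
    x = x / cs[:, None, None]

    def symmetrize(m):
        if _sym_mean is None:
            return m
        return 0.5 * (m + _mirror(m, _sym_mean))

    mean = symmetrize(x[0].copy())
    mean /= np.linalg.norm(mean)
    iterations = 0
    converged = x.shape[0] == 1
    for iterations in range(1, max_iter + 1):
        for i in range(x.shape[0]):
            x[i] = x[i] @ _optimal_rotation(x[i], mean)
        new_mean = symmetrize(x.mean(axis=0))
        new_mean /= np.linalg.norm(new_mean)
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        delta = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if delta < tol:
            converged = True
            break
    # final pass so every configuration is optimally rotated to the final mean
    for i in range(x.shape[0]):
        x[i] = x[i] @ _optimal_rotation(x[i], mean)

    aligned = LandmarkSet(list(landmarks.ids), x, centroid_size=cs)
    return ProcrustesFit(aligned=aligned, mean_shape=mean, iterations=iterations, converged=converged)


def gpa_object_symmetry(landmarks: LandmarkSet, sym: SymmetryMap) -> ProcrustesFit:
    """GPA with object symmetry (reflect, relabel, joint superimposition).

    The mirror copy of each configuration (first axis negated, paired
    landmarks swapped) is added to the sample; the doubled sample is
    superimposed with a symmetrized mean shape; the symmetric component of
    each individual is the average of its aligned original and aligned
    mirror copy, and the asymmetric component the half-difference.  Because
    the mean is symmetrized each iteration, the symmetric component is
    exactly invariant under reflect-and-relabel.

    Works for 2D and 3D configurations.
    """
    if sym.n_landmarks != landmarks.k:
        raise ValueError("symmetry map does not match landmark count")
    n = landmarks.n
    doubled = np.concatenate([landmarks.coords, _mirror(landmarks.coords, sym)], axis=0)
    dset = LandmarkSet([f"{i}" for i in landmarks.ids] + [f"{i}|mirror" for i in landmarks.ids], doubled)
    fit = gpa(dset, _sym_mean=sym)
    a = fit.aligned.coords
    # with a symmetrized mean, aligning the mirror copy commutes with
    # mirroring, so aligned[n+i] == mirror(aligned[i]) and the plain average
    # is the symmetric component; the explicit re-symmetrization below only
    # removes floating-point residue so invariance holds exactly.
    symm = 0.5 * (a[:n] + a[n:])
    symm = 0.5 * (symm + _mirror(symm, sym))
    asymm = a[:n] - symm
    aligned = LandmarkSet(list(landmarks.ids), a[:n], centroid_size=fit.aligned.centroid_size[:n])
    symmetric = LandmarkSet(list(landmarks.ids), symm, centroid_size=fit.aligned.centroid_size[:n])
    return ProcrustesFit(
        aligned=aligned,
        mean_shape=fit.mean_shape,
        iterations=fit.iterations,
        converged=fit.converged,
        symmetric=symmetric,
        asymmetric=asymm,
        sym=sym,
    )


def symmetric_dim(sym: SymmetryMap, d: int) -> int:
    """Expected non-null dimension of the symmetric shape space.

    For p bilateral pairs and m midline landmarks the symmetric component
    lives in a linear space of dimension 3p + 2m (3D; midline points are
    confined to the symmetry plane) or 2p + m (2D), from which superimposition
    removes translations within the plane of symmetry, scale, and the
    rotations that preserve symmetry: d=3 -> 3p + 2m - 4; d=2 -> 2p + m - 2.
    """
    p, m = sym.n_pairs, sym.n_midline
    if d == 3:
        return 3 * p + 2 * m - 4
    if d == 2:
        return 2 * p + m - 2
    raise ValueError("d must be 2 or 3")


# ---------------------------------------------------------------------------
# ILD catalog and matrix
# ---------------------------------------------------------------------------


def ild_catalog(sym: SymmetryMap) -> ILDCatalog:
    """Enumerate unordered landmark pairs and deduplicate by reflection orbit.

    Two pairs are duplicates iff one is the image of the other under the
    mirror relabeling; distances computed on symmetrized shapes are then
    identical.  One canonical representative is kept per orbit (the
    lexicographically smallest pair), and D-labels are assigned in catalog
    order.
    """
    k = sym.n_landmarks
    if k < 2:
        raise ValueError("need at least two landmarks")
    sigma = sym.mirror_permutation()
    seen: set[tuple[int, int]] = set()
    entries = []
    n_total = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        pair = (i, j)
        if pair in seen:
            continue
        mirrored = tuple(sorted((int(sigma[i]), int(sigma[j]))))
        orbit = [pair] if mirrored == pair else sorted([pair, mirrored])
        seen.update(orbit)
        entries.append({"pair": orbit[0], "orbit": orbit})
    ent = pd.DataFrame(entries)
    ent.insert(0, "ild_id", [f"D{i + 1}" for i in range(len(ent))])
    n_ret = len(ent)
    return ILDCatalog(
        entries=ent,
        n_total_pairs=n_total,
        n_duplicates_removed=n_total - n_ret,
        n_retained=n_ret,
    )


def compute_ilds(fit: ProcrustesFit, catalog: ILDCatalog, check_tol: float = 1e-10) -> ILDMatrix:
    """Euclidean distances between canonical landmark pairs on the symmetric
    component.

    Before dropping the duplicate member of each reflection orbit, its
    distance is verified equal to the canonical member's (<= check_tol).
    """
    if fit.symmetric is None:
        raise ValueError("fit has no symmetric component; run gpa_object_symmetry")
    coords = fit.symmetric.coords
    k = coords.shape[1]
    for e in catalog.entries.itertuples():
        if max(max(p) for p in e.orbit) >= k:
            raise ValueError("catalog landmark indices exceed configuration size")

    def dist(pair):
        a, b = pair
        return np.linalg.norm(coords[:, a, :] - coords[:, b, :], axis=1)

    cols = {}
    for e in catalog.entries.itertuples():
        v = dist(e.pair)
        for other in e.orbit[1:]:
            if np.max(np.abs(dist(other) - v)) > check_tol:
                raise AssertionError(
                    f"duplicate-class members {e.pair} and {other} disagree beyond {check_tol}"
                )
        cols[e.ild_id] = v
    values = pd.DataFrame(cols, index=list(fit.symmetric.ids))
    return ILDMatrix(values=values, catalog=catalog)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

ANGLE_COLUMNS = ("yaw", "pitch", "roll")


def qc_head_pose(
    covariates: pd.DataFrame,
    mad_factor: float = 4.0,
    abs_cap_deg: float = 15.0,
) -> pd.Series:
    """Keep-mask flagging extreme head pose.

    An individual is excluded when, for any of yaw/pitch/roll (degrees),
    |angle - median| > mad_factor * MAD (normal-consistent MAD) or
    |angle| > abs_cap_deg.
    """
    for col in ANGLE_COLUMNS:
        if col not in covariates.columns:
            raise SchemaError(f"missing head-angle column {col!r}")
    keep = pd.Series(True, index=covariates.index)
    for col in ANGLE_COLUMNS:
        a = covariates[col].to_numpy(float)
        med = np.median(a)
        mad = stats.median_abs_deviation(a, scale="normal")
        bad = np.abs(a) > abs_cap_deg
        if mad > 0:
            bad |= np.abs(a - med) > mad_factor * mad
        keep &= ~bad
    return keep


def qc_trait_outliers(ilds: ILDMatrix, sex: pd.Series, n_sd: float = 3.0) -> pd.DataFrame:
    """Per-trait keep-mask excluding values outside the sex-stratum mean +- 3 SD.

    The mean and SD are computed within each sex stratum in a single pass
    (no iterative re-trimming).  Strata with fewer than two individuals are
    skipped with a warning.
    """
    import warnings

    sex = sex.reindex(ilds.values.index)
    levels = pd.unique(sex.dropna())
    if len(levels) > 2:
        raise ValueError("sex must be binary-coded")
    keep = pd.DataFrame(True, index=ilds.values.index, columns=ilds.values.columns)
    for lev in levels:
        idx = sex == lev
        if idx.sum() < 2:
            warnings.warn(f"sex stratum {lev!r} has <2 individuals; skipped")
            continue
        block = ilds.values.loc[idx]
        mu, sd = block.mean(axis=0), block.std(axis=0, ddof=1)
        bad = (block - mu).abs() > n_sd * sd
        bad &= sd > 0  # constant traits exclude nothing
        keep.loc[idx] = ~bad
    return keep


# ---------------------------------------------------------------------------
# landmark-protocol agreement and covariate screening
# ---------------------------------------------------------------------------


def _icc_a1(x: np.ndarray, y: np.ndarray) -> float:
    # ICC(A,1): two-way random effects, absolute agreement, single rater
    n = x.shape[0]
    data = np.stack([x, y], axis=1)  # n targets x 2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        return np.nan
    return (msr - mse) / denom


def landmark_agreement(a: LandmarkSet, b: LandmarkSet) -> pd.DataFrame:
    """Per-landmark agreement between two landmarking protocols.

    Returns one row per landmark with the mean-over-axes two-way agreement
    ICC of the coordinates and the median over individuals of the
    per-landmark Euclidean distance (same units as the input, e.g. pixels).
    """
    if list(a.ids) != list(b.ids):
        raise ValueError("landmark sets must cover the same individuals in the same order")
    if a.k != b.k or a.d != b.d:
        raise ValueError("landmark sets must share landmark count and dimension")
    rows = []
    for j in range(a.k):
        iccs = [_icc_a1(a.coords[:, j, ax], b.coords[:, j, ax]) for ax in range(a.d)]
        dist = np.linalg.norm(a.coords[:, j, :] - b.coords[:, j, :], axis=1)
        rows.append({"landmark": j, "icc": float(np.nanmean(iccs)), "median_distance": float(np.median(dist))})
    return pd.DataFrame(rows)


def covariate_correlation(ilds: ILDMatrix, covariates: pd.DataFrame, sex_col: str = "sex") -> pd.DataFrame:
    """Trait-covariate screening table.

    Point-biserial correlation for sex; Spearman's rho for every other
    (numeric) covariate.  Two-sided p-values; constant traits yield NA rows.
    """
    cov = covariates.reindex(ilds.values.index)
    rows = []
    for trait in ilds.values.columns:
        y = ilds.values[trait].to_numpy(float)
        y_const = np.std(y) == 0
        for c in cov.columns:
            x = cov[c].to_numpy(float)
            if y_const or np.std(x) == 0:
                rows.append({"trait": trait, "covariate": c, "method": "NA", "statistic": np.nan, "p": np.nan})
                continue
            if c == sex_col:
                r, p = stats.pointbiserialr(x, y)
                rows.append({"trait": trait, "covariate": c, "method": "pointbiserial", "statistic": r, "p": p})
            else:
                r, p = stats.spearmanr(x, y)
                rows.append({"trait": trait, "covariate": c, "method": "spearman", "statistic": r, "p": p})
    return pd.DataFrame(rows)
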