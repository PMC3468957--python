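"""Filtering, significance and reporting layer.

The statistical policy applied to parallel-ICA output: Bonferroni
critical correlation over the component-pair family, z > 1.96 display
thresholding of z-scaled loading maps, minimum cluster extent in mm^3,
head-motion magnitude, and assembly of the per-network report records
(one row per significantly correlated component pair, with signed
suprathreshold clusters and behavioral entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .group import GroupDecomposition
from .parallel import ParaIcaConfig, ParaIcaResult, para_ica_fit, repeat_consistency

__all__ = [
    "fuse_network_behavior",
    "ClusterRecord",
    "SignificancePolicy",
    "zscore_columns",
    "choose_k_by_variance",
    "bonferroni_r_threshold",
    "min_cluster_voxels",
    "mask_network",
    "extract_clusters",
    "motion_summary",
    "build_report",
]


def zscore_columns(matrix: np.ndarray) -> np.ndarray:
    """Z-score each column (mean 0, population SD 1)."""
    X = np.asarray(matrix, dtype=float)
    sd = X.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance column(s): {bad.tolist()}")
    return (X - X.mean(axis=0)) / sd


def choose_k_by_variance(X: np.ndarray, target_fraction: float = 0.90) -> int:
    """Smallest k whose top-k eigenvalue share reaches ``target_fraction``.

    The eigen-spectrum is taken over the smaller data dimension, so the
    answer is orientation-free.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if X.shape[0] <= X.shape[1]:
        Xc = X - X.mean(axis=1, keepdims=True)
        C = Xc @ Xc.T
    else:
        Xc = X - X.mean(axis=0, keepdims=True)
        C = Xc.T @ Xc
    evals = np.sort(np.clip(np.linalg.eigvalsh(C), 0, None))[::-1]
    if evals.sum() <= 0:
        # centering removed everything (e.g. rank-one data): one axis
        # trivially explains all remaining variance
        return 1
    shares = np.cumsum(evals) / evals.sum()
    return int(np.searchsorted(shares, target_fraction - 1e-12) + 1)


def bonferroni_r_threshold(n_samples: int, n_tests: int, alpha: float = 0.05) -> float:
    """Critical |r| whose two-tailed p equals ``alpha / n_tests``.

    Uses the exact t-transform t = r sqrt(n-2) / sqrt(1-r^2) with
    df = n_samples - 2; the reporting rule keeps only component pairs
    whose absolute loading correlation exceeds this value.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    df = n_samples - 2
    t = stats.t.isf(alpha / n_tests / 2.0, df)
    return float(t / np.sqrt(t * t + df))


@dataclass
class SignificancePolicy:
    """Family-wise reporting policy for loading-pair correlations."""

    n_samples: int
    n_tests: int
    alpha: float = 0.05
    z_display: float = 1.96
    r_crit: float = field(init=False)

    def __post_init__(self) -> None:
        self.r_crit = bonferroni_r_threshold(self.n_samples, self.n_tests, self.alpha)


def min_cluster_voxels(min_volume_mm3: float = 100.0, voxel_size_mm: float = 3.0) -> int:
    """Smallest contiguous voxel count strictly exceeding a volume.

    At 3 mm isotropic voxels (27 mm^3 each), exceeding 100 mm^3 takes
    four contiguous voxels (108 mm^3).
    """
    vox_mm3 = voxel_size_mm**3
    return int(np.floor(min_volume_mm3 / vox_mm3)) + 1


def mask_network(z_map: np.ndarray, z_thr: float = 1.96) -> np.ndarray:
    """Boolean mask of voxels with z above threshold; errors when empty."""
    m = np.asarray(z_map, dtype=float) > z_thr
    if not m.any():
        raise ValueError(f"no voxels exceed z={z_thr}: empty network mask")
    return m


@dataclass
class ClusterRecord:
    """One suprathreshold cluster of a z-scaled loading map."""

    network: int
    sign: str                       # "+" or "-"
    voxel_count: int
    volume_mm3: float
    peak_index: tuple[int, int, int]
    peak_coordinate: tuple[float, float, float]
    peak_z: float
    voxel_indices: np.ndarray = None  # type: ignore[assignment]  # flat grid indices


def extract_clusters(
    z_map: np.ndarray,
    affine: np.ndarray,
    z_thr: float = 1.96,
    min_voxels: int = 4,
    connectivity: int = 1,
    network: int = 0,
) -> list[ClusterRecord]:
    """Signed connected components of ``|z| > z_thr``.

    Positive and negative loadings are clustered separately (a report row
    carries "+" and "-" sub-component areas).  ``connectivity=1`` is
    face adjacency.  The peak is the max-|z| voxel; its world coordinate
    comes from the affine.
    """
    z = np.asarray(z_map, dtype=float)
    if z.ndim != 3:
        raise ValueError("z_map must be 3-D")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
        raise ValueError("a finite 4x4 affine is required")
    vox_mm3 = float(abs(np.linalg.det(affine[:3, :3])))
    structure = ndimage.generate_binary_structure(3, connectivity)

    records: list[ClusterRecord] = []
    for sign, mask in (("+", z > z_thr), ("-", z < -z_thr)):
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            idx = np.nonzero(labels == lab)
            count = idx[0].size
            if count < min_voxels:
                continue
            vals = z[idx]
            peak_pos = int(np.argmax(np.abs(vals)))
            pk = (int(idx[0][peak_pos]), int(idx[1][peak_pos]), int(idx[2][peak_pos]))
            world = affine @ np.array([*pk, 1.0])
            records.append(
                ClusterRecord(
                    network=network,
                    sign=sign,
                    voxel_count=int(count),
                    volume_mm3=count * vox_mm3,
                    peak_index=pk,
                    peak_coordinate=tuple(float(v) for v in world[:3]),
                    peak_z=float(vals[peak_pos]),
                    voxel_indices=np.ravel_multi_index(idx, z.shape),
                )
            )
    records.sort(key=lambda r: -r.voxel_count)
    return records


def motion_summary(params: np.ndarray) -> np.ndarray:
    """Per-timepoint head-motion magnitude.

    The square root of the sum of squares of the first differences of the
    six rigid-body motion parameters: output length is T - 1.
    """
    P = np.asarray(params, dtype=float)
    if P.ndim != 2 or P.shape[1] != 6:
        raise ValueError("expected a T x 6 motion-parameter matrix")
    if P.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    d = np.diff(P, axis=0)
    return np.sqrt(np.sum(d**2, axis=1))


def fuse_network_behavior(
    decomposition: GroupDecomposition,
    component: int,
    behavior: np.ndarray,
    behavior_labels: list[str],
    grid: tuple[int, int, int],
    affine: np.ndarray,
    config: ParaIcaConfig | None = None,
    mask_thr: float = 1.96,
    seed: int = 0,
    n_repeats: int = 1,
    alpha: float = 0.05,
    min_voxels: int = 4,
):
    """Parallel-ICA fusion of one network's subject maps with behavior.

    The network's group map is masked at ``mask_thr``; each subject's
    back-reconstructed map restricted to that mask forms one row of the
    spatial matrix.  Both the spatial matrix and the behavioral table are
    column z-scored, decomposed with correlation-constrained parallel
    ICA (optionally over several repeats with a consensus pick), and the
    suprathreshold pairs are filtered by the Bonferroni policy and
    clustered.

    Returns ``(ParaIcaResult, list[ReportRecord], mask)``.
    """
    config = config or ParaIcaConfig()
    mask = mask_network(decomposition.group_maps[component], mask_thr)
    # each subject's back-reconstructed map is z-scored as a whole (scale
    # comparability across modalities) and only then restricted to the
    # network mask; z-scoring within the mask would tie the normalisation
    # to the very signal under study, and per-voxel scaling would equalise
    # pure-noise voxels with signal voxels
    full = np.stack([sm[component] for sm in decomposition.subject_maps])
    full = (full - full.mean(axis=1, keepdims=True)) / full.std(axis=1, keepdims=True)
    X1 = full[:, mask]
    X2 = zscore_columns(np.asarray(behavior, dtype=float))

    n_subj = X1.shape[0]
    k1 = min(config.k1, n_subj - 2)
    k2 = min(config.k2, X2.shape[1], n_subj - 2)
    if (k1, k2) != (config.k1, config.k2):
        from dataclasses import replace

        config = replace(config, k1=k1, k2=k2)

    if n_repeats > 1:
        seeds = [np.random.SeedSequence([seed, rep]) for rep in range(n_repeats)]
        result, _ = repeat_consistency(X1, X2, config, seeds=seeds)
    else:
        result = para_ica_fit(X1, X2, config, seed=seed)

    policy = SignificancePolicy(n_samples=n_subj, n_tests=k1 * k2, alpha=alpha)
    records = build_report(
        result,
        policy,
        grid,
        affine,
        behavior_labels,
        voxel_mask=mask,
        min_voxels=min_voxels,
        network=component,
    )
    return result, records, mask


@dataclass
class ReportRecord:
    """One Table-style row: a significantly correlated component pair."""

    network: int
    comp_spatial: int
    comp_behavioral: int
    r: float
    significant: bool
    clusters_pos: list[ClusterRecord]
    clusters_neg: list[ClusterRecord]
    behaviors: list[tuple[str, float]]   # (label, signed z) with |z| > display thr


def build_report(
    result: ParaIcaResult,
    policy: SignificancePolicy,
    grid: tuple[int, int, int],
    affine: np.ndarray,
    behavior_labels: list[str],
    voxel_mask: np.ndarray | None = None,
    z_thr: float | None = None,
    min_voxels: int = 4,
    network: int = 0,
) -> list[ReportRecord]:
    """Assemble report rows for every pair exceeding the critical |r|.

    For each significant link, the spatial component's z-scaled source
    map is clustered at the display threshold (signed, face-connected,
    minimum extent), and behavioral measures with |z| above the display
    threshold are listed with their signed z-scaled loadings.
    """
    z_thr = policy.z_display if z_thr is None else z_thr
    records: list[ReportRecord] = []
    S1 = result.result1.sources
    S2 = result.result2.sources
    if len(behavior_labels) != S2.shape[1]:
        raise ValueError("behavior label count does not match the behavioral features")

    for link in result.links:
        if abs(link.r) < policy.r_crit:
            continue
        smap = S1[link.comp1]
        # robust display scaling: a component map is heavy-tailed by
        # construction (its focus inflates a plain SD and suppresses the
        # very voxels of interest), so the z-scale comes from the median
        # and the normal-consistent MAD of the map
        smap_z = (smap - np.median(smap)) / stats.median_abs_deviation(
            smap, scale="normal"
        )
        vol = np.zeros(int(np.prod(grid)))
        if voxel_mask is not None:
            vol[np.asarray(voxel_mask).ravel()] = smap_z
        else:
            vol[:] = smap_z
        clusters = extract_clusters(
            vol.reshape(grid), affine, z_thr=z_thr, min_voxels=min_voxels, network=network
        )
        if not clusters:
            # a pair is reported only when its spatial map carries at
            # least one suprathreshold cluster of the minimum extent;
            # diffuse maps with no compact focus are not interpretable
            # sub-components and stay out of the table
            continue
        bmap = S2[link.comp2]
        bmap_z = (bmap - bmap.mean()) / bmap.std()
        behaviors = [
            (behavior_labels[i], float(bmap_z[i]))
            for i in np.nonzero(np.abs(bmap_z) > z_thr)[0]
        ]
        records.append(
            ReportRecord(
                network=network,
                comp_spatial=link.comp1,
                comp_behavioral=link.comp2,
                r=float(link.r),
                significant=True,
                clusters_pos=[c for c in clusters if c.sign == "+"],
                clusters_neg=[c for c in clusters if c.sign == "-"],
                behaviors=behaviors,
            )
        )
    return records
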