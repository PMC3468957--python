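"""Synthetic data generators.

Two generators make every pipeline stage testable offline:

* :func:`generate_linked_dataset` — the unbalanced-dimension validation
  setup: two sample-aligned matrices (default 100 x 10,000 and 100 x 5,
  with 8 and 4 super-Gaussian components) whose loading columns carry
  planted cross-modal correlations serving as ground truth.

* :func:`generate_phantom_study` — a miniature resting-state "study":
  per-subject 4-D volumes on a small 3 mm grid built from spatial network
  maps times smooth time-courses, plus a subjects x measures behavioral
  table seeded from a published battery of reaction-time/accuracy/span
  measures.  One network carries an extra spatial blob whose per-subject
  amplitude covaries with a weighted behavioral combination at a planted
  correlation.

Randomness: one master seed, split into independent child streams per
ingredient (sources, loadings, noise, behavior), so outputs are
bit-reproducible and individual ingredients stay stable under spec edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinkedSimulationSpec",
    "SimulationTruth",
    "PairedDataset",
    "PhantomStudySpec",
    "PhantomTruth",
    "generate_linked_dataset",
    "generate_phantom_study",
    "BEHAVIORAL_BATTERY",
    "behavior_column_names",
]

# Published battery means and standard errors (n = 24): task, measure,
# mean, SEM.  RT in ms, accuracy as proportion, spans as raw scores.
BEHAVIORAL_BATTERY: list[tuple[str, str, float, float]] = [
    ("verbal_wm", "rt", 1045.13, 50.77),
    ("verbal_wm", "accuracy", 0.98, 0.01),
    ("spatial_wm", "rt", 1124.37, 43.8),
    ("spatial_wm", "accuracy", 0.93, 0.01),
    ("unbound_wm", "rt", 1298.54, 47.55),
    ("unbound_wm", "accuracy", 0.93, 0.02),
    ("bound_wm", "rt", 1284.0, 50.45),
    ("bound_wm", "accuracy", 0.96, 0.01),
    ("bound_wm_congruent", "rt", 1263.57, 56.75),
    ("bound_wm_congruent", "accuracy", 0.95, 0.01),
    ("bound_wm_incongruent", "rt", 1406.05, 57.48),
    ("bound_wm_incongruent", "accuracy", 0.91, 0.02),
    ("digit_span", "forward", 11.5, 0.5),
    ("digit_span", "backward", 9.21, 0.74),
    ("digit_span", "total", 20.29, 0.96),
    ("spatial_span", "forward", 9.38, 0.36),
    ("spatial_span", "backward", 9.42, 0.36),
    ("spatial_span", "total", 18.79, 0.52),
    ("dsst", "items_per_sec", 0.74, 0.03),
    ("finger_tap", "rt", 386.98, 22.60),
    ("finger_tap", "rate", 2.86, 0.21),
    ("flanker", "rt", 502.07, 9.82),
    ("flanker", "accuracy", 0.98, 0.004),
    ("flanker_congruent", "rt", 478.63, 10.09),
    ("flanker_congruent", "accuracy", 0.99, 0.004),
    ("flanker_incongruent", "rt", 521.6, 11.67),
    ("flanker_incongruent", "accuracy", 0.97, 0.01),
    ("flanker_neutral", "rt", 499.43, 11.53),
    ("flanker_neutral", "accuracy", 0.99, 0.004),
    ("stroop", "rt", 844.84, 24.52),
    ("stroop", "accuracy", 0.97, 0.01),
    ("stroop_congruent", "rt", 826.45, 23.45),
    ("stroop_congruent", "accuracy", 0.99, 0.01),
    ("stroop_incongruent", "rt", 863.92, 26.75),
    ("stroop_incongruent", "accuracy", 0.95, 0.01),
    ("ravens_apm", "items", 27.38, 0.77),
]
# demographic columns appended to reach the full 39-column matrix:
# age (years), gender coded +-1, handedness coded -1/0/+1
_DEMOGRAPHICS = [("demo", "age", 25.0, 0.67), ("demo", "gender", 0.0, 0.0), ("demo", "handedness", 0.0, 0.0)]


def behavior_column_names() -> list[str]:
    return [f"{task}_{measure}" for task, measure, _, _ in BEHAVIORAL_BATTERY + _DEMOGRAPHICS]


@dataclass
class LinkedSimulationSpec:
    """Conditions of the unbalanced-dimension validation.

    Defaults reproduce the study design: 100 samples; modality 1 spans
    10,000 features with 8 components (simulated fMRI), modality 2 spans
    5 features with 4 components (simulated behavior).  ``links`` is a
    list of (comp1, comp2, rho) triples planting loading correlations.
    ``noise_sd`` of ~0.45 corresponds to a per-component SNR of about 5.
    """

    n_samples: int = 100
    n_feat1: int = 10_000
    n_feat2: int = 5
    k1: int = 8
    k2: int = 4
    links: list[tuple[int, int, float]] = field(default_factory=list)
    source_kurtosis: bool = True
    noise_sd: float = 0.45

    def validate(self) -> None:
        if self.k1 > self.n_feat1 or self.k2 > self.n_feat2:
            raise ValueError("component count exceeds feature count")
        if self.k1 > self.n_samples or self.k2 > self.n_samples:
            raise ValueError("component count exceeds sample count")
        if len(self.links) > min(self.k1, self.k2):
            raise ValueError(f"at most {min(self.k1, self.k2)} links allowed")
        seen1, seen2 = set(), set()
        for i, j, rho in self.links:
            if not (0 <= i < self.k1 and 0 <= j < self.k2):
                raise ValueError(f"link indices ({i}, {j}) out of range")
            if i in seen1 or j in seen2:
                raise ValueError("link indices must be unique per modality")
            seen1.add(i)
            seen2.add(j)
            if abs(rho) > 1:
                raise ValueError(f"|rho| must be <= 1, got {rho}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SimulationTruth:
    true_sources_1: np.ndarray
    true_sources_2: np.ndarray
    true_loadings_1: np.ndarray
    true_loadings_2: np.ndarray
    link_corrs: list[tuple[int, int, float]]


@dataclass
class PairedDataset:
    """Two sample-aligned matrices, the parallel-ICA input."""

    X1: np.ndarray
    X2: np.ndarray
    links: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.X1.shape[0]


def _laplace_sources(rng: np.random.Generator, k: int, n: int) -> np.ndarray:
    """Row-standardised Laplacian sources (positive excess kurtosis)."""
    S = rng.laplace(size=(k, n))
    return (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)


def _zscore_cols(M: np.ndarray) -> np.ndarray:
    return (M - M.mean(axis=0)) / M.std(axis=0)


def generate_linked_dataset(
    spec: LinkedSimulationSpec, seed: int
) -> tuple[PairedDataset, SimulationTruth]:
    """Build ``X_m = L_m @ S_m + noise`` with planted loading correlations.

    Linked loading-column pairs are drawn by the Gaussian-copula
    construction ``a2 = rho * a1 + sqrt(1 - rho^2) * eps`` followed by
    column z-scoring, so the target correlation holds in expectation;
    unlinked columns are independent.
    """
    spec.validate()
    s_src1, s_src2, s_load, s_noise = np.random.SeedSequence(seed).spawn(4)

    S1 = _laplace_sources(np.random.default_rng(s_src1), spec.k1, spec.n_feat1)
    S2 = _laplace_sources(np.random.default_rng(s_src2), spec.k2, spec.n_feat2)
    if not spec.source_kurtosis:
        g1 = np.random.default_rng(s_src1).standard_normal((spec.k1, spec.n_feat1))
        g2 = np.random.default_rng(s_src2).standard_normal((spec.k2, spec.n_feat2))
        S1 = (g1 - g1.mean(1, keepdims=True)) / g1.std(1, keepdims=True)
        S2 = (g2 - g2.mean(1, keepdims=True)) / g2.std(1, keepdims=True)

    rng_l = np.random.default_rng(s_load)
    L1 = _zscore_cols(rng_l.standard_normal((spec.n_samples, spec.k1)))
    L2 = _zscore_cols(rng_l.standard_normal((spec.n_samples, spec.k2)))
    for i, j, rho in spec.links:
        eps = rng_l.standard_normal(spec.n_samples)
        L2[:, j] = rho * L1[:, i] + np.sqrt(1.0 - rho**2) * eps
    L2 = _zscore_cols(L2)

    rng_n = np.random.default_rng(s_noise)
    X1 = L1 @ S1 + spec.noise_sd * rng_n.standard_normal((spec.n_samples, spec.n_feat1))
    X2 = L2 @ S2 + spec.noise_sd * rng_n.standard_normal((spec.n_samples, spec.n_feat2))

    realized = [
        (i, j, float(np.corrcoef(L1[:, i], L2[:, j])[0, 1])) for i, j, _ in spec.links
    ]
    truth = SimulationTruth(S1, S2, L1, L2, realized)
    return PairedDataset(X1, X2, links=realized), truth


@dataclass
class PhantomStudySpec:
    """Conditions of the phantom resting-state study.

    Defaults mirror the emulated acquisition: 24 subjects, 228 retained
    time points at TR = 2.6 s on a small 3 mm isotropic grid, and a
    39-column behavioral table.  ``planted_link`` = (network index, blob
    center voxel, blob radius in voxels, behavior weight vector or None
    for the latent speed factor, rho).
    """

    n_subjects: int = 24
    grid: tuple[int, int, int] = (20, 20, 20)
    n_timepoints: int = 228
    n_networks: int = 4
    n_behaviors: int = 39
    tr: float = 2.6
    planted_rho: float = 0.85
    planted_network: int = 0
    blob_radius: float = 2.0
    blob_center: tuple[int, int, int] | None = None
    # the sub-component is present in every subject (base amplitude, part
    # of the mean network) and modulated across subjects (gain = SD of the
    # modulation); a zero-mean blob would split off as its own network
    blob_base: float = 1.0
    blob_gain: float = 0.5
    network_amplitude: float = 1.0
    noise_sd: float = 0.5
    seed_from_battery: bool = True
    voxel_size_mm: float = 3.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects (correlation undefined for 1)")
        if min(self.grid) < 2 * int(np.ceil(self.blob_radius)) + 2:
            raise ValueError("grid too small to contain the planted blob")
        if abs(self.planted_rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if not 0 <= self.planted_network < self.n_networks:
            raise ValueError("planted network index out of range")
        if self.seed_from_battery and self.n_behaviors != 39:
            raise ValueError("battery seeding defines exactly 39 columns")


@dataclass
class PhantomTruth:
    network_maps: np.ndarray            # n_networks x voxels (flattened grid)
    blob_map: np.ndarray                # voxels, the planted sub-component
    blob_mask: np.ndarray               # boolean voxels
    subject_amplitudes: np.ndarray      # n_subjects
    behavior_score: np.ndarray          # n_subjects latent combination
    realized_rho: float
    affine: np.ndarray
    grid: tuple[int, int, int]


def _gaussian_blob(grid, center, radius) -> np.ndarray:
    zz = np.stack(np.meshgrid(*[np.arange(g) for g in grid], indexing="ij"))
    d2 = sum((zz[a] - center[a]) ** 2 for a in range(3))
    return np.exp(-d2 / (2.0 * radius**2))


def _smooth_timecourses(rng, n_tc, n_t) -> np.ndarray:
    """Slow AR(1) (phi = 0.9) signals, z-scored: low-frequency dominated."""
    tc = np.empty((n_tc, n_t))
    e = rng.standard_normal((n_tc, n_t))
    tc[:, 0] = e[:, 0]
    for t in range(1, n_t):
        tc[:, t] = 0.9 * tc[:, t - 1] + np.sqrt(1 - 0.81) * e[:, t]
    return (tc - tc.mean(1, keepdims=True)) / tc.std(1, keepdims=True)


def _behavior_table(spec: PhantomStudySpec, rng: np.random.Generator):
    """39-column table with block-correlated RT/accuracy/capacity structure.

    Latent subject factors (speed, accuracy, capacity) are Laplacian so a
    linear ICA of the table is identifiable.  Each numeric column is an
    exact-moment rescaling (sample mean = published mean, sample SD =
    SEM * sqrt(n)) of a factor-plus-noise score; RT columns load on the
    speed factor, accuracy columns (negatively) on the accuracy factor,
    span/reasoning columns on the capacity factor.
    """
    n = spec.n_subjects
    lat = rng.laplace(size=(3, n))
    lat = (lat - lat.mean(1, keepdims=True)) / lat.std(1, keepdims=True)
    speed, acc, cap = lat
    loading = 0.75

    cols, names = [], []
    for task, measure, mean, sem in BEHAVIORAL_BATTERY:
        if measure == "rt":
            factor = speed
        elif measure == "accuracy":
            factor = -acc
        elif measure in ("rate", "items_per_sec"):
            factor = -speed
        else:  # spans, items: capacity
            factor = cap
        z = loading * factor + np.sqrt(1 - loading**2) * rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)
        sd = sem * np.sqrt(n)
        cols.append(mean + sd * z)
        names.append(f"{task}_{measure}")

    age = 25.0 + 0.67 * np.sqrt(n) * rng.standard_normal(n)
    gender = rng.choice([-1.0, 1.0], size=n)
    handed = rng.choice([-1.0, 0.0, 1.0], size=n, p=[0.05, 0.12, 0.83])
    for name, col in (("demo_age", age), ("demo_gender", gender), ("demo_handedness", handed)):
        cols.append(col)
        names.append(name)

    table = pd.DataFrame(np.column_stack(cols), columns=names)
    return table, speed


def generate_phantom_study(
    spec: PhantomStudySpec, seed: int
) -> tuple[list[np.ndarray], pd.DataFrame, PhantomTruth]:
    """Generate subject 4-D volumes, a behavioral table, and the truth.

    Each subject's volume is a sum of network maps times smooth
    time-courses plus Gaussian noise; the planted network additionally
    carries ``amp_s * blob`` where the per-subject amplitude ``amp_s``
    correlates with the latent behavioral speed factor at ``planted_rho``.

    Returns volumes as 4-D arrays (x, y, z, t) on a 3 mm isotropic grid.
    """
    spec.validate()
    s_maps, s_beh, s_amp, s_tc, s_noise = np.random.SeedSequence(seed).spawn(5)
    grid = spec.grid
    n_vox = int(np.prod(grid))

    # network maps: one Gaussian blob each, centred on jittered octant
    # anchors so the networks are well separated on any grid size
    rng_m = np.random.default_rng(s_maps)
    lo = int(np.ceil(spec.blob_radius)) + 1
    anchors = [
        np.array([gx, gy, gz])
        for gx in (0.30, 0.70)
        for gy in (0.30, 0.70)
        for gz in (0.30, 0.70)
    ]
    if spec.n_networks > len(anchors):
        raise ValueError(f"at most {len(anchors)} networks supported")
    order = rng_m.permutation(len(anchors))[: spec.n_networks]
    centers = []
    maps = np.zeros((spec.n_networks, n_vox))
    for knet, a in enumerate(order):
        c = np.rint(anchors[a] * (np.array(grid) - 1)).astype(int)
        c = np.clip(c + rng_m.integers(-1, 2, size=3), lo, np.array(grid) - lo - 1)
        centers.append(tuple(int(v) for v in c))
        maps[knet] = _gaussian_blob(grid, c, 1.8 * spec.blob_radius).ravel()

    # planted sub-component blob: offset within the planted network's vicinity
    if spec.blob_center is None:
        base = np.array(centers[spec.planted_network])
        # offset by one radius: the blob core stays inside the parent
        # network's suprathreshold extent, as a sub-component must
        off = np.array([int(round(spec.blob_radius)), 0, 0])
        bc = np.clip(base + off, lo, np.array(grid) - lo - 1)
    else:
        bc = np.asarray(spec.blob_center)
        if np.any(bc < lo) or np.any(bc > np.array(grid) - lo - 1):
            raise ValueError("blob_center too close to the grid edge for the radius")
    blob = _gaussian_blob(grid, bc, spec.blob_radius).ravel()
    blob_mask = blob > np.exp(-0.5)  # within one radius of the center

    table, speed = _behavior_table(spec, np.random.default_rng(s_beh))

    rng_a = np.random.default_rng(s_amp)
    rho = spec.planted_rho
    eps = rng_a.laplace(size=spec.n_subjects)
    eps = (eps - eps.mean()) / eps.std()
    amp = rho * speed + np.sqrt(1 - rho**2) * eps
    realized = float(np.corrcoef(amp, speed)[0, 1]) if spec.n_subjects > 2 else rho

    rng_tc = np.random.default_rng(s_tc)
    rng_n = np.random.default_rng(s_noise)
    volumes = []
    for s in range(spec.n_subjects):
        tcs = _smooth_timecourses(rng_tc, spec.n_networks, spec.n_timepoints)
        net = maps.copy()
        net[spec.planted_network] = (
            net[spec.planted_network] + (spec.blob_base + spec.blob_gain * amp[s]) * blob
        )
        data = spec.network_amplitude * (tcs.T @ net)  # time x voxels
        data += spec.noise_sd * rng_n.standard_normal(data.shape)
        volumes.append(
            np.ascontiguousarray(data.T.reshape(grid + (spec.n_timepoints,)))
        )

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -spec.voxel_size_mm * (np.array(grid) - 1) / 2.0
    truth = PhantomTruth(
        network_maps=maps,
        blob_map=blob,
        blob_mask=blob_mask,
        subject_amplitudes=amp,
        behavior_score=speed,
        realized_rho=realized,
        affine=affine,
        grid=grid,
    )
    return volumes, table, truth
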