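"""Temporal-concatenation group ICA and network identification.

Subject time x voxel matrices are each PCA-reduced in time, stacked, and
reduced again at the group level before Infomax.  Subject-specific maps
and time-courses are recovered with the GICA3 back-reconstruction, whose
defining property — the mean of the subject maps equals the group map —
holds here exactly by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .ica import InfomaxParams, Whitening, infomax, pca_reduce

__all__ = [
    "GroupDecomposition",
    "TemplateMatch",
    "SpectralMetrics",
    "group_ica_fit",
    "template_match",
    "spectral_metrics",
]


@dataclass
class GroupDecomposition:
    """Group ICA fit with subject-level back-reconstruction.

    ``group_maps`` (k x voxels) are z-scored per map; ``subject_maps``
    (one k x voxels array per subject) are scaled by the same per-map
    affine so their subject-mean reproduces ``group_maps`` exactly.
    """

    group_maps: np.ndarray
    subject_maps: list[np.ndarray]
    subject_timecourses: list[np.ndarray]
    subject_reducers: list[Whitening]
    group_reducer: Whitening
    k: int
    unmixing: np.ndarray
    map_mean: np.ndarray
    map_sd: np.ndarray


def group_ica_fit(
    subjects: list[np.ndarray],
    k_subject: int,
    k_group: int,
    seed: int | np.random.SeedSequence = 0,
    params: InfomaxParams | None = None,
) -> GroupDecomposition:
    """Two-stage PCA + Infomax over temporally concatenated subjects.

    Parameters
    ----------
    subjects : list of time x voxel matrices on a shared voxel grid/mask.
    k_subject : per-subject PCA dimension (>= k_group use is typical).
    k_group : number of group components (40 in whole-brain use).
    """
    if not subjects:
        raise ValueError("no subject data supplied")
    n_vox = subjects[0].shape[1]
    for idx, X in enumerate(subjects):
        if X.ndim != 2 or X.shape[1] != n_vox:
            raise ValueError(
                f"subject {idx} has voxel dimension {X.shape[1:]} inconsistent with {n_vox}"
            )
    n_subj = len(subjects)
    if k_group > n_subj * k_subject:
        raise ValueError("k_group exceeds concatenated subject dimension")

    reducers: list[Whitening] = []
    reduced: list[np.ndarray] = []
    for X in subjects:
        wh, Y = pca_reduce(np.asarray(X, dtype=float), k_subject)
        reducers.append(wh)
        reduced.append(Y)

    Y = np.vstack(reduced)                       # (n_subj * k_subject) x voxels
    gw, Z = pca_reduce(Y, k_group)
    res = infomax(Z, params=params, seed=seed, whitening=gw)

    W = res.unmixing
    S = res.sources                              # k x voxels == W @ Z
    # GICA3: with G the group reducing matrix split into per-subject
    # column blocks G_i, S == sum_i W G_i Y_i_centered, so the subject map
    # S_i = n_subj * W G_i (Y_i - mu_i) averages exactly to S.
    mu = gw.mean_vector
    subject_maps = []
    subject_tcs = []
    WG = W @ gw.reducing                         # k x (n_subj*k_subject)
    Gdw = gw.dewhitening                         # (n_subj*k_subject) x k
    A_w = np.linalg.inv(W)
    for i in range(n_subj):
        sl = slice(i * k_subject, (i + 1) * k_subject)
        Yc = reduced[i] - mu[sl][:, None]
        subject_maps.append(n_subj * (WG[:, sl] @ Yc))
        # time-courses: X_i ~ D_i Gdw_i A_w S  =>  TC_i = D_i Gdw_i A_w
        subject_tcs.append(reducers[i].dewhitening @ Gdw[sl] @ A_w)

    map_mean = S.mean(axis=1)
    map_sd = S.std(axis=1)
    if np.any(map_sd == 0):
        raise ValueError("degenerate constant group map")
    group_maps = (S - map_mean[:, None]) / map_sd[:, None]
    subject_maps = [(Si - map_mean[:, None]) / map_sd[:, None] for Si in subject_maps]

    return GroupDecomposition(
        group_maps=group_maps,
        subject_maps=subject_maps,
        subject_timecourses=subject_tcs,
        subject_reducers=reducers,
        group_reducer=gw,
        k=k_group,
        unmixing=W,
        map_mean=map_mean,
        map_sd=map_sd,
    )


@dataclass
class TemplateMatch:
    component: int
    template: int
    r: float
    matched: bool


def template_match(
    group_maps: np.ndarray,
    templates: np.ndarray,
    z_thr: float = 3.0,
    template_thr: float | None = None,
    r_min: float = 0.4,
    mask: np.ndarray | None = None,
) -> list[TemplateMatch]:
    """Pair each template with its best-correlating component.

    Both maps and templates are thresholded (values below threshold set
    to zero — the thresholds live on each input's own statistic scale)
    and Pearson-correlated over the in-mask voxels.  A template whose
    best r falls below ``r_min``, or whose thresholded pattern is empty,
    is flagged unmatched.
    """
    G = np.asarray(group_maps, dtype=float)
    T = np.asarray(templates, dtype=float)
    if G.shape[-1] != T.shape[-1]:
        raise ValueError("maps and templates must share the voxel grid")
    if mask is not None:
        G = G[:, mask.ravel().astype(bool)]
        T = T[:, mask.ravel().astype(bool)]
    if template_thr is None:
        template_thr = z_thr

    Gt = np.where(G >= z_thr, G, 0.0)
    Tt = np.where(T >= template_thr, T, 0.0)

    out: list[TemplateMatch] = []
    for j in range(Tt.shape[0]):
        t = Tt[j]
        best_r, best_c = np.nan, -1
        if t.std() == 0:
            warnings.warn(f"template {j} empty after thresholding; unmatched")
            out.append(TemplateMatch(component=-1, template=j, r=np.nan, matched=False))
            continue
        for c in range(Gt.shape[0]):
            g = Gt[c]
            if g.std() == 0:
                continue
            r = float(np.corrcoef(g, t)[0, 1])
            if not np.isnan(r) and (best_c < 0 or r > best_r):
                best_r, best_c = r, c
        if best_c < 0:
            warnings.warn("all component maps empty after thresholding")
            out.append(TemplateMatch(component=-1, template=j, r=np.nan, matched=False))
        else:
            out.append(
                TemplateMatch(component=best_c, template=j, r=best_r, matched=bool(best_r >= r_min))
            )
    return out


@dataclass
class SpectralMetrics:
    """Spectral summaries of a component time-course.

    ``dynamic_range`` — peak power minus the minimum power at frequencies
    above the peak (a power difference; the frequency at which the peak
    occurs is reported separately as ``peak_frequency``).
    ``power_ratio`` — integrated power below 0.10 Hz over integrated
    power in the 0.15–0.25 Hz band (upper band truncated at Nyquist).
    """

    dynamic_range: float
    power_ratio: float
    peak_frequency: float


def spectral_metrics(
    timecourse: np.ndarray,
    tr: float,
    low_cut: float = 0.10,
    high_band: tuple[float, float] = (0.15, 0.25),
) -> SpectralMetrics:
    """Welch-spectrum dynamic range and low/high power ratio."""
    x = np.asarray(timecourse, dtype=float).ravel()
    if x.size < 32:
        raise ValueError("time-course too short (need >= 32 samples)")
    if tr <= 0:
        raise ValueError("TR must be positive")
    if np.ptp(x) == 0:
        raise ValueError("constant time-course: spectrum degenerate")

    fs = 1.0 / tr
    f, p = signal.welch(x, fs=fs, nperseg=min(x.size, 128), detrend="constant")
    # drop the DC bin; mean removal leaves it meaningless
    f, p = f[1:], p[1:]

    ipeak = int(np.argmax(p))
    above = p[ipeak:]
    dynamic_range = float(p[ipeak] - above.min())

    lo_band = (f > 0) & (f <= low_cut)
    hi_lo, hi_hi = high_band
    hi_hi = min(hi_hi, f[-1])
    hi_band = (f >= hi_lo) & (f <= hi_hi)
    if not lo_band.any() or not hi_band.any():
        raise ValueError("frequency grid does not cover the requested bands")
    low_power = float(np.trapezoid(p[lo_band], f[lo_band]))
    high_power = float(np.trapezoid(p[hi_band], f[hi_band]))
    if high_power == 0:
        raise ValueError("no power in the high band")
    return SpectralMetrics(
        dynamic_range=dynamic_range,
        power_ratio=low_power / high_power,
        peak_frequency=float(f[ipeak]),
    )
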