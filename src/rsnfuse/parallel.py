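"""Correlation-constrained parallel ICA.

Two Infomax decompositions — one per data modality, on sample-aligned
matrices — run simultaneously.  After each pair of natural-gradient
steps, the per-sample loading columns of the two mixing matrices are
correlated; up to ``max_pairs`` component pairs whose absolute loading
correlation exceeds ``r_th`` are selected one-to-one, and the mixing
columns of the selected pairs are nudged along the gradient of the
squared loading correlation, coupling the two unmixing matrices.  With
the constraint never firing the procedure is, bit for bit, two
independent ICAs.

Three controls govern the coupling: the *constrained connection*
threshold ``r_th`` (default 0.3), the *constrained components* cap
``max_pairs`` (default 3), and *endurance* (default -1e-3), the maximally
allowed descending trend of entropy — once a modality's entropy trend
falls below it, constraint updates cease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ica import IcaResult, InfomaxParams, Whitening, _finalize, _InfomaxState, match_components, pca_reduce

__all__ = [
    "ParaIcaConfig",
    "PairLink",
    "ParaIcaResult",
    "para_ica_fit",
    "select_constrained_pairs",
    "repeat_consistency",
]


@dataclass
class ParaIcaConfig:
    r_th: float = 0.3
    max_pairs: int = 3
    endurance: float = -1e-3
    k1: int = 10
    k2: int = 10
    learning_rate: float = 0.1
    constraint_rate: float = 0.12
    # optional per-firing-iteration decay of the constraint step
    # (1.0 = constant coupling weight, the default schedule)
    constraint_anneal: float = 1.0
    max_iter: int = 512
    tol: float = 1e-6
    n_repeats: int = 20
    endurance_window: int = 5
    # weight-change level at which a decomposition counts as past its
    # rapid initial descent; the coupling phase begins only once both
    # modalities are below it, so pair selection sees meaningful loadings
    activation_change: float = 1e-2

    def validate(self) -> None:
        if self.r_th <= 0:
            raise ValueError("r_th must be positive (values > 1 disable the constraint)")
        if self.max_pairs < 0:
            raise ValueError("max_pairs must be >= 0")
        if self.endurance >= 0:
            raise ValueError("endurance must be negative")

    def infomax_params(self) -> InfomaxParams:
        return InfomaxParams(learning_rate=self.learning_rate, max_iter=self.max_iter, tol=self.tol)


@dataclass
class PairLink:
    comp1: int
    comp2: int
    r: float
    significant: bool = False


@dataclass
class ParaIcaResult:
    result1: IcaResult
    result2: IcaResult
    loadings_z1: np.ndarray
    loadings_z2: np.ndarray
    links: list[PairLink]
    constraint_fire_count: int
    whitening1: Whitening = None  # type: ignore[assignment]
    whitening2: Whitening = None  # type: ignore[assignment]


def _corr_matrix(A1: np.ndarray, A2: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations, k1 x k2."""
    if np.any(A1.std(axis=0) == 0) or np.any(A2.std(axis=0) == 0):
        raise ValueError("zero-variance loading column")
    Z1 = (A1 - A1.mean(0)) / A1.std(0)
    Z2 = (A2 - A2.mean(0)) / A2.std(0)
    return Z1.T @ Z2 / A1.shape[0]


def select_constrained_pairs(
    A1: np.ndarray,
    A2: np.ndarray,
    r_th: float = 0.3,
    max_pairs: int = 3,
    method: str = "exact",
) -> list[PairLink]:
    """Best one-to-one suprathreshold loading pairs.

    With ``method="exact"`` (how reported links are computed), a
    branch-and-bound search over candidate pairs with ``|r| > r_th``
    finds the one-to-one assignment of up to ``max_pairs`` pairs
    maximising the summed absolute correlation.  ``method="greedy"``
    (used inside the fit loop, where the selection runs every iteration)
    repeatedly takes the strongest remaining candidate.  Ties break
    toward lower (comp1, comp2) indices either way.
    """
    A1 = np.asarray(A1, dtype=float)
    A2 = np.asarray(A2, dtype=float)
    if A1.shape[0] != A2.shape[0]:
        raise ValueError("loading matrices must have equal sample counts")
    R = _corr_matrix(A1, A2)
    cand = [
        (i, j, float(R[i, j]))
        for i in range(R.shape[0])
        for j in range(R.shape[1])
        if abs(R[i, j]) > r_th
    ]
    if not cand or max_pairs == 0:
        return []
    # sort for deterministic tie-breaking: by |r| desc then index asc
    cand.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))

    if method == "greedy":
        rows: set[int] = set()
        cols: set[int] = set()
        picked: list[PairLink] = []
        for i, j, r in cand:
            if i in rows or j in cols:
                continue
            picked.append(PairLink(comp1=i, comp2=j, r=r))
            rows.add(i)
            cols.add(j)
            if len(picked) == max_pairs:
                break
        return picked
    if method != "exact":
        raise ValueError(f"unknown selection method {method!r}")
    absr = [abs(c[2]) for c in cand]
    # suffix prefix-sums bound: best achievable from position p with s slots
    n_cand = len(cand)

    best_score = 0.0
    best_combo: tuple = ()

    def search(pos: int, chosen: tuple, score: float, rows: frozenset, cols: frozenset) -> None:
        nonlocal best_score, best_combo
        if score > best_score + 1e-15:
            best_score, best_combo = score, chosen
        if len(chosen) == max_pairs or pos >= n_cand:
            return
        slots = max_pairs - len(chosen)
        bound = score + sum(absr[pos : pos + slots])
        if bound <= best_score + 1e-15:
            return
        for p in range(pos, n_cand):
            i, j, r = cand[p]
            if i in rows or j in cols:
                continue
            # re-check the bound at this position before descending
            if score + sum(absr[p : p + slots]) <= best_score + 1e-15:
                return
            search(p + 1, chosen + ((i, j, r),), score + abs(r), rows | {i}, cols | {j})

    search(0, (), 0.0, frozenset(), frozenset())
    return [PairLink(comp1=i, comp2=j, r=r) for i, j, r in best_combo]


def _constraint_step(
    M: np.ndarray, D: np.ndarray, col: int, a_other: np.ndarray, rate: float
) -> None:
    """Gradient-ascent step on corr^2 w.r.t. one mixing column, in place.

    The loading column is ``a = D @ M[:, col]``; with ``b`` the partner
    modality's loading column, d(r^2)/dm = 2 r D^T dr/da.
    """
    a = D @ M[:, col]
    ac = a - a.mean()
    bc = a_other - a_other.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        return
    r = float(ac @ bc / (na * nb))
    grad_a = bc / (na * nb) - r * ac / na**2
    M[:, col] += rate * 2.0 * r * (D.T @ grad_a)


def para_ica_fit(
    X1: np.ndarray,
    X2: np.ndarray,
    config: ParaIcaConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ParaIcaResult:
    """Fit correlation-constrained parallel ICA on two aligned matrices.

    ``X1``/``X2`` are samples x features (columns expected z-scored).
    Each modality is PCA-whitened to ``k1``/``k2`` axes over the sample
    dimension, then the two Infomax engines advance in lock-step with the
    constraint phase between steps.  Deterministic for a given seed.
    """
    config = config or ParaIcaConfig()
    config.validate()
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape[0] != X2.shape[0]:
        raise ValueError("modalities must share the sample dimension")

    wh1, Z1 = pca_reduce(X1, config.k1)
    wh2, Z2 = pca_reduce(X2, config.k2)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    c1, c2 = ss.spawn(2)
    p = config.infomax_params()
    st1 = _InfomaxState(config.k1, p, np.random.default_rng(c1))
    st2 = _InfomaxState(config.k2, p, np.random.default_rng(c2))

    D1, D2 = wh1.dewhitening, wh2.dewhitening
    fire_count = 0
    w = config.endurance_window
    # per-modality coupling steps: a modality whose rotation is pinned
    # down by many feature realisations (small rotational uncertainty,
    # ~1/n_features) receives a proportionally smaller cross-modal nudge;
    # the scaling equalises the coupling-to-anchoring ratio across the
    # (typically very unbalanced) modalities
    c_rate = config.constraint_rate
    # the per-iteration step is additionally capped so a near-balanced
    # modality (features ~ components) cannot receive a destabilising step
    scale1 = min(0.05 / max(c_rate, 1e-12), min(1.0, config.k1 / X1.shape[1]) ** 2)
    scale2 = min(0.05 / max(c_rate, 1e-12), min(1.0, config.k2 / X2.shape[1]) ** 2)

    # phase 1: each modality's ICA runs to its natural solution (or the
    # iteration cap); with the constraint disabled this is the entire fit,
    # bit for bit identical to two standalone decompositions
    st1.run(Z1)
    st2.run(Z2)

    sticky_pairs: list[tuple[int, int]] | None = None
    if config.max_pairs > 0 and config.r_th <= 1.0:
        # pairs are selected once, on the natural (unconstrained) loading
        # correlations, and then held: re-selecting during the coupling
        # would let pairs the coupling itself inflated displace the
        # genuinely correlated ones from the cap
        A1 = D1 @ np.linalg.inv(st1.W)
        A2 = D2 @ np.linalg.inv(st2.W)
        cand = select_constrained_pairs(
            A1, A2, config.r_th, config.max_pairs, method="greedy"
        )
        if cand:
            sticky_pairs = [(l.comp1, l.comp2) for l in cand]

    # phase 2: coupled refinement of the selected pairs, interleaved with
    # further ICA polishing
    if sticky_pairs:
        for _ in range(config.max_iter):
            if not st1.converged:
                st1.step(Z1)
            if not st2.converged:
                st2.step(Z2)
            if c_rate < 1e-3 * config.constraint_rate:
                if st1.converged and st2.converged:
                    break
                continue

            # endurance, per modality: each decomposition defends its own
            # entropy — while a modality's entropy trend descends faster
            # than allowed, its side of the coupled update pauses, so the
            # constraint cannot drag a well-determined decomposition away
            # from its ICA optimum (the other, weakly anchored side may
            # keep aligning)
            active = []
            for st in (st1, st2):
                tr = st.entropy_trace
                ok = True
                if len(tr) > w:
                    trend = (tr[-1] - tr[-1 - w]) / w
                    ok = trend >= config.endurance
                active.append(ok)

            fired = False
            if any(active):
                M1 = np.linalg.inv(st1.W)
                M2 = np.linalg.inv(st2.W)
                A1 = D1 @ M1
                A2 = D2 @ M2
                R = _corr_matrix(A1, A2)
                # a held pair that falls back below threshold drops out
                pairs = [
                    PairLink(comp1=i, comp2=j, r=float(R[i, j]))
                    for i, j in sticky_pairs
                    if abs(R[i, j]) > config.r_th
                ]
                if pairs:
                    fire_count += 1
                    fired = True
                    for link in pairs:
                        b = A2[:, link.comp2].copy()
                        a = A1[:, link.comp1].copy()
                        if active[0]:
                            _constraint_step(M1, D1, link.comp1, b, c_rate * scale1)
                        if active[1]:
                            _constraint_step(M2, D2, link.comp2, a, c_rate * scale2)
                    c_rate *= config.constraint_anneal
                    if active[0]:
                        st1.W = np.linalg.inv(M1)
                        st1.converged = False
                    if active[1]:
                        st2.W = np.linalg.inv(M2)
                        st2.converged = False

            if st1.converged and st2.converged and not fired:
                break

    res1 = _finalize(st1.W, Z1, wh1, st1.converged, st1.n_iter, st1.entropy_trace)
    res2 = _finalize(st2.W, Z2, wh2, st2.converged, st2.n_iter, st2.entropy_trace)

    A1, A2 = res1.loadings, res2.loadings
    z1 = (A1 - A1.mean(0)) / A1.std(0)
    z2 = (A2 - A2.mean(0)) / A2.std(0)
    links = (
        select_constrained_pairs(A1, A2, config.r_th, config.max_pairs)
        if config.r_th <= 1.0
        else []
    )
    return ParaIcaResult(
        result1=res1,
        result2=res2,
        loadings_z1=z1,
        loadings_z2=z2,
        links=links,
        constraint_fire_count=fire_count,
        whitening1=wh1,
        whitening2=wh2,
    )


def repeat_consistency(
    X1: np.ndarray,
    X2: np.ndarray,
    config: ParaIcaConfig | None = None,
    seeds: list[int | np.random.SeedSequence] | None = None,
) -> tuple[ParaIcaResult, list[dict]]:
    """Run the fit over several seeds and report the consensus.

    Repeats are aligned with :func:`rsnfuse.ica.match_components` on the
    modality-1 sources; the consensus is the repeat with the highest mean
    pairwise similarity to the others.  Each repeat contributes one row
    per link with its correlation, plus a reproducibility fraction per
    consensus link (how often an aligned repeat shows the same pairing).
    """
    config = config or ParaIcaConfig()
    if seeds is None:
        seeds = list(range(config.n_repeats))
    if len(seeds) < 2:
        raise ValueError("need at least 2 repeats")

    fits = [para_ica_fit(X1, X2, config, seed=s) for s in seeds]
    n = len(fits)
    sim = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            _, _, r = match_components(fits[a].result1.sources, fits[b].result1.sources)
            sim[a, b] = sim[b, a] = float(r.mean())
    consensus_idx = int(np.argmax(sim.sum(axis=1)))
    consensus = fits[consensus_idx]

    table: list[dict] = []
    link_hits = {(l.comp1, l.comp2): 0 for l in consensus.links}
    for idx, fit in enumerate(fits):
        perm1, _, _ = match_components(fit.result1.sources, consensus.result1.sources)
        perm2, _, _ = match_components(fit.result2.sources, consensus.result2.sources)
        inv1 = np.argsort(perm1)
        inv2 = np.argsort(perm2)
        for link in fit.links:
            mapped = (int(inv1[link.comp1]), int(inv2[link.comp2]))
            table.append(
                {
                    "repeat": idx,
                    "seed": seeds[idx],
                    "comp1": mapped[0],
                    "comp2": mapped[1],
                    "r": link.r,
                    "is_consensus_repeat": idx == consensus_idx,
                }
            )
            if mapped in link_hits:
                link_hits[mapped] += 1
    for row in table:
        key = (row["comp1"], row["comp2"])
        row["reproducibility"] = link_hits.get(key, 0) / n
    return consensus, table
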