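"""Recombination fractions, marker ordering and multipoint genetic maps.

Model
-----
Each F2 autosome carries two independent recombinant gametes from
heterozygous AZ/UT F1 parents, so the hidden state at a marker is the
ordered pair of gamete origins (4 states); the observed genotype is the AZ
dosage with a symmetric mis-genotyping probability ``error_prob``. The X is
a single maternally recombined gamete (2 states): the paternal X is a
constitutively UT, non-recombined copy, so female AB calls imply a maternal
AZ allele and BB a maternal UT allele, while hemizygous males are read
directly from their homozygous-looking calls. Transition probabilities
between adjacent markers follow per-gamete recombination fractions, updated
by EM (forward-backward); fractions convert to cM through a map function
(Haldane by default, matching the no-interference simulation; Kosambi
available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from neoxqtl.containers import AA, AB, BB, NA, GeneticMap, GenotypeMatrix, LinkageGroup

log = logging.getLogger(__name__)

MIN_RF, MAX_RF = 1e-9, 0.49999


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------
def haldane_rf_to_cm(r: np.ndarray | float) -> np.ndarray | float:
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


def haldane_cm_to_rf(d: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 - np.exp(-np.asarray(d, dtype=float) / 50.0))


def kosambi_rf_to_cm(r: np.ndarray | float) -> np.ndarray | float:
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_cm_to_rf(d: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * np.tanh(np.asarray(d, dtype=float) / 50.0)


MAP_FUNCTIONS = {
    "haldane": (haldane_rf_to_cm, haldane_cm_to_rf),
    "kosambi": (kosambi_rf_to_cm, kosambi_cm_to_rf),
}


@dataclass(frozen=True)
class RfEstimate:
    rf: float
    lod: float


# ---------------------------------------------------------------------------
# cross-design X recoding
# ---------------------------------------------------------------------------
def maternal_x_origins(calls: np.ndarray, sexes: np.ndarray) -> np.ndarray:
    """Maternal-gamete origin per X call: 1 = AZ, 0 = UT, -1 = unresolved.

    Males: AA -> AZ, BB -> UT (hemizygous, read directly); AB impossible.
    Females: AB -> AZ, BB -> UT; AA (two AZ X's) impossible.
    """
    calls = np.asarray(calls)
    male = np.asarray(sexes) == "M"
    out = np.full(calls.shape, -1, dtype=np.int8)
    out[(calls == BB)] = 0
    if calls.ndim == 1:
        out[male & (calls == AA)] = 1
        out[~male & (calls == AB)] = 1
    else:
        out[:, male] = np.where(calls[:, male] == AA, 1, out[:, male])
        out[:, ~male] = np.where(calls[:, ~male] == AB, 1, out[:, ~male])
    return out


# ---------------------------------------------------------------------------
# two-point recombination fractions (EM on count tables)
# ---------------------------------------------------------------------------
def _aa_masks() -> tuple[np.ndarray, np.ndarray]:
    """Cell-membership masks and gamete-switch counts over (m1,m2,p1,p2)."""
    m1, m2, p1, p2 = np.meshgrid(*([np.arange(2)] * 4), indexing="ij")
    mask = np.zeros((3, 3, 2, 2, 2, 2))
    for d1 in range(3):
        for d2 in range(3):
            mask[d1, d2] = ((m1 + p1) == d1) & ((m2 + p2) == d2)
    switches = (m1 != m2).astype(float) + (p1 != p2).astype(float)
    return mask, switches


_AA_MASK, _AA_SWITCH = _aa_masks()


def _q(r: np.ndarray) -> np.ndarray:
    """Two-locus gamete-origin distribution, shape (..., 2, 2)."""
    r = np.asarray(r, dtype=float)
    q = np.empty(r.shape + (2, 2))
    q[..., 0, 0] = q[..., 1, 1] = (1.0 - r) / 2.0
    q[..., 0, 1] = q[..., 1, 0] = r / 2.0
    return q


def _aa_cell_probs(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P(d1,d2|r) and E[switches * P] per cell; shapes (..., 3, 3)."""
    q = _q(r)
    prior = np.einsum("...ab,...cd->...abcd", q, q)
    t = np.einsum("...abcd,ijabcd->...ij", prior, _AA_MASK)
    w = np.einsum("...abcd,abcd,ijabcd->...ij", prior, _AA_SWITCH, _AA_MASK)
    return t, w


def _em_rf_aa(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 2000) -> np.ndarray:
    """Vectorized EM over stacked 3x3 genotype-pair count tables (..., 3, 3)."""
    counts = np.asarray(counts, dtype=float)
    n_gam = 2.0 * counts.sum(axis=(-2, -1))
    r = np.full(counts.shape[:-2], 0.25)
    for _ in range(max_iter):
        t, w = _aa_cell_probs(r)
        with np.errstate(divide="ignore", invalid="ignore"):
            e_rec = np.where(t > 0, w / t, 0.0)
        r_new = np.clip(
            (counts * e_rec).sum(axis=(-2, -1)) / np.maximum(n_gam, 1.0), MIN_RF, 0.5
        )
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    return np.minimum(r, 0.5)


def _loglik_aa(counts: np.ndarray, r: np.ndarray) -> np.ndarray:
    t, _ = _aa_cell_probs(r)
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log10(np.maximum(t, 1e-300)), -300.0)
    return (counts * logt).sum(axis=(-2, -1))


def _ax_tables(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P(d1, o2 | r) and switch-weighted mass for autosome-X pairs."""
    q = _q(r)  # (..., m1, o2)
    t = np.zeros(r.shape + (3, 2))
    w = np.zeros(r.shape + (3, 2))
    for d1 in range(3):
        for o2 in range(2):
            for m1 in range(2):
                if 0 <= d1 - m1 <= 1:
                    t[..., d1, o2] += q[..., m1, o2] * 0.5
                    if m1 != o2:
                        w[..., d1, o2] += q[..., m1, o2] * 0.5
    return t, w


def _em_rf_ax(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 2000) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-2, -1))
    r = np.full(counts.shape[:-2], 0.25)
    for _ in range(max_iter):
        t, w = _ax_tables(r)
        with np.errstate(divide="ignore", invalid="ignore"):
            e_rec = np.where(t > 0, w / t, 0.0)
        r_new = np.clip((counts * e_rec).sum(axis=(-2, -1)) / np.maximum(n, 1.0), MIN_RF, 0.5)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    return r


def _loglik_ax(counts: np.ndarray, r: np.ndarray) -> np.ndarray:
    t, _ = _ax_tables(r)
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log10(np.maximum(t, 1e-300)), -300.0)
    return (counts * logt).sum(axis=(-2, -1))


def estimate_rf(
    g1: np.ndarray,
    g2: np.ndarray,
    sexes: np.ndarray,
    is_x1: bool,
    is_x2: bool,
    min_joint: int = 10,
) -> RfEstimate:
    """Maximum-likelihood recombination fraction between two markers.

    Uses F2 phase-known transmission probabilities: codominant 3x3 tables
    for autosomal pairs, direct maternal-gamete reads for X pairs, and the
    single shared maternal meiosis for mixed pairs. Returns NaNs (with a
    warning) below ``min_joint`` jointly informative individuals.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if is_x1 and not is_x2:
        return estimate_rf(g2, g1, sexes, is_x2, is_x1, min_joint)
    a = maternal_x_origins(g1, sexes) if is_x1 else g1
    b = maternal_x_origins(g2, sexes) if is_x2 else g2
    ok = (a != NA) & (b != NA) & (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n < min_joint:
        log.warning("fewer than %d jointly informative individuals", min_joint)
        return RfEstimate(float("nan"), float("nan"))
    if is_x1 and is_x2:
        k = int((a[ok] != b[ok]).sum())
        r = min(max(k / n, MIN_RF), 0.5)
        lod = k * np.log10(max(r, 1e-300)) + (n - k) * np.log10(1 - r) - n * np.log10(0.5)
        return RfEstimate(float(min(r, 0.5)), float(max(lod, 0.0)))
    if is_x2:  # autosome x X
        counts = np.zeros((3, 2))
        np.add.at(counts, (a[ok], b[ok]), 1.0)
        r = float(_em_rf_ax(counts[None])[0])
        lod = float(_loglik_ax(counts, np.array(r)) - _loglik_ax(counts, np.array(0.5)))
        return RfEstimate(min(r, 0.5), max(lod, 0.0))
    counts = np.zeros((3, 3))
    np.add.at(counts, (a[ok], b[ok]), 1.0)
    r = float(_em_rf_aa(counts[None])[0])
    lod = float(_loglik_aa(counts, np.array(r)) - _loglik_aa(counts, np.array(0.5)))
    return RfEstimate(min(r, 0.5), max(lod, 0.0))


def pairwise_rf(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs rf and lod matrices over F2 individuals (batched EM).

    X markers are first recoded to maternal origins. Count tables for every
    pair are built with indicator matmuls; EM runs vectorized per pair type.
    Pairs with < 10 jointly informative individuals get NaN.
    """
    f2 = gm.individual_mask(generation="F2")
    sexes = gm.individuals.loc[f2, "sex"].to_numpy()
    calls = gm.calls[:, f2].astype(np.int64)
    is_x = gm.marker_is_x()
    coded = calls.copy()
    if is_x.any():
        coded[is_x] = maternal_x_origins(calls[is_x], sexes)
    m = gm.n_markers
    # indicator stacks; NA/unresolved contribute nowhere
    ind = [(coded == g).astype(np.float64) for g in range(3)]
    counts = np.zeros((m, m, 3, 3))
    for g1 in range(3):
        for g2 in range(3):
            counts[:, :, g1, g2] = ind[g1] @ ind[g2].T
    joint_n = counts.sum(axis=(2, 3))

    rf = np.full((m, m), np.nan)
    lod = np.full((m, m), np.nan)
    iu, ju = np.triu_indices(m, k=1)
    enough = joint_n[iu, ju] >= 10

    kind = np.where(is_x[iu] & is_x[ju], 2, np.where(is_x[iu] | is_x[ju], 1, 0))
    half = np.log10(0.5)

    sel = enough & (kind == 0)
    if sel.any():
        c = counts[iu[sel], ju[sel]][:, :3, :3]
        r = _em_rf_aa(c)
        l = _loglik_aa(c, r) - _loglik_aa(c, np.full_like(r, 0.5))
        rf[iu[sel], ju[sel]] = np.minimum(r, 0.5)
        lod[iu[sel], ju[sel]] = np.maximum(l, 0.0)
    sel = enough & (kind == 1)
    if sel.any():
        # orient so the autosomal marker indexes rows of the 3x2 table
        ii, jj = iu[sel], ju[sel]
        swap = is_x[ii]
        a = np.where(swap, jj, ii)
        x = np.where(swap, ii, jj)
        c = counts[a, x][:, :3, :2]
        r = _em_rf_ax(c)
        l = _loglik_ax(c, r) - _loglik_ax(c, np.full_like(r, 0.5))
        rf[ii, jj] = np.minimum(r, 0.5)
        lod[ii, jj] = np.maximum(l, 0.0)
    sel = enough & (kind == 2)
    if sel.any():
        c = counts[iu[sel], ju[sel]][:, :2, :2]
        n = c.sum(axis=(1, 2))
        k = c[:, 0, 1] + c[:, 1, 0]
        r = np.clip(k / n, MIN_RF, 0.5)
        l = (
            k * np.log10(np.maximum(r, 1e-300))
            + (n - k) * np.log10(1 - np.minimum(r, 0.49999999))
            - n * half
        )
        rf[iu[sel], ju[sel]] = r
        lod[iu[sel], ju[sel]] = np.maximum(l, 0.0)

    rf[ju, iu] = rf[iu, ju]
    lod[ju, iu] = lod[iu, ju]
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, np.nan)
    return rf, lod


# ---------------------------------------------------------------------------
# marker ordering
# ---------------------------------------------------------------------------
def _order_length(order: list[int], rf: np.ndarray, rf_to_cm) -> float:
    if len(order) < 2:
        return 0.0
    r = rf[order[:-1], order[1:]]
    r = np.where(np.isnan(r), MAX_RF, np.minimum(r, MAX_RF))
    return float(np.sum(rf_to_cm(r)))


def order_and_validate(
    gm: GenotypeMatrix,
    map_function: str = "haldane",
    check_cross_linkage: bool = True,
) -> tuple[dict[str, list[str]], list[str]]:
    """Validate/repair physical marker order; drop cross-linked markers.

    Starting from physical order, single-marker relocation hill-climbing
    accepts moves that strictly shorten the chained two-point map length;
    the scan is deterministic (left to right) and ties keep the current
    position. Markers whose strongest linkage lod lies on another
    chromosome are removed. Returns (orders per chromosome, removed names).
    """
    rf_to_cm = MAP_FUNCTIONS[map_function][0]
    rf, lod = pairwise_rf(gm)
    chroms = gm.markers["chrom"].to_numpy()
    names = gm.markers["name"].to_numpy()
    removed: list[str] = []
    keep = np.ones(gm.n_markers, dtype=bool)
    if check_cross_linkage:
        with np.errstate(invalid="ignore"):
            for k in range(gm.n_markers):
                same = (chroms == chroms[k])
                same[k] = False
                intra = np.nanmax(lod[k, same]) if same.any() else -np.inf
                other = ~same
                other[k] = False
                inter = np.nanmax(lod[k, other]) if other.any() else -np.inf
                if inter > intra:
                    keep[k] = False
                    removed.append(str(names[k]))
    # pairwise chained distances for O(1) relocation deltas
    d = np.asarray(rf_to_cm(np.where(np.isnan(rf), MAX_RF, np.minimum(rf, MAX_RF))))
    orders: dict[str, list[str]] = {}
    for chrom in dict.fromkeys(chroms):
        idx = [i for i in np.flatnonzero((chroms == chrom) & keep)]
        order = list(idx)

        def dist(a: int | None, b: int | None) -> float:
            if a is None or b is None:
                return 0.0
            return float(d[a, b])

        improved = True
        passes = 0
        while improved and passes < 20:
            improved = False
            passes += 1
            for marker in list(order):
                k = order.index(marker)
                left = order[k - 1] if k > 0 else None
                right = order[k + 1] if k < len(order) - 1 else None
                remove_delta = dist(left, right) - dist(left, marker) - dist(marker, right)
                base = order[:k] + order[k + 1 :]
                best_delta, best_pos = -1e-9, None
                for pos in range(len(base) + 1):
                    if pos == k:
                        continue  # re-inserting in place is a no-op
                    c = base[pos - 1] if pos > 0 else None
                    e = base[pos] if pos < len(base) else None
                    insert_delta = dist(c, marker) + dist(marker, e) - dist(c, e)
                    delta = remove_delta + insert_delta
                    if delta < best_delta:
                        best_delta, best_pos = delta, pos
                if best_pos is not None:
                    order = base[:best_pos] + [marker] + base[best_pos:]
                    improved = True
            # segment-reversal (2-opt) moves: a relocation-only search stalls
            # on long reversed blocks (segregating inversions), which a
            # single reversal fixes; internal distances are symmetric so the
            # delta needs only the four boundary edges
            arr = order
            rev_improved = True
            while rev_improved:
                rev_improved = False
                n = len(arr)
                for i in range(n - 1):
                    left = arr[i - 1] if i > 0 else None
                    for j in range(i + 1, n):
                        right = arr[j + 1] if j < n - 1 else None
                        delta = (
                            dist(left, arr[j])
                            + dist(arr[i], right)
                            - dist(left, arr[i])
                            - dist(arr[j], right)
                        )
                        if delta < -1e-9:
                            arr = arr[:i] + arr[i : j + 1][::-1] + arr[j + 1 :]
                            rev_improved = True
                            improved = True
                            break
                    if rev_improved:
                        break
            order = arr
        # canonical orientation: physical coordinates ascending on balance
        bp = gm.markers["pos_bp"].to_numpy()
        ranks = np.argsort(np.argsort([bp[i] for i in order]))
        if len(order) > 2 and np.corrcoef(ranks, np.arange(len(order)))[0, 1] < 0:
            order = order[::-1]
        orders[str(chrom)] = [str(names[i]) for i in order]
    return orders, removed


# ---------------------------------------------------------------------------
# multipoint HMM
# ---------------------------------------------------------------------------
def _emissions(
    calls: np.ndarray, sexes: np.ndarray, is_x: bool, error_prob: float
) -> np.ndarray:
    """Emission probabilities, shape (n_ind, n_markers, n_states).

    Autosomes: states are ordered gamete-origin pairs (m, p), the true
    genotype is the dosage m + p. X: states are maternal origins; the true
    code depends on sex (male 2*o, female o). Observation error spreads
    ``error_prob`` uniformly over the two wrong codes; NA emits 1.
    """
    n_markers, n_ind = calls.shape
    e = error_prob
    if not is_x:
        dosage = np.array([0, 1, 1, 2])  # state order (m,p): 00,01,10,11
        em = np.ones((n_ind, n_markers, 4))
        obs = calls.T  # (ind, marker)
        for s in range(4):
            true_code = dosage[s]
            match = obs == true_code
            em[:, :, s] = np.where(obs == NA, 1.0, np.where(match, 1.0 - e, e / 2.0))
        return em
    male = (sexes == "M")[:, None]
    obs = calls.T
    em = np.ones((n_ind, n_markers, 2))
    for s in range(2):
        true_code = np.where(male, 2 * s, s)
        match = obs == true_code
        em[:, :, s] = np.where(obs == NA, 1.0, np.where(match, 1.0 - e, e / 2.0))
    return em


def _transition(r: float, is_x: bool) -> np.ndarray:
    t = np.array([[1 - r, r], [r, 1 - r]])
    if is_x:
        return t
    return np.kron(t, t)


_SWITCH_X = np.array([[0.0, 1.0], [1.0, 0.0]])
_SWITCH_A = np.kron(_SWITCH_X, np.ones((2, 2))) + np.kron(np.ones((2, 2)), _SWITCH_X)


def _forward_backward(
    em: np.ndarray, rs: np.ndarray, is_x: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward. Returns (alpha, beta, scales, loglik)."""
    n_ind, n_markers, S = em.shape
    alpha = np.empty_like(em)
    beta = np.empty_like(em)
    scales = np.empty((n_ind, n_markers))
    a = em[:, 0, :] / S
    c = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, None]
    scales[:, 0] = c
    trans = [_transition(float(r), is_x) for r in rs]
    for k in range(1, n_markers):
        a = (alpha[:, k - 1, :] @ trans[k - 1]) * em[:, k, :]
        c = a.sum(axis=1)
        c = np.maximum(c, 1e-300)
        alpha[:, k, :] = a / c[:, None]
        scales[:, k] = c
    beta[:, -1, :] = 1.0
    for k in range(n_markers - 2, -1, -1):
        b = (beta[:, k + 1, :] * em[:, k + 1, :]) @ trans[k].T
        beta[:, k, :] = b / scales[:, k + 1][:, None]
    loglik = float(np.log(scales).sum())
    return alpha, beta, scales, loglik


def _fit_chromosome(
    calls: np.ndarray,
    sexes: np.ndarray,
    is_x: bool,
    error_prob: float,
    r_init: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, bool, np.ndarray]:
    """EM over inter-marker recombination fractions for one chromosome.

    Returns (rf per interval, posterior state probs gamma, converged,
    loglik trace). The EM likelihood is checked to be non-decreasing.
    """
    em = _emissions(calls, sexes, is_x, error_prob)
    n_ind, n_markers, S = em.shape
    switch = _SWITCH_X if is_x else _SWITCH_A
    denom = n_ind * (1.0 if is_x else 2.0)
    rs = np.clip(np.asarray(r_init, dtype=float), MIN_RF, MAX_RF)
    prev_ll = -np.inf
    trace = []
    converged = False
    alpha = beta = scales = None
    for it in range(max_iter):
        alpha, beta, scales, ll = _forward_backward(em, rs, is_x)
        trace.append(ll)
        if ll < prev_ll - 1e-6:
            raise AssertionError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        new_rs = np.empty_like(rs)
        for k in range(n_markers - 1):
            t = _transition(float(rs[k]), is_x)
            # xi[i, s, s'] ~ alpha[i,k,s] T[s,s'] em[i,k+1,s'] beta[i,k+1,s']
            xi = alpha[:, k, :, None] * t[None] * (em[:, k + 1, :] * beta[:, k + 1, :])[:, None, :]
            xi /= np.maximum(xi.sum(axis=(1, 2), keepdims=True), 1e-300)
            new_rs[k] = (xi * switch[None]).sum() / denom
        rs = np.clip(new_rs, MIN_RF, MAX_RF)
    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
    return rs, gamma, converged, np.asarray(trace)


def _error_lod(
    calls: np.ndarray, gamma: np.ndarray, sexes: np.ndarray, is_x: bool
) -> np.ndarray:
    """log10 posterior error odds per call, shape like ``calls``; NA -> -inf."""
    n_markers, n_ind = calls.shape
    obs = calls.T
    if not is_x:
        dosage = np.array([0, 1, 1, 2])
        p_match = np.zeros((n_ind, n_markers))
        for s in range(4):
            p_match += gamma[:, :, s] * (obs == dosage[s])
    else:
        male = (np.asarray(sexes) == "M")[:, None]
        p_match = np.zeros((n_ind, n_markers))
        for s in range(2):
            true_code = np.where(male, 2 * s, s)
            p_match += gamma[:, :, s] * (obs == true_code)
    p_match = np.clip(p_match, 1e-12, 1.0)
    with np.errstate(divide="ignore"):
        out = np.log10(np.maximum(1.0 - p_match, 1e-300)) - np.log10(p_match)
    out[(obs == NA)] = -np.inf
    return out.T


def _initial_rf(calls: np.ndarray, sexes: np.ndarray, is_x: bool) -> np.ndarray:
    """Moment-style starting values from adjacent-marker discordance."""
    coded = maternal_x_origins(calls, sexes) if is_x else calls
    n_markers = calls.shape[0]
    r0 = np.full(max(n_markers - 1, 0), 0.05)
    for k in range(n_markers - 1):
        a, b = coded[k], coded[k + 1]
        ok = (a >= 0) & (b >= 0)
        if ok.sum() >= 10:
            diff = np.abs(a[ok] - b[ok]).sum()
            denom = ok.sum() * (1.0 if is_x else 2.0)
            r0[k] = min(max(diff / denom, 0.001), 0.45)
    return r0


def estimate_map(
    gm: GenotypeMatrix,
    orders: dict[str, list[str]] | None = None,
    error_prob: float = 0.001,
    map_function: str = "haldane",
    error_lod_cutoff: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> GeneticMap:
    """Multipoint EM map over F2 individuals.

    ``orders`` gives marker names per chromosome (default: physical order).
    With ``error_lod_cutoff`` set, calls whose posterior error odds exceed
    the cutoff after the first fit are masked and the map re-estimated once.
    """
    rf_to_cm = MAP_FUNCTIONS[map_function][0]
    f2 = gm.individual_mask(generation="F2")
    sexes = gm.individuals.loc[f2, "sex"].to_numpy()
    name_to_row = {n: i for i, n in enumerate(gm.markers["name"])}
    groups: list[LinkageGroup] = []
    for chrom in gm.chromosomes():
        if orders is not None and chrom in orders:
            rows = [name_to_row[n] for n in orders[chrom]]
        else:
            rows = list(np.flatnonzero((gm.markers["chrom"] == chrom).to_numpy()))
        calls = gm.calls[rows][:, f2]
        is_x = chrom == gm.x_chrom
        if len(rows) < 2:
            groups.append(
                LinkageGroup(
                    chrom=chrom,
                    marker_names=[gm.markers.at[r, "name"] for r in rows],
                    pos_bp=gm.markers.loc[rows, "pos_bp"].to_numpy(dtype=float),
                    cm=np.zeros(len(rows)),
                )
            )
            continue
        r0 = _initial_rf(calls, sexes, is_x)
        rs, gamma, conv, _ = _fit_chromosome(
            calls, sexes, is_x, error_prob, r0, tol, max_iter
        )
        if error_lod_cutoff is not None:
            elod = _error_lod(calls, gamma, sexes, is_x)
            bad = elod > error_lod_cutoff
            if bad.any():
                calls = np.where(bad, NA, calls).astype(np.int8)
                rs, gamma, conv, _ = _fit_chromosome(
                    calls, sexes, is_x, error_prob, rs, tol, max_iter
                )
        if not conv:
            log.warning("map EM did not converge on %s", chrom)
        cm = np.concatenate([[0.0], np.cumsum(rf_to_cm(rs))])
        groups.append(
            LinkageGroup(
                chrom=chrom,
                marker_names=[gm.markers.at[r, "name"] for r in rows],
                pos_bp=gm.markers.loc[rows, "pos_bp"].to_numpy(dtype=float),
                cm=cm,
                converged=conv,
            )
        )
    return GeneticMap(groups=groups, map_function=map_function, error_prob=error_prob)


def clean_genotypes(
    gm: GenotypeMatrix,
    orders: dict[str, list[str]] | None = None,
    error_prob: float = 0.001,
    error_lod_cutoff: float = 4.0,
) -> GenotypeMatrix:
    """Mask F2 calls whose posterior error odds exceed the cutoff.

    Runs the same per-chromosome HMM as map estimation and sets suspect
    calls (isolated apparent double crossovers, typically genotyping
    errors) to NA. Downstream crossover counting should use the cleaned
    matrix, as obligate counts are highly sensitive to single bad calls.
    """
    out = gm.copy()
    f2 = out.individual_mask(generation="F2")
    f2_cols = np.flatnonzero(f2)
    sexes = out.individuals.loc[f2, "sex"].to_numpy()
    name_to_row = {n: i for i, n in enumerate(out.markers["name"])}
    for chrom in out.chromosomes():
        if orders is not None and chrom in orders:
            rows = [name_to_row[n] for n in orders[chrom]]
        else:
            rows = list(np.flatnonzero((out.markers["chrom"] == chrom).to_numpy()))
        if len(rows) < 2:
            continue
        calls = out.calls[rows][:, f2]
        is_x = chrom == out.x_chrom
        r0 = _initial_rf(calls, sexes, is_x)
        _, gamma, _, _ = _fit_chromosome(calls, sexes, is_x, error_prob, r0)
        elod = _error_lod(calls, gamma, sexes, is_x)
        bad_r, bad_c = np.nonzero(elod > error_lod_cutoff)
        for r, c in zip(bad_r, bad_c):
            out.calls[rows[r], f2_cols[c]] = NA
    return out


def sex_specific_maps(
    gm: GenotypeMatrix,
    orders: dict[str, list[str]] | None = None,
    error_prob: float = 0.001,
    map_function: str = "haldane",
    min_per_sex: int = 10,
) -> tuple[GeneticMap, GeneticMap]:
    """(male map, female map): the final map step repeated per F2 sex.

    No normalization is applied -- both sexes inherit exactly one maternally
    recombined copy of each chromosome, so lengths are directly comparable.
    """
    out = []
    for sex in ("M", "F"):
        mask = gm.individual_mask(generation="F2", sex=sex) | gm.individual_mask("P0")
        sub = gm.take_individuals(mask)
        n = int(sub.individual_mask(generation="F2").sum())
        if n < min_per_sex:
            raise ValueError(f"only {n} F2 individuals of sex {sex}")
        out.append(estimate_map(sub, orders, error_prob, map_function))
    return out[0], out[1]
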