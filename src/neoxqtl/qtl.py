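"""Single-QTL genome scan by EM interval mapping.

At each grid position the phenotype is modelled as a normal mixture over
putative QTL genotypes, with mixing proportions equal to the posterior
genotype probabilities from the flanking-marker HMM (same genotyping-error
model as map estimation). The LOD is log10 of the fitted mixture likelihood
against the no-QTL normal fit.

The X chromosome needs special care in this cross: genotype classes are the
two maternal-gamete origins {UT, AZ}, sex enters the null model as a mean
covariate (sex and X genotype are partially confounded by design), the QTL
model fits origin means within sex, and X permutations are stratified by
sex. Significance thresholds are permutation quantiles with the alpha
budget split between autosomes and X in proportion to map length:
alpha_A = 1 - (1-alpha)^(L_A/L_T), alpha_X = 1 - (1-alpha)^(L_X/L_T).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from neoxqtl.containers import GeneticMap, GenotypeMatrix, ScanResult
from neoxqtl.linkmap import MAP_FUNCTIONS, _emissions, _forward_backward

log = logging.getLogger(__name__)

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# genotype probabilities on the scan grid
# ---------------------------------------------------------------------------
def genotype_probs(
    gmap: GeneticMap,
    gm: GenotypeMatrix,
    chrom: str,
    step_cm: float = 1.0,
    error_prob: float = 0.001,
    individual_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior QTL-genotype probabilities at markers plus a cM grid.

    Returns (grid_cm, grid_bp, probs) with probs of shape
    (n_ind, n_positions, n_classes); classes are AZ dosage {0,1,2} on
    autosomes and maternal origin {UT, AZ} on the X. Pseudomarkers are
    inserted as all-missing emissions in one forward-backward pass.
    """
    group = gmap.group(chrom)
    is_x = chrom == gm.x_chrom
    if individual_mask is None:
        individual_mask = gm.individual_mask(generation="F2")
    sexes = gm.individuals.loc[individual_mask, "sex"].to_numpy()
    name_to_row = {n: i for i, n in enumerate(gm.markers["name"])}
    rows = [name_to_row[n] for n in group.marker_names]
    calls = gm.calls[rows][:, individual_mask]

    marker_cm = group.cm
    grid = np.unique(
        np.concatenate([marker_cm, np.arange(0.0, group.length_cm + 1e-9, step_cm)])
    )
    # merge grid points that coincide with markers
    is_marker = np.isin(grid, marker_cm)
    n_pos = len(grid)
    n_ind = calls.shape[1]

    em_markers = _emissions(calls, sexes, is_x, error_prob)
    S = em_markers.shape[2]
    em = np.ones((n_ind, n_pos, S))
    # map each marker to its grid slot (first marker wins on cM ties)
    slot = np.searchsorted(grid, marker_cm)
    for j, s in enumerate(slot):
        em[:, s, :] *= em_markers[:, j, :]

    cm_to_rf = MAP_FUNCTIONS[gmap.map_function][1]
    rs = np.maximum(cm_to_rf(np.diff(grid)), 1e-9)
    alpha, beta, _, _ = _forward_backward(em, rs, is_x)
    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
    if is_x:
        probs = gamma  # states already {UT, AZ}
    else:
        probs = np.stack(
            [gamma[:, :, 0], gamma[:, :, 1] + gamma[:, :, 2], gamma[:, :, 3]], axis=2
        )
    grid_bp = np.interp(grid, marker_cm, group.pos_bp)
    return grid, grid_bp, probs


# ---------------------------------------------------------------------------
# normal-mixture fits
# ---------------------------------------------------------------------------
def _null_loglik(Y: np.ndarray, groups: np.ndarray | None) -> np.ndarray:
    """Exact ML log-likelihood of the no-QTL normal model, per column."""
    n, P = Y.shape
    if groups is None:
        resid = Y - Y.mean(axis=0, keepdims=True)
    else:
        resid = Y.copy()
        for g in np.unique(groups):
            m = groups == g
            resid[m] -= Y[m].mean(axis=0, keepdims=True)
    s2 = (resid**2).sum(axis=0) / n
    s2 = np.maximum(s2, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def _mixture_loglik(
    w: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """EM fit of a normal mixture with known mixing proportions per row.

    ``w`` is (n, C) posterior genotype probabilities; ``Y`` is (n, P)
    phenotype columns fitted independently (vectorized over permutations).
    With ``groups`` (e.g. sex codes) a separate mean is fitted per
    (group, class); the variance is common. Returns log-likelihood (P,).
    """
    n, C = w.shape
    P = Y.shape[1]
    if groups is None:
        groups = np.zeros(n, dtype=int)
    G = int(groups.max()) + 1
    onehot = np.eye(G)[groups]  # (n, G)

    # init: weighted class means within group, pooled variance
    resp = np.repeat(w[:, :, None], P, axis=2)  # (n, C, P)
    wsum0 = np.einsum("ng,nc->gc", onehot, w)  # (G, C)
    s2 = Y.var(axis=0) + 1e-12
    ll_prev = np.full(P, -np.inf)
    ll = ll_prev
    for it in range(max_iter):
        denom = np.maximum(np.einsum("ng,ncp->gcp", onehot, resp), 1e-12)
        mu = np.einsum("ng,ncp,np->gcp", onehot, resp, Y) / denom  # (G, C, P)
        mu_i = np.einsum("ng,gcp->ncp", onehot, mu)  # (n, C, P)
        resid2 = (Y[:, None, :] - mu_i) ** 2
        s2 = np.maximum(np.einsum("ncp,ncp->p", resp, resid2) / n, 1e-300)
        logphi = -0.5 * (np.log(2 * np.pi * s2)[None, None, :] + resid2 / s2[None, None, :])
        with np.errstate(divide="ignore"):
            logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -700.0)
        a = logw[:, :, None] + logphi
        amax = a.max(axis=1, keepdims=True)
        lse = amax[:, 0, :] + np.log(np.exp(a - amax).sum(axis=1))
        ll = lse.sum(axis=0)
        resp = np.exp(a - lse[:, None, :])
        if np.max(np.abs(ll - ll_prev)) < tol:
            break
        ll_prev = ll
    return ll


def _scan_positions(
    probs: np.ndarray,
    Y: np.ndarray,
    groups: np.ndarray | None,
) -> np.ndarray:
    """LOD at every position for every phenotype column: (n_pos, P)."""
    n_ind, n_pos, C = probs.shape
    ll0 = _null_loglik(Y, groups)
    out = np.empty((n_pos, Y.shape[1]))
    for p in range(n_pos):
        ll1 = _mixture_loglik(probs[:, p, :], Y, groups)
        out[p] = (ll1 - ll0) / _LN10
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# public scan API
# ---------------------------------------------------------------------------
def _prepare_phenotype(
    gm: GenotypeMatrix, phenotype: pd.Series | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Align phenotype to F2 individuals; drop missing pairwise."""
    f2 = gm.individual_mask(generation="F2")
    ids = gm.individuals.loc[f2, "id"]
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(ids).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if len(y) != f2.sum():
            raise ValueError("phenotype length does not match F2 count")
    keep = ~np.isnan(y)
    return y, keep


def scan_em(
    gmap: GeneticMap,
    gm: GenotypeMatrix,
    phenotype: pd.Series | np.ndarray,
    step_cm: float = 1.0,
    error_prob: float = 0.001,
    sex_adjust_autosomes: bool = False,
) -> ScanResult:
    """Genome-wide interval-mapping LOD curve.

    ``phenotype`` is indexed by F2 individual id (Series) or ordered as the
    F2 individuals. ``sex_adjust_autosomes`` additionally puts sex in the
    autosomal null and QTL models (always the case on the X).
    """
    y, keep = _prepare_phenotype(gm, phenotype)
    f2_idx = np.flatnonzero(gm.individual_mask(generation="F2"))
    mask = np.zeros(gm.n_individuals, dtype=bool)
    mask[f2_idx[keep]] = True
    yk = y[keep][:, None]
    constant = bool(np.allclose(yk, yk[0]))
    if constant:
        warnings.warn("constant phenotype: all LOD scores are 0")
    sexes = gm.individuals.loc[mask, "sex"].to_numpy()
    sex_codes = (sexes == "M").astype(int)

    frames = []
    for group in gmap.groups:
        is_x = group.chrom == gm.x_chrom
        grid_cm, grid_bp, probs = genotype_probs(
            gmap, gm, group.chrom, step_cm, error_prob, individual_mask=mask
        )
        groups = sex_codes if (is_x or sex_adjust_autosomes) else None
        if constant:
            lod = np.zeros(len(grid_cm))
        else:
            lod = _scan_positions(probs, yk, groups)[:, 0]
        frames.append(
            pd.DataFrame(
                {"chrom": group.chrom, "cm": grid_cm, "pos_bp": grid_bp, "lod": lod}
            )
        )
    positions = pd.concat(frames, ignore_index=True)
    peak_row = positions.loc[positions["lod"].idxmax()]
    return ScanResult(
        positions=positions,
        peak=(str(peak_row["chrom"]), float(peak_row["cm"]), float(peak_row["lod"])),
    )


def alpha_partition(l_auto: float, l_x: float, alpha: float = 0.05) -> tuple[float, float]:
    """Split a genome-wide alpha between autosomes and X by map length."""
    l_total = l_auto + l_x
    return (
        1.0 - (1.0 - alpha) ** (l_auto / l_total),
        1.0 - (1.0 - alpha) ** (l_x / l_total),
    )


def permutation_thresholds(
    gmap: GeneticMap,
    gm: GenotypeMatrix,
    phenotype: pd.Series | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    x_specific: bool = True,
    seed: int | np.random.Generator = 0,
    step_cm: float = 1.0,
    error_prob: float = 0.001,
    sex_adjust_autosomes: bool = False,
) -> tuple[float, float]:
    """(autosomal, X) LOD thresholds from stratified permutations.

    The genome-wide alpha is partitioned by map length; X permutations
    shuffle phenotypes within sex. With ``x_specific=False`` a single
    genome-wide null is used for both thresholds.
    """
    if n_perm < 100:
        log.warning("n_perm=%d gives unstable threshold quantiles", n_perm)
    rng = np.random.default_rng(seed)
    y, keep = _prepare_phenotype(gm, phenotype)
    f2_idx = np.flatnonzero(gm.individual_mask(generation="F2"))
    mask = np.zeros(gm.n_individuals, dtype=bool)
    mask[f2_idx[keep]] = True
    yk = y[keep]
    n = len(yk)
    sexes = gm.individuals.loc[mask, "sex"].to_numpy()
    sex_codes = (sexes == "M").astype(int)

    Y_auto = np.empty((n, n_perm))
    for p in range(n_perm):
        Y_auto[:, p] = yk[rng.permutation(n)]
    Y_x = np.empty((n, n_perm))
    for p in range(n_perm):
        col = yk.copy()
        for s in (0, 1):
            idx = np.flatnonzero(sex_codes == s)
            col[idx] = col[idx[rng.permutation(len(idx))]]
        Y_x[:, p] = col

    max_auto = np.full(n_perm, -np.inf)
    max_x = np.full(n_perm, -np.inf)
    l_auto = l_x = 0.0
    for group in gmap.groups:
        is_x = group.chrom == gm.x_chrom
        _, _, probs = genotype_probs(
            gmap, gm, group.chrom, step_cm, error_prob, individual_mask=mask
        )
        if is_x:
            l_x += group.length_cm
            lod = _scan_positions(probs, Y_x, sex_codes)
            max_x = np.maximum(max_x, lod.max(axis=0))
        else:
            l_auto += group.length_cm
            groups = sex_codes if sex_adjust_autosomes else None
            lod = _scan_positions(probs, Y_auto, groups)
            max_auto = np.maximum(max_auto, lod.max(axis=0))

    if not x_specific:
        both = np.maximum(max_auto, max_x)
        thr = float(np.quantile(both, 1 - alpha))
        return thr, thr
    alpha_a, alpha_x = alpha_partition(l_auto, l_x, alpha)
    return (
        float(np.quantile(max_auto, 1 - alpha_a)),
        float(np.quantile(max_x, 1 - alpha_x)),
    )


def bayes_interval(
    scan: ScanResult, chrom: str, prob: float = 0.95
) -> tuple[float, float]:
    """Approximate Bayes credible interval for QTL location on ``chrom``.

    10^LOD is normalized over the chromosome's grid to a discrete
    posterior; the interval grows greedily from the peak, always taking the
    higher-mass neighbor, until it holds >= ``prob`` of the mass.
    """
    sub = scan.positions[scan.positions["chrom"] == chrom].reset_index(drop=True)
    lod = sub["lod"].to_numpy()
    if np.allclose(lod, 0.0):
        warnings.warn("flat LOD curve: returning the whole chromosome")
        return float(sub["cm"].iloc[0]), float(sub["cm"].iloc[-1])
    mass = 10.0 ** (lod - lod.max())
    mass /= mass.sum()
    lo = hi = int(np.argmax(mass))
    cum = mass[lo]
    while cum < prob and (lo > 0 or hi < len(mass) - 1):
        left = mass[lo - 1] if lo > 0 else -1.0
        right = mass[hi + 1] if hi < len(mass) - 1 else -1.0
        if left >= right:
            lo -= 1
            cum += mass[lo]
        else:
            hi += 1
            cum += mass[hi]
    return float(sub["cm"].iloc[lo]), float(sub["cm"].iloc[hi])


def effect_table(
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    phenotype: pd.Series | np.ndarray,
    chrom: str,
    peak_cm: float,
) -> pd.DataFrame:
    """Phenotype mean +/- SE per genotype class per sex at the peak marker."""
    group = gmap.group(chrom)
    j = int(np.argmin(np.abs(group.cm - peak_cm)))
    marker = group.marker_names[j]
    row = int(np.flatnonzero((gm.markers["name"] == marker).to_numpy())[0])
    y, keep = _prepare_phenotype(gm, phenotype)
    f2 = gm.individual_mask(generation="F2")
    calls = gm.calls[row, f2][keep]
    sexes = gm.individuals.loc[f2, "sex"].to_numpy()[keep]
    yk = y[keep]
    rows = []
    from neoxqtl.containers import CODE_LABELS

    for sex in ("F", "M"):
        for code in (0, 1, 2):
            sel = (sexes == sex) & (calls == code)
            if sel.sum() == 0:
                continue
            vals = yk[sel]
            rows.append(
                (
                    marker,
                    sex,
                    CODE_LABELS[code],
                    int(sel.sum()),
                    float(vals.mean()),
                    float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=["marker", "sex", "genotype", "n", "mean", "se"])
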