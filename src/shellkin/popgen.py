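"""Population-structure layer: SNP filtering, LD pruning, PCA, Fst, AMOVA.

The estimators implemented here are the standard population-genetic toolkit
applied around the kinship analysis:

* :func:`filter_variants` — depth / missingness / MAF site filters in a
  fixed, documented order (genotype-depth masking first, MAF last, computed
  after masking).
* :func:`ld_prune` — greedy sliding-window r^2 pruning (window 50 SNPs,
  step 5, r^2 > 0.2 removes the later locus), matching the common
  ``--indep-pairwise 50 5 0.2`` convention.
* :func:`pca` — PCA of the variance-standardized relationship matrix
  (dosages centered by 2p and scaled by sqrt(2p(1-p)), missing values
  mean-imputed, degenerate loci dropped).
* :func:`fst_pairwise` — multi-locus Weir & Cockerham (1984)
  ratio-of-averages theta with permutation p-values.  WC theta estimates the
  among-deme variance parameter (the F of a Balding-Nichols divergence
  model); the frequency-level Wright/Nei quantity 1 - Hs/Ht is exposed
  separately as :func:`wright_fst` because the two differ for small numbers
  of demes.
* :func:`amova` — three-level hierarchical AMOVA on allele-level sums of
  squares (among populations / among individuals within populations /
  within individuals) with Phi-statistics.
* :func:`phi_pt` — distance-based two-level AMOVA on individual dosage
  vectors (the codominant-data PhiPT), which absorbs genotypic as well as
  allele-frequency differences and therefore runs above Fst on the same
  panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

# ---------------------------------------------------------------------------
# Filtering


@dataclass
class FilterConfig:
    """Site/genotype quality thresholds; ``None`` disables a rule."""

    min_mean_site_depth: float | None = None
    max_mean_site_depth: float | None = None
    genotype_depth_range: tuple[float, float] | None = None
    min_maf: float | None = None
    max_site_missingness: float | None = None

    def __post_init__(self) -> None:
        if (
            self.min_mean_site_depth is not None
            and self.max_mean_site_depth is not None
            and self.min_mean_site_depth > self.max_mean_site_depth
        ):
            raise ValueError("mean site depth bounds out of order")
        if self.genotype_depth_range is not None:
            lo, hi = self.genotype_depth_range
            if lo > hi:
                raise ValueError("genotype depth range out of order")
        for frac in (self.min_maf, self.max_site_missingness):
            if frac is not None and not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0,1]")


#: Thresholds used for the complete multi-site panel in the source study.
FULL_DATASET_FILTERS = FilterConfig(
    min_mean_site_depth=10,
    max_mean_site_depth=130,
    genotype_depth_range=(10, 130),
    min_maf=0.02,
    max_site_missingness=0.10,
)

#: Thresholds used for the two-nest single-site panel.
HULA_FILTERS = FilterConfig(
    min_mean_site_depth=10,
    max_mean_site_depth=190,
    genotype_depth_range=(10, 190),
    min_maf=0.05,
    max_site_missingness=0.05,
)


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    removed: dict[str, int]
    kept_locus_ids: list[str]
    n_genotypes_masked: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "sites_removed": v} for k, v in self.removed.items()]
        rows.append({"rule": "kept", "sites_removed": self.n_kept})
        return pd.DataFrame(rows)


def filter_variants(
    g: GenotypeMatrix,
    depth: np.ndarray | None,
    cfg: FilterConfig,
) -> tuple[GenotypeMatrix, np.ndarray | None, FilterReport]:
    """Apply site filters in order; each removed site is charged to the first
    rule it fails.

    Order: per-genotype depth masking -> site mean depth bounds -> site
    missingness -> MAF (allele frequencies computed after masking).  Site
    mean depth is taken over genotypes called in the input, before masking,
    so that a site failing the depth rules is reported as a depth failure
    rather than as a missingness one.
    """
    X = g.dosage.copy()
    DP = None if depth is None else np.asarray(depth, dtype=float).copy()
    if DP is not None and DP.shape != X.shape:
        raise ValueError("depth matrix shape mismatch")

    n_masked = 0
    if cfg.genotype_depth_range is not None:
        if DP is None:
            raise ValueError("genotype depth filter requires DP")
        lo, hi = cfg.genotype_depth_range
        bad = (~np.isnan(X)) & (~np.isnan(DP)) & ((DP < lo) | (DP > hi))
        n_masked = int(bad.sum())
        X[bad] = np.nan

    n_loci = g.n_loci
    keep = np.ones(n_loci, dtype=bool)
    removed = {
        "mean_site_depth": 0,
        "site_missingness": 0,
        "maf": 0,
    }

    if cfg.min_mean_site_depth is not None or cfg.max_mean_site_depth is not None:
        if DP is None:
            raise ValueError("mean site depth filter requires DP")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            called_dp = np.where(~np.isnan(g.dosage), DP, np.nan)
            mean_dp = np.nanmean(called_dp, axis=0)
        bad = np.zeros(n_loci, dtype=bool)
        if cfg.min_mean_site_depth is not None:
            bad |= ~(mean_dp >= cfg.min_mean_site_depth)
        if cfg.max_mean_site_depth is not None:
            bad |= mean_dp > cfg.max_mean_site_depth
        removed["mean_site_depth"] = int((keep & bad).sum())
        keep &= ~bad

    if cfg.max_site_missingness is not None:
        miss = np.isnan(X).mean(axis=0)
        bad = miss > cfg.max_site_missingness
        removed["site_missingness"] = int((keep & bad).sum())
        keep &= ~bad

    if cfg.min_maf is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            freq = np.nanmean(X, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        bad = ~(maf >= cfg.min_maf)  # NaN (all-missing) counts as failing
        removed["maf"] = int((keep & bad).sum())
        keep &= ~bad

    kept_ids = [l for l, k in zip(g.locus_ids, keep) if k]
    out = GenotypeMatrix(g.sample_ids, kept_ids, X[:, keep])
    out_dp = None if DP is None else DP[:, keep]
    report = FilterReport(
        n_input=n_loci,
        n_kept=len(kept_ids),
        removed=removed,
        kept_locus_ids=kept_ids,
        n_genotypes_masked=n_masked,
    )
    return out, out_dp, report


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy sliding-window LD pruning; returns kept locus IDs in order.

    Within each window, any pair with squared dosage correlation above
    ``r2_max`` loses its later member.  The window slides by ``step`` SNPs.
    Missing dosages are mean-imputed per locus for the correlation only.
    Deterministic, and idempotent on its own output.
    """
    X = g.dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])

    L = g.n_loci
    keep = np.ones(L, dtype=bool)
    sd = X.std(axis=0)
    for start in range(0, max(L - 1, 1), step):
        idx = [j for j in range(start, min(start + window, L)) if keep[j] and sd[j] > 0]
        if len(idx) < 2:
            continue
        block = X[:, idx]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(block, rowvar=False)
        r2 = corr**2
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and r2[a, b] > r2_max:
                    keep[idx[b]] = False
    return [l for l, k in zip(g.locus_ids, keep) if k]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x components
    variance_explained: np.ndarray  # per-component fractions, non-increasing
    eigenvalues: np.ndarray


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the variance-standardized genetic relationship matrix.

    Dosages are centered by 2p and scaled by sqrt(2p(1-p)) with p the sample
    allele frequency; missing dosages are mean-imputed (zero after
    centering); monomorphic loci are dropped.  Coordinates are eigenvectors
    scaled by the square roots of their eigenvalues, so duplicated samples
    land on coincident points.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    p = g.allele_frequencies()
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    X = g.dosage[:, usable]
    p = p[usable]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic loci")
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z = np.where(np.isnan(Z), 0.0, Z)
    grm = Z @ Z.T / Z.shape[1]
    eigval, eigvec = np.linalg.eigh(grm)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > 1e-12
    max_comp = int(positive.sum())
    if n_components > max_comp:
        warnings.warn(
            f"only {max_comp} non-degenerate components available; reducing",
            stacklevel=2,
        )
        n_components = max_comp
    coords = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])
    total = eigval[positive].sum()
    return PcaResult(
        sample_ids=list(g.sample_ids),
        coordinates=coords,
        variance_explained=eigval[:n_components] / total,
        eigenvalues=eigval[:n_components],
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst


def _pop_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n called, alt freq, observed het freq) for one population."""
    called = ~np.isnan(X)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * np.maximum(n, 1))
        h = np.nansum(X == 1.0, axis=0) / np.maximum(n, 1)
    return n, p, h


def weir_cockerham_theta(
    panels: list[np.ndarray], return_components: bool = False
):
    """Multi-locus Weir & Cockerham (1984) theta over r populations.

    ``panels`` holds one dosage matrix (samples x loci, NaN missing) per
    population.  Loci without at least two called samples in two or more
    populations, or monomorphic overall, contribute nothing to either sum
    (ratio-of-averages estimator).
    """
    r = len(panels)
    if r < 2:
        raise ValueError("need at least two populations")
    stats = [_pop_stats(X) for X in panels]
    ns = np.stack([s[0] for s in stats])  # r x L
    ps = np.stack([s[1] for s in stats])
    hs = np.stack([s[2] for s in stats])

    valid = (ns >= 1).sum(axis=0) >= 2
    ns = np.where(ns >= 1, ns, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        r_eff = (~np.isnan(ns)).sum(axis=0).astype(float)
        nbar = np.nanmean(ns, axis=0)
        nc = (r_eff * nbar - np.nansum(ns**2, axis=0) / (r_eff * nbar)) / (r_eff - 1)
        pbar = np.nansum(ns * ps, axis=0) / (r_eff * nbar)
        s2 = np.nansum(ns * (ps - pbar) ** 2, axis=0) / ((r_eff - 1) * nbar)
        hbar = np.nansum(ns * hs, axis=0) / (r_eff * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r_eff - 1) / r_eff - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r_eff - 1) / r_eff
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0

    poly = valid & (pbar > 0) & (pbar < 1) & (nbar > 1)
    a = np.where(poly, a, 0.0)
    b = np.where(poly, b, 0.0)
    c = np.where(poly, c, 0.0)
    denom = (a + b + c).sum()
    theta = float(a.sum() / denom) if denom > 0 else float("nan")
    if return_components:
        return theta, a, b, c
    return theta


def wright_fst(p1: float, p2: float) -> float:
    """Frequency-level Wright/Nei fixation index 1 - Hs/Ht for two demes."""
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    if ht == 0:
        return float("nan")
    return 1.0 - hs / ht


@dataclass
class FstMatrix:
    populations: list[str]
    estimates: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int


def _permutation_p(observed: float, permuted: np.ndarray) -> float:
    """Add-one permutation p-value; strictly positive by construction."""
    return float((1 + (permuted >= observed).sum()) / (len(permuted) + 1))


def fst_pairwise(
    g: GenotypeMatrix,
    pops: dict[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> FstMatrix:
    """Pairwise WC theta between populations with permutation p-values.

    The null distribution reassigns individuals to the two populations at
    random (sizes preserved).
    """
    rng = np.random.default_rng(seed)
    labels = sorted({pops[s] for s in g.sample_ids if s in pops})
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    idx = {
        lab: np.array([i for i, s in enumerate(g.sample_ids) if pops.get(s) == lab])
        for lab in labels
    }
    for lab in labels:
        if len(idx[lab]) < 2:
            raise ValueError(f"population {lab} has fewer than 2 samples")
    est = pd.DataFrame(np.nan, index=labels, columns=labels)
    pval = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            Xa, Xb = g.dosage[idx[la]], g.dosage[idx[lb]]
            obs = weir_cockerham_theta([Xa, Xb])
            pooled = np.vstack([Xa, Xb])
            na = len(Xa)
            perms = np.empty(n_perm)
            for k in range(n_perm):
                order = rng.permutation(len(pooled))
                perms[k] = weir_cockerham_theta(
                    [pooled[order[:na]], pooled[order[na:]]]
                )
            p = _permutation_p(obs, perms)
            est.loc[la, lb] = est.loc[lb, la] = obs
            pval.loc[la, lb] = pval.loc[lb, la] = p
    return FstMatrix(labels, est, pval, n_perm)


# ---------------------------------------------------------------------------
# AMOVA (three-level, allele-based)


@dataclass
class AmovaResult:
    components: dict[str, float]  # variance components, summed over loci
    percentages: dict[str, float]  # sum to 100 (after clamping if needed)
    phi: dict[str, float]  # phi_st, phi_is, phi_it
    p_value_among_populations: float | None
    n_permutations: int
    negative_components_clamped: bool = False


def _amova_components(X: np.ndarray, pop_idx: list[np.ndarray]) -> np.ndarray:
    """Summed variance components (among pops, among ind., within ind.).

    Allele-level nested ANOVA per locus: each called diploid contributes two
    allele values; within-individual SS is 1/2 per heterozygote.  Components
    are accumulated across loci (they may be negative locus-wise).
    """
    sig = np.zeros(3)
    k = len(pop_idx)
    L = X.shape[1]
    pops = [X[ix] for ix in pop_idx]
    called = [~np.isnan(P) for P in pops]
    n_j = np.stack([c.sum(axis=0).astype(float) for c in called])  # k x L
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_j = np.stack([np.nansum(P, axis=0) for P in pops])
        p_j = sum_j / (2 * np.maximum(n_j, 1))
        n_tot = n_j.sum(axis=0)
        p_tot = sum_j.sum(axis=0) / (2 * np.maximum(n_tot, 1))
        het_j = np.stack([np.nansum(P == 1.0, axis=0) for P in pops])

        ss_wi = het_j.sum(axis=0) * 0.5
        # among individuals within populations: 2 * sum_i (x_i/2 - p_j)^2
        ss_ai = np.zeros(L)
        for j, P in enumerate(pops):
            dev = P / 2.0 - p_j[j]
            ss_ai += 2.0 * np.nansum(dev**2, axis=0)
        ss_ap = (2 * n_j * (p_j - p_tot) ** 2).sum(axis=0)

        df_ap = np.full(L, float(k - 1))
        df_ai = n_tot - k
        df_wi = n_tot.astype(float)
        n0 = (n_tot - (n_j**2).sum(axis=0) / np.maximum(n_tot, 1)) / (k - 1)

        ok = (df_ai > 0) & (n_tot > 0) & (n0 > 0)
        ms_wi = np.where(df_wi > 0, ss_wi / np.maximum(df_wi, 1), 0.0)
        ms_ai = np.where(ok, ss_ai / np.maximum(df_ai, 1), 0.0)
        ms_ap = np.where(ok, ss_ap / df_ap, 0.0)

        sig_wi = ms_wi
        sig_ai = (ms_ai - ms_wi) / 2.0
        sig_ap = np.where(ok, (ms_ap - ms_ai) / (2.0 * np.maximum(n0, 1e-12)), 0.0)

    sig[0] = np.where(ok, sig_ap, 0.0).sum()
    sig[1] = np.where(ok, sig_ai, 0.0).sum()
    sig[2] = np.where(ok, sig_wi, 0.0).sum()
    return sig


def amova(
    g: GenotypeMatrix,
    pops: dict[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Three-level AMOVA: among populations / among individuals within
    populations / within individuals.

    Phi_ST is tested by permuting whole individuals across populations.
    With a single population only the individual/within partition is
    returned (no among-population test).
    """
    rng = np.random.default_rng(seed)
    labels = sorted({pops[s] for s in g.sample_ids if s in pops})
    idx = [
        np.array([i for i, s in enumerate(g.sample_ids) if pops.get(s) == lab])
        for lab in labels
    ]
    X = g.dosage

    if len(labels) < 2:
        # single population: two-level partition only
        sig = _amova_two_level_within(X)
        total = sig.sum()
        comp = {"among_individuals": float(sig[0]), "within_individuals": float(sig[1])}
        pct = {k_: 100 * v / total for k_, v in comp.items()} if total > 0 else comp
        phi_is = sig[0] / total if total > 0 else float("nan")
        return AmovaResult(comp, pct, {"phi_is": float(phi_is)}, None, 0)

    sig = _amova_components(X, idx)
    clamped = bool((sig < 0).any())
    sig_c = np.clip(sig, 0.0, None)
    total = sig_c.sum()
    comp = {
        "among_populations": float(sig[0]),
        "among_individuals": float(sig[1]),
        "within_individuals": float(sig[2]),
    }
    pct = {
        "among_populations": float(100 * sig_c[0] / total),
        "among_individuals": float(100 * sig_c[1] / total),
        "within_individuals": float(100 * sig_c[2] / total),
    }
    tot_raw = sig.sum()
    phi = {
        "phi_st": float(sig[0] / tot_raw),
        "phi_is": float(sig[1] / (sig[1] + sig[2])),
        "phi_it": float((sig[0] + sig[1]) / tot_raw),
    }

    p = None
    if n_perm > 0:
        sizes = [len(ix) for ix in idx]
        all_idx = np.concatenate(idx)
        perms = np.empty(n_perm)
        for kperm in range(n_perm):
            order = rng.permutation(all_idx)
            split = []
            at = 0
            for s in sizes:
                split.append(order[at : at + s])
                at += s
            s_perm = _amova_components(X, split)
            perms[kperm] = s_perm[0] / s_perm.sum() if s_perm.sum() > 0 else 0.0
        p = _permutation_p(phi["phi_st"], perms)
    return AmovaResult(comp, pct, phi, p, n_perm, clamped)


def _amova_two_level_within(X: np.ndarray) -> np.ndarray:
    """Among-individuals vs within-individuals components, single population."""
    called = ~np.isnan(X)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.nansum(X, axis=0) / (2 * np.maximum(n, 1))
        het = np.nansum(X == 1.0, axis=0)
        ss_wi = het * 0.5
        dev = X / 2.0 - p_hat
        ss_ai = 2.0 * np.nansum(dev**2, axis=0)
        ok = n > 1
        ms_wi = np.where(n > 0, ss_wi / np.maximum(n, 1), 0.0)
        ms_ai = np.where(ok, ss_ai / np.maximum(n - 1, 1), 0.0)
        sig_ai = (ms_ai - ms_wi) / 2.0
    return np.array(
        [np.where(ok, sig_ai, 0.0).sum(), np.where(n > 0, ms_wi, 0.0).sum()]
    )


# ---------------------------------------------------------------------------
# PhiPT (distance-based two-level AMOVA on dosage vectors)


@dataclass
class PhiPtResult:
    populations: list[str]
    estimates: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int


def _squared_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Euclidean distances, rescaled to all loci."""
    n, L = X.shape
    called = ~np.isnan(X)
    Xz = np.where(called, X, 0.0)
    d2 = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called
        m = both.sum(axis=1)
        diff = (Xz[i] - Xz) ** 2
        ss = np.where(both, diff, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2[i] = np.where(m > 0, ss * (L / np.maximum(m, 1)), np.nan)
    return d2


def _phi_pt_from_d2(d2: np.ndarray, group_sizes: list[int]) -> float:
    """PhiPT from a squared-distance matrix whose rows are grouped in blocks."""
    n = d2.shape[0]
    k = len(group_sizes)
    iu = np.triu_indices(n, 1)
    ssd_total = np.nansum(d2[iu]) / n
    ssd_within = 0.0
    at = 0
    for s in group_sizes:
        block = d2[at : at + s, at : at + s]
        biu = np.triu_indices(s, 1)
        ssd_within += np.nansum(block[biu]) / s
        at += s
    ssd_among = ssd_total - ssd_within
    df_a, df_w = k - 1, n - k
    if df_w <= 0:
        return float("nan")
    ms_w = ssd_within / df_w
    ms_a = ssd_among / df_a
    n0 = (n - sum(s**2 for s in group_sizes) / n) / (k - 1)
    sig_a = (ms_a - ms_w) / n0
    denom = sig_a + ms_w
    return float(sig_a / denom) if denom > 0 else float("nan")


def phi_pt(
    g: GenotypeMatrix,
    pops: dict[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PhiPtResult:
    """Pairwise PhiPT between populations with permutation p-values."""
    rng = np.random.default_rng(seed)
    labels = sorted({pops[s] for s in g.sample_ids if s in pops})
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    idx = {
        lab: [i for i, s in enumerate(g.sample_ids) if pops.get(s) == lab]
        for lab in labels
    }
    est = pd.DataFrame(np.nan, index=labels, columns=labels)
    pval = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            rows = idx[la] + idx[lb]
            sizes = [len(idx[la]), len(idx[lb])]
            d2 = _squared_distance_matrix(g.dosage[rows])
            obs = _phi_pt_from_d2(d2, sizes)
            perms = np.empty(n_perm)
            n = len(rows)
            for kperm in range(n_perm):
                order = rng.permutation(n)
                perms[kperm] = _phi_pt_from_d2(d2[np.ix_(order, order)], sizes)
            est.loc[la, lb] = est.loc[lb, la] = obs
            pval.loc[la, lb] = pval.loc[lb, la] = _permutation_p(obs, perms)
    return PhiPtResult(labels, est, pval, n_perm)
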