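"""Anchored identity-by-state (IBS) kinship statistic.

Raw IBS between two individuals averages a per-locus score over loci where
both are genotyped: 1 when the genotypes are identical (including het vs
het), 0.5 when they share one allele (het vs hom), 0 for opposite
homozygotes.  Equivalently, ``score = 1 - |d1 - d2| / 2`` on dosages.

The anchored normalization rescales the matrix so that 1 means "identical"
and 0 means "as similar as the average pair drawn from the two most
genetically distinct groups in the dataset" (nests when nest labels exist,
otherwise populations):

    nIBS = (IBS - av_min) / (1 - av_min)

Pairs less alike than the anchor average go negative, which is expected when
the anchor is within one population and a pair spans divergent populations.

Analytic calibration
--------------------
For founders in Hardy-Weinberg proportions at allele frequency ``p``
(``q = 1 - p``), the per-locus expectations by identity-by-descent state are

    E[IBS | IBD=0] = 1 - 2pq(1 - pq)
    E[IBS | IBD=1] = 1 - pq
    E[IBS | IBD=2] = 1

so a relationship with IBD-state probabilities ``(k0, k1, k2)`` has a
per-locus excess over unrelated of ``k2*2pq(1-pq) + k1*pq(1-2pq)``,
which :func:`expected_ibs` evaluates in closed form and
:func:`enumerate_expected_ibs` reproduces by brute force over the 9x9
genotype-pair table.  :func:`expected_normalized_ibs` integrates the
ratio-of-averages over a MAF spectrum; note that because mean IBS is not
linear in kinship, full sibs and parent-offspring pairs do *not* share an
expectation (e.g. 0.4365 vs 0.3731 for MAF ~ U(0.05, 0.5)), and the
full-sib value sits below the naive first-order guess of 1/2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .matrix import GenotypeMatrix

#: IBD-state probabilities (k0, k1, k2) for standard relationships.
RELATIONSHIPS: dict[str, tuple[float, float, float]] = {
    "unrelated": (1.0, 0.0, 0.0),
    "half_sib": (0.5, 0.5, 0.0),
    "parent_offspring": (0.0, 1.0, 0.0),
    "full_sib": (0.25, 0.5, 0.25),
    "self": (0.0, 0.0, 1.0),
}


# ---------------------------------------------------------------------------
# Pairwise scoring


def pairwise_ibs(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """IBS score and number of co-called loci for one pair of dosage vectors.

    Returns ``(nan, 0)`` when no locus is co-called (a missing result, not a
    similarity of zero).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    both = ~np.isnan(a) & ~np.isnan(b)
    n = int(both.sum())
    if n == 0:
        return float("nan"), 0
    score = 1.0 - np.abs(a[both] - b[both]) / 2.0
    return float(score.mean()), n


@dataclass
class IBSMatrix:
    sample_ids: list[str]
    values: np.ndarray  # square, [0, 1], NaN where overlap below threshold
    n_overlap: np.ndarray  # square int

    def value(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])


@dataclass
class NormalizedIBSMatrix:
    sample_ids: list[str]
    values: np.ndarray  # square, <= 1, may be negative
    n_overlap: np.ndarray
    anchor_value: float
    anchor_groups: tuple[str, str] | None = None

    def value(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])


def ibs_matrix(g: GenotypeMatrix, min_overlap: int = 500) -> IBSMatrix:
    """All-pairs IBS with a pairwise-complete locus rule.

    Pairs sharing fewer than ``min_overlap`` co-called loci are reported as
    missing (NaN) rather than as unreliable numbers.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    X = g.dosage
    called = ~np.isnan(X)
    n = g.n_samples
    values = np.full((n, n), np.nan)
    overlap = np.zeros((n, n), dtype=int)
    Xz = np.where(called, X, 0.0)
    for i in range(n):
        both = called[i] & called
        cnt = both.sum(axis=1)
        diff = np.abs(Xz[i] - Xz)
        score = np.where(both, 1.0 - diff / 2.0, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(cnt > 0, score / np.maximum(cnt, 1), np.nan)
        vals = np.where(cnt >= min_overlap, vals, np.nan)
        values[i] = vals
        overlap[i] = cnt
    return IBSMatrix(list(g.sample_ids), values, overlap)


# ---------------------------------------------------------------------------
# Anchor and normalization


def anchor_value(
    m: IBSMatrix, groups: dict[str, str]
) -> tuple[float, tuple[str, str]]:
    """Mean cross-group IBS for the most genetically distinct group pair.

    For every unordered pair of group labels the mean of the cross-group IBS
    entries (self-pairs and NaN excluded) is computed; the minimum mean and
    its group pair are returned.  Ties break toward the lexicographically
    smallest group pair.  Group pairs with no valid entries are skipped; if
    no pair has valid entries a ``ValueError`` is raised.
    """
    labels = sorted({groups[s] for s in m.sample_ids if s in groups})
    if len(labels) < 2:
        raise ValueError("anchor needs at least two groups")
    idx_by_label = {
        lab: [i for i, s in enumerate(m.sample_ids) if groups.get(s) == lab]
        for lab in labels
    }
    best: tuple[float, tuple[str, str]] | None = None
    for ga, gb in itertools.combinations(labels, 2):
        block = m.values[np.ix_(idx_by_label[ga], idx_by_label[gb])]
        block = block[~np.isnan(block)]
        if block.size == 0:
            continue
        cand = (float(block.mean()), (ga, gb))
        if best is None or cand < best:
            best = cand
    if best is None:
        raise ValueError("no group pair with valid IBS entries")
    return best


def normalize_ibs(m: IBSMatrix, av_min: float) -> NormalizedIBSMatrix:
    """Apply ``(IBS - av_min) / (1 - av_min)`` elementwise.

    The diagonal stays exactly 1; entries below the anchor become negative.
    No small-denominator regularization is applied — ``av_min`` must be < 1.
    """
    if not av_min < 1.0:
        raise ValueError(f"degenerate anchor: av_min={av_min} >= 1")
    values = (m.values - av_min) / (1.0 - av_min)
    np.fill_diagonal(values, np.where(np.isnan(np.diag(m.values)), np.nan, 1.0))
    return NormalizedIBSMatrix(
        list(m.sample_ids), values, m.n_overlap.copy(), float(av_min)
    )


def normalized_ibs_matrix(
    g: GenotypeMatrix, groups: dict[str, str], min_overlap: int = 500
) -> NormalizedIBSMatrix:
    """Convenience: IBS matrix -> anchor on ``groups`` -> normalization."""
    m = ibs_matrix(g, min_overlap=min_overlap)
    av_min, pair = anchor_value(m, groups)
    out = normalize_ibs(m, av_min)
    out.anchor_groups = pair
    return out


# ---------------------------------------------------------------------------
# Classification


@dataclass
class KinshipThresholds:
    """Interval bounds on normalized IBS for pair categories.

    Defaults follow midpoints between the observed class means for this
    marker panel style (full sibs ~0.49, half sibs ~0.30, unrelated ~0):
    >=0.90 duplicate, >=0.40 full-sib-or-parent-offspring, [0.18, 0.40)
    half-sib, <0.18 unrelated.
    """

    duplicate: float = 0.90
    full_sib: float = 0.40
    half_sib: float = 0.18

    def __post_init__(self) -> None:
        if not (self.duplicate > self.full_sib > self.half_sib):
            raise ValueError("thresholds must be ordered duplicate > full > half")


@dataclass
class KinshipCall:
    sample_a: str
    sample_b: str
    value: float
    n_overlap: int
    category: str


def classify_pair(
    value: float, thresholds: KinshipThresholds | None = None
) -> str:
    thresholds = thresholds or KinshipThresholds()
    if value >= thresholds.duplicate:
        return "duplicate"
    if value >= thresholds.full_sib:
        return "full_sib_or_parent_offspring"
    if value >= thresholds.half_sib:
        return "half_sib"
    return "unrelated"


def classify_matrix(
    m: NormalizedIBSMatrix, thresholds: KinshipThresholds | None = None
) -> list[KinshipCall]:
    """One call per unordered sample pair with a valid normalized value."""
    calls = []
    for i, a in enumerate(m.sample_ids):
        for j in range(i + 1, len(m.sample_ids)):
            v = m.values[i, j]
            if np.isnan(v):
                continue
            calls.append(
                KinshipCall(
                    a,
                    m.sample_ids[j],
                    float(v),
                    int(m.n_overlap[i, j]),
                    classify_pair(float(v), thresholds),
                )
            )
    return calls


def calls_to_frame(calls: list[KinshipCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_a": c.sample_a,
                "sample_b": c.sample_b,
                "nibs": c.value,
                "n_overlap": c.n_overlap,
                "category": c.category,
            }
            for c in calls
        ],
        columns=["sample_a", "sample_b", "nibs", "n_overlap", "category"],
    )


# ---------------------------------------------------------------------------
# Export


def export_matrix(
    m: IBSMatrix | NormalizedIBSMatrix,
    path,
    groups: dict[str, str] | None = None,
    heatmap_path=None,
) -> None:
    """Write a TSV matrix (samples ordered by group then ID), optional heatmap."""
    order = sorted(
        range(len(m.sample_ids)),
        key=lambda i: (groups.get(m.sample_ids[i], "") if groups else "", m.sample_ids[i]),
    )
    ids = [m.sample_ids[i] for i in order]
    df = pd.DataFrame(m.values[np.ix_(order, order)], index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="sample_id")
    if heatmap_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 7))
        im = ax.imshow(df.to_numpy(), cmap="RdYlGn_r", vmin=-0.2, vmax=1.0)
        ax.set_xticks(range(len(ids)))
        ax.set_yticks(range(len(ids)))
        ax.set_xticklabels(ids, rotation=90, fontsize=4)
        ax.set_yticklabels(ids, fontsize=4)
        fig.colorbar(im, ax=ax, label="normalized IBS")
        fig.tight_layout()
        fig.savefig(heatmap_path, dpi=200)
        plt.close(fig)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# Analytic calibration


def expected_ibs(p: float, k: tuple[float, float, float]) -> float:
    """Closed-form per-locus E[IBS] for IBD probabilities ``k = (k0, k1, k2)``."""
    q = 1.0 - p
    e0 = 1.0 - 2.0 * p * q * (1.0 - p * q)
    e1 = 1.0 - p * q
    k0, k1, k2 = k
    return k0 * e0 + k1 * e1 + k2


def enumerate_expected_ibs(p: float, k: tuple[float, float, float]) -> float:
    """Brute-force E[IBS]: sum over the 9x9 genotype-pair table per IBD state.

    Independent oracle for :func:`expected_ibs`; kept free of any shared
    algebra with it on purpose.
    """
    q = 1.0 - p
    hwe = [q * q, 2 * p * q, p * p]

    def score(d1: int, d2: int) -> float:
        return 1.0 - abs(d1 - d2) / 2.0

    e_ibd0 = sum(
        hwe[d1] * hwe[d2] * score(d1, d2) for d1 in range(3) for d2 in range(3)
    )
    # IBD=1: one allele identical by descent, remaining alleles independent.
    e_ibd1 = 0.0
    for a, pa in ((1, p), (0, q)):
        for x, px in ((1, p), (0, q)):
            for y, py in ((1, p), (0, q)):
                e_ibd1 += pa * px * py * score(a + x, a + y)
    e_ibd2 = sum(hwe[d] * score(d, d) for d in range(3))
    k0, k1, k2 = k
    return k0 * e_ibd0 + k1 * e_ibd1 + k2 * e_ibd2


def expected_normalized_ibs(
    relationship: str | tuple[float, float, float],
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> float:
    """Exact E[normalized IBS] for a relationship under a uniform MAF spectrum.

    The anchor is taken to be unrelated individuals from the same population,
    so the expectation is the ratio of MAF-averaged excess IBS to
    MAF-averaged (1 - E[IBS | unrelated]), matching the multi-locus
    ratio-of-averages structure of the statistic.
    """
    k = RELATIONSHIPS[relationship] if isinstance(relationship, str) else relationship
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    if lo == hi:
        e0 = expected_ibs(lo, RELATIONSHIPS["unrelated"])
        return (expected_ibs(lo, k) - e0) / (1.0 - e0)

    def excess(p: float) -> float:
        return expected_ibs(p, k) - expected_ibs(p, RELATIONSHIPS["unrelated"])

    def denom(p: float) -> float:
        return 1.0 - expected_ibs(p, RELATIONSHIPS["unrelated"])

    num = quad(excess, lo, hi)[0]
    den = quad(denom, lo, hi)[0]
    return num / den
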