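"""Count-level RNA-seq pipeline for the transcriptomic stage of the screen.

From a gene x sample count matrix onward: robust library-size (TMM-style)
scaling, transcript-length normalization, kernel-density active-expression
thresholding, a negative-binomial Wald test per line-vs-control contrast
with Benjamini-Hochberg correction, DEG calling at adjusted p < 1e-4
(optionally plus a fold-change criterion), Venn partitioning across lines,
subtraction of effector-generic "background" DEGs, label-based category
enrichment (hypergeometric), and efficiency-corrected qPCR normalization.

The differential-expression test is a deliberately transparent
negative-binomial Wald test: per-gene method-of-moments dispersions are
shrunk toward the common dispersion and the log-ratio of pseudo-counted
group means is compared to its delta-method standard error.  Its contract
is calibration (near-nominal type-I error) and power against planted
effects, not replication of any particular external DE package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# containers

@dataclass
class CountMatrix:
    """Integer gene x sample counts with per-sample group/replicate labels."""

    counts: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            gene, sample = np.argwhere(self.counts.values < 0)[0]
            raise ValueError(
                "negative count for gene "
                f"{self.counts.index[gene]!r} in sample "
                f"{self.counts.columns[sample]!r}"
            )
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicated gene ids: {list(dups[:5])}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, group: str) -> List[str]:
        sel = [s for s in self.samples if self.groups[s] == group]
        if not sel:
            raise KeyError(f"no samples in group {group!r}")
        return sel


@dataclass
class QpcrRecord:
    """Cq values for a target gene and two reference genes in one sample."""

    sample_id: str
    cq_target: float
    cq_ref1: float
    cq_ref2: float
    efficiency: float = 2.0


# ---------------------------------------------------------------------------
# normalization

def _tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> float:
    """Trimmed mean of M-values of one sample against the reference."""
    mask = (obs > 0) & (ref > 0)
    obs_p, ref_p = obs[mask] / lib_obs, ref[mask] / lib_ref
    m = np.log2(obs_p / ref_p)
    a = 0.5 * np.log2(obs_p * ref_p)
    # precision weights from the delta method on binomial counts
    w = (lib_obs - obs[mask]) / (lib_obs * obs[mask]) + (
        lib_ref - ref[mask]
    ) / (lib_ref * ref[mask])
    n = m.size
    if n == 0:
        return 1.0
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abundance_trim) + 1, n - np.floor(n * abundance_trim)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        # heavy ties can push whole rank blocks outside the trim window;
        # fall back to the untrimmed weighted mean
        keep = np.ones(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def estimate_size_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Robust per-sample scale factors by trimmed mean of M-values (TMM).

    M-values (log count-proportion ratios against a reference sample) are
    trimmed at 30% on each tail and A-values (mean log abundance) at 5%,
    and the precision-weighted mean of the rest gives each sample's scale
    factor relative to the reference.  Factors are normalized to geometric
    mean 1; they multiply the raw library size to give an effective library
    size robust to a minority of highly differential genes.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0]
        raise ValueError(f"all-zero samples: {list(bad)}")
    # reference: sample whose 75th count-proportion percentile is most typical
    q75 = np.percentile(mat / lib, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_factor(
                mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, abundance_trim,
            )
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def effective_library_sizes(
    counts: pd.DataFrame, size_factors: Optional[pd.Series] = None
) -> pd.Series:
    """Library size x TMM factor, rescaled to mean 1 across samples."""
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    eff = counts.sum(axis=0) * size_factors
    return eff / eff.mean()


def normalize(
    counts: pd.DataFrame,
    lengths_kbp: pd.Series,
    size_factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Depth- and length-normalized expression values.

    Each count is divided by the sample's effective relative library size
    (raw depth x TMM factor, so doubling every count of a sample leaves its
    values unchanged) and by the gene's mean annotated transcript length in
    kbp.  Raises when any gene lacks a length annotation.
    """
    missing = counts.index.difference(lengths_kbp.index)
    if len(missing) > 0:
        raise ValueError(
            f"genes without transcript length: {list(missing[:10])}"
        )
    lengths = lengths_kbp.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0]
        raise ValueError(f"nonpositive transcript lengths: {list(bad[:10])}")
    eff = effective_library_sizes(counts, size_factors)
    return counts.div(eff, axis=1).div(lengths, axis=0)


# ---------------------------------------------------------------------------
# active-expression thresholding

def _sample_active(
    values: np.ndarray, z_min: float, min_positive: int
) -> Tuple[np.ndarray, float, float]:
    positive = values > 0
    if positive.sum() < min_positive:
        raise ValueError(
            f"only {positive.sum()} genes with positive expression; "
            f"need >= {min_positive} for density estimation"
        )
    x = np.log2(values[positive])
    if np.ptp(x) == 0:
        raise ValueError(
            "degenerate expression distribution: all positive values equal; "
            "cannot locate a density mode"
        )
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    mu = float(grid[np.argmax(kde(grid))])
    upper = x[x > mu]
    if upper.size == 0:
        raise ValueError("no expression values above the density mode")
    sigma = float((upper.mean() - mu) * np.sqrt(np.pi / 2.0))
    z = np.full(values.size, -np.inf)
    z[positive] = (x - mu) / sigma
    return z > z_min, mu, sigma


def active_genes(
    expr: pd.DataFrame,
    groups: Optional[pd.Series] = None,
    z_min: float = -3.0,
    min_positive: int = 100,
) -> pd.Series:
    """Distinguish actively expressed genes from background noise.

    Per sample, the log2 distribution of positive expression values is
    kernel-density smoothed; the density maximum locates the mean mu of the
    active population, and sigma is estimated from the right half of the
    peak as (mean of values above mu - mu) * sqrt(pi/2) (the half-normal
    correction).  A gene is active in a sample when its z-score
    (x - mu)/sigma exceeds ``z_min`` (default -3), and globally active when
    active in every replicate of at least one group.  Without ``groups``
    each sample is its own group.
    """
    active = pd.DataFrame(index=expr.index, columns=expr.columns, dtype=bool)
    for sample in expr.columns:
        flags, _, _ = _sample_active(
            expr[sample].to_numpy(dtype=float), z_min, min_positive
        )
        active[sample] = flags
    if groups is None:
        return active.any(axis=1)
    result = pd.Series(False, index=expr.index)
    for group in pd.unique(groups.loc[expr.columns]):
        cols = [s for s in expr.columns if groups[s] == group]
        result |= active[cols].all(axis=1)
    return result


# ---------------------------------------------------------------------------
# differential expression

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def de_test(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    dispersion_shrinkage: float = 0.8,
    size_factors: Optional[pd.Series] = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test of ``group_a`` versus ``group_b``.

    Counts are scaled to a common effective depth, per-gene NB dispersions
    are estimated by the method of moments and shrunk toward the common
    dispersion with weight ``dispersion_shrinkage`` (1 = fully common), and
    the Wald statistic is

        z = (log m_a - log m_b) / sqrt(V_a + V_b),
        V_g = (1/n_g) * (1/m_g + phi),

    the delta-method variance of the log of an NB group mean.  Group means
    carry a pseudo-count (default 0.5) so zero-count groups yield finite
    log fold changes.  Returns a table with columns ``log2fc``, ``pvalue``,
    ``padj``, ``base_mean``; positive log2fc means higher in ``group_a``.
    """
    if not 0.0 <= dispersion_shrinkage <= 1.0:
        raise ValueError("dispersion_shrinkage must be in [0, 1]")
    samples_a = counts.samples_of(group_a)
    samples_b = counts.samples_of(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >= 2 replicates per group; got {len(samples_a)} in "
            f"{group_a!r} and {len(samples_b)} in {group_b!r}"
        )
    sub = counts.counts[samples_a + samples_b]
    eff = effective_library_sizes(sub, size_factors)
    norm = sub.div(eff, axis=1).to_numpy(dtype=float)
    na, nb = len(samples_a), len(samples_b)
    ya, yb = norm[:, :na], norm[:, na:]

    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    # method-of-moments dispersion pooled across both groups
    def _phi(y: np.ndarray, m: np.ndarray) -> np.ndarray:
        v = y.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v - m) / np.square(m)
        return np.where(np.isfinite(phi), phi, 0.0)

    phi_gene = np.clip((_phi(ya, ma) + _phi(yb, mb)) / 2.0, 0.0, None)
    informative = (ma > 0) & (mb > 0)
    phi_common = float(phi_gene[informative].mean()) if informative.any() else 0.0
    w = dispersion_shrinkage
    phi = np.clip((1.0 - w) * phi_gene + w * phi_common, 1e-8, None)

    ma_p, mb_p = ma + pseudocount, mb + pseudocount
    log_ratio = np.log(ma_p) - np.log(mb_p)
    var = (1.0 / ma_p + phi) / na + (1.0 / mb_p + phi) / nb
    z = log_ratio / np.sqrt(var)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.minimum(pvalue, 1.0)
    # identical raw counts in both groups carry no evidence
    identical = np.isclose(ma, mb)
    pvalue[identical] = 1.0

    table = pd.DataFrame(
        {
            "base_mean": (ma + mb) / 2.0,
            "log2fc": log_ratio / np.log(2.0),
            "stat": z,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "dispersion": phi,
        },
        index=sub.index,
    )
    table.attrs["contrast"] = f"{group_a}_vs_{group_b}"
    return table


def call_degs(
    table: pd.DataFrame,
    alpha: float = 1e-4,
    min_fold: Optional[float] = None,
) -> Tuple[Set[str], Set[str]]:
    """Call DEGs at adjusted p < alpha, optionally requiring |FC| >= min_fold.

    The default alpha 1e-4 is the compromise threshold for screens where a
    plain 0.05 cut floods the list and a 2-fold criterion discards highly
    expressed genes with small but extremely significant changes.  Returns
    (up, down) gene-id sets split by the sign of log2fc.
    """
    if table.empty:
        return set(), set()
    sig = table["padj"] < alpha
    if min_fold is not None:
        sig &= table["log2fc"].abs() >= np.log2(min_fold)
    up = set(table.index[sig & (table["log2fc"] > 0)])
    down = set(table.index[sig & (table["log2fc"] < 0)])
    return up, down


# ---------------------------------------------------------------------------
# set algebra and enrichment

def venn_partition(deg_sets: Mapping[str, Set[str]]) -> Dict[frozenset, int]:
    """Counts for every non-empty membership region of named gene sets.

    Keys are frozensets of set names; the value is the number of genes
    belonging to exactly those sets.  Region counts sum to the union size.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least two sets for a Venn partition")
    names = list(deg_sets)
    regions: Dict[frozenset, int] = {}
    universe = set().union(*deg_sets.values())
    for gene in universe:
        key = frozenset(n for n in names if gene in deg_sets[n])
        regions[key] = regions.get(key, 0) + 1
    return regions


def background_subtract(
    line_deg_sets: Mapping[str, Set[str]],
    background_deg_sets: Optional[Mapping[str, Set[str]]] = None,
) -> Set[str]:
    """DEGs shared by all selected lines but absent from every background pool.

    Background pools hold plants expressing related ZF-ATFs of the same
    effector class without the selected phenotype; subtracting their DEGs
    removes effector-generic expression changes, leaving candidate
    phenotype-associated genes: (intersection of line sets) minus (union of
    background sets).
    """
    if not line_deg_sets:
        raise ValueError("no line DEG sets given")
    shared = set.intersection(*(set(s) for s in line_deg_sets.values()))
    if background_deg_sets:
        shared -= set().union(*background_deg_sets.values())
    return shared


def category_enrichment(
    deg_set: Iterable[str],
    labels: pd.Series,
    universe: Optional[Iterable[str]] = None,
) -> Tuple[float, float]:
    """Fraction of a gene set carrying a boolean label, with hypergeometric p.

    ``labels`` maps every universe gene to True/False (e.g. annotated as
    chloroplast-localized).  Returns (labeled fraction of the set,
    upper-tail hypergeometric probability of at least that many labeled
    genes when drawing |set| genes from the universe).
    """
    genes = set(deg_set)
    if not genes:
        raise ValueError("deg_set is empty")
    if universe is not None:
        labels = labels.loc[list(universe)]
    outside = genes - set(labels.index)
    if outside:
        raise ValueError(f"genes not in universe: {list(outside)[:5]}")
    n_universe = len(labels)
    n_labeled = int(labels.sum())
    n_set = len(genes)
    k = int(labels.loc[list(genes)].sum())
    fraction = k / n_set
    p = float(stats.hypergeom.sf(k - 1, n_universe, n_labeled, n_set))
    return fraction, p


# ---------------------------------------------------------------------------
# QC and qPCR

def flag_replicate_outliers(
    expr: pd.DataFrame, groups: pd.Series, k: float = 5.0
) -> pd.Series:
    """Flag replicates unusually far from their group centroid.

    Distances are Euclidean on log2(expression + 1) to the component-wise
    *median* of the group's replicates (robust to the outlier itself); a
    sample is flagged when its distance exceeds the median distance by more
    than ``k`` times the MAD of all distances.  Flagging only — excluding a
    replicate is a user decision.
    """
    logx = np.log2(expr + 1.0)
    dist = pd.Series(0.0, index=expr.columns)
    for group in pd.unique(groups.loc[expr.columns]):
        cols = [s for s in expr.columns if groups[s] == group]
        centroid = logx[cols].median(axis=1)
        for s in cols:
            dist[s] = np.sqrt(((logx[s] - centroid) ** 2).sum())
    mad = float(stats.median_abs_deviation(dist, scale="normal"))
    if mad == 0:
        return pd.Series(False, index=expr.columns)
    return (dist - dist.median()) > k * mad


def qpcr_relative_expression(record: QpcrRecord) -> float:
    """Efficiency-corrected expression relative to two reference genes.

    Computes E^(mean(Cq_ref1, Cq_ref2) - Cq_target): the target's
    E^(-Cq) expression value divided by the geometric mean of the two
    reference genes' values.  Amplification efficiency E defaults to 2
    (perfect doubling per cycle) and must lie in (1, 2].
    """
    e = record.efficiency
    if not 1.0 < e <= 2.0:
        raise ValueError(f"amplification efficiency must be in (1, 2], got {e}")
    for name, cq in (
        ("cq_target", record.cq_target),
        ("cq_ref1", record.cq_ref1),
        ("cq_ref2", record.cq_ref2),
    ):
        if cq <= 0:
            raise ValueError(f"{name} must be positive, got {cq}")
    mean_ref = (record.cq_ref1 + record.cq_ref2) / 2.0
    return float(e ** (mean_ref - record.cq_target))
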