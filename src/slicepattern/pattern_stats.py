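"""Pattern classification, pattern-change quantification, and the
differential-response statistic.

All distances are unit-mass 1-D EMDs from :mod:`slicepattern.profiles`.
Genotype-level quantities aggregate replicates by averaging over all cross
pairs of embryos (configurable to min/median).

The differential-response score for a gene compared across two mutants M1,
M2 and wild type is::

    delta_d = EMD(M1, M2) - |EMD(M1, WT) - EMD(M2, WT)|

which is zero when the two mutant patterns coincide, zero when either mutant
equals wild type, and non-negative because EMD is a metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .profiles import (SliceProfile, emd_matrix, emd_to_uniform,
                       impute_bad_slices, max_normalize)
from .synthetic import EXPRESSED_FPKM, EmbryoSample

__all__ = [
    "PatternClass",
    "DeltaDRecord",
    "TransitionTable",
    "TRANSITIONS",
    "classify_pattern",
    "classify_cohort",
    "transition_table",
    "pattern_change",
    "pattern_change_table",
    "delta_d",
    "delta_d_table",
    "change_flags",
    "co_change_test",
    "top_changed_genes",
    "average_pattern",
    "cluster_genes",
    "level_response",
]

UNIFORM_EMD = 0.04
PATTERNED_EMD = 0.08

_AGGREGATORS = {"mean": np.mean, "median": np.median, "min": np.min}


@dataclass(frozen=True)
class PatternClass:
    """Per-gene, per-genotype spatial class."""

    gene_id: str
    genotype: str
    label: str  # low_expression | uniform | ambiguous | patterned
    emd_to_uniform: float | None


@dataclass(frozen=True)
class DeltaDRecord:
    gene_id: str
    d_m1_m2: float
    d_m1_wt: float
    d_m2_wt: float
    delta_d: float


@dataclass(frozen=True)
class TransitionTable:
    """Counts of the four reported class transitions plus a remainder cell.

    The universe is every gene expressed (not low_expression) in at least one
    of the two genotypes; genes with an ambiguous class in either genotype are
    excluded from the named cells and counted in ``excluded_ambiguous``.
    """

    low_to_patterned: int
    patterned_to_uniform: int
    patterned_to_low: int
    uniform_to_patterned: int
    remainder: int
    excluded_ambiguous: int

    @property
    def total(self) -> int:
        return (self.low_to_patterned + self.patterned_to_uniform
                + self.patterned_to_low + self.uniform_to_patterned
                + self.remainder + self.excluded_ambiguous)


TRANSITIONS = (
    ("low_expression", "patterned", "low_to_patterned"),
    ("patterned", "uniform", "patterned_to_uniform"),
    ("patterned", "low_expression", "patterned_to_low"),
    ("uniform", "patterned", "uniform_to_patterned"),
)


def _gene_profiles(embryos, gene_id=None):
    for e in embryos:
        idx = e.gene_ids.index(gene_id)
        yield SliceProfile(gene_id, e.embryo_id, e.values[idx], e.qc_mask)


def classify_pattern(gene_id: str, embryos: list[EmbryoSample],
                     expressed_fpkm: float = EXPRESSED_FPKM,
                     uniform_emd: float = UNIFORM_EMD,
                     patterned_emd: float = PATTERNED_EMD) -> PatternClass:
    """Classify one gene within one genotype (replicate embryos).

    The expression test uses raw FPKM: low_expression iff the max over slices
    is below ``expressed_fpkm`` in every replicate.  Otherwise the EMD to a
    uniform distribution is computed per embryo (after imputing QC-failed
    slices) and averaged; thresholds are applied to the mean.
    """
    if not embryos:
        raise ValueError("no embryos supplied")
    profiles = [impute_bad_slices(p) for p in _gene_profiles(embryos, gene_id)]
    if all(p.values.max() < expressed_fpkm for p in profiles):
        return PatternClass(gene_id, embryos[0].genotype, "low_expression", None)
    d = float(np.mean([emd_to_uniform(p) for p in profiles
                       if p.values.sum() > 0]))
    if d < uniform_emd:
        label = "uniform"
    elif d > patterned_emd:
        label = "patterned"
    else:
        label = "ambiguous"
    return PatternClass(gene_id, embryos[0].genotype, label, d)


def classify_cohort(embryos: list[EmbryoSample],
                    expressed_fpkm: float = EXPRESSED_FPKM,
                    uniform_emd: float = UNIFORM_EMD,
                    patterned_emd: float = PATTERNED_EMD) -> pd.DataFrame:
    """Vectorised classification of all genes across replicate embryos.

    Equivalent to :func:`classify_pattern` per gene; returns a DataFrame with
    gene_id, genotype, label, emd_to_uniform.
    """
    if not embryos:
        raise ValueError("no embryos supplied")
    gene_ids = embryos[0].gene_ids
    per_embryo_d = []
    expressed_any = np.zeros(len(gene_ids), dtype=bool)
    for e in embryos:
        values = _impute_matrix(e)
        expressed_any |= values.max(axis=1) >= expressed_fpkm
        n = values.shape[1]
        uniform = np.full((len(gene_ids), n), 1.0 / n) * values.sum(
            axis=1, keepdims=True)
        # rows with zero total give NaN; treated as maximally uninformative
        per_embryo_d.append(emd_matrix(values, uniform))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_d = np.nanmean(np.stack(per_embryo_d), axis=0)
    labels = np.where(mean_d < uniform_emd, "uniform",
                      np.where(mean_d > patterned_emd, "patterned", "ambiguous"))
    labels = np.where(expressed_any, labels, "low_expression")
    out = pd.DataFrame({
        "gene_id": gene_ids,
        "genotype": embryos[0].genotype,
        "label": labels,
        "emd_to_uniform": np.where(expressed_any, mean_d, np.nan),
    })
    return out


def _impute_matrix(e: EmbryoSample) -> np.ndarray:
    """Matrix-level adjacent-slice imputation of QC-failed slices."""
    if e.qc_mask.all():
        return e.values
    if not e.qc_mask.any():
        raise ValueError(f"embryo {e.embryo_id}: all slices failed QC")
    values = e.values.copy()
    good = np.flatnonzero(e.qc_mask)
    for i in np.flatnonzero(~e.qc_mask):
        left = good[good < i]
        right = good[good > i]
        if left.size and right.size:
            values[:, i] = 0.5 * (values[:, left[-1]] + values[:, right[0]])
        elif left.size:
            values[:, i] = values[:, left[-1]]
        else:
            values[:, i] = values[:, right[0]]
    return values


def transition_table(wt_classes: pd.DataFrame,
                     mut_classes: pd.DataFrame) -> TransitionTable:
    """Tabulate wild-type -> mutant class transitions.

    Both inputs are ``classify_cohort`` frames over the same gene universe.
    """
    wt = wt_classes.set_index("gene_id")["label"]
    mut = mut_classes.set_index("gene_id")["label"]
    if set(wt.index) != set(mut.index):
        raise ValueError("wild-type and mutant gene sets differ")
    mut = mut.reindex(wt.index)
    expressed = (wt != "low_expression") | (mut != "low_expression")
    wt, mut = wt[expressed], mut[expressed]
    ambiguous = (wt == "ambiguous") | (mut == "ambiguous")
    counts = {}
    named = np.zeros(len(wt), dtype=bool)
    for src, dst, attr in TRANSITIONS:
        hit = (wt == src) & (mut == dst) & ~ambiguous
        counts[attr] = int(hit.sum())
        named |= hit.to_numpy()
    return TransitionTable(
        remainder=int((~named & ~ambiguous.to_numpy()).sum()),
        excluded_ambiguous=int(ambiguous.sum()),
        **counts)


def pattern_change(gene_id: str, embryos_a: list[EmbryoSample],
                   embryos_b: list[EmbryoSample],
                   expressed_fpkm: float = EXPRESSED_FPKM,
                   aggregate: str = "mean") -> float | None:
    """Pattern distance of one gene between two genotypes.

    Aggregates EMD over all cross pairs (replicate of a x replicate of b).
    Returns None when the gene fails the expression filter in both genotypes.
    """
    table = pattern_change_table(embryos_a, embryos_b, expressed_fpkm, aggregate)
    val = table.set_index("gene_id").loc[gene_id, "emd"]
    return None if np.isnan(val) else float(val)


def pattern_change_table(embryos_a, embryos_b,
                         expressed_fpkm: float = EXPRESSED_FPKM,
                         aggregate: str = "mean") -> pd.DataFrame:
    """Per-gene cross-pair EMD between two genotype replicate groups.

    Genes unexpressed (< ``expressed_fpkm`` in every slice) in both groups get
    NaN, as do genes whose profile is all-zero in any compared embryo.
    """
    if not embryos_a or not embryos_b:
        raise ValueError("both genotype groups need at least one embryo")
    agg = _AGGREGATORS[aggregate]
    gene_ids = embryos_a[0].gene_ids
    mats_a = [_impute_matrix(e) for e in embryos_a]
    mats_b = [_impute_matrix(e) for e in embryos_b]
    pair_d = [emd_matrix(ma, mb) for ma in mats_a for mb in mats_b]
    stacked = np.stack(pair_d)
    d = np.where(np.any(np.isnan(stacked), axis=0), np.nan,
                 agg(stacked, axis=0))
    expressed = np.zeros(len(gene_ids), dtype=bool)
    for m in mats_a + mats_b:
        expressed |= m.max(axis=1) >= expressed_fpkm
    d = np.where(expressed, d, np.nan)
    return pd.DataFrame({"gene_id": gene_ids, "emd": d})


def delta_d(gene_id: str, wt_embryos, m1_embryos, m2_embryos,
            expressed_fpkm: float = EXPRESSED_FPKM,
            aggregate: str = "mean") -> DeltaDRecord:
    """Differential-response score of one gene across WT and two mutants."""
    table = delta_d_table(wt_embryos, m1_embryos, m2_embryos,
                          expressed_fpkm, aggregate)
    row = table.set_index("gene_id").loc[gene_id]
    if row.isna().any():
        raise ValueError(
            f"gene {gene_id} fails the expression filter in some genotype")
    return DeltaDRecord(gene_id, float(row.d_m1_m2), float(row.d_m1_wt),
                        float(row.d_m2_wt), float(row.delta_d))


def delta_d_table(wt_embryos, m1_embryos, m2_embryos,
                  expressed_fpkm: float = EXPRESSED_FPKM,
                  aggregate: str = "mean") -> pd.DataFrame:
    """Per-gene delta-D over the whole cohort (NaN where inputs are missing)."""
    for group, name in ((wt_embryos, "wt"), (m1_embryos, "m1"), (m2_embryos, "m2")):
        if not group:
            raise ValueError(f"missing genotype group: {name}")
    d12 = pattern_change_table(m1_embryos, m2_embryos, expressed_fpkm, aggregate)
    d1w = pattern_change_table(m1_embryos, wt_embryos, expressed_fpkm, aggregate)
    d2w = pattern_change_table(m2_embryos, wt_embryos, expressed_fpkm, aggregate)
    out = pd.DataFrame({
        "gene_id": d12["gene_id"],
        "d_m1_m2": d12["emd"],
        "d_m1_wt": d1w["emd"],
        "d_m2_wt": d2w["emd"],
    })
    out["delta_d"] = out["d_m1_m2"] - (out["d_m1_wt"] - out["d_m2_wt"]).abs()
    return out


def change_flags(distances: pd.Series, quantile: float = 0.80) -> pd.Series:
    """Flag genes in the top (1 - quantile) tail of a distance distribution.

    The cutoff is the empirical order statistic at rank
    ``floor(quantile * n) + 1`` (1-based); genes at or above the cutoff are
    flagged, so boundary ties are included.  A constant vector flags nothing.
    """
    distances = distances.dropna()
    n = len(distances)
    if n < 5:
        raise ValueError("need at least 5 genes")
    values = distances.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        warnings.warn("all distances equal; flagging no genes")
        return pd.Series(False, index=distances.index)
    rank = int(np.floor(quantile * n))  # number of genes left unflagged
    if rank >= n:
        return pd.Series(False, index=distances.index)
    cutoff = np.sort(values)[rank]
    return pd.Series(values >= cutoff, index=distances.index)


def co_change_test(flags_a: pd.Series, flags_b: pd.Series):
    """Pearson chi-squared test of independence of change between genotypes.

    Returns (chi2, p, ratio) where ratio = observed both-changed count over
    the count expected under independence.
    """
    if not flags_a.index.equals(flags_b.index):
        flags_b = flags_b.reindex(flags_a.index)
        if flags_b.isna().any():
            raise ValueError("flag vectors cover different gene sets")
    a = flags_a.to_numpy(dtype=bool)
    b = flags_b.to_numpy(dtype=bool)
    table = np.array([[np.sum(a & b), np.sum(a & ~b)],
                      [np.sum(~a & b), np.sum(~a & ~b)]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table: zero margin")
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn("chi-squared expected cell count below 5")
    n = table.sum()
    expected_both = n * (a.mean()) * (b.mean())
    ratio = table[0, 0] / expected_both if expected_both > 0 else np.inf
    return float(res.statistic), float(res.pvalue), float(ratio)


def top_changed_genes(distances: pd.Series, n: int = 100) -> list[str]:
    """The n genes with the largest distance, ties broken by gene_id."""
    distances = distances.dropna()
    if n > len(distances):
        raise ValueError(f"asked for top {n} of {len(distances)} genes")
    df = distances.rename("d").rename_axis("gene_id").reset_index()
    df = df.sort_values(["d", "gene_id"], ascending=[False, True],
                        kind="mergesort")
    return df["gene_id"].head(n).tolist()


def average_pattern(gene_ids, embryo: EmbryoSample,
                    floor: float = 10.0) -> np.ndarray:
    """Slice-wise mean of max-normalised profiles of the given genes."""
    if not gene_ids:
        raise ValueError("empty gene list")
    values = _impute_matrix(embryo)
    idx = [embryo.gene_ids.index(g) for g in gene_ids]
    normed = np.stack([max_normalize(values[i], floor) for i in idx])
    return normed.mean(axis=0)


def cluster_genes(embryos: list[EmbryoSample],
                  expressed_fpkm: float = EXPRESSED_FPKM):
    """Hierarchically cluster genes by mean EMD across embryos.

    The gene-gene distance is the mean EMD over all embryos in which both
    genes have non-zero expression; pairs sharing no embryo get the maximal
    distance 1.  Returns ``(gene_ids, linkage, leaf_order)`` where gene_ids
    is the (deterministically sorted) subset of genes expressed at
    ``expressed_fpkm`` in at least one embryo.
    """
    if not embryos:
        raise ValueError("no embryos supplied")
    all_genes = embryos[0].gene_ids
    mats = [_impute_matrix(e) for e in embryos]
    expressed = np.zeros(len(all_genes), dtype=bool)
    for m in mats:
        expressed |= m.max(axis=1) >= expressed_fpkm
    gene_ids = sorted(np.asarray(all_genes)[expressed])
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 expressed genes")
    order = [all_genes.index(g) for g in gene_ids]
    k = len(gene_ids)
    dist_sum = np.zeros((k, k))
    dist_cnt = np.zeros((k, k), dtype=int)
    for m in mats:
        sub = m[order]
        totals = sub.sum(axis=1)
        ok = totals > 0
        if ok.sum() < 2:
            continue
        masses = sub[ok] / totals[ok, None]
        cdf = np.cumsum(masses, axis=1)[:, :-1]  # last column is all 1
        # pairwise EMD on a shared grid = city-block distance of CDFs / N
        n = sub.shape[1]
        d = squareform(pdist(cdf, metric="cityblock")) / n
        ii = np.flatnonzero(ok)
        dist_sum[np.ix_(ii, ii)] += d
        dist_cnt[np.ix_(ii, ii)] += 1
    with np.errstate(invalid="ignore"):
        dist = np.where(dist_cnt > 0, dist_sum / np.maximum(dist_cnt, 1), 1.0)
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False),
                                method="average")
    leaf_order = hierarchy.leaves_list(linkage)
    return gene_ids, linkage, leaf_order


def level_response(wt_embryos, up_embryos, down_embryos, gene_ids=None,
                   fold: float = 1.5):
    """Count genes whose mean level moves the same way in both conditions.

    Expression per genotype is the mean FPKM over all slices of all replicate
    embryos.  A gene counts as up if its mean is >= fold x the wild-type mean
    in BOTH conditions, down if <= wild-type / fold in both (boundary
    inclusive).  Returns (n_up_both, n_down_both).
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")

    def mean_level(embryos):
        return np.mean([_impute_matrix(e).mean(axis=1) for e in embryos], axis=0)

    wt = mean_level(wt_embryos)
    a = mean_level(up_embryos)
    b = mean_level(down_embryos)
    if gene_ids is not None:
        universe = list(wt_embryos[0].gene_ids)
        sel = np.array([universe.index(g) for g in gene_ids])
        wt, a, b = wt[sel], a[sel], b[sel]
    with np.errstate(invalid="ignore", divide="ignore"):
        up = (a >= fold * wt) & (b >= fold * wt) & (wt > 0)
        down = (a <= wt / fold) & (b <= wt / fold) & (wt > 0)
    return int(up.sum()), int(down.sum())
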