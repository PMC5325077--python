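"""TF ChIP-binding enrichment around patterning statistics.

Peaks are assigned to genes by any overlap with a +/-10 kb window around the
TSS; enrichment of binding in gene categories or in high differential-response
genes uses Pearson chi-squared 2x2 tests with Bonferroni correction, plus
combinatorial-binding trends and binding-signature KS tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PeakSet, enhancer_centers

__all__ = [
    "DEFAULT_TFS",
    "TSS_WINDOW",
    "EnrichmentResult",
    "assign_peaks_to_genes",
    "nearest_gene_for_enhancer",
    "chi2_2x2",
    "tf_enrichment_by_category",
    "delta_d_enrichment",
    "combinatorial_binding_curve",
    "binding_group_tests",
]

#: the 10 early AP factors used by default (9 non-pair-rule AP TFs + Zld)
DEFAULT_TFS = ("bcd", "cad", "D", "gt", "hb", "hkb", "kni", "kr", "tll", "zld")
TSS_WINDOW = 10_000


@dataclass(frozen=True)
class EnrichmentResult:
    tf: str
    odds_ratio: float  # np.inf flagged when a zero cell forces it
    base_frequency: float
    chi2: float
    p: float
    significant_after_bonferroni: bool


def assign_peaks_to_genes(peaks: PeakSet, tss: pd.DataFrame,
                          window: int = TSS_WINDOW,
                          tf_names=None) -> pd.DataFrame:
    """Gene x TF boolean binding matrix.

    A gene is bound by a TF iff at least one of that TF's peaks overlaps
    ``[TSS - window, TSS + window]`` (any overlap, strand-agnostic).  Peaks on
    chromosomes absent from the TSS table are skipped with a warning.
    """
    if tf_names is None:
        tf_names = sorted(peaks.intervals["name"].unique())
    matrix = pd.DataFrame(False, index=list(tss["gene_id"]),
                          columns=list(tf_names))
    known_chroms = set(tss["chrom"])
    unknown = set(peaks.intervals["chrom"]) - known_chroms
    if unknown:
        warnings.warn(f"skipping peaks on unknown chromosomes: {sorted(unknown)}")
    for chrom, chrom_tss in tss.groupby("chrom"):
        tss0 = chrom_tss["position"].to_numpy() - 1  # to 0-based
        genes = chrom_tss["gene_id"].to_numpy()
        sub = peaks.intervals[peaks.intervals["chrom"] == chrom]
        for tf, tf_peaks in sub.groupby("name"):
            if tf not in matrix.columns:
                continue
            starts = tf_peaks["start"].to_numpy()
            ends = tf_peaks["end"].to_numpy()
            # peak [s, e) overlaps window [t - w, t + w] (inclusive, 0-based)
            hit = ((starts[:, None] <= tss0[None, :] + window)
                   & (ends[:, None] > tss0[None, :] - window)).any(axis=0)
            matrix.loc[genes[hit], tf] = True
    return matrix


def nearest_gene_for_enhancer(enhancers: PeakSet, tss: pd.DataFrame,
                              window: int = TSS_WINDOW) -> pd.DataFrame:
    """Map each enhancer to the closest TSS within ``window`` of its centre.

    Returns one row per (enhancer, gene) assignment; exact distance ties
    report every tied gene.  Enhancers with no TSS in range yield a row with
    a null gene_id.
    """
    if tss.empty:
        raise ValueError("empty TSS table")
    centers = enhancer_centers(enhancers)
    rows = []
    for rec in centers.itertuples():
        chrom_tss = tss[tss["chrom"] == rec.chrom]
        if chrom_tss.empty:
            rows.append((rec.name, None, np.nan))
            continue
        dist = np.abs((chrom_tss["position"].to_numpy() - 1) - rec.center)
        dmin = dist.min()
        if dmin > window:
            rows.append((rec.name, None, np.nan))
            continue
        for g in chrom_tss["gene_id"].to_numpy()[dist == dmin]:
            rows.append((rec.name, g, int(dmin)))
    return pd.DataFrame(rows, columns=["enhancer", "gene_id", "distance"])


def chi2_2x2(in_bound: int, in_unbound: int, out_bound: int, out_unbound: int):
    """Pearson chi-squared without continuity correction, plus odds ratio.

    The odds ratio uses the Haldane-Anscombe 0.5 correction only when a zero
    cell occurs (then flagged infinite if it would still divide by zero
    without correction in the numerator direction).
    """
    table = np.array([[in_bound, in_unbound], [out_bound, out_unbound]],
                     dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table: zero margin")
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn("chi-squared expected cell count below 5")
    if in_unbound == 0 or out_bound == 0:
        odds = np.inf
    elif in_bound == 0 or out_unbound == 0:
        odds = (in_bound + 0.5) * (out_unbound + 0.5) / (
            (in_unbound + 0.5) * (out_bound + 0.5))
    else:
        odds = in_bound * out_unbound / (in_unbound * out_bound)
    return float(res.statistic), float(res.pvalue), float(odds)


def _enrich(category: list[str], background: list[str],
            binding: pd.DataFrame, base_universe: list[str],
            alpha: float) -> list[EnrichmentResult]:
    results = []
    n_tf = binding.shape[1]
    for tf in binding.columns:
        bound = binding[tf]
        in_b = int(bound.loc[category].sum())
        out_b = int(bound.loc[background].sum())
        try:
            chi2, p, odds = chi2_2x2(in_b, len(category) - in_b,
                                     out_b, len(background) - out_b)
        except ValueError:
            # TF bound everywhere or nowhere: no contrast to test
            chi2, p, odds = 0.0, 1.0, np.nan
        results.append(EnrichmentResult(
            tf=tf, odds_ratio=odds,
            base_frequency=float(bound.loc[base_universe].mean()),
            chi2=chi2, p=p,
            significant_after_bonferroni=bool(p < alpha / n_tf)))
    return results


def tf_enrichment_by_category(category_genes, background_genes,
                              binding: pd.DataFrame,
                              alpha: float = 0.05) -> list[EnrichmentResult]:
    """Per-TF 2x2 enrichment of binding in a gene category vs background.

    Bonferroni correction is over the number of TFs in the binding matrix;
    base frequency is the bound fraction over category + background.
    """
    category = list(category_genes)
    background = list(background_genes)
    if not category:
        raise ValueError("empty gene category")
    overlap = set(category) & set(background)
    if overlap:
        raise ValueError(f"genes in both category and background: {sorted(overlap)[:3]}")
    return _enrich(category, background, binding, category + background, alpha)


def delta_d_enrichment(delta_d_ranking: pd.Series, binding: pd.DataFrame,
                       expressed_genes=None, top_n: int = 50,
                       control_n: int = 200,
                       alpha: float = 0.05) -> list[EnrichmentResult]:
    """Binding enrichment in top differential-response genes vs median controls.

    ``delta_d_ranking`` maps gene_id -> delta-D for the eligible genes (those
    changing in both mutants).  The test set is the ``top_n`` genes by score;
    the control set is the ``control_n`` genes closest to the median score.
    Base frequency is the bound fraction among ``expressed_genes`` (defaults
    to the eligible set).
    """
    ranking = delta_d_ranking.dropna()
    if len(ranking) < top_n + control_n:
        raise ValueError(
            f"need >= {top_n + control_n} eligible genes, have {len(ranking)}")
    ordered = ranking.rename("d").rename_axis("gene_id").reset_index()
    ordered = ordered.sort_values(["d", "gene_id"], ascending=[False, True],
                                  kind="mergesort")
    top = ordered["gene_id"].head(top_n).tolist()
    rest = ordered.iloc[top_n:].copy()
    median = float(ranking.median())
    rest["gap"] = (rest["d"] - median).abs()
    rest = rest.sort_values(["gap", "gene_id"], kind="mergesort")
    control = rest["gene_id"].head(control_n).tolist()
    universe = list(expressed_genes) if expressed_genes is not None else list(ranking.index)
    return _enrich(top, control, binding, universe, alpha)


def combinatorial_binding_curve(delta_d_values: pd.Series,
                                binding: pd.DataFrame, window: int = 50,
                                k_values=range(3, 10)) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of genes bound by >= k TFs in consecutive delta-D windows.

    Genes are rank-sorted by score and grouped into non-overlapping windows
    of ``window`` genes (remainder dropped).  Returns (per-window fractions,
    per-k OLS slope/intercept of fraction on window mean score).
    """
    scores = delta_d_values.dropna().sort_values(kind="mergesort")
    n_windows = len(scores) // window
    if n_windows < 2:
        raise ValueError("need at least 2 full windows of genes")
    n_bound = binding.sum(axis=1)
    rows = []
    for w in range(n_windows):
        genes = scores.index[w * window:(w + 1) * window]
        mean_d = float(scores.loc[genes].mean())
        for k in k_values:
            rows.append({"window": w, "mean_delta_d": mean_d, "k": k,
                         "fraction": float((n_bound.loc[genes] >= k).mean())})
    curves = pd.DataFrame(rows)
    fits = []
    for k, sub in curves.groupby("k"):
        if sub["fraction"].nunique() == 1:
            slope, intercept = 0.0, float(sub["fraction"].iloc[0])
        else:
            fit = stats.linregress(sub["mean_delta_d"], sub["fraction"])
            slope, intercept = float(fit.slope), float(fit.intercept)
        fits.append({"k": k, "slope": slope, "intercept": intercept})
    return curves, pd.DataFrame(fits)


def binding_group_tests(binding: pd.DataFrame, summed_emd: pd.Series,
                        min_group: int = 30,
                        alpha: float = 0.05) -> pd.DataFrame:
    """KS-test each exact binding signature's summed-EMD distribution.

    Groups are genes sharing an identical boolean TF-binding pattern; groups
    with at least ``min_group`` genes are compared to the distribution over
    all genes with a two-sample Kolmogorov-Smirnov test, Bonferroni-corrected
    over the number of groups tested.
    """
    summed = summed_emd.dropna()
    genes = summed.index.intersection(binding.index)
    summed = summed.loc[genes]
    sig = binding.loc[genes].apply(
        lambda row: "".join("1" if v else "0" for v in row), axis=1)
    groups = [(pattern, idx) for pattern, idx in summed.groupby(sig).groups.items()
              if len(idx) >= min_group]
    if not groups:
        warnings.warn(f"no binding signature has >= {min_group} genes")
        return pd.DataFrame(columns=["signature", "n_genes", "ks_statistic",
                                     "p", "significant_after_bonferroni"])
    all_values = summed.to_numpy()
    rows = []
    for pattern, idx in groups:
        res = stats.ks_2samp(summed.loc[idx].to_numpy(), all_values)
        rows.append({"signature": pattern, "n_genes": len(idx),
                     "ks_statistic": float(res.statistic), "p": float(res.pvalue)})
    out = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    out["significant_after_bonferroni"] = out["p"] < alpha / len(groups)
    return out
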