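"""Differential contact analysis between two conditions.

Per-fragment counts are modeled as negative binomial.  Library depth is
normalized with median-of-ratios size factors; per-fragment dispersions are
estimated by method of moments and shrunk toward a log-linear
mean-dispersion trend (with two or three replicates per condition the
per-fragment estimate is very noisy, so the trend carries most of the
weight).  Condition means are compared with a Wald test on the
log2 fold change; fragments with p below the nominal ``diff_p`` threshold
(default 0.05, no multiple-testing correction — the threshold is nominal
by design) are flagged, and maximal runs of adjacent significant fragments
are merged into differential regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import DomainSegment
from .config import AnalysisConfig
from .counts import CountMatrix
from .fragment_map import Fragment

_ALPHA_MIN, _ALPHA_MAX = 1e-8, 10.0
_PRIOR_DF = 10.0  # weight of the dispersion trend in the shrinkage


@dataclass
class DifferentialResult:
    """Per-fragment Wald results plus merged differential regions (bp)."""

    table: pd.DataFrame  # columns: base_mean, lfc, se, p, significant
    regions: list[tuple[int, int]]
    condition_a: str
    condition_b: str
    size_factors: pd.Series


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors over all-positive fragments."""
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = log_counts.notna().all(axis=1)
    if usable.sum() < 10:
        raise ValueError("too few fragments with positive counts in every "
                         "library to estimate size factors")
    ratios = log_counts.loc[usable].sub(log_geo.loc[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf / np.exp(np.log(sf).mean())  # geometric-mean centred


def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray,
                      n_bins: int = 10) -> np.ndarray:
    """Log-linear mean-dispersion trend fitted to binned moment estimates.

    Per-fragment moment estimates are averaged within mean-expression
    quantile bins *before* the log-linear fit; fitting on the log of the
    raw (frequently non-positive) per-fragment estimates instead would
    bias the trend downward and inflate the Wald test.
    """
    ok = mu > 0
    if ok.sum() < 30:
        fallback = alpha_mom[ok].mean() if ok.any() else 0.05
        return np.full_like(mu, np.clip(fallback, 1e-4, _ALPHA_MAX))
    log_mu = np.log(mu[ok])
    edges = np.quantile(log_mu, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.digitize(log_mu, edges[1:-1]), 0, n_bins - 1)
    bx, bm = [], []
    for b in range(n_bins):
        m = bins == b
        if m.sum() >= 10:
            bx.append(log_mu[m].mean())
            bm.append(alpha_mom[ok][m].mean())
    bx, bm = np.array(bx), np.array(bm)
    pos = bm > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(bx[pos], np.log(bm[pos]), 1)
        trend = np.exp(intercept + slope * np.log(np.maximum(mu, 1e-8)))
    else:
        trend = np.full_like(mu, max(float(bm.mean()), 1e-4))
    return np.clip(trend, _ALPHA_MIN, _ALPHA_MAX)


def differential_fragments(cm: CountMatrix, condition_a: str, condition_b: str,
                           reference_label: str | None = None,
                           cfg: AnalysisConfig | None = None,
                           candidates: set[int] | None = None,
                           ) -> DifferentialResult:
    """NB Wald test of condition_b vs condition_a per candidate fragment.

    ``reference_label`` names the condition whose mean is the fold-change
    denominator (defaults to ``condition_a``).  Each condition needs at
    least two replicate libraries for the dispersion to be estimable.
    """
    cfg = cfg or AnalysisConfig()
    ref = reference_label or condition_a
    if ref not in (condition_a, condition_b):
        raise ValueError(f"reference {ref!r} is neither condition")
    other = condition_b if ref == condition_a else condition_a
    libs_a = cm.libraries_for(ref)
    libs_b = cm.libraries_for(other)
    for cond, libs in ((ref, libs_a), (other, libs_b)):
        if len(libs) < 2:
            raise ValueError(f"condition {cond!r} has {len(libs)} replicate(s); "
                             "dispersion is not estimable with fewer than 2")

    counts = cm.counts[libs_a + libs_b]
    sf = size_factors_median_of_ratios(counts)
    q = counts / sf

    if candidates is None:
        candidates = set(counts.index[q.mean(axis=1) >= cfg.min_count])
    idx = sorted(candidates)
    qa = q.loc[idx, libs_a].to_numpy(float)
    qb = q.loc[idx, libs_b].to_numpy(float)
    na, nb = qa.shape[1], qb.shape[1]
    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)
    mu = q.loc[idx].mean(axis=1).to_numpy(float)

    # Method-of-moments dispersion from pooled within-condition variance:
    # Var(K/s) = mu/s + alpha * mu^2, so pooled excess variance over the
    # Poisson term identifies alpha.
    var_w = (qa.var(axis=1, ddof=1) * (na - 1) + qb.var(axis=1, ddof=1) * (nb - 1))
    var_w = var_w / (na + nb - 2)
    inv_s = float((1.0 / sf).mean())
    alpha_mom = (var_w - mu * inv_s) / np.maximum(mu, 1e-8) ** 2
    trend = _dispersion_trend(mu, alpha_mom)
    resid_df = na + nb - 2
    alpha = ((resid_df * np.maximum(alpha_mom, 0) + _PRIOR_DF * trend)
             / (resid_df + _PRIOR_DF))
    alpha = np.clip(alpha, _ALPHA_MIN, _ALPHA_MAX)

    inv_s_a = (1.0 / sf[libs_a]).to_numpy()
    inv_s_b = (1.0 / sf[libs_b]).to_numpy()
    mu_a_ = np.maximum(mu_a, 0.5)  # guard all-zero groups
    mu_b_ = np.maximum(mu_b, 0.5)
    var_mu_a = (mu_a_ * inv_s_a.sum() + alpha * mu_a_ ** 2 * na) / na ** 2
    var_mu_b = (mu_b_ * inv_s_b.sum() + alpha * mu_b_ ** 2 * nb) / nb ** 2
    ln2 = np.log(2.0)
    se_lfc = np.sqrt(var_mu_a / mu_a_ ** 2 + var_mu_b / mu_b_ ** 2) / ln2
    lfc = np.log2(mu_b_ / mu_a_)
    wald = lfc / se_lfc
    p = 2 * stats.norm.sf(np.abs(wald))

    table = pd.DataFrame(
        {"base_mean": mu, "lfc": lfc, "se": se_lfc, "p": p,
         "significant": p < cfg.diff_p},
        index=pd.Index(idx, name="fragment"))
    regions = merge_regions(table["significant"], cm.fragments)
    return DifferentialResult(table=table, regions=regions,
                              condition_a=ref, condition_b=other,
                              size_factors=sf)


def merge_regions(flags: pd.Series, fragments: Sequence[Fragment],
                  ) -> list[tuple[int, int]]:
    """Maximal runs of adjacent significant fragments as bp intervals.

    Adjacency means consecutive fragment indices; a non-significant or
    untested fragment in between splits the run.
    """
    by_index = {f.index: f for f in fragments}
    sig = sorted(flags.index[flags])
    regions: list[tuple[int, int]] = []
    run_start = prev = None
    for idx in sig:
        if run_start is None:
            run_start = prev = idx
        elif idx == prev + 1:
            prev = idx
        else:
            regions.append((by_index[run_start].start, by_index[prev].end))
            run_start = prev = idx
    if run_start is not None:
        regions.append((by_index[run_start].start, by_index[prev].end))
    return regions


def overlap_report(diff_regions: Sequence[tuple[int, int]],
                   domains: Sequence[DomainSegment],
                   fragments: Sequence[Fragment]) -> tuple[int, int]:
    """Count differential regions overlapping a high-interacting domain.

    A region counts as overlapping when it shares >= 1 bp with any
    high-state segment ("fully or in part").  Returns
    (n_differential_regions, n_overlapping_high).
    """
    by_index = {f.index: f for f in fragments}
    high_bp = [(by_index[d.start_fragment].start, by_index[d.end_fragment - 1].end)
               for d in domains if d.state == "high"]
    n_overlap = 0
    for (rs, re_) in diff_regions:
        if any(rs < he and re_ > hs for hs, he in high_bp):
            n_overlap += 1
    return len(diff_regions), n_overlap


def write_differential_tsv(result: DifferentialResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index_label="fragment")


def write_regions_bed(result: DifferentialResult, chrom: str,
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (start, end) in enumerate(result.regions):
            fh.write(f"{chrom}\t{start}\t{end}\tdiff_{i}\t0\t.\n")
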