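"""Significant-interaction calling and chromatin-domain segmentation.

4C contact counts decay monotonically with genomic distance from the
viewpoint.  Fragments contacting the viewpoint above that background are
detected by (1) fitting a monotone non-increasing expected curve to
log1p-transformed counts with isotonic (pool-adjacent-violators) regression,
separately upstream and downstream of the viewpoint; (2) scoring each
candidate fragment with a z-score against a robust, locally estimated
residual scale (1.4826 x MAD in sliding distance bins); and (3) declaring a
fragment significant when its upper-tail z-score reaches ``z_thresh`` and
its Benjamini-Hochberg q-value is at or below ``fdr_thresh``.

Independently, the smoothed condition profile is segmented into high-,
low-, and non-interacting domains with a 3-state Gaussian-emission hidden
Markov model over window-mean log signal (Baum-Welch fitting, Viterbi
decoding); states are ordered by emission mean for identifiability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import stats
from scipy.optimize import isotonic_regression
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .fragment_map import Fragment, Viewpoint

logger = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor for the normal distribution
_MIN_SCALE = 1e-3
_MAD_BIN = 101  # sliding-window width (fragments) for the residual scale


@dataclass
class DecayFit:
    """Monotone distance-decay fit over the candidate fragments.

    ``table`` is indexed by fragment index with columns: side (+1 downstream
    / -1 upstream of the viewpoint), distance (bp), obs (log1p count),
    expected (fitted log1p count, non-increasing with distance on each
    side), scale (robust residual SD, > 0).
    """

    table: pd.DataFrame
    viewpoint: Viewpoint
    transformation: str = "log1p"


@dataclass
class InteractionCalls:
    """Per-candidate-fragment z-score, one-sided p, BH q, significance flag."""

    table: pd.DataFrame  # columns: z, p, q, significant
    z_thresh: float
    fdr_thresh: float


@dataclass(frozen=True)
class DomainSegment:
    start_fragment: int  # inclusive
    end_fragment: int  # exclusive
    state: str  # high | low | non


def _rolling_mad_scale(residuals: np.ndarray, bin_width: int = _MAD_BIN) -> np.ndarray:
    """Robust residual SD in a sliding distance bin around each fragment."""
    s = pd.Series(residuals)
    med = s.rolling(bin_width, center=True, min_periods=5).median()
    mad = (s - med).abs().rolling(bin_width, center=True, min_periods=5).median()
    scale = (MAD_TO_SD * mad).to_numpy()
    # Fall back to the global scale where the local bin is too sparse/flat.
    global_scale = MAD_TO_SD * float(np.median(np.abs(residuals - np.median(residuals))))
    scale = np.where(np.isfinite(scale), scale, global_scale)
    return np.maximum(scale, max(global_scale * 0.1, _MIN_SCALE))


def fit_distance_decay(avg_counts: pd.Series, fragments: Sequence[Fragment],
                       viewpoint: Viewpoint,
                       candidates: set[int]) -> DecayFit:
    """Fit the monotone background curve per side of the viewpoint.

    ``avg_counts`` is the replicate-averaged count per fragment (count
    scale, not RPM).  Only candidate fragments (those passing the
    minimum-count rule) enter the fit.  Each side needs >= 10 candidates.
    """
    mid = {f.index: f.midpoint for f in fragments}
    rows = []
    for idx in sorted(candidates):
        if idx == viewpoint.fragment_index:
            continue
        d = mid[idx] - viewpoint.position
        rows.append((idx, 1 if d > 0 else -1, abs(d),
                     float(np.log1p(avg_counts.loc[idx]))))
    df = pd.DataFrame(rows, columns=["fragment", "side", "distance", "obs"])
    df = df.set_index("fragment")

    parts = []
    for side, grp in df.groupby("side"):
        if len(grp) < 10:
            raise ValueError(
                f"only {len(grp)} candidate fragments on side {side:+d} of the "
                "viewpoint (need >= 10); enlarge the analysis window or lower "
                "min_count")
        grp = grp.sort_values("distance")
        fit = isotonic_regression(grp["obs"].to_numpy(), increasing=False)
        grp = grp.assign(expected=fit.x)
        grp = grp.assign(scale=_rolling_mad_scale(
            (grp["obs"] - grp["expected"]).to_numpy()))
        parts.append(grp)
    table = pd.concat(parts).sort_index()
    return DecayFit(table=table, viewpoint=viewpoint)


def call_interactions(fit: DecayFit,
                      cfg: AnalysisConfig | None = None) -> InteractionCalls:
    """Score candidates against the decay fit and flag significant contacts.

    z = (log1p(obs) - expected) / scale; p is the upper-tail normal
    probability (only enrichment over the background is of interest);
    q is Benjamini-Hochberg over the candidate set.  A fragment is
    significant iff z >= z_thresh and q <= fdr_thresh.
    """
    cfg = cfg or AnalysisConfig()
    t = fit.table
    z = (t["obs"] - t["expected"]) / t["scale"]
    p = stats.norm.sf(z)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({"z": z, "p": p, "q": q}, index=t.index)
    out["significant"] = (out["z"] >= cfg.z_thresh) & (out["q"] <= cfg.fdr_thresh)
    return InteractionCalls(table=out, z_thresh=cfg.z_thresh,
                            fdr_thresh=cfg.fdr_thresh)


# ---------------------------------------------------------------------------
# Domain segmentation

_STATE_NAMES = ("non", "low", "high")  # ordered by emission mean


def _window_observations(sig: np.ndarray, k: int) -> tuple[np.ndarray, list[int]]:
    """Window-mean observations over blocks of k values; trailing partial
    window folded into the last full one."""
    n_win = len(sig) // k
    bounds = [i * k for i in range(n_win)] + [len(sig)]
    obs = np.array([sig[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    return obs, bounds


def _init_hmm(obs: np.ndarray, seed: int) -> GaussianHMM:
    """Deterministic 3-state HMM with quantile-spread means and sticky
    transitions; explicit initialization avoids the degenerate all-states-
    equal fixed point that k-means seeding can fall into on step signals."""
    model = GaussianHMM(n_components=3, covariance_type="diag",
                        n_iter=100, tol=1e-6, random_state=seed,
                        init_params="", params="stmc")
    model.startprob_ = np.full(3, 1 / 3)
    model.transmat_ = np.full((3, 3), 0.05) + np.eye(3) * 0.85
    model.means_ = np.quantile(obs, [0.1, 0.5, 0.9]).reshape(-1, 1)
    model.covars_ = np.full((3, 1), max(float(obs.var()) / 4, 1e-4))
    return model


def segment_domains(profile_values: pd.Series,
                    cfg: AnalysisConfig | None = None,
                    seed: int = 0) -> list[DomainSegment]:
    """Segment the smoothed profile into high/low/non-interacting domains.

    Observations are window means of log1p signal over consecutive blocks of
    ``hmm_k`` fragments.  A 3-state Gaussian HMM is fit by Baum-Welch
    (k-means initialization, fixed seed; 100 iterations or 1e-6 tolerance)
    and decoded with Viterbi; states are relabeled in increasing order of
    emission mean so the labels (non < low < high) are identifiable.
    Adjacent windows in the same state are merged into segments that tile
    the analyzed fragment range.
    """
    cfg = cfg or AnalysisConfig()
    k = cfg.hmm_k
    n = len(profile_values)
    if n < 3 * k:
        raise ValueError(f"need at least {3 * k} fragments for segmentation, got {n}")
    frag_index = profile_values.index.to_numpy()
    sig = np.log1p(profile_values.to_numpy(float))
    obs, bounds = _window_observations(sig, k)
    n_win = len(obs)

    if np.ptp(obs) < 1e-9:  # flat signal: no structure to segment
        return [DomainSegment(int(frag_index[0]), int(frag_index[-1]) + 1, "non")]

    X = obs.reshape(-1, 1)
    model = _init_hmm(obs, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
    if not model.monitor_.converged:
        logger.warning("Baum-Welch did not converge in %d iterations; "
                       "using the best iterate", model.n_iter)
    states = model.predict(X)
    order = np.argsort(model.means_.ravel())
    rank = np.empty(3, dtype=int)
    rank[order] = np.arange(3)
    labels = [_STATE_NAMES[rank[s]] for s in states]

    segments: list[DomainSegment] = []
    seg_start = 0
    for w in range(1, n_win + 1):
        if w == n_win or labels[w] != labels[seg_start]:
            a = bounds[seg_start]
            b = bounds[w]
            segments.append(DomainSegment(int(frag_index[a]),
                                          int(frag_index[b - 1]) + 1,
                                          labels[seg_start]))
            seg_start = w
    return segments


def baum_welch_loglik_history(profile_values: pd.Series,
                              cfg: AnalysisConfig | None = None,
                              seed: int = 0) -> list[float]:
    """Per-iteration log-likelihood of the segmentation HMM fit (diagnostic)."""
    cfg = cfg or AnalysisConfig()
    sig = np.log1p(profile_values.to_numpy(float))
    obs, _ = _window_observations(sig, cfg.hmm_k)
    model = _init_hmm(obs, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(obs.reshape(-1, 1))
    return list(model.monitor_.history)


# ---------------------------------------------------------------------------
# I/O

def write_calls_bed(calls: InteractionCalls, fragments: Sequence[Fragment],
                    path: str | Path) -> None:
    """Significant fragments as BED with the z-score in the name column."""
    by_index = {f.index: f for f in fragments}
    with open(path, "w") as fh:
        sig = calls.table[calls.table["significant"]]
        for idx, row in sig.iterrows():
            f = by_index[idx]
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tz={row.z:.3f}\t0\t.\n")


def write_calls_tsv(calls: InteractionCalls, path: str | Path) -> None:
    calls.table.to_csv(path, sep="\t", index_label="fragment")


def write_domains_bed(segments: Sequence[DomainSegment],
                      fragments: Sequence[Fragment], path: str | Path) -> None:
    by_index = {f.index: f for f in fragments}
    with open(path, "w") as fh:
        for seg in segments:
            start = by_index[seg.start_fragment].start
            end = by_index[seg.end_fragment - 1].end
            chrom = by_index[seg.start_fragment].chrom
            fh.write(f"{chrom}\t{start}\t{end}\t{seg.state}\t0\t.\n")
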