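"""Bootstrapped per-group Spearman correlations and the reversal cascade.

Differential-correlation analysis asks a different question from per-feature
testing: not "did this metabolite's level change" but "did the *coupling*
between metabolites change".  Per biological group, every unordered feature
pair with enough complete (both-observed) sample pairs gets a Spearman rank
correlation aggregated over bootstrap resamples.  The cascade then keeps
pairs whose correlation is

  (a) high (|rho| > ``high_corr``) in healthy controls,
  (b) lost or sign-switched in untreated diabetics
      (|rho_control - rho_diabetic| > ``delta``), and
  (c) high again (|rho| > ``high_corr``) in treated diabetics,

drops pairs whose two features are adducts/charge states of the same
metabolite, and reports features showing the pattern against at least
``min_degree`` *different* partner metabolites — a degree filter on the
differential-correlation graph, counting metabolites rather than features so
adduct redundancy cannot inflate a hub.

Bootstrap aggregation is by median over resample correlations, which is
robust to the occasional degenerate resample at small n.  Each pair's
resampling stream is seeded from the (order-independent) pair identity, so
results do not depend on feature ordering.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import StageError
from .peaktable import FeatureTable

_MAX_REDRAW_ROUNDS = 50


@dataclass
class CascadeThresholds:
    """Filter settings for the reversal cascade.

    ``high_corr`` and ``delta`` are the (arbitrary but fixed) 0.5 thresholds;
    ``min_pairs`` is the minimum number of complete observation pairs for a
    correlation to be computed at all (6-versus-6 rule); ``min_degree`` is
    the minimum number of different partner metabolites; ``n_boot`` the
    bootstrap resample count.
    """

    high_corr: float = 0.5
    delta: float = 0.5
    min_pairs: int = 6
    min_degree: int = 10
    n_boot: int = 100

    def __post_init__(self) -> None:
        assert 0 < self.high_corr < 1
        assert 0 < self.delta <= 2
        assert self.min_pairs >= 3
        assert self.n_boot >= 1


@dataclass
class CorrelationSet:
    """Bootstrap-aggregated Spearman rho per unordered feature pair."""

    group: str
    pairs: dict = field(default_factory=dict)   # (fid_a, fid_b) sorted -> (rho, n_complete)

    def rho(self, a: str, b: str):
        return self.pairs.get(_pair_key(a, b), (None, 0))[0]


@dataclass
class ReversalCandidate:
    feature_id: str
    partners: list    # (partner_fid, rho_nd, rho_dm, rho_dmt)
    partner_metabolite_count: int


def _pair_key(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Pairs with a missing value in either vector are excluded.  Returns NaN
    with fewer than 3 complete pairs or zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    rx = sstats.rankdata(x[ok])
    ry = sstats.rankdata(y[ok])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def _resample_rhos(x: np.ndarray, y: np.ndarray, n_boot: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Spearman rho for n_boot with-replacement resamples of complete pairs.

    Degenerate resamples (< 3 distinct sample pairs, or zero rank variance in
    either margin) are redrawn; rows still degenerate after the redraw budget
    are dropped from the aggregate.
    """
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    rhos = np.full(n_boot, np.nan)
    pending = np.arange(n_boot)
    for _ in range(_MAX_REDRAW_ROUNDS):
        if len(pending) == 0:
            break
        sub = idx[pending]
        xb, yb = x[sub], y[sub]
        distinct = (np.diff(np.sort(sub, axis=1), axis=1) > 0).sum(axis=1) + 1
        rx = sstats.rankdata(xb, axis=1)
        ry = sstats.rankdata(yb, axis=1)
        vx = np.ptp(rx, axis=1) > 0
        vy = np.ptp(ry, axis=1) > 0
        valid = (distinct >= 3) & vx & vy
        if valid.any():
            rxc = rx[valid] - rx[valid].mean(axis=1, keepdims=True)
            ryc = ry[valid] - ry[valid].mean(axis=1, keepdims=True)
            num = (rxc * ryc).sum(axis=1)
            den = np.sqrt((rxc ** 2).sum(axis=1) * (ryc ** 2).sum(axis=1))
            rhos[pending[valid]] = num / den
        pending = pending[~valid]
        if len(pending):
            idx[pending] = rng.integers(0, n, size=(len(pending), n))
    return rhos[np.isfinite(rhos)]


def bootstrap_rho(x, y, n_boot: int = 100, seed: int = 0,
                  min_pairs: int = 6) -> tuple:
    """Median Spearman rho over bootstrap resamples of complete pairs.

    Returns (rho_aggregate, n_complete_pairs); rho is NaN when fewer than
    ``min_pairs`` complete pairs exist (the pair is then excluded upstream).
    Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < min_pairs:
        return float("nan"), n
    rng = np.random.default_rng(seed)
    rhos = _resample_rhos(x[ok], y[ok], n_boot, rng)
    if len(rhos) == 0:
        return float("nan"), n
    return float(np.median(rhos)), n


def pair_seed(seed: int, a: str, b: str) -> np.random.SeedSequence:
    """Order-independent per-pair seed, stable across runs and platforms."""
    key = "|".join(_pair_key(a, b))
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(key.encode())])


def n_candidate_pairs(n_features: int) -> int:
    """Number of unordered pairs the correlation stage evaluates: C(n, 2)."""
    return math.comb(n_features, 2)


def group_correlation_matrix(table: FeatureTable, group: str,
                             thresholds: CascadeThresholds | None = None,
                             seed: int = 0) -> CorrelationSet:
    """Bootstrap-aggregated Spearman rho for all eligible pairs in one group.

    All n(n-1)/2 unordered feature pairs are candidates; a pair enters the
    result only with at least ``thresholds.min_pairs`` complete observation
    pairs in the group.
    """
    thresholds = thresholds or CascadeThresholds()
    sample_ids = table.manifest.group_ids(group)
    if len(sample_ids) == 0:
        raise StageError(f"group {group!r} absent from manifest")
    data = table.intensities[sample_ids]
    fids = list(data.index)
    values = data.to_numpy(dtype=float)
    finite = np.isfinite(values)

    out = CorrelationSet(group=group)
    for i, j in combinations(range(len(fids)), 2):
        ok = finite[i] & finite[j]
        n = int(ok.sum())
        if n < thresholds.min_pairs:
            continue
        rng = np.random.default_rng(pair_seed(seed, fids[i], fids[j]))
        rhos = _resample_rhos(values[i, ok], values[j, ok], thresholds.n_boot, rng)
        if len(rhos) == 0:
            continue
        out.pairs[_pair_key(fids[i], fids[j])] = (float(np.median(rhos)), n)
    return out


def pair_passes_cascade(rho_nd: float, rho_dm: float, rho_dmt: float,
                        thresholds: CascadeThresholds) -> bool:
    """The three-condition reversal rule on one pair's (ND, DM, DM+TETA) rhos."""
    return (
        abs(rho_nd) > thresholds.high_corr
        and abs(rho_dmt) > thresholds.high_corr
        and abs(rho_nd - rho_dm) > thresholds.delta
    )


def reversal_candidates(c_nd: CorrelationSet, c_dm: CorrelationSet,
                        c_dmt: CorrelationSet,
                        thresholds: CascadeThresholds | None = None,
                        metabolite_map: dict | None = None):
    """Features whose correlations are lost in disease and restored by treatment.

    Evaluates the cascade over pairs present in all three correlation sets,
    removes pairs whose features belong to the same metabolite (features
    without an assignment count as their own singleton metabolite), and
    reports features whose passing pairs span at least ``min_degree``
    different partner metabolites.

    Returns ``(candidates, edges)``: a list of :class:`ReversalCandidate`
    sorted by descending partner count then feature id, and a DataFrame of
    all evaluated shared pairs with their three rhos and pass flags.
    """
    thresholds = thresholds or CascadeThresholds()
    metabolite_map = metabolite_map or {}
    shared = set(c_nd.pairs) & set(c_dm.pairs) & set(c_dmt.pairs)
    if not shared and c_nd.pairs and c_dm.pairs and c_dmt.pairs:
        raise StageError("correlation sets share no feature pairs")

    def met(fid: str) -> str:
        return metabolite_map.get(fid, fid)

    rows = []
    passing: dict = {}
    for a, b in sorted(shared):
        rho_nd = c_nd.pairs[(a, b)][0]
        rho_dm = c_dm.pairs[(a, b)][0]
        rho_dmt = c_dmt.pairs[(a, b)][0]
        same_met = met(a) == met(b)
        ok = (not same_met) and pair_passes_cascade(rho_nd, rho_dm, rho_dmt, thresholds)
        rows.append((a, b, rho_nd, rho_dm, rho_dmt, same_met, ok))
        if ok:
            passing.setdefault(a, []).append((b, rho_nd, rho_dm, rho_dmt))
            passing.setdefault(b, []).append((a, rho_nd, rho_dm, rho_dmt))
    edges = pd.DataFrame(rows, columns=[
        "feature_a", "feature_b", "rho_nd", "rho_dm", "rho_dmt",
        "same_metabolite", "passes_cascade",
    ])

    candidates = []
    for fid, partners in passing.items():
        n_mets = len({met(p[0]) for p in partners})
        if n_mets >= thresholds.min_degree:
            candidates.append(ReversalCandidate(fid, sorted(partners), n_mets))
    candidates.sort(key=lambda c: (-c.partner_metabolite_count, c.feature_id))
    return candidates, edges
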