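"""Chromatin-domain segmentation of histone-mark tracks.

Repressive-mark (H3K9me3/H3K27me3-like) profiles over a Hox cluster look
like alternating blocks: domains enriched around the Hox genes, depleted
over interspersed non-Hox regions.  Loop anchors of interest tend to sit at
the transitions.  This module makes the by-eye "transition point" call
reproducible: a two-state Gaussian hidden Markov model on log(1+signal),
fit by EM with deterministic initialisation, Viterbi-decoded, then smoothed
by reassigning domains shorter than ``min_domain_bins`` to their flanks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from hmmlearn.hmm import GaussianHMM

# EM stopping at tol is expected behaviour, not a problem worth a log line
logging.getLogger("hmmlearn").setLevel(logging.ERROR)

__all__ = [
    "SignalTrack",
    "Domain",
    "segment_track",
    "combine_marks",
    "extract_boundaries",
    "bin_intervals",
]

ENRICHED = "enriched"
DEPLETED = "depleted"


@dataclass
class SignalTrack:
    """Uniformly binned non-negative signal for one mark."""

    chrom: str
    bin_size: int
    values: np.ndarray
    mark: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if np.any(self.values < 0):
            raise ValueError("signal values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def span(self) -> int:
        return self.n_bins * self.bin_size


@dataclass(frozen=True)
class Domain:
    start: int
    end: int
    state: str
    mean_signal: float = float("nan")


def bin_intervals(
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
    bin_size: int,
    span: int,
) -> np.ndarray:
    """Coverage-weighted mean of interval values on a uniform bin grid.

    Bins with no coverage get 0.  Used to regrid bedGraph input before
    segmentation.
    """
    n_bins = int(np.ceil(span / bin_size))
    total = np.zeros(n_bins)
    cover = np.zeros(n_bins)
    for s, e, v in zip(starts, ends, values):
        b0, b1 = int(s) // bin_size, (int(e) - 1) // bin_size
        for b in range(max(b0, 0), min(b1, n_bins - 1) + 1):
            lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
            if hi > lo:
                total[b] += v * (hi - lo)
                cover[b] += hi - lo
    out = np.zeros(n_bins)
    nz = cover > 0
    out[nz] = total[nz] / cover[nz]
    return out


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, start_bin, end_bin) runs of a label vector."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), start, i))
            start = i
    return runs


def _smooth(labels: np.ndarray, min_bins: int) -> np.ndarray:
    """Reassign runs shorter than ``min_bins`` to the flanking state.

    Shortest run first; merging a run between two same-state neighbours
    coalesces them.  A single remaining run is never removed, so
    min_bins -> infinity collapses to one domain.
    """
    labels = labels.copy()
    while True:
        runs = _runs(labels)
        if len(runs) <= 1:
            return labels
        short = [r for r in runs if r[2] - r[1] < min_bins]
        if not short:
            return labels
        lab, s, e = min(short, key=lambda r: r[2] - r[1])
        labels[s:e] = 1 - lab


def segment_track(
    track: SignalTrack,
    min_domain_bins: int = 5,
    n_iter: int = 200,
    tol: float = 1e-6,
) -> list[Domain]:
    """Two-state segmentation of a mark track into enriched/depleted domains.

    A 2-state Gaussian HMM on log(1+signal) is fit by EM (means initialised
    at the 25th/75th signal percentiles, no random restarts, so the result
    is deterministic) and Viterbi-decoded; the higher-mean state is
    "enriched".  Runs shorter than ``min_domain_bins`` are reassigned to
    their flanks.  A contrast-free (constant) track yields one domain,
    labeled depleted by convention, with no boundaries.
    """
    if track.n_bins < 10:
        raise ValueError(f"need >= 10 bins to segment, got {track.n_bins}")
    y = np.log1p(track.values)

    if np.ptp(y) < 1e-9:
        return [Domain(0, track.span, DEPLETED, float(np.mean(track.values)))]

    lo, hi = np.percentile(y, [25, 75])
    if hi - lo < 1e-9:
        lo, hi = float(np.min(y)), float(np.max(y))
    var = max(float(np.var(y)), 1e-6)

    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        init_params="",
        params="stmc",
        n_iter=n_iter,
        tol=tol,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
    model.means_ = np.array([[lo], [hi]])
    model.covars_ = np.array([[var], [var]])
    X = y.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
        states = model.predict(X)

    # relabel so 1 = enriched (higher fitted mean)
    if model.means_[0, 0] > model.means_[1, 0]:
        states = 1 - states
    states = _smooth(states.astype(int), min_domain_bins)

    domains = []
    for lab, s, e in _runs(states):
        start, end = s * track.bin_size, min(e * track.bin_size, track.span)
        domains.append(
            Domain(start, end, ENRICHED if lab == 1 else DEPLETED,
                   float(np.mean(track.values[s:e])))
        )
    if len(domains) == 1:
        # no segmentation contrast survived smoothing
        d = domains[0]
        domains = [Domain(d.start, d.end, d.state, d.mean_signal)]
    return domains


def combine_marks(
    domain_lists: list[list[Domain]], rule: str = "any"
) -> list[Domain]:
    """Consensus domains across marks.

    ``rule="any"``: a position is enriched if enriched in at least one mark
    (marks need not share boundaries).  ``rule="all"``: enriched only where
    every mark is enriched.  All inputs must tile the same interval.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    if not domain_lists:
        raise ValueError("no domain lists given")
    spans = {(dl[0].start, dl[-1].end) for dl in domain_lists}
    if len(spans) != 1:
        raise ValueError(f"domain lists cover different intervals: {sorted(spans)}")
    for dl in domain_lists:
        for a, b in zip(dl[:-1], dl[1:]):
            if a.end != b.start:
                raise ValueError("domain list does not tile its interval")

    edges = sorted({d.start for dl in domain_lists for d in dl}
                   | {d.end for dl in domain_lists for d in dl})

    def enriched_at(dl: list[Domain], pos: int) -> bool:
        for d in dl:
            if d.start <= pos < d.end:
                return d.state == ENRICHED
        raise AssertionError("position outside tiling")

    combine = any if rule == "any" else all
    pieces = []
    for a, b in zip(edges[:-1], edges[1:]):
        flag = combine(enriched_at(dl, a) for dl in domain_lists)
        pieces.append((a, b, flag))

    merged: list[Domain] = []
    for a, b, flag in pieces:
        state = ENRICHED if flag else DEPLETED
        if merged and merged[-1].state == state:
            prev = merged.pop()
            merged.append(Domain(prev.start, b, state))
        else:
            merged.append(Domain(a, b, state))
    return merged


def extract_boundaries(domains: list[Domain]) -> list[int]:
    """Coordinates of junctions between adjacent domains of opposite state.

    Locus ends are not boundaries; k alternating domains give k-1 boundaries.
    """
    out = []
    for a, b in zip(domains[:-1], domains[1:]):
        if a.end != b.start:
            raise ValueError("domains must tile the locus")
        if a.state != b.state:
            out.append(a.end)
    return out
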