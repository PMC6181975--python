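"""Loop-anchor/boundary colocalization and looping selectivity.

Two claims about a tethering-element screen are made quantitative here:

* called loop anchors sit at chromatin-domain boundaries more often than
  random placement would produce (permutation test: anchor midpoints are
  uniformly re-placed within the locus and the boundary coverage recounted);
* looping among insulator-bound candidate sites is selective — only a few
  of the many sites with similar binding profiles are called (exact
  hypergeometric tail on called vs candidate-overlapping fragments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fragments import RestrictionFragment

__all__ = [
    "ColocResult",
    "SelectivityResult",
    "coloc_permutation",
    "selectivity_test",
    "classify_sites",
    "CLASS_I",
    "CLASS_II",
    "CLASS_GAF",
]

CLASS_I = "I"      # dCTCF-bound (typically with CP190/Mod(mdg4))
CLASS_II = "II"    # SuHw-bound
CLASS_GAF = "GAF"  # GAGA-factor only


@dataclass(frozen=True)
class ColocResult:
    observed_overlap: int
    n_anchors: int
    n_boundaries: int
    tolerance_bp: int
    n_permutations: int
    null_mean: float
    empirical_p: float


@dataclass(frozen=True)
class SelectivityResult:
    n_candidate_sites: int      # N: tested fragments overlapping a candidate site
    n_called_among_candidates: int  # k
    n_tested_fragments: int     # T
    n_total_calls: int          # m
    hypergeometric_p: float     # P[X >= k]


def _boundary_cover(midpoints: np.ndarray, boundaries: np.ndarray, tol: int) -> np.ndarray:
    """Number of boundaries with >= 1 anchor midpoint within tol, per row of midpoints."""
    if midpoints.ndim == 1:
        midpoints = midpoints[None, :]
    if midpoints.shape[1] == 0 or len(boundaries) == 0:
        return np.zeros(midpoints.shape[0], dtype=int)
    hit = np.abs(midpoints[:, :, None] - boundaries[None, None, :]) <= tol
    return hit.any(axis=1).sum(axis=1)


def coloc_permutation(
    anchors,
    boundaries,
    locus_length: int,
    tolerance_bp: int = 5_000,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    blacklist=None,
) -> ColocResult:
    """Permutation test for anchors colocalizing with domain boundaries.

    ``anchors`` are (start, end) intervals (called loop fragments); the
    observed statistic is the number of boundaries having at least one
    anchor midpoint within ``tolerance_bp`` (distal tethering elements span
    several kb, so boundary-in-fragment is the natural match scale).  The
    null re-places anchor midpoints uniformly in the locus, excluding
    optional blacklist intervals, and the empirical p carries the +1
    correction, so p >= 1/(n_permutations+1) always.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if tolerance_bp >= locus_length:
        raise ValueError("tolerance as large as the locus makes the test degenerate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mids = np.array([(a + b) // 2 for a, b in anchors], dtype=float)
    if np.any((mids < 0) | (mids >= locus_length)):
        raise ValueError("anchors must lie within the locus")
    bnds = np.asarray(sorted(boundaries), dtype=float)
    observed = int(_boundary_cover(mids, bnds, tolerance_bp)[0]) if len(mids) else 0

    if len(mids) == 0:
        return ColocResult(0, 0, len(bnds), tolerance_bp, n_permutations, 0.0, 1.0)

    black = [(int(s), int(e)) for s, e in blacklist] if blacklist else []

    def draw(size: int) -> np.ndarray:
        out = np.empty(size)
        filled = 0
        while filled < size:
            cand = rng.uniform(0, locus_length, size=size - filled)
            for s, e in black:
                cand = cand[(cand < s) | (cand >= e)]
            out[filled : filled + len(cand)] = cand
            filled += len(cand)
        return out

    null_mids = draw(n_permutations * len(mids)).reshape(n_permutations, len(mids))
    null_counts = _boundary_cover(null_mids, bnds, tolerance_bp)
    p = (1 + int(np.sum(null_counts >= observed))) / (n_permutations + 1)
    return ColocResult(
        observed, len(mids), len(bnds), tolerance_bp, n_permutations,
        float(null_counts.mean()), float(p),
    )


def _overlaps(frag: RestrictionFragment, start: int, end: int) -> bool:
    return frag.start < end and start < frag.end


def selectivity_test(
    candidates,
    called_ids: set[str] | list[str],
    tested_fragments: list[RestrictionFragment],
) -> SelectivityResult:
    """Exact hypergeometric test of looping selectivity among candidate sites.

    ``candidates`` are insulator-bound intervals (objects with start/end or
    (start, end) pairs); the candidate universe is the set of *tested*
    fragments overlapping at least one candidate, since only tested
    fragments could have been called.  The tail P[X >= k] is the chance
    that a random choice of m called fragments out of T tested hits at
    least k of the N candidate-overlapping ones.
    """
    def span(c):
        if hasattr(c, "start"):
            return int(c.start), int(c.end)
        return int(c[0]), int(c[1])

    spans = [span(c) for c in candidates]
    called = set(called_ids)
    T = len(tested_fragments)
    m = sum(1 for f in tested_fragments if f.id in called)
    if len(called - {f.id for f in tested_fragments}):
        raise ValueError("called fragments must be among the tested fragments")

    candidate_frags = {
        f.id for f in tested_fragments if any(_overlaps(f, s, e) for s, e in spans)
    }
    N = len(candidate_frags)
    k = len(candidate_frags & called)
    # P[X >= k] for X ~ Hypergeom(T, N, m)
    p = float(stats.hypergeom.sf(k - 1, T, N, m))
    return SelectivityResult(N, k, T, m, p)


def classify_sites(protein_set) -> set[str]:
    """Insulator class labels from the bound-protein combination.

    Class I if dCTCF is bound, class II if SuHw is bound (a site may carry
    both), GAF if GAGA factor is the only bound protein; anything else is
    labeled "other".
    """
    proteins = set(protein_set)
    if not proteins:
        raise ValueError("empty protein set")
    labels: set[str] = set()
    if "dCTCF" in proteins:
        labels.add(CLASS_I)
    if "SuHw" in proteins:
        labels.add(CLASS_II)
    if proteins == {"GAF"}:
        labels.add(CLASS_GAF)
    return labels or {"other"}
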