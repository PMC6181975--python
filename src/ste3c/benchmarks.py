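"""Self-validation experiments on synthetic data.

Each function here runs the pipeline against the generator's known ground
truth and reports a recovery or calibration rate: decay-slope recovery,
screen-scale loop-calling sensitivity and specificity, type-I calibration
of the capture test, domain-boundary recovery, and validity of the
colocalization permutation p-value.  These are the quantitative claims the
package makes about itself; the test suite asserts them and the acceptance
script reports them.
"""

from __future__ import annotations

import numpy as np

from .calling import call_stes, fit_decay_curve, test_fragment, test_table
from .config import DomainSpec, SimulationConfig
from .coloc import coloc_permutation
from .domains import extract_boundaries, segment_track
from .fragments import digest
from .quant import build_capture_table
from .simulate import (
    simulate_captures,
    simulate_locus,
    simulate_ratio_replicates,
    simulate_reference_pairs,
    simulate_tracks,
)

__all__ = [
    "slope_recovery",
    "screen_recovery",
    "type_i_rate",
    "boundary_recovery",
    "permutation_calibration",
]


def slope_recovery(
    n_runs: int = 200,
    seed: int = 0,
    n_pairs: int = 500,
    tol: float = 0.1,
    config: SimulationConfig | None = None,
) -> dict:
    """Fraction of reference-curve fits recovering the true decay exponent.

    Each run draws ``n_pairs`` background captures (distances log-uniform,
    1-200 kb) and fits the log-log OLS curve; a run succeeds when the
    fitted slope is within ``tol`` of the generative exponent.
    """
    cfg = config or SimulationConfig()
    slopes = np.empty(n_runs)
    for i in range(n_runs):
        rng = np.random.default_rng([11, seed, i])
        pairs = simulate_reference_pairs(cfg, n_pairs=n_pairs, rng=rng)
        curve = fit_decay_curve(pairs["distance_bp"], pairs["ratio"], censored=pairs["censored"])
        slopes[i] = curve.slope
    hits = np.abs(slopes - cfg.decay_exponent) <= tol
    return {
        "rate": float(hits.mean()),
        "n_runs": n_runs,
        "mean_slope": float(slopes.mean()),
        "true_slope": cfg.decay_exponent,
        "slopes": slopes,
    }


def screen_recovery(
    n_runs: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    config: SimulationConfig | None = None,
) -> dict:
    """Sensitivity/specificity of loop calling on the default screen.

    One synthetic locus (viewpoint plus 39 screened fragments, 3 planted
    loops) is built once; each run redraws the capture noise and a fresh
    reference-curve capture set, then calls tethering elements at BH level
    ``alpha``.  Reports the fraction of runs recovering all planted loops,
    the fraction with zero false calls, and the joint rate.
    """
    cfg = config or SimulationConfig()
    sequence, truth = simulate_locus(cfg, rng=np.random.default_rng([21, seed]))
    frags = digest(sequence, cfg.motif, cfg.cut_offset, cfg.chrom)
    vp_id = truth["viewpoint"]["fragment_id"]
    true_loops = {l["fragment_id"] for l in truth["loops"]}

    all_found = np.zeros(n_runs, dtype=bool)
    no_false = np.zeros(n_runs, dtype=bool)
    n_called = np.zeros(n_runs)
    for i in range(n_runs):
        captures = simulate_captures(cfg, frags, rng=np.random.default_rng([22, seed, i]))
        pairs = simulate_reference_pairs(cfg, rng=np.random.default_rng([23, seed, i]))
        curve = fit_decay_curve(pairs["distance_bp"], pairs["ratio"], censored=pairs["censored"])
        table = build_capture_table(captures, frags, vp_id)
        calls = call_stes(test_table(table, curve), alpha=alpha)
        called = {c.target_id for c in calls if c.is_ste}
        all_found[i] = true_loops <= called
        no_false[i] = not (called - true_loops)
        n_called[i] = len(called)
    return {
        "full_recovery_rate": float(all_found.mean()),
        "false_call_free_rate": float(no_false.mean()),
        "perfect_rate": float((all_found & no_false).mean()),
        "mean_n_called": float(n_called.mean()),
        "n_runs": n_runs,
        "n_true_loops": len(true_loops),
    }


def type_i_rate(
    n_fragments: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    n_reference: int = 500,
    config: SimulationConfig | None = None,
) -> dict:
    """Type-I calibration of the capture significance test under the null.

    ``n_fragments`` background fragments (no planted loops, distances
    log-uniform within the reference-curve range) are each tested against
    a curve fit from an independent reference capture set; reports the
    fraction with p <= alpha and the 99% binomial band around alpha.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng([31, seed])
    pairs = simulate_reference_pairs(cfg, n_pairs=n_reference, rng=rng)
    curve = fit_decay_curve(pairs["distance_bp"], pairs["ratio"], censored=pairs["censored"])

    d = np.exp(rng.uniform(np.log(1_000), np.log(200_000), size=n_fragments))
    ratios, censored = simulate_ratio_replicates(d, np.ones(n_fragments), cfg, rng)
    ps = np.empty(n_fragments)
    for i in range(n_fragments):
        keep = ~censored[i]
        logs = np.log(ratios[i][keep])
        if len(logs) == 0:
            ps[i] = 1.0
            continue
        rc = {
            "target_id": f"frag{i}",
            "distance_bp": d[i],
            "mean_ratio": float(ratios[i].mean()),
            "log_mean": float(logs.mean()),
            "log_sd": float(logs.std(ddof=1)) if len(logs) > 1 else 0.0,
            "n_uncensored": int(keep.sum()),
            "status": "ok",
        }
        ps[i] = test_fragment(rc, curve).p_value
    rate = float((ps <= alpha).mean())
    half = 2.5758 * np.sqrt(alpha * (1 - alpha) / n_fragments)
    return {
        "rate": rate,
        "alpha": alpha,
        "n_fragments": n_fragments,
        "ci99": (alpha - half, alpha + half),
        "p_values": ps,
    }


def _three_domain_config(noise_frac: float = 0.2) -> SimulationConfig:
    hi, lo = 10.0, 1.0
    return SimulationConfig(
        locus_length=150_000,
        viewpoint_position=75_000,
        planted_loops=[],
        insulator_sites=[],
        domain_spec={
            "H3K9me3": [
                DomainSpec(0, 50_000, hi, "enriched"),
                DomainSpec(50_000, 100_000, lo, "depleted"),
                DomainSpec(100_000, 150_000, hi, "enriched"),
            ]
        },
        track_noise_sd=noise_frac * (hi - lo),
    )


def boundary_recovery(
    n_runs: int = 200,
    seed: int = 0,
    bin_size: int = 500,
    noise_frac: float = 0.2,
    tol_bins: int = 2,
) -> dict:
    """Boundary recovery of the 2-state segmentation on 3-domain tracks.

    Tracks alternate enriched/depleted/enriched with Gaussian noise at
    ``noise_frac`` of the level gap; a run succeeds when exactly the two
    true boundaries are found, each within ``tol_bins`` bins.
    """
    cfg = _three_domain_config(noise_frac)
    true_bnds = [50_000, 100_000]
    tol = tol_bins * bin_size
    ok = np.zeros(n_runs, dtype=bool)
    for i in range(n_runs):
        tracks = simulate_tracks(cfg, bin_size, rng=np.random.default_rng([41, seed, i]))
        domains = segment_track(tracks["H3K9me3"])
        found = extract_boundaries(domains)
        ok[i] = len(found) == len(true_bnds) and all(
            min(abs(f - t) for f in found) <= tol for t in true_bnds
        )
    return {"rate": float(ok.mean()), "n_runs": n_runs, "tol_bins": tol_bins}


def permutation_calibration(
    n_replications: int = 1000,
    n_permutations: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
    locus_length: int = 500_000,
    n_anchors: int = 5,
    boundaries=(50_000, 150_000, 250_000, 350_000, 450_000),
    tolerance_bp: int = 5_000,
) -> dict:
    """Validity of the colocalization permutation p under the null.

    Anchors are themselves drawn uniformly (no true colocalization); the
    empirical p must satisfy P(p <= alpha) <= alpha + 1/(n_permutations+1).
    """
    ps = np.empty(n_replications)
    for i in range(n_replications):
        rng = np.random.default_rng([51, seed, i])
        mids = rng.uniform(0, locus_length, size=n_anchors)
        anchors = [(int(m), int(m) + 1) for m in mids]
        res = coloc_permutation(
            anchors, list(boundaries), locus_length,
            tolerance_bp=tolerance_bp, n_permutations=n_permutations, seed=rng,
        )
        ps[i] = res.empirical_p
    rate = float((ps <= alpha).mean())
    return {
        "rate_at_alpha": rate,
        "alpha": alpha,
        "bound": alpha + 1.0 / (n_permutations + 1),
        "n_replications": n_replications,
    }
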