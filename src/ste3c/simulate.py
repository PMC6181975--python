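"""Synthetic data generator for the whole pipeline.

Emulates, with known ground truth, everything a viewpoint 3C screen
consumes: the locus sequence and its restriction map, replicate capture
band intensities under a power-law distance decay with planted loop
enrichments, a separate reference-curve capture set, blocky repressive
histone-mark tracks, insulator binding sites, and transgenic embryo
reporter scores.

Generative model for captures
-----------------------------
For a fragment at center-to-center distance ``d`` (bp) from the viewpoint,
the expected relative crosslinking is

    mu(d) = a * (d / 1000)**b * e

with ``a`` the background scale (ratio at 1 kb), ``b`` the decay exponent,
and ``e`` the fold enrichment (>1 only for planted loop partners).  Each
replicate emits a control intensity PCR_C (lognormal around a constant:
the control template is religated genomic DNA, linkage-free and hence
distance-independent) and an experimental intensity
``PCR_E = mu(d) * PCR_C * exp(eps)``, ``eps ~ Normal(0, sigma^2)``.
Ratios below the detection floor are reported at the floor and flagged
censored rather than dropped.

All randomness flows from ``numpy.random.Generator`` instances derived
from the config seed plus a fixed per-stage offset; no global state.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .domains import SignalTrack
from .fragments import RestrictionFragment, digest, find_motif_positions

__all__ = [
    "simulate_locus",
    "simulate_captures",
    "simulate_reference_pairs",
    "simulate_tracks",
    "simulate_embryos",
    "expected_background",
    "generate_dataset",
]

# fixed per-stage RNG stream offsets (reproducibility without global state)
_STAGE = {"locus": 1, "captures": 2, "reference": 3, "tracks": 4, "embryos": 5}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(config: SimulationConfig, stage: str, seed: int | None = None) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], config.seed if seed is None else seed])


def expected_background(config: SimulationConfig, d) -> np.ndarray | float:
    """Expected relative crosslinking at distance ``d`` bp, no enrichment."""
    return config.background_scale * (np.asarray(d, dtype=float) / 1000.0) ** config.decay_exponent


# ---------------------------------------------------------------------------
# locus


def _scrub_motif(seq: np.ndarray, motif: str, protected: set[int], rng: np.random.Generator) -> None:
    """Destroy motif occurrences whose start is not in ``protected`` (in place)."""
    m = len(motif)
    for _ in range(50):
        s = seq.tobytes().decode()
        stray = [p for p in find_motif_positions(s, motif) if p not in protected]
        if not stray:
            return
        for p in stray:
            # flip the middle base to a different one, avoiding protected sites
            j = p + m // 2
            old = seq[j]
            choices = [b for b in _BASES if b != old]
            seq[j] = choices[rng.integers(len(choices))]
    raise RuntimeError("failed to scrub stray motif occurrences")


def simulate_locus(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[str, dict]:
    """Generate the locus sequence and its ground-truth record.

    Recognition sites are implanted so that the viewpoint and every planted
    loop target fall on distinct restriction fragments: each such "special"
    position gets flanking cut sites at ``special_flank`` bp on either side
    (distal tethering elements sit on fragments of a few kb), and additional
    cut sites are scattered to reach ``n_fragments`` fragments in total.
    The returned truth record lists every motif position, the fragment of
    record for the viewpoint and each loop, per-mark domain boundaries, and
    the full config.
    """
    rng = rng if rng is not None else _rng(config, "locus")
    L = config.locus_length
    motif, m = config.motif, len(config.motif)
    flank = config.special_flank

    specials = [("viewpoint", config.viewpoint_position)] + [
        (f"loop@{p.position}", p.position) for p in config.planted_loops
    ]
    order = sorted(specials, key=lambda t: t[1])
    for (_, p), (name_q, q) in zip(order[:-1], order[1:]):
        if q - p < m + 2:
            raise ValueError(
                f"locus too short to separate {name_q} at {q} from neighbor at {p}: "
                f"gap {q - p} bp cannot host a cut site"
            )

    cuts: set[int] = set()
    for (_, p), (name_q, q) in zip(order[:-1], order[1:]):
        if q - p < 2 * flank:
            cuts.add((p + q) // 2)  # single midpoint cut still separates them
    for _, p in order:
        for c in (p - flank, p + flank):
            if m < c < L - m:
                cuts.add(c)

    n_extra = config.n_fragments - 1 - len(cuts)
    forbidden = [(p - flank, p + flank) for _, p in order]
    attempts = 0
    while n_extra > 0 and attempts < 10_000:
        attempts += 1
        c = int(rng.integers(m + 1, L - m))
        if any(lo <= c <= hi for lo, hi in forbidden):
            continue
        if any(abs(c - other) < 2 * m for other in cuts):
            continue
        cuts.add(c)
        n_extra -= 1

    cut_list = sorted(cuts)
    site_starts = [c - config.cut_offset for c in cut_list]

    seq = _BASES[rng.integers(4, size=L)].copy()
    motif_arr = np.frombuffer(motif.encode(), dtype="S1")
    for s in site_starts:
        seq[s : s + m] = motif_arr
    _scrub_motif(seq, motif, set(site_starts), rng)
    sequence = seq.tobytes().decode()

    frags = digest(sequence, motif, config.cut_offset, config.chrom)

    def fragment_of(pos: int) -> RestrictionFragment:
        for f in frags:
            if f.contains(pos):
                return f
        raise AssertionError(f"position {pos} not covered by any fragment")

    vp_frag = fragment_of(config.viewpoint_position)
    loops_truth = []
    for loop in config.planted_loops:
        f = fragment_of(loop.position)
        if f.id == vp_frag.id:
            raise AssertionError("planted loop landed on the viewpoint fragment")
        loops_truth.append(
            {"position": loop.position, "enrichment": loop.enrichment, "fragment_id": f.id}
        )

    boundaries = {
        mark: [d.end for d in sorted(doms, key=lambda d: d.start)[:-1]]
        for mark, doms in config.domain_spec.items()
    }

    truth = {
        "motif_positions": find_motif_positions(sequence, motif),
        "cut_positions": cut_list,
        "viewpoint": {"position": config.viewpoint_position, "fragment_id": vp_frag.id},
        "loops": loops_truth,
        "domain_boundaries": boundaries,
        "insulator_sites": [
            {"start": s.start, "end": s.end, "proteins": list(s.proteins)}
            for s in config.insulator_sites
        ],
        "config": config.to_dict(),
    }
    return sequence, truth


# ---------------------------------------------------------------------------
# captures


def simulate_ratio_replicates(
    distances: np.ndarray,
    enrichments: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_replicates: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw replicate relative-crosslinking ratios for fragments at given distances.

    Returns ``(ratios, censored)`` of shape (n_fragments, n_replicates);
    censored entries are reported at the detection floor.
    """
    k = config.n_replicates if n_replicates is None else n_replicates
    mu = expected_background(config, distances) * np.asarray(enrichments, dtype=float)
    eps = rng.normal(0.0, config.replicate_noise_sd, size=(len(mu), k))
    ratios = mu[:, None] * np.exp(eps)
    censored = ratios < config.detection_floor
    ratios = np.where(censored, config.detection_floor, ratios)
    return ratios, censored


def simulate_captures(
    config: SimulationConfig,
    fragments: list[RestrictionFragment],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate band intensities for every non-viewpoint fragment.

    Columns: viewpoint_id, target_id, replicate, pcr_e, pcr_c, censored.
    """
    rng = rng if rng is not None else _rng(config, "captures")
    vp = next((f for f in fragments if f.contains(config.viewpoint_position)), None)
    if vp is None:
        raise ValueError("viewpoint fragment absent from fragment list")

    loop_by_frag = {}
    for loop in config.planted_loops:
        host = next((f for f in fragments if f.contains(loop.position)), None)
        if host is not None:
            loop_by_frag[host.id] = loop.enrichment

    targets = [f for f in fragments if f.id != vp.id]
    d = np.array([abs(f.center - vp.center) for f in targets], dtype=float)
    e = np.array([loop_by_frag.get(f.id, 1.0) for f in targets])

    ratios, censored = simulate_ratio_replicates(d, e, config, rng)
    k = config.n_replicates
    pcr_c = config.control_level * np.exp(
        rng.normal(0.0, config.control_log_sd, size=ratios.shape)
    )
    rows = []
    for i, f in enumerate(targets):
        for r in range(k):
            rows.append(
                {
                    "viewpoint_id": vp.id,
                    "target_id": f.id,
                    "replicate": r + 1,
                    "pcr_e": ratios[i, r] * pcr_c[i, r],
                    "pcr_c": pcr_c[i, r],
                    "censored": bool(censored[i, r]),
                }
            )
    return pd.DataFrame(rows)


def simulate_reference_pairs(
    config: SimulationConfig,
    n_pairs: int = 500,
    d_min: float = 1_000,
    d_max: float = 200_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Background capture set for fitting the distance-decay reference curve.

    Emulates a reference dataset of ~500 individual captures between sites
    up to ~200 kb apart, with no loop enrichment.  Distances are drawn
    log-uniformly; each row is one capture (one replicate measurement).
    Columns: distance_bp, ratio, censored.
    """
    rng = rng if rng is not None else _rng(config, "reference", seed)
    d = np.exp(rng.uniform(np.log(d_min), np.log(d_max), size=n_pairs))
    ratios, censored = simulate_ratio_replicates(
        d, np.ones(n_pairs), config, rng, n_replicates=1
    )
    return pd.DataFrame(
        {"distance_bp": d, "ratio": ratios[:, 0], "censored": censored[:, 0]}
    )


# ---------------------------------------------------------------------------
# tracks


def simulate_tracks(
    config: SimulationConfig, bin_size: int, rng: np.random.Generator | None = None
) -> dict[str, SignalTrack]:
    """Binned histone-mark signal per mark: domain mean + truncated Gaussian noise."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if bin_size > config.locus_length:
        raise ValueError("bin_size exceeds locus length")
    rng = rng if rng is not None else _rng(config, "tracks")
    n_bins = int(np.ceil(config.locus_length / bin_size))
    centers = (np.arange(n_bins) + 0.5) * bin_size

    tracks = {}
    for mark, doms in config.domain_spec.items():
        level = np.zeros(n_bins)
        for d in doms:
            sel = (centers >= d.start) & (centers < d.end)
            level[sel] = d.mean_level
        values = np.clip(level + rng.normal(0.0, config.track_noise_sd, size=n_bins), 0.0, None)
        tracks[mark] = SignalTrack(chrom=config.chrom, bin_size=bin_size, values=values, mark=mark)
    return tracks


# ---------------------------------------------------------------------------
# embryos


def simulate_embryos(
    config: SimulationConfig,
    construct: str,
    n_embryos: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-embryo reporter staining levels for one transgenic construct.

    Draws the H/N ratio from the construct's mixture spec (lognormal
    components), an NEE-domain level N from a lognormal scale, and sets
    H = ratio * N.  Embryos are assigned round-robin to insertion lines.
    Columns: construct, line_id, embryo_id, h_level, n_level.
    """
    if construct not in config.construct_spec:
        raise KeyError(f"unknown construct {construct!r}")
    rng = rng if rng is not None else _rng(config, "embryos")
    comps = config.construct_spec[construct]
    w = np.array([c.weight for c in comps], dtype=float)
    w = w / w.sum()
    idx = rng.choice(len(comps), size=n_embryos, p=w)
    med = np.array([c.median_ratio for c in comps])[idx]
    sd = np.array([c.log_sd for c in comps])[idx]
    ratio = med * np.exp(rng.normal(0.0, 1.0, size=n_embryos) * sd)
    n_level = config.embryo_n_median * np.exp(
        rng.normal(0.0, config.embryo_n_log_sd, size=n_embryos)
    )
    return pd.DataFrame(
        {
            "construct": construct,
            "line_id": [f"line_{i % config.n_lines + 1}" for i in range(n_embryos)],
            "embryo_id": np.arange(1, n_embryos + 1),
            "h_level": ratio * n_level,
            "n_level": n_level,
        }
    )


# ---------------------------------------------------------------------------
# one-stop dataset writer


def generate_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    bin_size: int = 500,
    n_reference_pairs: int = 500,
    n_embryos_per_construct: int = 60,
) -> dict[str, Path]:
    """Simulate and write every pipeline input to ``outdir``; returns file paths."""
    from . import io as ste_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sequence, truth = simulate_locus(config)
    frags = digest(sequence, config.motif, config.cut_offset, config.chrom)

    paths["fasta"] = outdir / "locus.fa"
    ste_io.write_fasta(paths["fasta"], config.chrom, sequence)
    paths["fragments"] = outdir / "fragments.bed"
    ste_io.write_fragments_bed(paths["fragments"], frags)

    captures = simulate_captures(config, frags)
    paths["captures"] = outdir / "captures.tsv"
    captures.to_csv(paths["captures"], sep="\t", index=False)

    reference = simulate_reference_pairs(config, n_pairs=n_reference_pairs)
    paths["reference_pairs"] = outdir / "reference_pairs.tsv"
    reference.to_csv(paths["reference_pairs"], sep="\t", index=False)

    tracks = simulate_tracks(config, bin_size)
    for mark, track in tracks.items():
        p = outdir / f"track_{mark}.bedgraph"
        ste_io.write_bedgraph(p, track)
        paths[f"track_{mark}"] = p

    paths["insulator_sites"] = outdir / "insulator_sites.bed"
    ste_io.write_insulator_bed(paths["insulator_sites"], config.insulator_sites, config.chrom)

    rng = _rng(config, "embryos")
    embryos = pd.concat(
        [simulate_embryos(config, c, n_embryos_per_construct, rng) for c in config.construct_spec],
        ignore_index=True,
    )
    paths["embryos"] = outdir / "embryos.tsv"
    embryos.to_csv(paths["embryos"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
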