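"""Relative-crosslinking quantification with replicate QC.

A capture is quantified as the band intensity of the experimental PCR over
the same primer pair's intensity on the random-religation control template
(relative crosslinking, PCR_E/PCR_C); the ratio cancels primer efficiency
and densitometry units.  Captures are repeated in at least three biological
replicates; pairs with fewer are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import RestrictionFragment, fragment_distance

__all__ = [
    "CaptureMeasurement",
    "RelativeCrosslinking",
    "Rejected",
    "relative_crosslinking",
    "aggregate_replicates",
    "build_capture_table",
    "STATUS_OK",
    "STATUS_NO_CAPTURE",
    "STATUS_REJECTED",
]

STATUS_OK = "ok"
STATUS_NO_CAPTURE = "no capture"
STATUS_REJECTED = "insufficient replicates"


@dataclass(frozen=True)
class CaptureMeasurement:
    """One replicate's band intensities for a viewpoint-target pair."""

    viewpoint_id: str
    target_id: str
    replicate: int
    pcr_e: float
    pcr_c: float
    censored: bool = False


@dataclass(frozen=True)
class RelativeCrosslinking:
    """Replicate-aggregated capture frequency for one viewpoint-target pair.

    ``mean_ratio`` is the arithmetic mean of the per-replicate ratios (the
    headline "average capture frequency over control"); log-scale mean/sd
    over the uncensored replicates are retained for testing, and the
    geometric mean is emitted alongside.  Censored replicates count toward
    the replicate total but carry no intensity information, so they are
    excluded from the log statistics.
    """

    viewpoint_id: str
    target_id: str
    ratios: tuple[float, ...]
    censored: tuple[bool, ...]
    mean_ratio: float
    geom_mean_ratio: float
    log_mean: float
    log_sd: float
    n_replicates: int
    n_uncensored: int
    status: str


@dataclass(frozen=True)
class Rejected:
    viewpoint_id: str
    target_id: str
    reason: str


def relative_crosslinking(m: CaptureMeasurement) -> float:
    """PCR_E / PCR_C for one replicate; the control intensity must be positive."""
    if m.pcr_c <= 0:
        raise ValueError(
            f"non-positive control intensity (pcr_c={m.pcr_c}) for "
            f"{m.viewpoint_id} x {m.target_id} replicate {m.replicate}"
        )
    if m.pcr_e < 0:
        raise ValueError(f"negative experimental intensity for {m.target_id}")
    return m.pcr_e / m.pcr_c


def aggregate_replicates(
    ms: list[CaptureMeasurement], min_replicates: int = 3
) -> RelativeCrosslinking | Rejected:
    """Aggregate one pair's replicates into a scoreable capture frequency."""
    if not ms:
        raise ValueError("no measurements given")
    keys = {(m.viewpoint_id, m.target_id) for m in ms}
    if len(keys) != 1:
        raise ValueError(f"measurements mix viewpoint/target pairs: {sorted(keys)}")
    reps = [m.replicate for m in ms]
    if len(set(reps)) != len(reps):
        raise ValueError(f"duplicate replicate indices for {ms[0].target_id}")
    vp, tgt = next(iter(keys))

    if len(ms) < min_replicates:
        return Rejected(vp, tgt, STATUS_REJECTED)

    ms = sorted(ms, key=lambda m: m.replicate)
    ratios = tuple(relative_crosslinking(m) for m in ms)
    cens = tuple(m.censored for m in ms)
    unc = [r for r, c in zip(ratios, cens) if not c]

    if unc:
        logs = np.log(unc)
        log_mean = float(np.mean(logs))
        log_sd = float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0
        geo = float(math.exp(log_mean))
        status = STATUS_OK
    else:
        log_mean = log_sd = float("nan")
        geo = float("nan")
        status = STATUS_NO_CAPTURE

    return RelativeCrosslinking(
        viewpoint_id=vp,
        target_id=tgt,
        ratios=ratios,
        censored=cens,
        mean_ratio=float(np.mean(ratios)),
        geom_mean_ratio=geo,
        log_mean=log_mean,
        log_sd=log_sd,
        n_replicates=len(ratios),
        n_uncensored=len(unc),
        status=status,
    )


def _measurements_from_frame(df: pd.DataFrame) -> list[CaptureMeasurement]:
    required = {"viewpoint_id", "target_id", "replicate", "pcr_e", "pcr_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"captures table missing columns: {sorted(missing)}")
    cens = df["censored"] if "censored" in df.columns else pd.Series(False, index=df.index)
    return [
        CaptureMeasurement(
            str(r.viewpoint_id), str(r.target_id), int(r.replicate),
            float(r.pcr_e), float(r.pcr_c), bool(c),
        )
        for r, c in zip(df.itertuples(index=False), cens)
    ]


def build_capture_table(
    measurements: pd.DataFrame | list[CaptureMeasurement],
    fragments: list[RestrictionFragment],
    viewpoint_id: str,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Per-target capture table with genomic distance to the viewpoint.

    One row per tested fragment, sorted by genomic coordinate; the viewpoint
    never appears as its own target.  Fragments that were not tested are
    simply absent (a screen covers most, not all, of a locus).  Rows failing
    the replicate gate keep their identity with status "insufficient
    replicates" and no statistics.
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = _measurements_from_frame(measurements)
    by_id = {f.id: f for f in fragments}
    if viewpoint_id not in by_id:
        raise KeyError(f"viewpoint fragment {viewpoint_id!r} not in fragment list")
    vp_frag = by_id[viewpoint_id]

    vps = {m.viewpoint_id for m in measurements}
    if vps - {viewpoint_id}:
        raise ValueError(f"measurements contain foreign viewpoints: {sorted(vps - {viewpoint_id})}")

    unknown = sorted({m.target_id for m in measurements} - set(by_id))
    if unknown:
        raise KeyError(f"target fragments not in fragment list: {unknown}")

    groups: dict[str, list[CaptureMeasurement]] = {}
    for m in measurements:
        if m.target_id == viewpoint_id:
            continue  # no self-pair
        groups.setdefault(m.target_id, []).append(m)

    rows = []
    for tgt, ms in groups.items():
        frag = by_id[tgt]
        agg = aggregate_replicates(ms, min_replicates=min_replicates)
        base = {
            "target_id": tgt,
            "chrom": frag.chrom,
            "start": frag.start,
            "end": frag.end,
            "center": frag.center,
            "distance_bp": fragment_distance(frag, vp_frag),
        }
        if isinstance(agg, Rejected):
            rows.append({**base, "n_reps": len(ms), "n_uncensored": 0,
                         "mean_ratio": float("nan"), "geom_mean_ratio": float("nan"),
                         "log_mean": float("nan"), "log_sd": float("nan"),
                         "status": STATUS_REJECTED})
        else:
            rows.append({**base, "n_reps": agg.n_replicates, "n_uncensored": agg.n_uncensored,
                         "mean_ratio": agg.mean_ratio, "geom_mean_ratio": agg.geom_mean_ratio,
                         "log_mean": agg.log_mean, "log_sd": agg.log_sd,
                         "status": agg.status})
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values("center", kind="mergesort").reset_index(drop=True)
    return table
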