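"""Distance-decay reference curve and loop (tethering-element) calling.

The null model for a viewpoint 3C screen is that capture frequency decays
with genomic separation as a power law (linkage background).  The reference
curve is an ordinary least-squares fit of log(ratio) on log(distance) over
background captures; a screened fragment is a loop partner when its
replicate capture frequency is significantly above the curve's expected
value at its distance, and (by default) at least twofold above it.

Significance
------------
The default test compares the fragment's mean log ratio to the curve's
prediction using the model-wide pooled error, in the manner of a
least-squares-means contrast: the residual standard deviation of the curve
fit estimates the per-capture noise, so

    t = (log_mean - log f(d)) / (residual_sd * sqrt(1/n + 1/N + leverage))

on N-2 degrees of freedom, where n is the fragment's uncensored replicate
count, N the number of captures behind the curve, and leverage the usual
OLS prediction term.  This is exactly calibrated when background scatter
and replicate noise share one scale.  A per-fragment variant using the
replicate standard error with the curve residual added in quadrature is
available as ``variance="replicate"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayCurve",
    "LoopCall",
    "fit_decay_curve",
    "expected_ratio",
    "test_fragment",
    "test_table",
    "call_stes",
]

LONG_RANGE = "long-range"
PROXIMAL = "proximal"


@dataclass(frozen=True)
class DecayCurve:
    """Fitted log-log distance-decay reference (null) model.

    ``log_a`` and ``slope`` parameterise log(ratio) = log_a + slope*log(d)
    with d in bp; ``x_mean``/``s_xx`` (moments of log d over the fit points)
    support prediction standard errors.  Beyond ``d_max`` the curve is held
    at its value at ``d_max``: long-range linkage background is at a
    minimum and flat at such distances.
    """

    log_a: float
    slope: float
    residual_sd: float
    d_min: float
    d_max: float
    n_points: int
    x_mean: float
    s_xx: float
    method: str = "ols-loglog"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DecayCurve":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DecayCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class LoopCall:
    target_id: str
    distance: float
    observed: float      # arithmetic-mean relative crosslinking
    expected: float      # curve value at the fragment's distance
    fold: float
    log_mean: float
    n_uncensored: int
    p_value: float
    regime: str
    extrapolated: bool
    status: str
    q_value: float = float("nan")
    is_ste: bool = False


def fit_decay_curve(
    distances,
    ratios,
    fit_range: tuple[float, float] | None = None,
    exclude=None,
    censored=None,
    min_points: int = 10,
) -> DecayCurve:
    """OLS fit of log(ratio) on log(distance) over background captures.

    ``exclude`` masks known/suspected loop pairs out of the fit; censored
    (detection-floor) captures are excluded as they carry no intensity.
    """
    d = np.asarray(distances, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be > 0")
    keep = np.ones(len(d), dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if censored is not None:
        keep &= ~np.asarray(censored, dtype=bool)
    if fit_range is not None:
        lo, hi = fit_range
        keep &= (d >= lo) & (d <= hi)
    keep &= r > 0
    d, r = d[keep], r[keep]

    if len(d) < min_points:
        raise ValueError(f"need >= {min_points} background pairs in range, got {len(d)}")
    x, y = np.log(d), np.log(r)
    s_xx = float(np.sum((x - x.mean()) ** 2))
    if s_xx < 1e-12:
        raise ValueError("all fit distances equal: decay slope is unidentifiable")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / s_xx)
    log_a = float(y.mean() - slope * x.mean())
    resid = y - (log_a + slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (len(d) - 2))) if len(d) > 2 else 0.0
    return DecayCurve(
        log_a=log_a,
        slope=slope,
        residual_sd=residual_sd,
        d_min=float(d.min()),
        d_max=float(d.max()),
        n_points=len(d),
        x_mean=float(x.mean()),
        s_xx=s_xx,
    )


def expected_ratio(curve: DecayCurve, d: float, with_flag: bool = False):
    """Curve value at distance ``d`` bp; clamped beyond the fitted range.

    With ``with_flag=True`` returns ``(value, extrapolated)`` where the flag
    marks distances beyond ``d_max`` (value held at the d_max floor).
    """
    if d <= 0:
        raise ValueError(f"distance must be > 0, got {d}")
    extrapolated = d > curve.d_max
    d_eff = min(d, curve.d_max)
    value = math.exp(curve.log_a + curve.slope * math.log(d_eff))
    return (value, extrapolated) if with_flag else value


def _prediction_term(curve: DecayCurve, d: float) -> float:
    """Leverage part of the prediction variance, (1/N + (x - x_mean)^2 / S_xx)."""
    x = math.log(min(d, curve.d_max))
    return 1.0 / curve.n_points + (x - curve.x_mean) ** 2 / curve.s_xx


def test_fragment(
    rc,
    curve: DecayCurve,
    long_range_cutoff: float = 100_000,
    variance: str = "pooled",
) -> LoopCall:
    """One-sided test of a fragment's capture against the distance-expected value.

    ``rc`` is any object with attributes target_id, distance_bp (or
    distance), mean_ratio, log_mean, log_sd, n_uncensored, status.
    Fragments with every replicate at the detection floor are "no capture"
    (p = 1).  Identical replicate values give replicate sd 0; the pooled
    error (or, in replicate mode, the curve residual alone) then carries
    the test.
    """
    get = lambda name, alt=None: getattr(rc, name, None) if not isinstance(rc, dict) else rc.get(name, alt)
    target_id = get("target_id")
    d = float(get("distance_bp") or get("distance"))
    status = get("status")
    n_unc = int(get("n_uncensored"))
    mean_ratio = float(get("mean_ratio"))
    log_mean = float(get("log_mean"))
    log_sd = float(get("log_sd"))

    exp_val, extrapolated = expected_ratio(curve, d, with_flag=True)
    regime = LONG_RANGE if d > long_range_cutoff else PROXIMAL

    if status == "no capture":
        return LoopCall(target_id, d, mean_ratio, exp_val, mean_ratio / exp_val,
                        float("nan"), 0, 1.0, regime, extrapolated, status)
    if n_unc == 0:
        raise ValueError(f"{target_id}: no uncensored replicates but status {status!r}")

    diff = log_mean - math.log(exp_val)
    lev = _prediction_term(curve, d)
    if variance == "pooled":
        se = curve.residual_sd * math.sqrt(1.0 / n_unc + lev)
        df = curve.n_points - 2
    elif variance == "replicate":
        s = 0.0 if (n_unc < 2 or not np.isfinite(log_sd)) else log_sd
        se = math.sqrt(s**2 / n_unc + curve.residual_sd**2 * (1.0 + lev))
        df = max(n_unc - 1, 1)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")

    if se <= 0:
        p = 0.5 if diff == 0 else (0.0 if diff > 0 else 1.0)
    else:
        p = float(stats.t.sf(diff / se, df))

    return LoopCall(target_id, d, mean_ratio, exp_val, mean_ratio / exp_val,
                    log_mean, n_unc, p, regime, extrapolated, status)


def test_table(
    table: pd.DataFrame,
    curve: DecayCurve,
    long_range_cutoff: float = 100_000,
    variance: str = "pooled",
) -> list[LoopCall]:
    """Run ``test_fragment`` over every scoreable row of a capture table."""
    calls = []
    for row in table.itertuples(index=False):
        if row.status == "insufficient replicates":
            continue
        calls.append(test_fragment(row, curve, long_range_cutoff, variance))
    return calls


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH q-values (scipy's step-up false discovery control)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


def call_stes(
    calls: list[LoopCall],
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> list[LoopCall]:
    """Finalize loop calls: BH correction across the screen plus a fold gate.

    A fragment is a tethering element when its BH q-value is <= alpha AND
    its observed capture is at least ``min_fold`` times the expected value
    (set min_fold=1 to reproduce pure-significance behaviour).  Output is
    sorted by genomic coordinate (parsed from the chrom:start-end ids), so
    results depend on input content, not input order.
    """
    if not calls:
        raise ValueError("no calls to finalize")

    def coord(c: LoopCall):
        try:
            chrom, span = c.target_id.rsplit(":", 1)
            return (chrom, int(span.split("-")[0]))
        except (ValueError, AttributeError):
            return ("", 0) if c.target_id is None else (str(c.target_id), 0)

    order = sorted(range(len(calls)), key=lambda i: coord(calls[i]))
    ps = np.array([calls[i].p_value for i in order])
    qs = benjamini_hochberg(ps)
    out = []
    for q, i in zip(qs, order):
        c = calls[i]
        is_ste = bool(q <= alpha and c.status == "ok" and c.observed >= min_fold * c.expected)
        out.append(LoopCall(c.target_id, c.distance, c.observed, c.expected, c.fold,
                            c.log_mean, c.n_uncensored, c.p_value, c.regime,
                            c.extrapolated, c.status, float(q), is_ste))
    out.sort(key=coord)
    return out


def calls_to_frame(calls: list[LoopCall]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(c) for c in calls])
    return df.rename(columns={"p_value": "p", "q_value": "q"})
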