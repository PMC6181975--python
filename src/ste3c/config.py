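"""Simulation configuration.

The synthetic generator emulates every input of a viewpoint 3C screen over a
Hox-cluster-sized locus: a restriction map with the viewpoint and each loop
partner on its own fragment, replicate band intensities following a power-law
distance decay with planted loop enrichments and lognormal noise, blocky
repressive histone-mark tracks, insulator binding sites, and per-construct
embryo reporter ratios for enhancer-blocking assays.

Distance convention of the decay model: ``background_scale`` (a) is the
expected relative-crosslinking ratio at 1 kb separation, i.e.
``mu(d) = a * (d / 1000)**b`` with d in bp.  With the defaults
(a=100, b=-1.2, floor=0.05) background is ~0.9 at 50 kb and ~0.19 at 184 kb,
so distal loop partners remain above the detection floor while the floor is
reached beyond ~560 kb — the regime in which genuine long-range partners
stand out against near-zero linkage background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = ["PlantedLoop", "DomainSpec", "InsulatorSiteSpec", "RatioComponent", "SimulationConfig"]


@dataclass(frozen=True)
class PlantedLoop:
    """A ground-truth loop partner: target position and fold enrichment over background."""

    position: int
    enrichment: float

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError(f"loop enrichment must be >= 1, got {self.enrichment}")


@dataclass(frozen=True)
class DomainSpec:
    """One chromatin domain of a simulated histone-mark track."""

    start: int
    end: int
    mean_level: float
    state: str  # "enriched" | "depleted"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("domain start must be < end")
        if self.state not in ("enriched", "depleted"):
            raise ValueError(f"domain state must be enriched|depleted, got {self.state!r}")
        if self.mean_level < 0:
            raise ValueError("domain mean_level must be >= 0")


@dataclass(frozen=True)
class InsulatorSiteSpec:
    start: int
    end: int
    proteins: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("insulator site start must be < end")
        if not self.proteins:
            raise ValueError("insulator site needs a non-empty protein set")


@dataclass(frozen=True)
class RatioComponent:
    """One mixture component of a construct's embryo H/N ratio distribution."""

    weight: float
    median_ratio: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.weight < 0 or self.median_ratio <= 0 or self.log_sd < 0:
            raise ValueError("invalid ratio component")


def _default_domain_spec() -> dict[str, list[DomainSpec]]:
    # Two repressive marks sharing boundaries at the three planted loop
    # anchors: Hox-like enriched blocks alternating with depleted non-Hox
    # blocks, as seen around tethering elements in embryonic ChIP profiles.
    def blocks(hi: float, lo: float) -> list[DomainSpec]:
        return [
            DomainSpec(0, 66_000, hi, "enriched"),
            DomainSpec(66_000, 300_000, lo, "depleted"),
            DomainSpec(300_000, 396_000, hi, "enriched"),
            DomainSpec(396_000, 500_000, lo, "depleted"),
        ]

    return {"H3K9me3": blocks(10.0, 1.0), "H3K27me3": blocks(8.0, 1.0)}


def _default_insulator_sites() -> list[InsulatorSiteSpec]:
    cI = ("dCTCF", "CP190", "Mod(mdg4)")
    sites = [
        InsulatorSiteSpec(64_500, 66_500, cI + ("SuHw",)),   # LP2-like, class I+II, loop anchor
        InsulatorSiteSpec(249_000, 251_000, cI),             # viewpoint itself, class I
        InsulatorSiteSpec(299_000, 301_000, cI),             # DS1-like, class I, loop anchor
        InsulatorSiteSpec(395_000, 397_000, ("GAF",)),       # AU1-like, GAF-only, loop anchor
    ]
    # Non-looping candidate sites with similar binding profiles, spread over
    # the screened fragments: looping is selective among them.
    for pos in (30_000, 95_000, 130_000, 165_000, 200_000, 330_000, 360_000, 430_000, 470_000):
        sites.append(InsulatorSiteSpec(pos - 1_000, pos + 1_000, cI))
    return sites


def _default_construct_spec() -> dict[str, list[RatioComponent]]:
    # H/N reporter-ratio distributions per transgene: a neutral spacer does
    # not block (ratio ~1); single insulators block strongly (~5.5-6);
    # tandem pairings either bypass (ratio back near 1) or augment (>6).
    return {
        "spacer": [RatioComponent(1.0, 1.0, 0.10)],
        "SF1": [RatioComponent(1.0, 5.5, 0.15)],
        "DS1": [RatioComponent(1.0, 5.0, 0.15)],
        "AU1": [RatioComponent(1.0, 4.5, 0.15)],
        "LP2": [RatioComponent(1.0, 5.0, 0.15)],
        "SF1-DS1-ff": [RatioComponent(1.0, 1.2, 0.15)],   # bypass
        "SF1-AU1-ff": [RatioComponent(1.0, 1.3, 0.15)],   # bypass
        "LP2-SF1-ff": [RatioComponent(1.0, 5.5, 0.15)],   # no bypass
        "LP2-SF1-rf": [RatioComponent(1.0, 7.5, 0.15)],   # augmentation
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen; defaults define the study conditions."""

    locus_length: int = 500_000
    chrom: str = "locus"
    motif: str = "GAATTC"
    cut_offset: int = 1
    viewpoint_position: int = 250_000
    background_scale: float = 100.0     # a: expected ratio at 1 kb
    decay_exponent: float = -1.2        # b: log-log slope
    replicate_noise_sd: float = 0.2     # sigma of log-intensity noise
    detection_floor: float = 0.05       # minimum observable relative crosslinking
    n_replicates: int = 3
    planted_loops: list[PlantedLoop] = field(
        default_factory=lambda: [
            PlantedLoop(66_000, 5.0),    # LP2-like, 184 kb upstream
            PlantedLoop(300_000, 5.0),   # DS1-like, 50 kb downstream
            PlantedLoop(396_000, 5.0),   # AU1-like, 146 kb downstream
        ]
    )
    n_fragments: int = 40               # viewpoint + 39 screened targets
    special_flank: int = 3_000          # half-width of viewpoint/loop fragments
    control_level: float = 100.0        # median control-template band intensity
    control_log_sd: float = 0.1
    domain_spec: dict[str, list[DomainSpec]] = field(default_factory=_default_domain_spec)
    track_noise_sd: float = 1.8         # 20% of the default 10-vs-1 level gap
    insulator_sites: list[InsulatorSiteSpec] = field(default_factory=_default_insulator_sites)
    construct_spec: dict[str, list[RatioComponent]] = field(default_factory=_default_construct_spec)
    embryo_n_median: float = 10.0       # NEE-domain staining level scale
    embryo_n_log_sd: float = 0.2
    n_lines: int = 3                    # independent insertion lines per construct
    seed: int = 0

    def __post_init__(self) -> None:
        self._coerce()
        if not 0 <= self.viewpoint_position < self.locus_length:
            raise ValueError("viewpoint_position must lie within the locus")
        for loop in self.planted_loops:
            if not 0 <= loop.position < self.locus_length:
                raise ValueError(f"planted loop at {loop.position} outside locus")
        if self.background_scale <= 0:
            raise ValueError("background_scale must be > 0")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")
        for mark, domains in self.domain_spec.items():
            ordered = sorted(domains, key=lambda d: d.start)
            if ordered[0].start != 0 or ordered[-1].end != self.locus_length:
                raise ValueError(f"{mark}: domains must tile the locus")
            for a, b in zip(ordered[:-1], ordered[1:]):
                if a.end != b.start:
                    raise ValueError(f"{mark}: domains must be non-overlapping and contiguous")

    def _coerce(self) -> None:
        """Rebuild nested dataclasses from plain dicts/lists (YAML round-trip)."""
        self.planted_loops = [
            p if isinstance(p, PlantedLoop) else PlantedLoop(**p) if isinstance(p, dict) else PlantedLoop(*p)
            for p in self.planted_loops
        ]
        self.domain_spec = {
            mark: [d if isinstance(d, DomainSpec) else DomainSpec(**d) if isinstance(d, dict) else DomainSpec(*d)
                   for d in doms]
            for mark, doms in self.domain_spec.items()
        }
        self.insulator_sites = [
            s if isinstance(s, InsulatorSiteSpec)
            else InsulatorSiteSpec(s["start"], s["end"], tuple(s["proteins"])) if isinstance(s, dict)
            else InsulatorSiteSpec(s[0], s[1], tuple(s[2]))
            for s in self.insulator_sites
        ]
        self.construct_spec = {
            name: [c if isinstance(c, RatioComponent) else RatioComponent(**c) if isinstance(c, dict) else RatioComponent(*c)
                   for c in comps]
            for name, comps in self.construct_spec.items()
        }

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        for site in d["insulator_sites"]:
            site["proteins"] = list(site["proteins"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
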