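"""In-silico restriction digestion and fragment bookkeeping.

A viewpoint 3C screen measures ligation ("capture") frequency between one
anchor restriction fragment and a panel of distal fragments.  Everything
downstream is keyed on the fragments produced by digesting the locus with
the screen's enzyme (EcoRI by default, recognition site GAATTC, cut after
the first base: G^AATTC).

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "RestrictionFragment",
    "PrimerPlacement",
    "digest",
    "find_motif_positions",
    "fragment_distance",
    "fragment_id",
    "check_primer_design",
]

VALID_BASES = frozenset("ACGT")


def fragment_id(chrom: str, start: int, end: int) -> str:
    """Stable join-friendly fragment key, ``chrom:start-end``."""
    return f"{chrom}:{start}-{end}"


@dataclass(frozen=True)
class RestrictionFragment:
    """A genomic interval produced by in-silico digestion."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"fragment requires start < end, got [{self.start}, {self.end})")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return fragment_id(self.chrom, self.start, self.end)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class PrimerPlacement:
    """A primer's offset (bp) from the nearer restriction boundary of its fragment."""

    fragment_id: str
    primer_offset: int


def find_motif_positions(sequence: str, motif: str) -> list[int]:
    """All start positions of ``motif`` in ``sequence``, overlapping hits included.

    Scans every position (``str.find`` restarted one base after each hit),
    so e.g. AAAA contains AA at 0, 1, 2.
    """
    positions: list[int] = []
    i = sequence.find(motif)
    while i != -1:
        positions.append(i)
        i = sequence.find(motif, i + 1)
    return positions


def digest(
    sequence: str,
    motif: str = "GAATTC",
    cut_offset: int = 1,
    chrom: str = "locus",
) -> list[RestrictionFragment]:
    """Digest a sequence at every motif occurrence.

    Cut positions are ``site_start + cut_offset`` for each occurrence of the
    recognition motif on the given strand (EcoRI's site is palindromic so one
    strand suffices).  Fragments are the intervals between consecutive cuts
    plus the two flanks; they tile the sequence.

    Parameters
    ----------
    sequence : str
        Uppercase-normalised DNA; any characters allowed in the sequence
        itself, only the motif is restricted to ACGT.
    motif : str
        Recognition sequence; must be non-empty and unambiguous (ACGT only).
    cut_offset : int
        Bases from the motif start to the cut, ``0 <= cut_offset <= len(motif)``.
        Default 1 for EcoRI (G^AATTC).
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif) - VALID_BASES:
        raise ValueError(f"motif may contain only ACGT, got {motif!r}")
    if not 0 <= cut_offset <= len(motif):
        raise ValueError(f"cut_offset must lie in [0, {len(motif)}], got {cut_offset}")

    sequence = sequence.upper()
    n = len(sequence)
    if len(motif) > n:
        return [RestrictionFragment(chrom, 0, n)]

    cuts = sorted({p + cut_offset for p in find_motif_positions(sequence, motif)})
    bounds = [0] + [c for c in cuts if 0 < c < n] + [n]
    return [
        RestrictionFragment(chrom, a, b)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]


def fragment_distance(f1: RestrictionFragment, f2: RestrictionFragment) -> int:
    """Center-to-center genomic separation in bp.

    Capture frequency is conventionally plotted against the distance between
    fragment centers; trans (different-chromosome) pairs are out of scope.
    """
    if f1.chrom != f2.chrom:
        raise ValueError(
            f"fragments on different sequences ({f1.chrom} vs {f2.chrom}); "
            "trans contacts are not supported"
        )
    return abs(f1.center - f2.center)


@dataclass
class PrimerReport:
    fragment_id: str
    primer_offset: int | None
    designable: bool
    offset_ok: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.designable and self.offset_ok


def check_primer_design(
    fragments: list[RestrictionFragment],
    placements: list[PrimerPlacement],
    min_offset: int = 100,
    max_offset: int = 150,
) -> list[PrimerReport]:
    """QC primer placements against the comparable-product-size rule.

    Capture PCR primers sit a fixed small distance from the restriction
    boundary so all capture products have comparable size; the default window
    is 100-150 bp.  Fragments shorter than ``2 * min_offset`` cannot host a
    conforming primer measured from the nearer boundary and are flagged
    undesignable.  Report-only: nothing raises.
    """
    by_id = {f.id: f for f in fragments}
    placed = {p.fragment_id: p for p in placements}
    unknown = [p.fragment_id for p in placements if p.fragment_id not in by_id]
    if unknown:
        raise KeyError(f"placements reference unknown fragments: {unknown}")

    reports = []
    for frag in fragments:
        p = placed.get(frag.id)
        designable = frag.length >= 2 * min_offset
        reasons = []
        if not designable:
            reasons.append(f"fragment length {frag.length} < {2 * min_offset} (undesignable)")
        if p is None:
            reports.append(PrimerReport(frag.id, None, designable, False, reasons + ["no placement"]))
            continue
        offset_ok = min_offset <= p.primer_offset <= max_offset
        if not offset_ok:
            side = "below" if p.primer_offset < min_offset else "above"
            reasons.append(f"offset {p.primer_offset} {side} window [{min_offset}, {max_offset}]")
        reports.append(PrimerReport(frag.id, p.primer_offset, designable, offset_ok, reasons))
    return reports
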