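"""Exact/degenerate consensus-core matching for circadian motif families.

Six families are bundled by default: the canonical E-box (CACGTG), the
degenerate E-box (CANNTG), the D-box (TTATGYAA), the CRE (TGACGTCA), the
Pdp1 core (ATTTAT/ATAAAT) and the PER-repeat core (CATAC/GTATG).  Patterns
are IUPAC strings; a sequence N never matches any pattern position (including
pattern N), so masked sequence cannot produce hits.  Positions are reported
on the + strand of the extracted promoter window; because every canonical
E-box is also a degenerate E-box, degenerate hits that coincide with a
canonical hit are removed by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import yaml

from .errors import MotifParseError
from .pwm_model import MotifHit
from .sequence_io import PromoterRegion, reverse_complement

__all__ = [
    "IUPAC",
    "ConsensusMotif",
    "ConsensusConfig",
    "CompiledPattern",
    "compile_pattern",
    "default_families",
    "load_families",
    "scan_consensus",
    "count_by_family",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class CompiledPattern:
    """Position-wise allowed-base matcher compiled from an IUPAC string."""

    iupac: str
    allowed: tuple[frozenset[str], ...]
    regex: re.Pattern

    @property
    def width(self) -> int:
        return len(self.allowed)

    def matches(self, window: str) -> bool:
        if len(window) != self.width:
            return False
        return all(b in ok for b, ok in zip(window, self.allowed))

    def finditer(self, sequence: str):
        """0-based start indices of all (overlapping) matches."""
        return (m.start() for m in self.regex.finditer(sequence))


def compile_pattern(iupac: str) -> CompiledPattern:
    """Compile an IUPAC string into a window matcher.

    N in the pattern allows {A,C,G,T}; an N in the *sequence* matches no
    pattern position.
    """
    if not iupac:
        raise ValueError("empty IUPAC pattern")
    allowed = []
    rx_parts = []
    for ch in iupac.upper():
        if ch not in IUPAC:
            raise ValueError(f"illegal IUPAC code {ch!r} in pattern {iupac!r}")
        bases = IUPAC[ch]
        allowed.append(bases)
        rx_parts.append(
            next(iter(bases)) if len(bases) == 1
            else "[" + "".join(sorted(bases)) + "]"
        )
    # Lookahead makes overlapping occurrences visible.
    regex = re.compile(r"(?=" + "".join(rx_parts) + r")")
    return CompiledPattern(iupac=iupac.upper(), allowed=tuple(allowed), regex=regex)


@dataclass(frozen=True)
class ConsensusMotif:
    """A motif family: one or more equal-width IUPAC alternatives."""

    family: str
    patterns: tuple[CompiledPattern, ...]

    @property
    def width(self) -> int:
        return self.patterns[0].width

    @property
    def iupac_patterns(self) -> tuple[str, ...]:
        return tuple(p.iupac for p in self.patterns)


def consensus_motif(family: str, patterns) -> ConsensusMotif:
    compiled = tuple(compile_pattern(p) for p in patterns)
    if not compiled:
        raise MotifParseError(f"family {family!r}: no patterns")
    if len({p.width for p in compiled}) != 1:
        raise MotifParseError(f"family {family!r}: alternatives differ in width")
    return ConsensusMotif(family=family, patterns=compiled)


@dataclass(frozen=True)
class ConsensusConfig:
    """Consensus scan policy.

    ``strands='plus_only'`` reproduces the + strand reporting convention
    (near-palindromic cores may act in either orientation; both-strand
    scanning is the explicit alternative).  ``dedup_degenerate_ebox`` drops
    degenerate E-box hits that coincide with a canonical E-box hit.
    """

    strands: str = "plus_only"  # "plus_only" | "both"
    dedup_degenerate_ebox: bool = True

    def __post_init__(self) -> None:
        if self.strands not in ("plus_only", "both"):
            raise ValueError("strands must be 'plus_only' or 'both'")


def default_families() -> list[ConsensusMotif]:
    """The six bundled circadian families."""
    text = resources.files("circamotif").joinpath("data/families.yaml").read_text()
    return _families_from_mapping(yaml.safe_load(text))


def load_families(path) -> list[ConsensusMotif]:
    """Load family definitions from a YAML mapping {family: [IUPAC, ...]}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise MotifParseError(f"{path}: expected a non-empty family mapping")
    return _families_from_mapping(data)


def _families_from_mapping(data: dict) -> list[ConsensusMotif]:
    out = []
    for family, patterns in data.items():
        if isinstance(patterns, str):
            patterns = [patterns]
        out.append(consensus_motif(str(family), [str(p) for p in patterns]))
    return out


def scan_consensus(
    region: PromoterRegion,
    motifs: list[ConsensusMotif] | None = None,
    config: ConsensusConfig | None = None,
) -> list[MotifHit]:
    """Find every consensus-core occurrence in a promoter window.

    Hits carry no scores (source='consensus').  In 'both' mode, windows whose
    reverse complement matches a pattern are additionally reported with
    strand '-', still anchored at the + strand 5'-most base; ``matched`` is
    always the + strand substring.
    """
    motifs = default_families() if motifs is None else motifs
    config = config or ConsensusConfig()
    L = region.length
    seq = region.sequence
    for m in motifs:
        if m.width > L:
            raise ValueError(
                f"family {m.family!r} width {m.width} exceeds promoter length {L}"
            )

    hits: list[MotifHit] = []
    rc_seq = reverse_complement(seq) if config.strands == "both" else None
    for motif in motifs:
        w = motif.width
        starts: set[tuple[int, str]] = set()
        for pat in motif.patterns:
            for i in pat.finditer(seq):
                starts.add((i, "+"))
            if rc_seq is not None:
                for j in pat.finditer(rc_seq):
                    starts.add((L - j - w, "-"))
        for i, strand in sorted(starts):
            hits.append(
                MotifHit(
                    family=motif.family,
                    source="consensus",
                    rel_start=i - L,
                    strand=strand,
                    matched=seq[i : i + w],
                )
            )

    if config.dedup_degenerate_ebox:
        canonical = {
            (h.rel_start, h.strand)
            for h in hits
            if h.family == "Ebox_canonical"
        }
        hits = [
            h
            for h in hits
            if not (
                h.family == "Ebox_degenerate"
                and (h.rel_start, h.strand) in canonical
            )
        ]

    hits.sort(key=lambda h: (h.rel_start, h.family, h.strand))
    return hits


def count_by_family(hits: list[MotifHit]) -> dict[str, int]:
    """Per-family hit counts; values sum to len(hits)."""
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.family] = counts.get(h.family, 0) + 1
    return counts
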