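"""Synthetic promoter fixtures with known ground truth.

Backgrounds are sampled from a zero- or first-order Markov model and can be
*purged* of chosen motif families (offending windows are locally resampled
until no match remains), after which exact motif cores — or PWM-sampled
sites — are planted at specified TSS-relative positions.  The emitted
TruthTable records exactly what was planted, so scanner recall and precision
can be measured without any genomic download.

``ammtr_layout`` encodes the published site map of the honeybee
melatonin-receptor (AmMTR) 3 kb promoter: three clustered Pdp1 cores
(-820, -357, -102), degenerate E-boxes (-2762, -1580, -1383), a canonical
CLOCK-type E-box (-1334), a CRE at -93 and D-box sites at -2701, -2498,
-457 and -132.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus_scan import ConsensusMotif, default_families
from .enrichment import BackgroundModel, sample_base_array
from .errors import GenerationError, RangeError
from .pwm_model import PWM, relative_score
from .sequence_io import (
    PromoterRegion,
    decode_bases,
    encode_bases,
    reverse_complement,
)

__all__ = [
    "PlantSpec",
    "TruthTable",
    "generate_background",
    "plant_motifs",
    "ammtr_layout",
    "sample_pwm_site",
    "make_fixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantSpec:
    """One site to plant: family, exact sequence, TSS-relative start, strand."""

    family: str
    site_sequence: str
    rel_start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.site_sequence:
            raise ValueError("site_sequence must be non-empty")

    @property
    def width(self) -> int:
        return len(self.site_sequence)

    @property
    def rel_end(self) -> int:
        return self.rel_start + self.width

    def validate_bounds(self, length: int) -> None:
        if self.rel_start < -length or self.rel_end > 0:
            raise RangeError(
                f"plant {self.family} at {self.rel_start} (width {self.width}) "
                f"outside the window [-{length}, -1]"
            )


@dataclass(frozen=True)
class TruthTable:
    """Ledger of planted sites plus generator metadata."""

    rows: tuple[PlantSpec, ...]
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": r.family,
                    "rel_start": r.rel_start,
                    "strand": r.strand,
                    "site_sequence": r.site_sequence,
                }
                for r in self.rows
            ],
            columns=["family", "rel_start", "strand", "site_sequence"],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


def _match_positions(
    codes: np.ndarray, families: list[ConsensusMotif], both_strands: bool
) -> list[tuple[int, int]]:
    """(start, width) of every + strand (and optionally -) family match."""
    seq = decode_bases(codes)
    seqs = [seq]
    if both_strands:
        seqs.append(reverse_complement(seq))
    L = codes.size
    out = []
    for motif in families:
        w = motif.width
        for pat in motif.patterns:
            for i in pat.finditer(seqs[0]):
                out.append((i, w))
            if both_strands:
                for j in pat.finditer(seqs[1]):
                    out.append((L - j - w, w))
    return out


def generate_background(
    length: int,
    model: BackgroundModel | None = None,
    seed: int = 0,
    purge_families: list[ConsensusMotif] | None = None,
    both_strands: bool = False,
    max_sweeps: int = 200,
) -> str:
    """Sample one background sequence, optionally free of listed motif cores.

    Purging locally resamples every window that matches a listed family
    (+ strand by default) and repeats until the sequence is clean, up to
    ``max_sweeps`` passes.  Deterministic given (seed, parameters).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    model = model or BackgroundModel.uniform()
    rng = np.random.default_rng(seed)
    codes = sample_base_array(model, length, 1, rng)[0]
    if purge_families:
        for motif in purge_families:
            if motif.width > length:
                raise ValueError(
                    f"purge family {motif.family!r} wider than sequence"
                )
        for _ in range(max_sweeps):
            offending = _match_positions(codes, purge_families, both_strands)
            if not offending:
                break
            for start, w in offending:
                # Resample the window; for order 1, continue the chain from
                # the base preceding the window (or the initial law at 0).
                if model.order == 0:
                    cum = np.cumsum(model.initial)
                    codes[start : start + w] = np.searchsorted(
                        cum, rng.random(w), side="right"
                    )
                else:
                    prev = codes[start - 1] if start > 0 else None
                    cum_t = np.cumsum(model.transitions, axis=1)
                    for k in range(start, start + w):
                        if prev is None:
                            cum = np.cumsum(model.initial)
                        else:
                            cum = cum_t[prev]
                        codes[k] = np.searchsorted(cum, rng.random(), side="right")
                        prev = codes[k]
        else:
            raise GenerationError(
                f"purge did not converge within {max_sweeps} sweeps"
            )
    return decode_bases(codes)


def plant_motifs(
    background: str,
    plants: list[PlantSpec],
    source_id: str = "synthetic_promoter",
    tss_genomic: int | None = None,
    strand: str = "+",
    assembly_label: str = "synthetic",
    metadata: dict | None = None,
) -> tuple[PromoterRegion, TruthTable]:
    """Write sites into a background sequence at their TSS-relative positions.

    Minus-strand plants are inserted as the reverse complement of their
    ``site_sequence`` so the site reads correctly on the - strand.  Plants
    must be pairwise non-overlapping and fully inside the window.
    """
    L = len(background)
    for p in plants:
        p.validate_bounds(L)
    ordered = sorted(plants, key=lambda p: p.rel_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.rel_start < a.rel_end:
            raise ValueError(
                f"overlapping plants: {a.family}@{a.rel_start} (width {a.width}) "
                f"and {b.family}@{b.rel_start}"
            )
    seq = bytearray(background, "ascii")
    for p in ordered:
        i = p.rel_start + L
        inserted = (
            p.site_sequence if p.strand == "+"
            else reverse_complement(p.site_sequence)
        )
        seq[i : i + p.width] = inserted.encode("ascii")
    region = PromoterRegion(
        source_id=source_id,
        tss_genomic=L + 1 if tss_genomic is None else tss_genomic,
        strand=strand,
        length=L,
        sequence=seq.decode("ascii"),
        assembly_label=assembly_label,
    )
    truth = TruthTable(rows=tuple(ordered), metadata=dict(metadata or {}))
    return region, truth


def ammtr_layout() -> list[PlantSpec]:
    """The published AmMTR promoter site layout as plant specs (all + strand).

    Degenerate E-box plants use CAGTTG — a CANNTG instance that is not
    CACGTG — so the canonical and degenerate families stay disjoint in
    fixtures; the D-box instance TTATGCAA and the cores CACGTG, TGACGTCA and
    ATTTAT are the families' canonical alternatives.
    """
    layout = [
        ("Ebox_degenerate", "CAGTTG", -2762),
        ("Dbox", "TTATGCAA", -2701),
        ("Dbox", "TTATGCAA", -2498),
        ("Ebox_degenerate", "CAGTTG", -1580),
        ("Ebox_degenerate", "CAGTTG", -1383),
        ("Ebox_canonical", "CACGTG", -1334),
        ("Pdp1", "ATTTAT", -820),
        ("Dbox", "TTATGCAA", -457),
        ("Pdp1", "ATTTAT", -357),
        ("Dbox", "TTATGCAA", -132),
        ("Pdp1", "ATTTAT", -102),
        ("CRE", "TGACGTCA", -93),
    ]
    return [
        PlantSpec(family=f, site_sequence=s, rel_start=r, strand="+")
        for f, s, r in layout
    ]


def sample_pwm_site(
    pwm: PWM, min_rel_score: float = 0.85, seed: int = 0, max_tries: int = 1000
) -> str:
    """Draw a site word with relative score >= min_rel_score.

    Words are sampled column-wise from the PWM's corrected site frequencies
    and rejected until the score clears the floor; after ``max_tries``
    rejections the consensus word (which always scores 1.0) is returned.
    """
    if not 0.0 <= min_rel_score <= 1.0:
        raise ValueError("min_rel_score must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w = pwm.width
    cum = np.cumsum(pwm.freqs, axis=0)  # 4 x w
    for _ in range(max_tries):
        draws = (rng.random(w)[None, :] < cum).argmax(axis=0)
        word = "".join(_BASES[b] for b in draws)
        if relative_score(pwm, pwm.score_word(word)) >= min_rel_score:
            return word
    return pwm.consensus()


def _purge_around_plants(
    codes: np.ndarray,
    plants: list[PlantSpec],
    families: list[ConsensusMotif],
    rng: np.random.Generator,
    model: BackgroundModel,
    both_strands: bool,
    max_sweeps: int = 200,
) -> None:
    """Resample non-planted bases until only the planted windows match.

    Planting into a purged background can still create matches spanning a
    plant/background junction; this pass removes them while freezing every
    planted base.  A match window is left alone only when it coincides
    exactly with a planted interval.
    """
    L = codes.size
    frozen = np.zeros(L, dtype=bool)
    planted_intervals = set()
    for p in plants:
        i = p.rel_start + L
        frozen[i : i + p.width] = True
        planted_intervals.add((i, p.width))
    cum_init = np.cumsum(model.initial)
    for _ in range(max_sweeps):
        spurious = [
            (s, w)
            for s, w in _match_positions(codes, families, both_strands)
            if (s, w) not in planted_intervals
        ]
        if not spurious:
            return
        for start, w in spurious:
            free = [k for k in range(start, start + w) if not frozen[k]]
            if not free:
                raise GenerationError(
                    f"cannot remove match at index {start}: every base is planted"
                )
            for k in free:
                if model.order == 0:
                    codes[k] = np.searchsorted(cum_init, rng.random(), "right")
                else:
                    prev = codes[k - 1] if k > 0 else None
                    cum = (
                        cum_init if prev is None
                        else np.cumsum(model.transitions[prev])
                    )
                    codes[k] = np.searchsorted(cum, rng.random(), "right")
    raise GenerationError(f"plant-aware purge did not converge in {max_sweeps} sweeps")


def make_fixture(
    length: int = 3000,
    seed: int = 7,
    layout: list[PlantSpec] | None = None,
    model: BackgroundModel | None = None,
    purge: bool = True,
    both_strands: bool = False,
) -> tuple[PromoterRegion, TruthTable]:
    """Purged background + published-layout plants, with a guarantee that the
    only family-core matches are the planted ones (when ``purge`` is set)."""
    layout = ammtr_layout() if layout is None else layout
    model = model or BackgroundModel.uniform()
    purge_families = default_families() if purge else None
    background = generate_background(
        length,
        model=model,
        seed=seed,
        purge_families=purge_families,
        both_strands=both_strands,
    )
    metadata = {
        "seed": seed,
        "background_order": model.order,
        "purged": bool(purge),
        "length": length,
        "n_planted": len(layout),
    }
    region, truth = plant_motifs(background, layout, metadata=metadata)
    if purge:
        codes = encode_bases(region.sequence)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        _purge_around_plants(
            codes, list(truth.rows), default_families(), rng, model, both_strands
        )
        region = PromoterRegion(
            source_id=region.source_id,
            tss_genomic=region.tss_genomic,
            strand=region.strand,
            length=region.length,
            sequence=decode_bases(codes),
            assembly_label=region.assembly_label,
        )
    return region, truth
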