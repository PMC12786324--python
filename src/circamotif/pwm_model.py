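"""Position frequency/weight matrices and relative-score promoter scanning.

A PFM holds per-position nucleotide counts (rows A,C,G,T).  It is converted
to a log-odds PWM against a background distribution with a pseudocount
distributed by background:

    f_bj = (counts_bj + pseudocount * background_b) / (N_j + pseudocount)
    w_bj = log2(f_bj / background_b)

A candidate window of width w scores ``raw = sum_j w[base_j, j]``; the
min-max normalised *relative score* ``(raw - s_min) / (s_max - s_min)`` lies
in [0, 1], where ``s_min``/``s_max`` are the sums of per-column weight
extrema (the worst and best attainable words).  High-confidence hits are
windows whose relative score meets a threshold (default >= 0.85).  The
relative score is invariant to the logarithm base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateMatrixError, MotifParseError
from .sequence_io import PromoterRegion, encode_bases

__all__ = [
    "PFM",
    "ScoreParams",
    "PWM",
    "ScanConfig",
    "MotifHit",
    "parse_jaspar",
    "read_jaspar",
    "pfm_to_pwm",
    "relative_score",
    "scan_pwm",
    "prune_overlaps",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: 4 x w non-negative counts, rows A,C,G,T."""

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise MotifParseError(
                f"motif {self.motif_id!r}: counts must be 4 x w with w >= 1"
            )
        if (counts < 0).any():
            raise MotifParseError(f"motif {self.motif_id!r}: negative counts")
        colsum = counts.sum(axis=0)
        if (colsum <= 0).any():
            col = int(np.argmax(colsum <= 0))
            raise MotifParseError(
                f"motif {self.motif_id!r}: column {col} sums to zero"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        """Highest-count base per column (ties broken toward A<C<G<T)."""
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class ScoreParams:
    """Constants of the PFM -> log-odds conversion.

    ``pseudocount`` is distributed across bases proportionally to the
    background; the log base is fixed at 2 (the relative score does not
    depend on it).
    """

    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if bg.shape != (4,) or (bg <= 0).any():
            raise ValueError("background must be 4 strictly positive probabilities")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")


@dataclass(frozen=True)
class PWM:
    """Log-odds matrix with min/max attainable scores and site frequencies."""

    motif_id: str
    name: str
    weights: np.ndarray
    s_min: float
    s_max: float
    freqs: np.ndarray  # corrected column frequencies, kept for site sampling

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=0))

    def score_word(self, word: str) -> float:
        idx = encode_bases(word)
        if len(idx) != self.width or (idx > 3).any():
            raise ValueError(
                f"word must be {self.width} unambiguous bases, got {word!r}"
            )
        return float(self.weights[idx, np.arange(self.width)].sum())


@dataclass(frozen=True)
class ScanConfig:
    """PWM scan policy: relative-score threshold, strands, N handling."""

    rel_threshold: float = 0.85
    strands: str = "both"  # "plus_only" | "both"
    skip_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_threshold <= 1.0:
            raise ValueError("rel_threshold must lie in [0, 1]")
        if self.strands not in ("plus_only", "both"):
            raise ValueError("strands must be 'plus_only' or 'both'")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, reported in + strand promoter coordinates.

    ``rel_start`` is the TSS-relative position of the hit's 5'-most base on
    the + strand of the promoter; ``matched`` is the + strand promoter
    substring at that window even for - strand hits.
    """

    family: str
    source: str  # "pwm" | "consensus"
    rel_start: int
    strand: str
    matched: str
    raw_score: float | None = None
    rel_score: float | None = None

    @property
    def width(self) -> int:
        return len(self.matched)

    @property
    def rel_end(self) -> int:
        """TSS-relative position one past the hit's last base (<= 0)."""
        return self.rel_start + self.width


# --- JASPAR parsing ---------------------------------------------------------

_HEADER = re.compile(r"^>\s*(\S+)\s*(.*)$")
_ROW = re.compile(r"^([ACGTacgt])\s*[:|]?\s*\[?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def parse_jaspar(text: str) -> list[PFM]:
    """Parse JASPAR raw PFM text into PFMs.

    Accepts the raw dialect: a ``>ID name`` header followed by four labelled
    count rows (``A [ 4 12 0 ] ...``); brackets are optional and rows may
    appear in any order — the labels drive the A,C,G,T assignment.
    """
    records: list[PFM] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        motif_id, name = header
        missing = sorted(set(_BASES) - set(rows))
        if missing:
            raise MotifParseError(
                f"motif {motif_id!r}: missing row(s) {', '.join(missing)}"
            )
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise MotifParseError(
                f"motif {motif_id!r}: ragged rows (widths {sorted(widths)})"
            )
        if widths == {0}:
            raise MotifParseError(f"motif {motif_id!r}: empty count rows")
        counts = np.array([rows[b] for b in _BASES], dtype=float)
        records.append(PFM(motif_id=motif_id, name=name, counts=counts))
        header, rows = None, {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        m = _HEADER.match(line)
        if m:
            _flush()
            header = (m.group(1), m.group(2).strip())
            continue
        m = _ROW.match(line)
        if m is None or header is None:
            raise MotifParseError(f"line {lineno}: cannot parse {line!r}")
        base = m.group(1).upper()
        if base in rows:
            raise MotifParseError(
                f"motif {header[0]!r}: duplicate row for base {base}"
            )
        try:
            rows[base] = [float(x) for x in m.group(2).split()]
        except ValueError as exc:
            raise MotifParseError(f"line {lineno}: bad count in {line!r}") from exc
    _flush()
    if not records:
        raise MotifParseError("no PFM records found")
    return records


def read_jaspar(path) -> list[PFM]:
    with open(path) as fh:
        return parse_jaspar(fh.read())


# --- PFM -> PWM -------------------------------------------------------------


def pfm_to_pwm(pfm: PFM, params: ScoreParams | None = None) -> PWM:
    """Convert counts to a log2-odds PWM with min/max attainable scores."""
    params = params or ScoreParams()
    bg = params.background
    totals = pfm.counts.sum(axis=0)
    freqs = (pfm.counts + params.pseudocount * bg[:, None]) / (
        totals + params.pseudocount
    )
    weights = np.log2(freqs / bg[:, None])
    s_min = float(weights.min(axis=0).sum())
    s_max = float(weights.max(axis=0).sum())
    if not s_min < s_max:
        raise DegenerateMatrixError(
            f"motif {pfm.motif_id!r}: degenerate PWM (s_min == s_max)"
        )
    return PWM(
        motif_id=pfm.motif_id,
        name=pfm.name or pfm.motif_id,
        weights=weights,
        s_min=s_min,
        s_max=s_max,
        freqs=freqs,
    )


def relative_score(pwm: PWM, raw: float) -> float:
    """Min-max normalise a raw log-odds score into [0, 1]."""
    return (raw - pwm.s_min) / (pwm.s_max - pwm.s_min)


# --- scanning ---------------------------------------------------------------


def _window_scores(codes: np.ndarray, weights5: np.ndarray) -> np.ndarray:
    """Raw scores of every width-w window of an encoded sequence.

    ``weights5`` is the 5 x w weight matrix whose N row is -inf, so windows
    containing N score -inf and never pass a finite threshold.
    """
    w = weights5.shape[1]
    n_win = codes.size - w + 1
    scores = np.zeros(n_win)
    for j in range(w):
        scores += weights5[codes[j : j + n_win], j]
    return scores


def _weights5(pwm: PWM, skip_ambiguous: bool = True) -> np.ndarray:
    # N row: -inf excludes ambiguous windows; otherwise N scores the column
    # minimum (worst case), the conservative finite alternative.
    n_row = np.full(pwm.width, -np.inf) if skip_ambiguous else pwm.weights.min(axis=0)
    return np.vstack([pwm.weights, n_row])


_RC_ROW = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


def scan_pwm(
    pwm: PWM,
    region: PromoterRegion,
    config: ScanConfig | None = None,
    family: str | None = None,
) -> list[MotifHit]:
    """Scan a promoter window with a PWM at a relative-score threshold.

    Every window whose relative score meets ``config.rel_threshold``
    (inclusive) becomes a hit.  With ``strands='both'`` the reverse
    complement of each window is scored with the same PWM and reported with
    strand '-' anchored at the + strand 5'-most base.  Windows containing N
    are skipped.  Hits are sorted by rel_start, '+' before '-'.
    """
    config = config or ScanConfig()
    w = pwm.width
    L = region.length
    if w > L:
        raise ValueError(f"motif width {w} exceeds promoter length {L}")
    family = family or pwm.name or pwm.motif_id
    codes = encode_bases(region.sequence)
    weights5 = _weights5(pwm, config.skip_ambiguous)
    span = pwm.s_max - pwm.s_min

    hits: list[MotifHit] = []

    def _emit(scores: np.ndarray, strand: str) -> None:
        rel = (scores - pwm.s_min) / span
        for i in np.flatnonzero(rel >= config.rel_threshold):
            i = int(i)
            hits.append(
                MotifHit(
                    family=family,
                    source="pwm",
                    rel_start=i - L,
                    strand=strand,
                    matched=region.sequence[i : i + w],
                    raw_score=float(scores[i]),
                    rel_score=float(rel[i]),
                )
            )

    _emit(_window_scores(codes, weights5), "+")
    if config.strands == "both":
        # Score the reverse complement of each window: equivalent to scoring
        # the + strand with the reverse-complemented weight matrix.
        rc_weights5 = weights5[_RC_ROW][:, ::-1]
        _emit(_window_scores(codes, rc_weights5), "-")

    hits.sort(key=lambda h: (h.rel_start, h.strand))
    return hits


def prune_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy non-overlap pruning within each (family, strand) group.

    Keeps the highest relative score; ties go to the 5'-most hit, then to the
    + strand.  Off by default in the scanners — all overlapping hits are
    reported unless this is applied explicitly.
    """
    order = sorted(
        hits,
        key=lambda h: (-(h.rel_score if h.rel_score is not None else 1.0),
                       h.rel_start, h.strand),
    )
    kept: list[MotifHit] = []
    for h in order:
        clash = any(
            k.family == h.family
            and k.strand == h.strand
            and h.rel_start < k.rel_end
            and k.rel_start < h.rel_end
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.rel_start, h.strand))
    return kept
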