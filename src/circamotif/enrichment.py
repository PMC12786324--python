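"""Resampling-based motif enrichment against a Markov background.

The question: does a promoter contain more copies of a motif family than
expected under a null sequence model?  The null is a zero- or first-order
Markov model — either fitted to the query promoter itself (default) or to a
user-supplied promoter set — from which ``n`` background sequences of the
same length are sampled.  The empirical one-sided p-value is

    p = (1 + #{null counts >= observed}) / (1 + n)

(never zero, by the add-one permutation-test convention), corrected across
families by Benjamini-Hochberg or Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .consensus_scan import (
    ConsensusConfig,
    ConsensusMotif,
    count_by_family,
    default_families,
    scan_consensus,
)
from .pwm_model import PWM, ScanConfig, scan_pwm
from .sequence_io import PromoterRegion, decode_bases, encode_bases

__all__ = [
    "BackgroundModel",
    "EnrichmentConfig",
    "EnrichmentResult",
    "fit_markov",
    "sample_sequences",
    "sample_base_array",
    "count_consensus_batch",
    "count_pwm_batch",
    "empirical_enrichment",
    "adjust_pvalues",
    "motif_enrichment",
]


@dataclass(frozen=True)
class BackgroundModel:
    """Zero- or first-order Markov model over {A,C,G,T}.

    ``initial`` is the stationary/order-0 base distribution; ``transitions``
    (order 1 only) is a 4x4 row-stochastic matrix P(next | current).
    """

    order: int
    initial: np.ndarray
    transitions: np.ndarray | None = None
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        init = np.asarray(self.initial, dtype=float)
        object.__setattr__(self, "initial", init)
        if init.shape != (4,) or (init <= 0).any() or abs(init.sum() - 1) > 1e-9:
            raise ValueError("initial must be 4 strictly positive probs summing to 1")
        if self.order == 1:
            trans = np.asarray(self.transitions, dtype=float)
            object.__setattr__(self, "transitions", trans)
            if trans.shape != (4, 4) or (trans <= 0).any():
                raise ValueError("transitions must be a strictly positive 4x4 matrix")
            if np.abs(trans.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError("transition rows must sum to 1")

    @staticmethod
    def uniform() -> "BackgroundModel":
        return BackgroundModel(order=0, initial=np.full(4, 0.25))


def fit_markov(seqs, order: int = 0, pseudocount: float = 1.0) -> BackgroundModel:
    """Fit a Markov background to nucleotide strings (N bases are excluded).

    Order 0 uses add-pseudocount smoothed base frequencies; order 1 smooths
    each transition row likewise and uses the order-0 frequencies as the
    initial distribution.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    seqs = list(seqs)
    if not seqs:
        raise ValueError("need at least one sequence to fit a background model")
    base_counts = np.zeros(4)
    trans_counts = np.zeros((4, 4))
    usable = 0
    for s in seqs:
        codes = encode_bases(s)
        valid = codes < 4
        usable += int(valid.sum())
        base_counts += np.bincount(codes[valid], minlength=4)
        if order == 1 and codes.size > 1:
            a, b = codes[:-1], codes[1:]
            ok = (a < 4) & (b < 4)
            np.add.at(trans_counts, (a[ok], b[ok]), 1)
    if usable == 0:
        raise ValueError("no usable (non-N) bases in input")
    initial = (base_counts + pseudocount) / (usable + 4 * pseudocount)
    transitions = None
    if order == 1:
        rows = trans_counts + pseudocount
        transitions = rows / rows.sum(axis=1, keepdims=True)
    return BackgroundModel(
        order=order, initial=initial, transitions=transitions,
        pseudocount=pseudocount,
    )


def sample_base_array(
    model: BackgroundModel, length: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample an (n, length) uint8 array of base codes from the model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if n == 0:
        return np.zeros((0, length), dtype=np.uint8)
    if model.order == 0:
        cum = np.cumsum(model.initial)
        u = rng.random((n, length))
        return np.searchsorted(cum, u, side="right").astype(np.uint8)
    out = np.empty((n, length), dtype=np.uint8)
    cum_init = np.cumsum(model.initial)
    out[:, 0] = np.searchsorted(cum_init, rng.random(n), side="right")
    cum_trans = np.cumsum(model.transitions, axis=1)
    u = rng.random((n, length))
    for j in range(1, length):
        rows = cum_trans[out[:, j - 1]]
        out[:, j] = (u[:, j, None] > rows).sum(axis=1)
    return out


def sample_sequences(
    model: BackgroundModel, length: int, n: int, seed: int
) -> list[str]:
    """Sample n sequences of the given length; same seed, same output."""
    rng = np.random.default_rng(seed)
    arr = sample_base_array(model, length, n, rng)
    return [decode_bases(row) for row in arr]


# --- vectorised per-sequence motif counting ---------------------------------


def _allowed_tables(motif: ConsensusMotif) -> list[np.ndarray]:
    """Per-alternative (w, 5) boolean lookup tables; N (code 4) never matches."""
    tables = []
    for pat in motif.patterns:
        t = np.zeros((pat.width, 5), dtype=bool)
        for k, bases in enumerate(pat.allowed):
            for b in bases:
                t[k, "ACGTN".index(b)] = True
        tables.append(t)
    return tables


def count_consensus_batch(
    arr: np.ndarray, motif: ConsensusMotif, both_strands: bool = False
) -> np.ndarray:
    """Per-row counts of windows matching any alternative of one family.

    With ``both_strands`` a window is also counted (again) when its reverse
    complement matches, mirroring the scanner's 'both' mode.
    """
    n, L = arr.shape
    w = motif.width
    n_win = L - w + 1
    if n_win < 1:
        raise ValueError(f"family {motif.family!r} wider than sequences")
    rc = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    counts = np.zeros(n, dtype=np.int64)
    for strand in ("+", "-") if both_strands else ("+",):
        match = np.zeros((n, n_win), dtype=bool)
        for table in _allowed_tables(motif):
            ok = np.ones((n, n_win), dtype=bool)
            for k in range(w):
                col = table[k]
                if strand == "+":
                    ok &= col[arr[:, k : k + n_win]]
                else:
                    # pattern position k sits at window offset w-1-k, complemented
                    ok &= col[rc[arr[:, w - 1 - k : w - 1 - k + n_win]]]
            match |= ok
        counts += match.sum(axis=1)
    return counts


def count_pwm_batch(
    arr: np.ndarray, pwm: PWM, config: ScanConfig | None = None
) -> np.ndarray:
    """Per-row counts of windows at or above the relative-score threshold."""
    config = config or ScanConfig()
    n, L = arr.shape
    w = pwm.width
    n_win = L - w + 1
    if n_win < 1:
        raise ValueError(f"motif {pwm.motif_id!r} wider than sequences")
    weights5 = np.vstack([pwm.weights, np.full(w, -np.inf)])
    mats = [weights5]
    if config.strands == "both":
        mats.append(weights5[np.array([3, 2, 1, 0, 4])][:, ::-1])
    tau_raw = pwm.s_min + config.rel_threshold * (pwm.s_max - pwm.s_min)
    counts = np.zeros(n, dtype=np.int64)
    for mat in mats:
        scores = np.zeros((n, n_win))
        for j in range(w):
            scores += mat[arr[:, j : j + n_win], j]
        counts += (scores >= tau_raw - 1e-12).sum(axis=1)
    return counts


# --- the test itself ---------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentConfig:
    """Resampling-test parameters."""

    n_samples: int = 999
    seed: int = 0
    alpha: float = 0.05
    correction: str = "BH"  # "BH" | "Bonferroni"
    background_mode: str = "markov_shuffle"  # | "promoter_set"
    order: int = 0
    alternative: str = "enrichment"  # | "depletion"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("BH", "Bonferroni"):
            raise ValueError("correction must be 'BH' or 'Bonferroni'")
        if self.background_mode not in ("markov_shuffle", "promoter_set"):
            raise ValueError("unknown background_mode")
        if self.alternative not in ("enrichment", "depletion"):
            raise ValueError("alternative must be 'enrichment' or 'depletion'")


@dataclass(frozen=True)
class EnrichmentResult:
    family: str
    observed: int
    null_mean: float
    null_sd: float
    p_raw: float
    q_adj: float
    enriched: bool


def adjust_pvalues(p, method: str = "BH") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    BH is the step-up FDR procedure; Bonferroni multiplies by the number of
    tests; both cap at 1.
    """
    p = list(p)
    if not p:
        return []
    if any(not 0 < x <= 1 for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    sm_method = {"BH": "fdr_bh", "Bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError("method must be 'BH' or 'Bonferroni'")
    _, q, _, _ = multipletests(p, method=sm_method)
    return [float(x) for x in q]


def empirical_enrichment(
    observed: dict[str, int],
    null_counts: dict[str, "np.ndarray | list[int]"],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Empirical one-sided test of observed counts against null counts.

    Every family in ``observed`` must appear in ``null_counts`` with exactly
    ``config.n_samples`` entries.  Null moments are the sample mean and
    standard deviation (ddof=1).
    """
    config = config or EnrichmentConfig()
    n = config.n_samples
    rows = []
    for family, obs in observed.items():
        if family not in null_counts:
            raise ValueError(f"family {family!r} missing from null_counts")
        null = np.asarray(null_counts[family])
        if null.size != n:
            raise ValueError(
                f"family {family!r}: expected {n} null counts, got {null.size}"
            )
        if config.alternative == "enrichment":
            extreme = int((null >= obs).sum())
        else:
            extreme = int((null <= obs).sum())
        p_raw = (1 + extreme) / (1 + n)
        sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
        rows.append((family, obs, float(null.mean()), sd, p_raw))
    q = adjust_pvalues([r[4] for r in rows], config.correction)
    return [
        EnrichmentResult(
            family=f, observed=o, null_mean=m, null_sd=s, p_raw=p,
            q_adj=qv, enriched=qv <= config.alpha,
        )
        for (f, o, m, s, p), qv in zip(rows, q)
    ]


def motif_enrichment(
    region: PromoterRegion,
    families: list[ConsensusMotif] | None = None,
    pwms: list[PWM] | None = None,
    config: EnrichmentConfig | None = None,
    model: BackgroundModel | None = None,
    background_seqs: list[str] | None = None,
    consensus_config: ConsensusConfig | None = None,
    scan_config: ScanConfig | None = None,
) -> list[EnrichmentResult]:
    """End-to-end enrichment test on a promoter window.

    Observed counts come from the same scanners (and the same strand/dedup
    conventions) used for reporting.  Null counts come from ``n_samples``
    sequences drawn from ``model`` (fitted to the query promoter when not
    given), or — in 'promoter_set' mode — from the supplied background
    promoter sequences directly, with n = number of sequences.
    """
    families = default_families() if families is None else families
    pwms = pwms or []
    config = config or EnrichmentConfig()
    consensus_config = consensus_config or ConsensusConfig()
    scan_config = scan_config or ScanConfig()

    observed: dict[str, int] = {m.family: 0 for m in families}
    observed.update(count_by_family(scan_consensus(region, families, consensus_config)))
    for pwm in pwms:
        key = pwm.name or pwm.motif_id
        observed[key] = len(scan_pwm(pwm, region, scan_config))

    if config.background_mode == "promoter_set":
        if not background_seqs:
            raise ValueError("promoter_set mode needs background_seqs")
        arr = np.stack([encode_bases(s) for s in background_seqs])
        n = len(background_seqs)
        config = EnrichmentConfig(
            n_samples=n, seed=config.seed, alpha=config.alpha,
            correction=config.correction, background_mode=config.background_mode,
            order=config.order, alternative=config.alternative,
        )
    else:
        if model is None:
            model = fit_markov([region.sequence], order=config.order)
        rng = np.random.default_rng(config.seed)
        arr = sample_base_array(model, region.length, config.n_samples, rng)

    both = consensus_config.strands == "both"
    null_counts: dict[str, np.ndarray] = {}
    by_name = {m.family: m for m in families}
    for m in families:
        null_counts[m.family] = count_consensus_batch(arr, m, both_strands=both)
    # Mirror the scanner's canonical/degenerate E-box dedup: every canonical
    # window is also a degenerate window, so subtract the canonical counts.
    if (
        consensus_config.dedup_degenerate_ebox
        and "Ebox_degenerate" in by_name
        and "Ebox_canonical" in by_name
    ):
        null_counts["Ebox_degenerate"] = (
            null_counts["Ebox_degenerate"] - null_counts["Ebox_canonical"]
        )
    for pwm in pwms:
        key = pwm.name or pwm.motif_id
        null_counts[key] = count_pwm_batch(arr, pwm, scan_config)

    return empirical_enrichment(observed, null_counts, config)
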