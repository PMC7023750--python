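"""LTR retrotransposon detection and insertion-time estimation.

An LTR retrotransposon inserts with two identical long terminal repeats
flanked by a short (5-20 bp) target-site duplication (TSD).  After
insertion the two LTRs diverge neutrally, so their pairwise distance under
a substitution model, divided by twice the per-site mutation rate, dates
the insertion (T = d / 2mu).

Detection seeds direct-repeat candidates with exact k-mer matches on a
shared diagonal, extends and verifies them by global alignment, and pins
element boundaries by locating an exact 5-20 bp duplication immediately
outside the two repeats.  Divergence of the two LTRs is summarized with
Kimura two-parameter (K2P) and gamma-corrected K2P (shape a = 1)
distances after complete deletion of gapped columns, with a column-level
bootstrap for the age's uncertainty.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")
_PURINES = frozenset("AG")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

DEFAULT_MUTATION_RATE = 2.5e-9  # substitutions per site per year

# protein domains diagnostic of autonomous elements (gag/pol machinery)
AUTONOMY_DOMAINS = (
    "gag",
    "protease",
    "reverse transcriptase",
    "rt",
    "rnase h",
    "rnaseh",
    "integrase",
    "pol",
)


@dataclass
class LTRElement:
    """One detected candidate element (0-based half-open coordinates)."""

    start: int  # element start (5' LTR start, after the left TSD copy)
    end: int  # element end (3' LTR end, before the right TSD copy)
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    tsd: str
    ltr_identity: float
    ltr_length: int

    @property
    def has_tsd(self) -> bool:
        return len(self.tsd) >= 5


@dataclass
class InsertionAgeEstimate:
    """Insertion age from LTR-LTR divergence: T = d / (2 mu)."""

    distance: float
    age_years: float
    age_sd_years: float
    model: str
    n_sites: int
    n_differences: int
    saturated: bool = False
    bootstrap_ages: np.ndarray | None = field(default=None, repr=False)


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _align_rows(a: str, b: str) -> tuple[str, str]:
    """Global (NW) alignment of a vs b; returns the two gapped rows."""
    res = edlib.align(a, b, mode="NW", task="path")
    ra, rb = [], []
    ia = ib = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op in "=XM":
            ra.append(a[ia : ia + n])
            rb.append(b[ib : ib + n])
            ia += n
            ib += n
        elif op == "I":  # in edlib: consumes query (a)
            ra.append(a[ia : ia + n])
            rb.append("-" * n)
            ia += n
        elif op == "D":
            ra.append("-" * n)
            rb.append(b[ib : ib + n])
            ib += n
    return "".join(ra), "".join(rb)


def _identity(a: str, b: str) -> float:
    ra, rb = _align_rows(a, b)
    matches = sum(1 for x, y in zip(ra, rb) if x == y)
    return 100.0 * matches / len(ra) if ra else 0.0


def detect_ltr_candidates(
    sequence: str,
    min_ltr_length: int = 100,
    max_ltr_length: int = 5000,
    min_separation: int = 1000,
    max_separation: int = 20000,
    min_ltr_identity: float = 85.0,
    seed_k: int = 24,
    seed_step: int = 4,
    max_tsd_shift: int = 8,
) -> list[LTRElement]:
    """Find direct-repeat pairs consistent with LTR retrotransposons.

    Exact ``seed_k``-mers sampled every ``seed_step`` bp are matched against
    all downstream exact occurrences; seed pairs sharing a diagonal
    (separation) within a tolerance are clustered, extended outward by
    exact match, and the repeat pair is verified by global alignment at
    >= ``min_ltr_identity`` percent identity.  Element boundaries are then
    pinned by searching for an exact 5-20 bp target-site duplication within
    ``max_tsd_shift`` bp of the alignment ends; candidates whose repeats
    overlap a better-scoring candidate are dropped (score = identity x
    repeat length).
    """
    sequence = sequence.upper()
    n = len(sequence)
    if seed_k < 12:
        raise ValueError("seed_k must be >= 12")
    index: dict[str, list[int]] = {}
    for t in range(0, n - seed_k + 1):
        index.setdefault(sequence[t : t + seed_k], []).append(t)

    # seed pairs (q < t) grouped by diagonal (separation t - q)
    diag_hits: dict[int, list[int]] = {}
    for q in range(0, n - seed_k + 1, seed_step):
        km = sequence[q : q + seed_k]
        if "N" in km:
            continue
        for t in index.get(km, ()):
            sep = t - q
            if min_separation <= sep <= max_separation:
                diag_hits.setdefault(sep, []).append(q)

    # cluster nearby diagonals
    raw: list[tuple[int, int, int]] = []  # (diag, qmin, qmax+k)
    for diag in sorted(diag_hits):
        qs = sorted(diag_hits[diag])
        start = prev = qs[0]
        for q in qs[1:]:
            if q - prev > 4 * seed_k:
                raw.append((diag, start, prev + seed_k))
                start = q
            prev = q
        raw.append((diag, start, prev + seed_k))

    # merge clusters with near-identical diagonals (indel tolerance 20 bp)
    raw.sort(key=lambda r: (r[0], r[1]))
    merged: list[list[int]] = []
    for diag, qs, qe in raw:
        if merged and abs(diag - merged[-1][0]) <= 20 and qs <= merged[-1][2] + 4 * seed_k:
            merged[-1][2] = max(merged[-1][2], qe)
        else:
            merged.append([diag, qs, qe])

    candidates: list[LTRElement] = []
    for diag, qs, qe in merged:
        # exact outward extension on the main diagonal
        a0, a1 = qs, qe
        b0, b1 = qs + diag, qe + diag
        while a0 > 0 and b0 > 0 and sequence[a0 - 1] == sequence[b0 - 1] and a1 <= b0 - 1:
            a0 -= 1
            b0 -= 1
        while a1 < b0 and b1 < n and sequence[a1] == sequence[b1]:
            a1 += 1
            b1 += 1
        length = a1 - a0
        if not (min_ltr_length <= length <= max_ltr_length):
            continue
        ident = _identity(sequence[a0:a1], sequence[b0:b1])
        if ident < min_ltr_identity:
            continue
        tsd = _find_tsd(sequence, a0, b1, max_tsd_shift)
        candidates.append(
            LTRElement(
                start=a0,
                end=b1,
                ltr5=(a0, a1),
                ltr3=(b0, b1),
                tsd=tsd,
                ltr_identity=ident,
                ltr_length=length,
            )
        )

    # resolve overlaps: keep the higher-scoring element
    candidates.sort(key=lambda e: e.ltr_identity * e.ltr_length, reverse=True)
    kept: list[LTRElement] = []
    for e in candidates:
        if any(e.start < k.end and k.start < e.end for k in kept):
            continue
        kept.append(e)
    kept.sort(key=lambda e: e.start)
    return kept


def _find_tsd(sequence: str, left: int, right: int, max_shift: int) -> str:
    """Longest exact 5-20 bp duplication flanking [left, right)."""
    n = len(sequence)
    best = ""
    for da in range(-max_shift, max_shift + 1):
        for db in range(-max_shift, max_shift + 1):
            a = left + da
            b = right + db
            for t in range(20, 4, -1):
                if a - t < 0 or b + t > n:
                    continue
                if sequence[a - t : a] == sequence[b : b + t]:
                    if t > len(best):
                        best = sequence[a - t : a]
                    break
            if len(best) == 20:
                return best
    return best


# --------------------------------------------------------------------------
# divergence and dating


def _ungapped_columns(a: str, b: str) -> list[tuple[str, str]]:
    ra, rb = _align_rows(a.upper(), b.upper())
    return [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]


def _pq(columns: list[tuple[str, str]]) -> tuple[int, int, int]:
    """(n_sites, n_transitions, n_transversions) over ungapped columns."""
    ts = tv = 0
    for x, y in columns:
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return len(columns), ts, tv


def k2p_distance(P: float, Q: float) -> float:
    """Kimura (1980) two-parameter distance from transition/transversion
    proportions P and Q; raises on saturation (log argument <= 0)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("K2P distance undefined: proportions at or beyond saturation")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def gamma_k2p_distance(P: float, Q: float, shape: float = 1.0) -> float:
    """Gamma-rate-corrected K2P distance (Jin & Nei 1990), shape ``a``:
    d = (a/2)[(1-2P-Q)^(-1/a) - 1] + (a/4)[(1-2Q)^(-1/a) - 1]."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("gamma-K2P distance undefined: proportions at or beyond saturation")
    a = shape
    return (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (w2 ** (-1.0 / a) - 1.0)


def ltr_divergence(ltr_a: str, ltr_b: str, model: str = "k2p", gamma_shape: float = 1.0) -> dict:
    """Distance between the two LTRs of one element.

    Aligns globally, removes gapped columns (complete deletion), counts
    transition (P) and transversion (Q) proportions, and applies the
    requested correction (``k2p``, ``gamma_k2p``, or ``raw`` = p-distance).
    Returns distance, P, Q, n_sites, n_differences, and a saturation flag
    (saturated distances are returned as None).
    """
    cols = _ungapped_columns(ltr_a, ltr_b)
    if not cols:
        raise ValueError("no comparable (ungapped) columns between LTRs")
    n, ts, tv = _pq(cols)
    P, Q = ts / n, tv / n
    saturated = False
    if model == "raw":
        d = P + Q
    elif model in ("k2p", "gamma_k2p"):
        fn = k2p_distance if model == "k2p" else (lambda p, q: gamma_k2p_distance(p, q, gamma_shape))
        try:
            d = fn(P, Q)
        except ValueError:
            d, saturated = None, True
    else:
        raise ValueError(f"unknown model {model!r}")
    return {
        "distance": d,
        "P": P,
        "Q": Q,
        "n_sites": n,
        "n_differences": ts + tv,
        "model": model,
        "saturated": saturated,
    }


def insertion_age(
    ltr_a: str,
    ltr_b: str,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    model: str = "k2p",
    gamma_shape: float = 1.0,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> InsertionAgeEstimate:
    """Date one insertion: T = d / (2 mu), with a column bootstrap SD.

    Bootstrap replicates resample alignment columns with replacement and
    recompute the corrected distance; replicates that hit saturation are
    dropped from the SD.  A saturated point estimate yields age NaN with
    ``saturated=True``.
    """
    if mutation_rate <= 0:
        raise ValueError("mutation_rate must be > 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    cols = _ungapped_columns(ltr_a, ltr_b)
    if not cols:
        raise ValueError("no comparable (ungapped) columns between LTRs")
    n, ts, tv = _pq(cols)

    def dist(n_s, n_ts, n_tv):
        P, Q = n_ts / n_s, n_tv / n_s
        if model == "raw":
            return P + Q
        fn = k2p_distance if model == "k2p" else (lambda p, q: gamma_k2p_distance(p, q, gamma_shape))
        return fn(P, Q)

    try:
        d = dist(n, ts, tv)
    except ValueError:
        return InsertionAgeEstimate(
            distance=float("nan"), age_years=float("nan"), age_sd_years=float("nan"),
            model=model, n_sites=n, n_differences=ts + tv, saturated=True,
        )
    age = d / (2.0 * mutation_rate)

    boot_ages = []
    if n_bootstrap > 0:
        # each column is (match | transition | transversion); multinomial resample
        probs = np.array([n - ts - tv, ts, tv], dtype=float) / n
        draws = rng.multinomial(n, probs, size=n_bootstrap)
        for _, b_ts, b_tv in draws:
            try:
                boot_ages.append(dist(n, int(b_ts), int(b_tv)) / (2.0 * mutation_rate))
            except ValueError:
                continue
    boot = np.array(boot_ages, dtype=float)
    sd = float(boot.std(ddof=1)) if boot.size > 1 else float("nan")
    return InsertionAgeEstimate(
        distance=float(d),
        age_years=float(age),
        age_sd_years=sd,
        model=model,
        n_sites=n,
        n_differences=ts + tv,
        saturated=False,
        bootstrap_ages=boot,
    )


def classify_autonomy(domain_hits: dict[str, list[str]]) -> dict[str, str]:
    """Label elements autonomous/non-autonomous from protein-domain hits.

    ``domain_hits`` maps element id -> list of domain names found in its
    internal region.  Elements carrying both a gag-related and a
    pol-related domain (reverse transcriptase / integrase / RNase H /
    protease) are ``autonomous``; anything else is ``non_autonomous``.
    """
    out = {}
    pol_terms = ("reverse transcriptase", "rt", "rnase", "integrase", "protease", "pol")
    for elem, domains in domain_hits.items():
        low = [d.lower() for d in domains]
        has_gag = any("gag" in d for d in low)
        has_pol = any(any(t in d for t in pol_terms) for d in low)
        out[elem] = "autonomous" if has_gag and has_pol else "non_autonomous"
    return out
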