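"""Palindrome (large inverted repeat) detection by self-comparison.

The detector mirrors the classic seed-and-extend self-alignment strategy:
exact k-mer seeds (default k=100) sampled every ``step`` positions (default
20) are matched between the sequence and its reverse complement, chained
along anti-diagonals, extended, and verified by gapped alignment.  Arm pairs
sharing a center are assembled into palindrome records, and arm-to-arm
divergence is profiled in 100-bp windows of the alignment columns.

Internal coordinates are 0-based half-open; palindrome reports are emitted
1-based inclusive so that size = end - start + 1, the convention used in
published palindrome coordinate tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._seq import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# column classes of a pairwise alignment
_MATCH, _SUB, _GAP = 0, 1, 2


def _align_columns(a: str, b: str) -> np.ndarray:
    """Global-align two sequences; return per-column class codes."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    res = edlib.align(a, b, mode="NW", task="path")
    cols = []
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(count)
        if op == "=":
            cols.append(np.full(n, _MATCH, dtype=np.uint8))
        elif op == "X":
            cols.append(np.full(n, _SUB, dtype=np.uint8))
        else:  # I or D
            cols.append(np.full(n, _GAP, dtype=np.uint8))
    return np.concatenate(cols) if cols else np.empty(0, dtype=np.uint8)


def _identity_stats(a: str, b: str) -> tuple[float, int, int, int]:
    """(percent identity, aligned columns, substitutions, gap bp)."""
    cols = _align_columns(a, b)
    n = cols.size
    subs = int((cols == _SUB).sum())
    gaps = int((cols == _GAP).sum())
    ident = 100.0 * (n - subs - gaps) / n if n else 0.0
    return ident, n, subs, gaps


# --------------------------------------------------------------------------
# seeding


@dataclass(frozen=True)
class Seed:
    """One exact inverted k-mer match: seq[plus:plus+k] == revcomp(seq[minus:minus+k])."""

    plus: int
    minus: int
    k: int


def find_inverted_seeds(sequence: str, k: int = 100, step: int = 20) -> list[Seed]:
    """Exact inverted k-mer seeds between a sequence and its reverse complement.

    Query k-mers are sampled every ``step`` positions; their reverse
    complements are looked up at every position of the sequence.  Matches
    whose two footprints overlap (a k-mer matching its own reverse-complement
    footprint, e.g. a perfect hairpin center) are excluded, and each
    unordered pair of footprints is reported once with ``plus < minus``.
    """
    if k < 20:
        raise ValueError("seed length k must be >= 20")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(sequence)
    if n < k:
        return []
    sequence = sequence.upper()
    # map revcomp of each sampled query k-mer -> sampled positions
    targets: dict[str, list[int]] = {}
    for q in range(0, n - k + 1, step):
        kmer = sequence[q : q + k]
        if "N" in kmer:
            continue
        targets.setdefault(revcomp(kmer), []).append(q)
    pairs: set[tuple[int, int]] = set()
    for t in range(0, n - k + 1):
        qs = targets.get(sequence[t : t + k])
        if not qs:
            continue
        for q in qs:
            if abs(q - t) < k:  # overlapping footprints: self-trivial
                continue
            pairs.add((min(q, t), max(q, t)))
    return [Seed(p, m, k) for p, m in sorted(pairs)]


# --------------------------------------------------------------------------
# chaining + extension


@dataclass
class InvertedRepeatHit:
    """A verified inverted-repeat arm pair on one sequence."""

    plus: tuple[int, int]
    minus: tuple[int, int]
    percent_identity: float
    aligned_length: int
    n_substitutions: int
    n_gap_bp: int
    seeds: list[Seed] = field(default_factory=list)

    @property
    def separation(self) -> int:
        return self.minus[0] - self.plus[1]


def extend_and_chain(
    sequence: str,
    seeds: list[Seed],
    min_identity: float = 90.0,
    min_length: int = 1000,
    band: int = 600,
    max_seed_gap: int = 2000,
    block: int = 50,
) -> list[InvertedRepeatHit]:
    """Chain co-anti-diagonal seeds, extend the chains, verify by alignment.

    Seeds whose anti-diagonal (plus + minus) agrees within ``band`` and whose
    plus coordinates are within ``max_seed_gap`` of each other form one
    chain.  Chains are extended outward base-by-base while exact, then in
    ``block``-bp blocks while block identity stays above ``min_identity``,
    and finally verified by global alignment of the plus arm against the
    reverse complement of the minus arm.  Hits below ``min_identity`` or
    shorter than ``min_length`` are dropped.
    """
    if not seeds:
        return []
    n = len(sequence)
    sequence = sequence.upper()
    # group by anti-diagonal
    by_d = sorted(seeds, key=lambda s: (s.plus + s.minus, s.plus))
    d_groups: list[list[Seed]] = [[by_d[0]]]
    for s in by_d[1:]:
        if (s.plus + s.minus) - (d_groups[-1][-1].plus + d_groups[-1][-1].minus) <= band:
            d_groups[-1].append(s)
        else:
            d_groups.append([s])
    chains: list[list[Seed]] = []
    for grp in d_groups:
        grp = sorted(grp, key=lambda s: s.plus)
        cur = [grp[0]]
        for s in grp[1:]:
            if s.plus - cur[-1].plus <= max_seed_gap:
                cur.append(s)
            else:
                chains.append(cur)
                cur = [s]
        chains.append(cur)

    comp = str.maketrans("ACGT", "TGCA")
    hits: list[InvertedRepeatHit] = []
    for chain in chains:
        ps = min(s.plus for s in chain)
        pe = max(s.plus + s.k for s in chain)
        ms = min(s.minus for s in chain)
        me = max(s.minus + s.k for s in chain)
        # exact outward extension: in an inverted repeat, the plus arm's
        # right end pairs with the minus arm's left end and vice versa
        while pe < ms and sequence[pe] == sequence[ms - 1].translate(comp):
            pe += 1
            ms -= 1
        while ps > 0 and me < n and sequence[ps - 1] == sequence[me].translate(comp):
            ps -= 1
            me += 1

        # tolerant block extension
        def block_ok(a: str, b_rc: str) -> bool:
            if not a or len(a) != len(b_rc):
                return False
            mism = sum(1 for x, y in zip(a, b_rc) if x != y)
            return 100.0 * (len(a) - mism) / len(a) >= min_identity

        while pe + block <= ms - block:
            if block_ok(sequence[pe : pe + block], revcomp(sequence[ms - block : ms])):
                pe += block
                ms -= block
            else:
                break
        while ps - block >= 0 and me + block <= n:
            if block_ok(sequence[ps - block : ps], revcomp(sequence[me : me + block])):
                ps -= block
                me += block
            else:
                break
        plus_arm = sequence[ps:pe]
        minus_arm = sequence[ms:me]
        if min(len(plus_arm), len(minus_arm)) < min_length:
            continue
        ident, ncols, subs, gaps = _identity_stats(plus_arm, revcomp(minus_arm))
        if ident < min_identity:
            continue
        hits.append(
            InvertedRepeatHit(
                plus=(ps, pe),
                minus=(ms, me),
                percent_identity=ident,
                aligned_length=ncols,
                n_substitutions=subs,
                n_gap_bp=gaps,
                seeds=chain,
            )
        )
    hits.sort(key=lambda h: h.plus)
    return hits


# --------------------------------------------------------------------------
# palindrome assembly


@dataclass
class Palindrome:
    """An assembled palindrome: inverted arm pairs sharing one center."""

    name: str
    arms: list[tuple[str, int, int, str]]  # (label, start0, end0, orientation)
    spacers: list[tuple[str, int, int]]  # (label, start0, end0); empty interval = unidentified
    pre_arm: tuple[int, int] | None = None
    ambiguous: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (min(a[1] for a in self.arms), max(a[2] for a in self.arms))

    def report(self) -> pd.DataFrame:
        """1-based inclusive coordinate table (size = end - start + 1)."""
        rows = []
        if self.pre_arm is not None:
            s, e = self.pre_arm
            rows.append({"name": self.name, "component": "pre-arm", "start": s + 1, "end": e, "size": e - s, "orientation": "+"})
        for label, s, e, orient in self.arms:
            rows.append({"name": self.name, "component": label, "start": s + 1, "end": e, "size": e - s, "orientation": orient})
        for label, s, e in self.spacers:
            if e > s:
                rows.append({"name": self.name, "component": label, "start": s + 1, "end": e, "size": e - s, "orientation": "."})
            else:
                rows.append({"name": self.name, "component": label, "start": None, "end": None, "size": None, "orientation": "."})
        df = pd.DataFrame(rows)
        for col in ("start", "end", "size"):
            df[col] = df[col].astype("Int64")
        return df

    @classmethod
    def from_coordinates_1based(
        cls, name: str, components: list[tuple[str, int, int, str]]
    ) -> "Palindrome":
        """Build from printed 1-based inclusive (label, start, end, orientation)."""
        arms = []
        spacers = []
        pre = None
        for label, s1, e1, orient in components:
            s0, e0 = s1 - 1, e1
            low = label.lower()
            if low.startswith("pre"):
                pre = (s0, e0)
            elif low.startswith("spacer"):
                spacers.append((label, s0, e0))
            else:
                arms.append((label, s0, e0, orient))
        return cls(name=name, arms=arms, spacers=spacers, pre_arm=pre)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def assemble_palindromes(
    hits: list[InvertedRepeatHit],
    name_prefix: str = "W.P",
) -> tuple[list[Palindrome], list[InvertedRepeatHit]]:
    """Group arm-pair hits into palindrome records.

    Hits are accepted greedily, longest alignment first with ties broken by
    higher identity and then tighter separation: a palindrome's own arm pair
    is full-length and near-identical (conversion keeps arms homogeneous),
    whereas cross-palindrome pairings are more diverged and partial copies
    are shorter.  A hit whose arm would re-use sequence already claimed by
    an accepted arm becomes a secondary hit (cross-palindrome homology, or a
    pre-arm when one side is a partial copy outside any palindrome).  Nested accepted hits share a center and
    merge into one palindrome; the innermost gap is the spacer, reported as
    an empty ("unidentified") interval when the inner arms abut.

    Returns (palindromes ordered by position, secondary hits).
    """
    if not hits:
        return [], []
    order = sorted(
        hits, key=lambda h: (-h.aligned_length, -h.percent_identity, h.separation)
    )
    claimed: list[tuple[int, int]] = []
    accepted: list[InvertedRepeatHit] = []
    secondary: list[InvertedRepeatHit] = []
    for h in order:
        if any(_overlaps(h.plus, c) or _overlaps(h.minus, c) for c in claimed):
            secondary.append(h)
        else:
            accepted.append(h)
            claimed.extend([h.plus, h.minus])

    # group nested accepted hits (shared center)
    groups: list[list[InvertedRepeatHit]] = []
    for h in sorted(accepted, key=lambda x: x.plus):
        placed = False
        for grp in groups:
            for g in grp:
                inner, outer = (h, g) if g.plus[1] <= h.plus[0] else (g, h)
                if outer.plus[1] <= inner.plus[0] and inner.minus[1] <= outer.minus[0]:
                    grp.append(h)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            groups.append([h])

    groups.sort(key=lambda grp: min(g.plus[0] for g in grp))
    palindromes: list[Palindrome] = []
    arm_base = 1
    for i, grp in enumerate(groups):
        grp_sorted = sorted(grp, key=lambda g: g.plus[0])  # outermost first
        left = arm_base
        right = arm_base + 1
        arms: list[tuple[str, int, int, str]] = []
        n_shells = len(grp_sorted)
        for shell, g in enumerate(grp_sorted):
            if n_shells == 1:
                lab_p, lab_m = f"arm{left}", f"arm{right}"
            else:
                suffix = chr(ord("a") + shell)
                lab_p, lab_m = f"arm{left}{suffix}", f"arm{right}{suffix}"
            arms.append((lab_p, g.plus[0], g.plus[1], "+"))
            arms.append((lab_m, g.minus[0], g.minus[1], "-"))
        arms.sort(key=lambda a: a[1])
        inner = grp_sorted[-1]
        gap = (inner.plus[1], inner.minus[0])
        spacer_label = f"Spacer{i + 1}"
        spacers = [(spacer_label, gap[0], gap[1])]
        palindromes.append(
            Palindrome(name=f"{name_prefix}{i + 1}", arms=arms, spacers=spacers)
        )
        arm_base += 2

    # pre-arm assignment from secondary hits: one side overlaps a claimed
    # arm, the other is a shorter partial copy outside every palindrome span
    spans = [p.span for p in palindromes]
    for h in secondary:
        for side, other in ((h.plus, h.minus), (h.minus, h.plus)):
            outside = not any(_overlaps(side, sp) for sp in spans)
            partner_claimed = any(_overlaps(other, c) for c in claimed)
            if outside and partner_claimed and (side[1] - side[0]) < (other[1] - other[0]) * 1.5:
                # attach to the nearest palindrome
                target = min(palindromes, key=lambda p: abs(p.span[0] - side[1]))
                if target.pre_arm is None:
                    target.pre_arm = side
                elif not _overlaps(target.pre_arm, side):
                    # a second, distinct partial copy competes for the slot
                    target.ambiguous = True
                break
    return palindromes, secondary


def detect_palindromes(
    sequence: str,
    k: int = 100,
    step: int = 20,
    min_identity: float = 90.0,
    min_length: int = 1000,
) -> tuple[list[Palindrome], list[InvertedRepeatHit]]:
    """Full pipeline: seeds -> chained/extended hits -> palindrome records."""
    seeds = find_inverted_seeds(sequence, k=k, step=step)
    hits = extend_and_chain(sequence, seeds, min_identity=min_identity, min_length=min_length)
    return assemble_palindromes(hits)


# --------------------------------------------------------------------------
# arm divergence profiling


@dataclass
class ArmDivergenceProfile:
    """Windowed substitution/gap profile of one arm pair alignment."""

    arm_pair: tuple[str, str]
    window: int
    window_starts: np.ndarray  # alignment-column start of each window
    differences: np.ndarray  # substitutions per window
    gap_bp: np.ndarray  # gap columns per window
    overall_identity: float
    n_columns: int

    @property
    def total_differences(self) -> int:
        return int(self.differences.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm_pair": "|".join(self.arm_pair),
                "window_start": self.window_starts,
                "differences": self.differences,
                "gap_bp": self.gap_bp,
            }
        )


def arm_divergence_profile(
    arm_a: str,
    arm_b: str,
    window: int = 100,
    arm_labels: tuple[str, str] = ("armA", "armB"),
    orient_b: str = "as_is",
) -> ArmDivergenceProfile:
    """Per-100-bp substitution and gap profile of a global arm alignment.

    ``arm_b`` is reverse-complemented first when ``orient_b ==
    'reverse_complement'`` (pass arms in genome orientation); with
    ``'as_is'`` both arms must already be orientation-normalized.  Windows
    tile the alignment columns; the per-window substitution counts sum to
    the total substitution count of the alignment.
    """
    if not arm_a or not arm_b:
        raise ValueError("arms must be non-empty")
    if orient_b == "reverse_complement":
        arm_b = revcomp(arm_b)
    elif orient_b != "as_is":
        raise ValueError("orient_b must be 'as_is' or 'reverse_complement'")
    cols = _align_columns(arm_a, arm_b)
    n = cols.size
    starts = np.arange(0, n, window)
    diffs = np.array([(cols[s : s + window] == _SUB).sum() for s in starts], dtype=int)
    gaps = np.array([(cols[s : s + window] == _GAP).sum() for s in starts], dtype=int)
    n_match = int((cols == _MATCH).sum())
    return ArmDivergenceProfile(
        arm_pair=arm_labels,
        window=window,
        window_starts=starts,
        differences=diffs,
        gap_bp=gaps,
        overall_identity=100.0 * n_match / n if n else 0.0,
        n_columns=n,
    )


def palindrome_report(palindromes: list[Palindrome]) -> pd.DataFrame:
    """Concatenated 1-based coordinate report for all palindromes."""
    if not palindromes:
        return pd.DataFrame(columns=["name", "component", "start", "end", "size", "orientation"])
    return pd.concat([p.report() for p in palindromes], ignore_index=True)
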