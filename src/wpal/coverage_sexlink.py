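"""Depth-of-coverage identification of W-linked sequence.

Implements the sexed-coverage machinery used to separate the female-specific
(hemizygous) portion of a ZW pair from Z-W homologous sequence:

* windowed median depth (non-overlapping or sliding windows),
* log2 female/male depth ratios with a pseudo-count,
* the two-rule female-specific marker classifier over pooled-by-sex GBS
  interval depths plus deep resequencing of one clone per sex,
* the >=3-marker candidate-W-contig rule,
* a W-specific vs Z-W-homologous region classifier from male depth medians,
* recoding of hemizygous presence/absence markers to backcross genotypes.

Rule 1 calls an interval female-specific when log2((M_pool+1)/(F_pool+1))
falls below a lower bound L derived from the statistic's own distribution
(by default the 5th percentile divided by the number of intervals tested);
rule 2 additionally requires log2((F_reseq+1)/(M_reseq+1)) above a fixed
cutoff (default 5, i.e. a >32-fold female excess).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import DepthTrack


@dataclass
class ContigSexCall:
    contig: str
    n_female_specific_markers: int
    call: str  # "W_candidate" | "not_W"


def window_median_depth(
    track: DepthTrack, window: int, step: int | None = None
) -> pd.DataFrame:
    """Median per-base depth in windows of ``window`` bp every ``step`` bp.

    ``step`` defaults to ``window`` (non-overlapping).  The last window may
    be shorter than ``window``; it is kept and flagged in the ``short``
    column.  The median of an even-sized window is the lower median, which
    is deterministic and integer-preserving.
    """
    if window <= 0 or (step is not None and step <= 0):
        raise ValueError("window and step must be > 0")
    step = window if step is None else step
    if step > window:
        raise ValueError("step must be <= window")
    depth = np.asarray(track.depth)
    n = depth.size
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "median_depth", "short"])
    starts = np.arange(0, n, step)
    rows = []
    for s in starts:
        e = min(s + window, n)
        win = np.sort(depth[s:e])
        med = win[(win.size - 1) // 2]  # lower median
        rows.append(
            {
                "chrom": track.chrom,
                "start": int(s + track.start),
                "end": int(e + track.start),
                "median_depth": float(med),
                "short": e - s < window,
            }
        )
        if e == n:
            break
    return pd.DataFrame(rows)


def log2_depth_ratio(depth_a, depth_b, pseudo: float = 1.0):
    """log2((a + pseudo) / (b + pseudo)); accepts scalars or arrays."""
    a = np.asarray(depth_a, dtype=float)
    b = np.asarray(depth_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("depths must be >= 0")
    out = np.log2((a + pseudo) / (b + pseudo))
    return float(out) if out.ndim == 0 else out


def call_female_specific_markers(
    intervals: pd.DataFrame,
    l_quantile: float = 0.05,
    rule2_cutoff: float = 5.0,
    l_divisor: str = "n_intervals",
    fixed_l: float | None = None,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Two-rule female-specific marker classifier over GBS intervals.

    Expects columns ``pooled_F, pooled_M, reseq_F, reseq_M``.  Adds
    ``rule1_stat`` = log2((M_pool+1)/(F_pool+1)), ``rule2_stat`` =
    log2((F_reseq+1)/(M_reseq+1)), the threshold ``L`` used, and the call
    ``is_female_specific`` (rule1_stat < L AND rule2_stat > rule2_cutoff).

    ``L`` defaults to quantile(rule1_stat, l_quantile) / N_intervals — the
    literal reading of "fifth percentile divided by the number of intervals
    tested".  ``l_divisor='one'`` uses the raw quantile instead, and
    ``fixed_l`` overrides the data-derived bound entirely.
    """
    if len(intervals) < 2:
        raise ValueError("need at least 2 intervals to form a rule-1 distribution")
    df = intervals.copy()
    df["rule1_stat"] = log2_depth_ratio(df["pooled_M"], df["pooled_F"], pseudo)
    df["rule2_stat"] = log2_depth_ratio(df["reseq_F"], df["reseq_M"], pseudo)
    if fixed_l is not None:
        L = float(fixed_l)
    else:
        q = float(np.quantile(df["rule1_stat"], l_quantile))
        if l_divisor == "n_intervals":
            L = q / len(df)
        elif l_divisor == "one":
            L = q
        else:
            raise ValueError("l_divisor must be 'n_intervals' or 'one'")
    df["L"] = L
    if df[["pooled_F", "pooled_M", "reseq_F", "reseq_M"]].to_numpy().sum() == 0:
        import warnings

        warnings.warn("all depths are zero; degenerate distribution, no calls made")
        df["is_female_specific"] = False
        return df
    df["is_female_specific"] = (df["rule1_stat"] < L) & (df["rule2_stat"] > rule2_cutoff)
    return df


def classify_w_contigs(
    markers: pd.DataFrame, min_markers: int = 3, contig_col: str = "contig"
) -> list[ContigSexCall]:
    """Candidate-W call per contig: >= ``min_markers`` female-specific markers."""
    calls = []
    for contig, grp in markers.groupby(contig_col, sort=True):
        n = int(grp["is_female_specific"].sum())
        calls.append(
            ContigSexCall(
                contig=str(contig),
                n_female_specific_markers=n,
                call="W_candidate" if n >= min_markers else "not_W",
            )
        )
    return calls


def classify_zw_regions(
    male_window_stats: pd.DataFrame, max_male_depth: float = 10.0
) -> pd.DataFrame:
    """Label windowed male depth medians as W_specific vs ZW_homologous.

    Windows with median male depth <= ``max_male_depth`` are W-specific
    (hemizygous insertions invisible to male reads); contiguous same-label
    windows are merged into intervals.  Works on coarse (50-kb) or fine
    (10-kb) window tables alike.
    """
    if male_window_stats.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "label"])
    df = male_window_stats.sort_values("start").reset_index(drop=True)
    labels = np.where(df["median_depth"] <= max_male_depth, "W_specific", "ZW_homologous")
    rows = []
    cur_label, cur_start, cur_end, cur_chrom = labels[0], df.start.iloc[0], df.end.iloc[0], df.chrom.iloc[0]
    for i in range(1, len(df)):
        if labels[i] == cur_label and df.start.iloc[i] <= cur_end and df.chrom.iloc[i] == cur_chrom:
            cur_end = max(cur_end, df.end.iloc[i])
        else:
            rows.append({"chrom": cur_chrom, "start": int(cur_start), "end": int(cur_end), "label": cur_label})
            cur_label, cur_start, cur_end, cur_chrom = (
                labels[i], df.start.iloc[i], df.end.iloc[i], df.chrom.iloc[i],
            )
    rows.append({"chrom": cur_chrom, "start": int(cur_start), "end": int(cur_end), "label": cur_label})
    return pd.DataFrame(rows)


def recode_hemizygous_markers(
    mother_pattern: str, father_pattern: str, offspring_presence: list[bool]
) -> dict:
    """Recode presence/absence segregation to backcross genotypes.

    A hemizygous marker segregating +/- x -/- becomes AB x BB: the
    presence-carrying parent is AB, the absent parent BB, offspring with the
    marker are AB and offspring without it BB.
    """
    patterns = {mother_pattern, father_pattern}
    if patterns != {"+/-", "-/-"}:
        raise ValueError(
            f"unsupported segregation pattern {mother_pattern} x {father_pattern}; "
            "only +/- x -/- hemizygous markers can be recoded"
        )
    mother = "AB" if mother_pattern == "+/-" else "BB"
    father = "AB" if father_pattern == "+/-" else "BB"
    return {
        "mother": mother,
        "father": father,
        "offspring": ["AB" if p else "BB" for p in offspring_presence],
    }


# --------------------------------------------------------------------------
# truth-ledger scoring helpers (used by tests and the acceptance script)


def score_marker_calls(
    called: pd.DataFrame, hemizygous_intervals: list[tuple[int, int]]
) -> dict:
    """Confusion-matrix summary of marker calls against truth intervals.

    A GBS interval is truly female-specific when its midpoint lies inside a
    hemizygous truth interval.  Returns sensitivity and false-positive rate.
    """
    mid = ((called["start"] + called["end"]) // 2).to_numpy()
    truth = np.zeros(len(called), dtype=bool)
    for s, e in hemizygous_intervals:
        truth |= (mid >= s) & (mid < e)
    pred = called["is_female_specific"].to_numpy()
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fpr": fp / (fp + tn) if fp + tn else float("nan"),
    }
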