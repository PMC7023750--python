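"""Gene-conversion signature detection on a collapsed single-arm reference.

When reads from all palindrome arms of two species are mapped onto a single
arm copy, arm-to-arm differences appear as paralogous sequence variants
(PSVs, intermediate allele fractions near m/copy-number) while
species-to-species differences appear as near-fixed alternate alleles.  A
region carrying interspecific fixed differences but no PSVs in either
species — at the elevated (~4N) read depth expected of four collapsed
copies — is the signature of gene conversion homogenizing the arms within
each species.

Sites enter as a table with per-species reference/alternate depths
(columns: pos, ref, alt, qual, depth, depth_A_ref, depth_A_alt,
depth_B_ref, depth_B_alt); species A is focal, B the sister.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def filter_variants(
    sites: pd.DataFrame, min_qual: float = 20.0, max_depth: float = 300.0
) -> pd.DataFrame:
    """Keep sites with quality >= min_qual and depth <= max_depth.

    Idempotent: filtering a filtered table changes nothing.
    """
    if sites.empty:
        return sites.copy()
    keep = (sites["qual"] >= min_qual) & (sites["depth"] <= max_depth)
    return sites[keep].reset_index(drop=True)


def drop_shadow_sites(sites: pd.DataFrame, shadow_intervals) -> pd.DataFrame:
    """Drop sites inside user-supplied paralog-shadow intervals.

    Stands in for manual curation of reads cross-mapped from autosomal
    paralogs: any site whose position falls inside one of the supplied
    (start, end) intervals on the arm reference is removed.
    """
    if sites.empty or not len(shadow_intervals):
        return sites.copy()
    pos = sites["pos"].to_numpy()
    bad = np.zeros(len(sites), dtype=bool)
    for s, e in shadow_intervals:
        bad |= (pos >= s) & (pos < e)
    return sites[~bad].reset_index(drop=True)


def classify_sites(
    sites: pd.DataFrame, arm_copy_number: int = 4, af_tol: float = 0.15
) -> pd.DataFrame:
    """Classify sites as PSV, fixed interspecific difference, shared or other.

    Per species, the alternate-allele fraction is tested against
    near-fixation (<= af_tol from 0 or 1) and against the PSV bands
    m/arm_copy_number +/- af_tol for m = 1..copy-1 (arm-private variants on
    a collapsed reference).  Classes:

    * ``fixed_difference`` — both species near-fixed, for opposite alleles;
    * ``shared_variant`` — PSV-like fractions in both species;
    * ``psv_focal`` / ``psv_sister`` — PSV-like in one species, near-fixed
      (either allele) in the other;
    * ``other`` — anything else (including sites without coverage).
    """
    if arm_copy_number < 2:
        raise ValueError("arm_copy_number must be >= 2")
    df = sites.copy()
    if df.empty:
        df["classification"] = pd.Series(dtype=str)
        return df

    def fractions(ref_col, alt_col):
        tot = df[ref_col].to_numpy(float) + df[alt_col].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, df[alt_col].to_numpy(float) / np.maximum(tot, 1), np.nan), tot

    fa, tot_a = fractions("depth_A_ref", "depth_A_alt")
    fb, tot_b = fractions("depth_B_ref", "depth_B_alt")

    bands = np.array([m / arm_copy_number for m in range(1, arm_copy_number)])

    def psv_like(f):
        f = f[:, None]
        return np.any(np.abs(f - bands[None, :]) <= af_tol, axis=1)

    def near_fixed(f):
        return (f <= af_tol) | (f >= 1 - af_tol)

    pa, pb = psv_like(fa), psv_like(fb)
    na, nb = near_fixed(fa), near_fixed(fb)
    opposite = near_fixed(fa) & near_fixed(fb) & (np.abs(fa - fb) >= 1 - 2 * af_tol)

    cls = np.full(len(df), "other", dtype=object)
    cls[opposite] = "fixed_difference"
    cls[pa & pb] = "shared_variant"
    cls[pa & ~pb & nb] = "psv_focal"
    cls[pb & ~pa & na] = "psv_sister"
    cls[np.isnan(fa) | np.isnan(fb)] = "other"
    df["classification"] = cls
    return df


def density_tracks(
    sites: pd.DataFrame, reference_length: int, window: int = 100
) -> pd.DataFrame:
    """Per-class site counts in non-overlapping windows tiling the reference.

    Returns one row per window with columns ``fixed``, ``psv_focal``,
    ``psv_sister``, ``shared``, ``other``; windowed counts sum to the
    per-class site totals.
    """
    starts = np.arange(0, max(reference_length, 1), window)
    out = pd.DataFrame({"window_start": starts, "window_end": np.minimum(starts + window, reference_length)})
    colmap = {
        "fixed": "fixed_difference",
        "psv_focal": "psv_focal",
        "psv_sister": "psv_sister",
        "shared": "shared_variant",
        "other": "other",
    }
    for col in colmap:
        out[col] = 0
    if not sites.empty:
        idx = (sites["pos"].to_numpy() // window).astype(int)
        for col, klass in colmap.items():
            sel = idx[(sites["classification"] == klass).to_numpy()]
            counts = np.bincount(sel, minlength=len(starts))
            out[col] = counts[: len(starts)]
    return out


def relative_depth(depth: np.ndarray, genome_mean_depth: float) -> np.ndarray:
    """Depth rescaled to 'N' units: genome-wide diploid mean maps to 2N."""
    if genome_mean_depth <= 0:
        raise ValueError("genome_mean_depth must be > 0")
    return np.asarray(depth, dtype=float) / genome_mean_depth * 2.0


def windowed_mean(values: np.ndarray, window: int = 100) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n_win = int(np.ceil(values.size / window))
    out = np.empty(n_win)
    for i in range(n_win):
        out[i] = values[i * window : (i + 1) * window].mean()
    return out


def detect_converted_regions(
    tracks: pd.DataFrame,
    min_span: int = 1000,
    max_psv_per_100bp: float = 0.0,
    min_fixed_per_window: float = 1.0,
    depth_band: tuple[float, float] | None = (3.0, 5.0),
    psv_columns: tuple[str, ...] = ("psv_focal",),
) -> pd.DataFrame:
    """Candidate converted intervals from the density/depth tracks.

    Maximal runs of windows whose PSV count (summed over ``psv_columns``)
    is <= ``max_psv_per_100bp`` define candidates; a candidate is reported
    when it spans >= ``min_span`` bp, contains at least
    ``min_fixed_per_window * min_span / window`` fixed differences in total,
    and (when ``depth_band`` is set and a ``depth_n`` column exists) its
    mean relative depth lies in the band.  The PSV condition defines the
    run while the fixed-difference condition is a run-total floor, so a
    single fixed-poor window inside a genuine tract cannot fragment it and
    relaxing ``max_psv_per_100bp`` (with ``depth_band=None``) never shrinks
    the union of reported intervals.
    """
    if tracks.empty:
        return pd.DataFrame(
            columns=["start", "end", "span", "n_fixed", "n_psv_focal", "n_psv_sister", "mean_depth_n"]
        )
    psv = sum(tracks[c].to_numpy(float) for c in psv_columns)
    ok = psv <= max_psv_per_100bp
    window_size = int(tracks["window_end"].iloc[0] - tracks["window_start"].iloc[0])
    required_fixed = min_fixed_per_window * (min_span / max(window_size, 1))
    rows = []
    i = 0
    n = len(tracks)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        sub = tracks.iloc[i : j + 1]
        start = int(sub["window_start"].iloc[0])
        end = int(sub["window_end"].iloc[-1])
        span = end - start
        total_fixed = float(sub["fixed"].sum())
        mean_depth = float(sub["depth_n"].mean()) if "depth_n" in sub else float("nan")
        passes = span >= min_span and total_fixed >= required_fixed
        if depth_band is not None and "depth_n" in sub:
            passes = passes and depth_band[0] <= mean_depth <= depth_band[1]
        if passes:
            rows.append(
                {
                    "start": start,
                    "end": end,
                    "span": span,
                    "n_fixed": int(sub["fixed"].sum()),
                    "n_psv_focal": int(sub["psv_focal"].sum()),
                    "n_psv_sister": int(sub["psv_sister"].sum()),
                    "mean_depth_n": mean_depth,
                }
            )
        i = j + 1
    return pd.DataFrame(
        rows, columns=["start", "end", "span", "n_fixed", "n_psv_focal", "n_psv_sister", "mean_depth_n"]
    )


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|); 0 when disjoint."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))
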