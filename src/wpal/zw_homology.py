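"""Z-W gene categorization and synonymous-divergence estimation.

Cross-haplotype gene relations are established by an all-vs-all protein
search (k-mer prefiltered Smith-Waterman via Biopython's PairwiseAligner),
reduced to mutual best hits (MBH) at identity/coverage thresholds, with
tandem arrays collapsed by single-linkage clustering of significant hits
within a physical window.  W genes are then assigned to the categories a
female-specific region accumulates: Z-W homologs (single-copy MBH across
haplotypes), tandem duplicates, transpositions from autosomes, ancestral
genes lost on Z (outgroup homolog on the homologous chromosome), non-mutual
best hits, and genes with no hit.

Synonymous/nonsynonymous divergence of Z-W pairs uses a protein-guided
codon alignment and the Nei-Gojobori (1986) estimator: per-position
synonymous site fractions (changes to stop codons excluded), all mutational
pathways between differing codons averaged with equal weight (pathways
through stop codons discarded when avoidable), and Jukes-Cantor correction
d = -3/4 ln(1 - 4/3 p).  A positional scan of dS along the Z coordinate
with a penalized mean-shift segmentation flags candidate evolutionary
strata.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11, extend 1),
# used only to convert raw scores into a BLAST-like significance proxy
_KA_LAMBDA = 0.267
_KA_K = 0.041

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_protein_search(
    set_a: dict[str, str],
    set_b: dict[str, str],
    k: int = 4,
    min_shared_kmers: int = 2,
    min_score: float = 40.0,
) -> pd.DataFrame:
    """Protein search of every sequence in ``set_a`` against ``set_b``.

    Pairs sharing at least ``min_shared_kmers`` exact amino-acid k-mers are
    aligned (local, BLOSUM62, gap open -11 / extend -1).  Hits carry percent
    identity over the aligned region, query coverage (aligned query residues
    / query length), the raw score, and an E-value-style significance proxy
    from fixed Karlin-Altschul parameters with the subject set's total
    residue count as the database size.  Self-hits (same id) are excluded.
    Sequences with invalid residues are skipped with a warning.
    """
    if not set_a or not set_b:
        raise ValueError("protein sets must be non-empty")

    def clean(s: dict[str, str], tag: str) -> dict[str, str]:
        out = {}
        for name, seq in s.items():
            if not seq or set(seq) - _VALID_AA:
                warnings.warn(f"skipping {tag} sequence {name!r}: invalid residues")
                continue
            out[name] = seq
        return out

    set_a = clean(set_a, "query")
    set_b = clean(set_b, "subject")
    db_size = sum(len(s) for s in set_b.values())
    kmer_index: dict[str, set[str]] = {}
    for name, seq in set_b.items():
        for km in _kmers(seq, k):
            kmer_index.setdefault(km, set()).add(name)

    aligner = _make_aligner("local")
    rows = []
    for qname, qseq in set_a.items():
        counts: dict[str, int] = {}
        for km in _kmers(qseq, k):
            for sname in kmer_index.get(km, ()):
                counts[sname] = counts.get(sname, 0) + 1
        for sname, shared in counts.items():
            if sname == qname or shared < min_shared_kmers:
                continue
            aln = aligner.align(qseq, set_b[sname])[0]
            score = float(aln.score)
            if score < min_score:
                continue
            counts = aln.counts()
            identities = counts.identities
            ncols = counts.internal_gaps + identities + counts.mismatches
            q_aligned = sum(int(e - s) for s, e in aln.aligned[0])
            bitscore = (_KA_LAMBDA * score - np.log(_KA_K)) / np.log(2)
            evalue = len(qseq) * db_size * 2.0 ** (-bitscore)
            rows.append(
                {
                    "query": qname,
                    "subject": sname,
                    "identity": 100.0 * identities / ncols if ncols else 0.0,
                    "coverage": q_aligned / len(qseq),
                    "score": score,
                    "bitscore": float(bitscore),
                    "evalue": float(evalue),
                }
            )
    return pd.DataFrame(
        rows, columns=["query", "subject", "identity", "coverage", "score", "bitscore", "evalue"]
    )


def best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query by (score, identity, subject id) ordering."""
    if hits.empty:
        return {}
    ordered = hits.sort_values(
        ["query", "score", "identity", "subject"], ascending=[True, False, False, True]
    )
    return ordered.groupby("query", sort=False).first()["subject"].to_dict()


def mutual_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    min_identity: float = 90.0,
    min_coverage: float = 0.7,
) -> pd.DataFrame:
    """Reciprocal best-hit pairs passing identity/coverage in both directions.

    (a, b) is an MBH iff b is a's best hit, a is b's best hit, and both
    direction hits show identity > ``min_identity`` over coverage >=
    ``min_coverage`` of the query.  The pair set is identical whichever
    input order the two genomes are given in.
    """
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)

    def passes(hits, q, s):
        row = hits[(hits["query"] == q) & (hits["subject"] == s)]
        if row.empty:
            return False
        r = row.iloc[0]
        return r["identity"] > min_identity and r["coverage"] >= min_coverage

    pairs = []
    for a, b in best_ab.items():
        if best_ba.get(b) == a and passes(hits_ab, a, b) and passes(hits_ba, b, a):
            pairs.append({"a": a, "b": b})
    return pd.DataFrame(pairs, columns=["a", "b"])


def tandem_arrays(
    intra_hits: pd.DataFrame,
    positions: pd.DataFrame,
    proteins: dict[str, str],
    window: int = 500_000,
    evalue_threshold: float = 1e-10,
) -> pd.DataFrame:
    """Single-linkage tandem arrays from significant intra-genome hits.

    Gene pairs with E-value <= threshold on the same chromosome whose starts
    lie within ``window`` bp are linked; connected components form arrays.
    One representative per array: the longest protein, ties broken by
    lexicographic gene id.  Returns gene_id, array_id, array_size,
    is_representative.
    """
    pos = positions.set_index("gene_id")
    parent: dict[str, str] = {g: g for g in pos.index}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    if not intra_hits.empty:
        sig = intra_hits[intra_hits["evalue"] <= evalue_threshold]
        for r in sig.itertuples():
            q, s = r.query, r.subject
            if q not in parent or s not in parent or q == s:
                continue
            if pos.loc[q, "chrom"] != pos.loc[s, "chrom"]:
                continue
            if abs(int(pos.loc[q, "start"]) - int(pos.loc[s, "start"])) <= window:
                union(q, s)

    clusters: dict[str, list[str]] = {}
    for g in pos.index:
        clusters.setdefault(find(g), []).append(g)
    rows = []
    for i, (_, members) in enumerate(sorted(clusters.items())):
        rep = max(members, key=lambda g: (len(proteins.get(g, "")), [-ord(c) for c in g]))
        # tie-break: longest protein, then lexicographically first id
        best_len = len(proteins.get(rep, ""))
        rep = min(m for m in members if len(proteins.get(m, "")) == best_len)
        for g in members:
            rows.append(
                {
                    "gene_id": g,
                    "array_id": f"array_{i}",
                    "array_size": len(members),
                    "is_representative": g == rep,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "array_id", "array_size", "is_representative"])


CATEGORY_PRIORITY = [
    "ZW_homolog",
    "tandem_duplicate",
    "transposed_from_autosome",
    "ancestral",
    "non_mutual",
    "no_hit",
]


def categorize_genes(
    w_ids: list[str],
    mbh_to_partner: dict[str, str],
    mbh_to_autosome: dict[str, str],
    tandem: pd.DataFrame,
    outgroup_hits: pd.DataFrame | None = None,
    outgroup_positions: pd.DataFrame | None = None,
    homologous_outgroup_chrom: str = "outChr15",
    any_best_hit: dict[str, str] | None = None,
    evalue_threshold: float = 1e-10,
) -> pd.DataFrame:
    """Assign each W gene to exactly one category by fixed priority.

    Priority: ZW_homolog (MBH on the partner haplotype) > tandem_duplicate
    (member of an intra-genome array of size >= 2) > transposed_from_autosome
    (MBH on an autosome) > ancestral (significant outgroup hit mapping to
    the homologous outgroup chromosome) > non_mutual (some best hit, not
    reciprocated) > no_hit.  The output is a partition: every input gene
    appears exactly once.
    """
    arrays = {}
    if tandem is not None and not tandem.empty:
        arrays = tandem[tandem["array_size"] >= 2].set_index("gene_id")["array_id"].to_dict()
    outgroup_chrom: dict[str, str] = {}
    if outgroup_hits is not None and not outgroup_hits.empty and outgroup_positions is not None:
        opos = outgroup_positions.set_index("gene_id")["chrom"].to_dict()
        sig = outgroup_hits[outgroup_hits["evalue"] <= evalue_threshold]
        for q, grp in sig.groupby("query"):
            top = grp.sort_values(["score", "identity", "subject"], ascending=[False, False, True]).iloc[0]
            outgroup_chrom[q] = opos.get(top["subject"], "")
    any_best_hit = any_best_hit or {}

    rows = []
    for g in w_ids:
        if g in mbh_to_partner:
            cat, partner = "ZW_homolog", mbh_to_partner[g]
        elif g in arrays:
            cat, partner = "tandem_duplicate", arrays[g]
        elif g in mbh_to_autosome:
            cat, partner = "transposed_from_autosome", mbh_to_autosome[g]
        elif outgroup_chrom.get(g) == homologous_outgroup_chrom:
            cat, partner = "ancestral", outgroup_chrom[g]
        elif g in any_best_hit:
            cat, partner = "non_mutual", any_best_hit[g]
        else:
            cat, partner = "no_hit", ""
        rows.append({"gene_id": g, "category": cat, "partner": partner})
    out = pd.DataFrame(rows, columns=["gene_id", "category", "partner"])
    if out["gene_id"].duplicated().any():
        raise RuntimeError("internal consistency error: a gene was categorized twice")
    return out


# --------------------------------------------------------------------------
# codon alignment + NG86


_STOPS = set(standard_dna_table.stop_codons)
_FWD = dict(standard_dna_table.forward_table)


def _translate_codon(codon: str) -> str:
    return "*" if codon in _STOPS else _FWD[codon]


def codon_align(
    cds_a: str,
    cds_b: str,
    protein_alignment=None,
    names: tuple[str, str] = ("seq_a", "seq_b"),
) -> list[tuple[str, str]]:
    """Protein-guided codon alignment; returns ungapped codon column pairs.

    CDS lengths must be divisible by 3 and translate consistently with the
    protein alignment (a trailing stop codon is tolerated and trimmed).
    Codon columns follow the protein alignment; gap columns are excluded
    from the returned pairs.
    """
    cleaned = []
    for cds, name in zip((cds_a, cds_b), names):
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length of {name} is not divisible by 3")
        if len(cds) >= 3 and cds[-3:] in _STOPS:
            cds = cds[:-3]
        cleaned.append(cds)
    cds_a, cds_b = cleaned
    prot_a = "".join(_translate_codon(cds_a[i : i + 3]) for i in range(0, len(cds_a), 3))
    prot_b = "".join(_translate_codon(cds_b[i : i + 3]) for i in range(0, len(cds_b), 3))
    if "*" in prot_a or "*" in prot_b:
        bad = names[0] if "*" in prot_a else names[1]
        raise ValueError(f"internal stop codon in {bad}")
    if protein_alignment is None:
        protein_alignment = _make_aligner("global").align(prot_a, prot_b)[0]
    row_a, row_b = str(protein_alignment[0]), str(protein_alignment[1])
    if row_a.replace("-", "") != prot_a or row_b.replace("-", "") != prot_b:
        raise ValueError(
            f"protein alignment inconsistent with CDS translations of {names[0]}/{names[1]}"
        )
    pairs = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            pairs.append((cds_a[3 * ia : 3 * ia + 3], cds_b[3 * ib : 3 * ib + 3]))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return pairs


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon (stop-producing changes excluded)."""
    aa = _translate_codon(codon)
    total = 0.0
    for i in range(3):
        syn = 0
        valid = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt in _STOPS:
                continue
            valid += 1
            if _translate_codon(alt) == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over pathways.

    All orders of the differing positions are enumerated with equal weight;
    pathways passing through a stop codon are discarded unless every
    pathway does.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if nxt in _STOPS:
                blocked = True
            if _translate_codon(cur) == _translate_codon(nxt) and not (
                cur in _STOPS or nxt in _STOPS
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    usable = [p for p in paths if not p[0]] or paths
    sd = float(np.mean([p[1] for p in usable]))
    nd = float(np.mean([p[2] for p in usable]))
    return sd, nd


@dataclass
class DsDnResult:
    """Synonymous/nonsynonymous divergence of one codon-aligned pair."""

    ds: float | None
    dn: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_differences: float
    nonsyn_differences: float
    n_codons: int
    saturated_s: bool = False
    saturated_n: bool = False


def estimate_ds_dn(codon_pairs: list[tuple[str, str]], min_codons: int = 10) -> DsDnResult:
    """Nei-Gojobori (1986) dS/dN with Jukes-Cantor correction.

    Site counts are averaged over the two sequences; differences are
    averaged over equally weighted mutational pathways.  When a proportion
    reaches the Jukes-Cantor singularity (p >= 3/4) the corresponding rate
    is flagged saturated and returned as None.
    """
    if len(codon_pairs) < min_codons:
        raise ValueError(f"need >= {min_codons} comparable codons, got {len(codon_pairs)}")
    s_a = sum(_syn_sites(a) for a, _ in codon_pairs)
    s_b = sum(_syn_sites(b) for _, b in codon_pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(codon_pairs) - S
    sd = nd = 0.0
    for a, b in codon_pairs:
        ds_i, dn_i = _pathway_counts(a, b)
        sd += ds_i
        nd += dn_i

    def jc(p: float) -> tuple[float | None, bool]:
        if p >= 0.75:
            return None, True
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False

    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ds, sat_s = jc(ps)
    dn, sat_n = jc(pn)
    return DsDnResult(
        ds=ds,
        dn=dn,
        syn_sites=S,
        nonsyn_sites=N,
        syn_differences=sd,
        nonsyn_differences=nd,
        n_codons=len(codon_pairs),
        saturated_s=sat_s,
        saturated_n=sat_n,
    )


def ds_for_pairs(
    pairs: pd.DataFrame,
    cds_a: dict[str, str],
    cds_b: dict[str, str],
    positions_b: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """dS/dN per MBH pair, optionally with the partner's chromosome position."""
    pos = {}
    if positions_b is not None:
        pos = positions_b.set_index("gene_id")["start"].to_dict()
    rows = []
    for r in pairs.itertuples():
        cp = codon_align(cds_a[r.a], cds_b[r.b], names=(r.a, r.b))
        res = estimate_ds_dn(cp)
        rows.append(
            {
                "a": r.a,
                "b": r.b,
                "ds": res.ds,
                "dn": res.dn,
                "z_pos": pos.get(r.b, np.nan),
                "saturated": res.saturated_s,
            }
        )
    return pd.DataFrame(rows, columns=["a", "b", "ds", "dn", "z_pos", "saturated"])


# --------------------------------------------------------------------------
# strata scan


def _segment_mean_shift(values: np.ndarray, penalty: float | None = None) -> list[int]:
    """Optimal mean-shift segmentation by penalized least squares (DP).

    Returns the segment boundaries (indices where a new segment starts,
    excluding 0).  Penalty defaults to 2 * var * log(n) per extra segment.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return []
    if penalty is None:
        v = float(np.var(x))
        penalty = 2.0 * v * np.log(max(n, 2)) if v > 0 else 1.0
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:  # [i, j)
        s, s2, m = c1[j] - c1[i], c2[j] - c2[i], j - i
        return s2 - s * s / m

    best = np.full(n + 1, np.inf)
    best[0] = -penalty
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        for i in range(j):
            cost = best[i] + penalty + sse(i, j)
            if cost < best[j]:
                best[j] = cost
                back[j] = i
    bounds = []
    j = n
    while j > 0:
        i = back[j]
        if i > 0:
            bounds.append(i)
        j = i
    return sorted(bounds)


def strata_scan(
    pairs_with_ds: pd.DataFrame,
    window: int = 100_000,
    penalty: float | None = None,
) -> dict:
    """Positional dS summary along the Z coordinate plus a strata indicator.

    Windowed mean dS (windows of ``window`` bp along Z), the overall mean
    with its standard error, and the number of segments found by a
    penalized mean-shift fit of the position-ordered dS values (1 segment =
    no evidence of strata).
    """
    df = pairs_with_ds.dropna(subset=["ds", "z_pos"]).sort_values("z_pos")
    if len(df) < 2:
        raise ValueError("need >= 2 pairs with dS and positions")
    ds = df["ds"].to_numpy(float)
    zpos = df["z_pos"].to_numpy(float)
    win_idx = (zpos // window).astype(int)
    windowed = (
        pd.DataFrame({"window": win_idx, "ds": ds})
        .groupby("window")["ds"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_ds", "count": "n_pairs"})
    )
    windowed["window_start"] = windowed["window"] * window
    bounds = _segment_mean_shift(ds, penalty=penalty)
    segments = []
    edges = [0] + bounds + [len(ds)]
    for i in range(len(edges) - 1):
        seg = ds[edges[i] : edges[i + 1]]
        segments.append(
            {
                "start_index": edges[i],
                "end_index": edges[i + 1],
                "mean_ds": float(seg.mean()),
                "z_start": float(zpos[edges[i]]),
                "z_end": float(zpos[edges[i + 1] - 1]),
            }
        )
    return {
        "windowed": windowed[["window_start", "mean_ds", "n_pairs"]],
        "mean_ds": float(ds.mean()),
        "se_ds": float(ds.std(ddof=1) / np.sqrt(len(ds))) if len(ds) > 1 else float("nan"),
        "n_segments": len(segments),
        "segments": segments,
    }
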