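"""Low-level DNA utilities shared across modules.

Sequences cross module boundaries as plain Python strings over the ACGT
alphabet; internally hot paths operate on ``uint8`` arrays with the encoding
A=0, G=1, C=2, T=3.  That ordering puts each purine/pyrimidine transition
partner one XOR-bit away (``base ^ 1``), which keeps transition/transversion
bookkeeping branch-free.
"""

from __future__ import annotations

import numpy as np

_ALPHABET = "AGCT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)

# complement under A=0,G=1,C=2,T=3: A<->T (0<->3), G<->C (1<->2) == 3 - x
_COMPLEMENT_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def seq_to_arr(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, G=1, C=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(np.frombuffer(seq.encode(), dtype=np.uint8)[arr > 3][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def arr_to_seq(arr: np.ndarray) -> str:
    """Decode a uint8 array back to an ACGT string."""
    return _DECODE[arr].tobytes().decode()


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def random_dna_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return arr_to_seq(random_dna_arr(rng, n))


def evolve_arr(
    arr: np.ndarray,
    rng: np.random.Generator,
    d: float,
    kappa: float | None = None,
) -> np.ndarray:
    """Apply substitutions at an expected density of ``d`` events per site.

    The number of substitution events per site is Poisson(d), so multiple
    hits at one site are possible and observed divergence saturates the way
    distance corrections (Jukes-Cantor, K2P) assume.  ``kappa`` biases each
    event toward transitions with probability kappa/(kappa+2); by default all
    three alternative bases are equally likely.
    """
    if d < 0:
        raise ValueError("substitution density must be >= 0")
    out = arr.copy()
    if d == 0 or out.size == 0:
        return out
    n_events = rng.poisson(d, size=out.size)
    # apply rounds until no site has remaining events; round r mutates all
    # sites with n_events > r, preserving sequential multiple-hit behaviour
    max_rounds = int(n_events.max()) if out.size else 0
    if kappa is None:
        p_transition = 1.0 / 3.0
    else:
        p_transition = kappa / (kappa + 2.0)
    for r in range(max_rounds):
        idx = np.nonzero(n_events > r)[0]
        if idx.size == 0:
            break
        is_ts = rng.random(idx.size) < p_transition
        delta = np.where(
            is_ts, 1, np.where(rng.random(idx.size) < 0.5, 2, 3)
        ).astype(np.uint8)
        # base^1 is the transition partner; ^2 and ^3 are the transversions
        out[idx] = out[idx] ^ delta
    return out


def evolve(seq: str, rng: np.random.Generator, d: float, kappa: float | None = None) -> str:
    return arr_to_seq(evolve_arr(seq_to_arr(seq), rng, d, kappa))


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(seq_to_arr(a) != seq_to_arr(b)))
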