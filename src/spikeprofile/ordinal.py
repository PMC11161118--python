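"""Ordinal-pattern encoding, entropies, and Lempel-Ziv complexity of ISI sequences.

The order-sensitive measures work on a symbolized version of the ISI
sequence: each non-overlapping window of D consecutive intervals is mapped
to its rank-order permutation (an *ordinal pattern*, OP), giving a symbol
sequence over an alphabet of D! patterns.  Two quantities summarize it:

* **OP Entropy** — Shannon entropy of the pattern distribution, normalized
  by log(D!) so 0 means a single pattern dominates and 1 means all D!
  patterns are equiprobable.  Magnitude-blind: it sees only local order.
* **PLZC** — Lempel-Ziv-76 complexity of the pattern sequence, normalized by
  the sequence length, sensitive to repeated motifs across the sequence.

A third, order-blind measure, **Bins Entropy**, is the normalized Shannon
entropy of the histogram of ISI magnitudes.

Defaults mirror a fixed-length design: N = 225 intervals per neuron, D = 3
(so 6 patterns, ~75 non-overlapping windows, doubled by a second encoding
offset), and Nb = 18 histogram bins, chosen so that the a-priori counts per
pattern and per bin are comparable (~25 and ~12.5 respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ISISequence, InvalidParameterError

__all__ = [
    "OPEncoding",
    "SymbolDistribution",
    "LZParse",
    "add_tiebreak_noise",
    "ordinal_pattern",
    "encode_ordinal",
    "symbol_distribution",
    "shannon_entropy_normalized",
    "op_entropy",
    "bins_entropy",
    "lz76_parse",
    "lz_normalize",
    "plzc",
    "DEFAULT_D",
    "DEFAULT_NB",
    "DEFAULT_TIEBREAK_SCALE",
]

DEFAULT_D = 3
DEFAULT_NB = 18
#: Tie-break noise SD as a fraction of the ISI standard deviation.
DEFAULT_TIEBREAK_SCALE = 1e-6


def _values(isi) -> np.ndarray:
    if isinstance(isi, ISISequence):
        return isi.values
    return np.asarray(isi, dtype=float)


@dataclass(frozen=True)
class OPEncoding:
    """Ordinal-pattern symbol sequences for one ISI sequence.

    ``symbols[o]`` holds the symbols of the encoding that starts at index
    ``o`` (0-based); offset o yields floor((N - o)/D) non-overlapping
    windows.  Symbols are lexicographic permutation indices in
    {0, ..., D!-1} with (1,2,3) -> 0 and (3,2,1) -> D!-1.
    """

    D: int
    offsets_used: tuple[int, ...]
    symbols: dict[int, np.ndarray] = field(repr=False)

    @property
    def alphabet_size(self) -> int:
        return math.factorial(self.D)

    def pooled(self) -> np.ndarray:
        """Symbols of all offsets concatenated in offset order."""
        return np.concatenate([self.symbols[o] for o in self.offsets_used])


@dataclass(frozen=True)
class SymbolDistribution:
    """Relative frequencies of symbols over a finite alphabet."""

    probabilities: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def alphabet_size(self) -> int:
        return int(self.probabilities.size)


@dataclass(frozen=True)
class LZParse:
    """Exhaustive-history Lempel-Ziv-76 parse of a symbol sequence."""

    words: tuple[tuple[int, ...], ...]
    c_lz: int
    length: int
    alphabet_size: int

    def __post_init__(self) -> None:
        if self.c_lz != len(self.words):
            raise InvalidParameterError("c_lz must equal the number of words")


def add_tiebreak_noise(
    isi,
    scale: float = DEFAULT_TIEBREAK_SCALE,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Add negligible white noise to break exact ties before OP encoding.

    Ordinal patterns are undefined on tied values; a zero-mean Gaussian
    perturbation with SD = ``scale`` x SD(isi) makes all values distinct
    with probability 1 while being far too small to reorder genuinely
    different intervals.  For a constant input (SD = 0) the noise SD falls
    back to ``scale`` x |mean| so ties are still broken.  ``scale=0`` is the
    identity.  The input is never modified.
    """
    if scale < 0:
        raise InvalidParameterError("scale must be >= 0")
    v = _values(isi).copy()
    if scale == 0:
        return v
    sd = float(np.std(v))
    if sd == 0.0:
        sd = abs(float(np.mean(v))) or 1.0
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return v + rng.normal(0.0, scale * sd, size=v.size)


def ordinal_pattern(window) -> int:
    """Map D distinct values to the lexicographic index of their rank permutation.

    The symbol is the lexicographic rank of the argsort permutation (the
    index order that sorts the window ascending): (1,2,3) -> 0, (3,2,1) ->
    D!-1.  Any bijective labeling yields identical entropies; this one is
    frozen for serialization stability.

    Raises
    ------
    InvalidParameterError
        On tied values; apply :func:`add_tiebreak_noise` first.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise InvalidParameterError("window must be 1-D with >= 2 values")
    if np.unique(w).size != w.size:
        raise InvalidParameterError("tied values in window; apply tie-break noise first")
    return int(_encode_windows(w.reshape(1, -1))[0])


def _encode_windows(windows: np.ndarray) -> np.ndarray:
    """Vectorized lexicographic permutation index per row (rows distinct-valued)."""
    d = windows.shape[1]
    perm = np.argsort(windows, axis=1, kind="stable")
    # Lehmer code: digit i counts later entries smaller than perm[:, i]
    idx = np.zeros(windows.shape[0], dtype=np.int64)
    for i in range(d - 1):
        smaller_later = np.sum(perm[:, i + 1 :] < perm[:, i : i + 1], axis=1)
        idx = idx * (d - i) + smaller_later
    return idx


def encode_ordinal(
    isi, D: int = DEFAULT_D, offsets: tuple[int, ...] = (0, 1)
) -> OPEncoding:
    """Symbolize an ISI sequence with non-overlapping ordinal-pattern windows.

    Offset 0 splits the sequence into consecutive D-tuples from the first
    value; offset 1 repeats the split starting from the second value,
    doubling the number of patterns available to estimate the distribution
    (floor(N/D) + floor((N-1)/D) symbols at D=3, N=225: 75 + 74 = 149).
    """
    v = _values(isi)
    n = v.size
    if D < 2:
        raise InvalidParameterError("D must be >= 2")
    if n < D:
        raise InvalidParameterError(f"sequence length {n} < embedding dimension {D}")
    offsets = tuple(int(o) for o in offsets)
    if any(o < 0 or o >= D for o in offsets):
        raise InvalidParameterError("offsets must lie in [0, D)")
    symbols: dict[int, np.ndarray] = {}
    for o in offsets:
        n_win = (n - o) // D
        if n_win == 0:
            raise InvalidParameterError(f"offset {o} leaves no complete window")
        win = v[o : o + n_win * D].reshape(n_win, D)
        # Ties make ranks ambiguous; refuse rather than silently tie-break.
        if np.any(np.diff(np.sort(win, axis=1), axis=1) == 0):
            raise InvalidParameterError(
                "tied values within a window; apply add_tiebreak_noise first"
            )
        symbols[o] = _encode_windows(win)
    return OPEncoding(D=D, offsets_used=offsets, symbols=symbols)


def symbol_distribution(enc: OPEncoding) -> SymbolDistribution:
    """Relative pattern frequencies pooled across the encoding offsets."""
    pooled = enc.pooled()
    counts = np.bincount(pooled, minlength=enc.alphabet_size)
    return SymbolDistribution(probabilities=counts / counts.sum(), counts=counts)


def shannon_entropy_normalized(dist, K: int | None = None) -> float:
    """Shannon entropy normalized to [0, 1] by log of the alphabet size.

    ``H = -sum p log_K p`` with ``0 log 0 = 0``; equals 1 for the uniform
    distribution over K outcomes and 0 for a degenerate one.
    """
    if isinstance(dist, SymbolDistribution):
        p = dist.probabilities
        K = dist.alphabet_size if K is None else K
    else:
        p = np.asarray(dist, dtype=float)
        K = p.size if K is None else K
    if K < 2:
        raise InvalidParameterError("alphabet size K must be >= 2")
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz)) / math.log(K)
    return float(h)


def op_entropy(
    isi,
    D: int = DEFAULT_D,
    tiebreak_seed: int | None = None,
    tiebreak_scale: float = DEFAULT_TIEBREAK_SCALE,
    offsets: tuple[int, ...] = (0, 1),
) -> float:
    """Permutation entropy of an ISI sequence (normalized, in [0, 1]).

    Tie-break noise is applied, the sequence is encoded at the given
    offsets, and the pooled pattern distribution's normalized Shannon
    entropy (base D!) is returned.  Invariant under strictly increasing
    transforms of the ISI values; *not* invariant under shuffling.
    """
    v = _values(isi)
    if v.size < 2 * D + 1:
        raise InvalidParameterError(f"need at least {2 * D + 1} intervals")
    noisy = add_tiebreak_noise(v, scale=tiebreak_scale, seed=tiebreak_seed)
    enc = encode_ordinal(noisy, D=D, offsets=offsets)
    return shannon_entropy_normalized(symbol_distribution(enc), enc.alphabet_size)


def bins_entropy(isi, nb: int = DEFAULT_NB) -> float:
    """Normalized Shannon entropy of the ISI magnitude histogram.

    The histogram uses ``nb`` equal-width bins spanning [min, max] of the
    sequence (per-neuron adaptive range, last bin right-closed); entropy is
    normalized by log(nb).  Order-blind: exactly invariant under any
    permutation of the values.  A constant sequence occupies one bin and
    returns 0.
    """
    if nb < 2:
        raise InvalidParameterError("nb must be >= 2")
    v = _values(isi)
    if v.size < 2:
        raise InvalidParameterError("need >= 2 intervals")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=nb, range=(lo, hi))
    return shannon_entropy_normalized(counts / counts.sum(), nb)


def lz76_parse(symbols, alphabet_size: int | None = None) -> LZParse:
    """Exhaustive-history Lempel-Ziv-76 parse of a finite-alphabet sequence.

    Scanning left to right, each new word is the shortest prefix of the
    remaining sequence that does not occur as a substring of the text
    preceding its final symbol; the final word is counted even when it is
    reproducible.  The words concatenate exactly to the input.  Example:
    ``100110111001010001011`` parses into 7 words
    ``1|0|01|101|1100|1010|001011``.

    Parameters
    ----------
    symbols:
        String or sequence of hashable symbols.
    alphabet_size:
        Alphabet size recorded in the parse (and used downstream for
        normalization).  Defaults to the number of distinct symbols present.
    """
    seq = tuple(symbols)
    if len(seq) == 0:
        raise InvalidParameterError("cannot parse an empty sequence")
    # Map symbols to single unicode chars so novelty checks use fast
    # substring search; alphabets here are tiny (D! at most).
    uniq = sorted(set(seq), key=lambda s: (str(type(s)), s))
    if len(uniq) > 0x10000:
        raise InvalidParameterError("alphabet too large")
    enc = {s: chr(i) for i, s in enumerate(uniq)}
    text = "".join(enc[s] for s in seq)
    n = len(text)

    words: list[tuple] = []
    start = 0
    while start < n:
        j = start
        while j < n and text[start : j + 1] in text[:j]:
            j += 1
        if j == n:  # ran off the end: final (possibly reproducible) word
            j = n - 1
        words.append(seq[start : j + 1])
        start = j + 1

    alpha = len(uniq) if alphabet_size is None else int(alphabet_size)
    return LZParse(words=tuple(words), c_lz=len(words), length=n, alphabet_size=alpha)


def lz_normalize(c_lz: int, T: int, alpha: int) -> float:
    """Normalize an LZ76 word count: ``C = c_lz * log_alpha(T) / T``.

    Random sequences of length T over an alphabet of size alpha have
    c_lz ~ T / log_alpha(T), so C is close to 1 for fully random input and
    near 0 for highly compressible input.
    """
    if T < 2:
        raise InvalidParameterError("T must be >= 2")
    if alpha < 2:
        raise InvalidParameterError("alphabet size must be >= 2")
    return float(c_lz * (math.log(T) / math.log(alpha)) / T)


def plzc(
    isi,
    D: int = DEFAULT_D,
    tiebreak_seed: int | None = None,
    tiebreak_scale: float = DEFAULT_TIEBREAK_SCALE,
) -> float:
    """Permutation Lempel-Ziv complexity of an ISI sequence.

    The offset-0 ordinal-pattern sequence (T = floor(N/D) symbols over an
    alphabet of D! patterns) is LZ76-parsed and the word count normalized by
    :func:`lz_normalize`.  Only the single non-overlapping encoding is used:
    concatenating the two offset readings would splice together overlapping
    passes of the same data and manufacture spurious words.
    """
    v = _values(isi)
    if v.size < 2 * D + 1:
        raise InvalidParameterError(f"need at least {2 * D + 1} intervals")
    noisy = add_tiebreak_noise(v, scale=tiebreak_scale, seed=tiebreak_seed)
    enc = encode_ordinal(noisy, D=D, offsets=(0,))
    syms = enc.symbols[0]
    parse = lz76_parse(syms.tolist(), alphabet_size=enc.alphabet_size)
    return lz_normalize(parse.c_lz, parse.length, parse.alphabet_size)
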