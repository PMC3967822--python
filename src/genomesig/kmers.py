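"""Degenerate (reverse-complement-pooled) k-mer counting and frequency features.

Because only one strand of a double-stranded genome is deposited in sequence
databases, and the choice of strand is arbitrary, genome-signature analyses
pool each oligonucleotide with its reverse complement (e.g. AAAC with GTTT)
into a single *degenerate set*.  This halves the feature dimensionality and
makes the representation strand-independent: for k=4 there are 136 degenerate
sets (120 complementary pairs + 16 reverse-complement palindromes), for k=5
there are 512 (no odd-length word equals its reverse complement).

Fragments are vectorized as degenerate k-mer *frequencies*: counts over all
N-free length-k windows, divided by the number of countable windows, so every
row sums to one regardless of how many undetermined (N) bases the fragment
carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .ingest import Fragment

__all__ = [
    "FeatureError",
    "DegenerateIndex",
    "build_degenerate_index",
    "reverse_complement",
    "count_fragment",
    "vectorize",
    "FeatureMatrix",
    "DegenerateKmerVectorizer",
    "mononucleotide_profile",
    "expected_frequencies",
    "observed_expected_ratio",
    "observed_expected_ratios",
]

BASES = "ACGT"

# base -> 2-bit code; anything that is not an unambiguous base maps to 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FeatureError(ValueError):
    """Raised for invalid k, uncountable fragments, or inconsistent vectors."""


def reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement word codes (base-4 integers, first base most significant)."""
    rc = np.zeros_like(codes)
    for j in range(k):
        digit = (codes >> (2 * (k - 1 - j))) & 3
        rc |= (3 - digit) << (2 * j)
    return rc


def _decode(code: int, k: int) -> str:
    return "".join(BASES[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


@dataclass(frozen=True, eq=False)
class DegenerateIndex:
    """Canonical complementary-pair k-mer alphabet.

    Every one of the 4**k k-mers maps to exactly one column; a k-mer and its
    reverse complement always share a column.  The canonical member of each
    set is the lexicographically smaller of the pair, and columns are ordered
    lexicographically by canonical member.
    """

    k: int
    canonical: tuple[str, ...]
    members: tuple[tuple[str, ...], ...]
    code_to_col: np.ndarray = field(repr=False)
    gc_counts: np.ndarray = field(repr=False)
    set_sizes: np.ndarray = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.canonical)

    def lookup(self, word: str) -> int:
        """Column index of a k-mer (either member of the pair)."""
        if len(word) != self.k:
            raise FeatureError(
                f"word {word!r} has length {len(word)}, index expects k={self.k}"
            )
        b = _CODE[np.frombuffer(word.upper().encode(), dtype=np.uint8)]
        if (b >= 4).any():
            raise FeatureError(f"word {word!r} contains non-ACGT characters")
        code = 0
        for d in b:
            code = (code << 2) | int(d)
        return int(self.code_to_col[code])


def build_degenerate_index(k: int) -> DegenerateIndex:
    """Enumerate all 4**k k-mers and pool each with its reverse complement.

    Column count is 4**k/2 + (#palindromes)/2: 136 for k=4, 512 for k=5.
    """
    if not isinstance(k, (int, np.integer)) or not 1 <= k <= 8:
        raise FeatureError(f"k must be an integer in [1, 8], got {k!r}")
    k = int(k)
    codes = np.arange(4**k, dtype=np.int64)
    rc = _revcomp_codes(codes, k)
    # A<C<G<T matches 0<1<2<3, so lexicographic order == numeric code order.
    canon_codes = np.minimum(codes, rc)
    cols = np.unique(canon_codes)
    code_to_col = np.searchsorted(cols, canon_codes).astype(np.int32)

    canonical = tuple(_decode(int(c), k) for c in cols)
    rc_of_cols = _revcomp_codes(cols, k)
    members = tuple(
        (w,) if int(r) == int(c) else (w, _decode(int(r), k))
        for w, c, r in zip(canonical, cols, rc_of_cols)
    )
    digits = np.stack([(cols >> (2 * (k - 1 - j))) & 3 for j in range(k)])
    gc_counts = ((digits == 1) | (digits == 2)).sum(axis=0).astype(np.int64)
    set_sizes = np.fromiter((len(m) for m in members), dtype=np.int64)
    code_to_col.setflags(write=False)
    gc_counts.setflags(write=False)
    set_sizes.setflags(write=False)
    return DegenerateIndex(k, canonical, members, code_to_col, gc_counts, set_sizes)


def encode(sequence: str) -> np.ndarray:
    """Sequence -> uint8 codes (A,C,G,T -> 0..3; anything else -> 4)."""
    return _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all length-k windows plus a validity mask (no N)."""
    n = len(codes)
    if n < k:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    m = n - k + 1
    word = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        seg = codes[j : j + m]
        valid = seg < 4
        word = (word << 2) | np.where(valid, seg, 0)
        ok &= valid
    return word, ok


def _counts(sequence: str, index: DegenerateIndex) -> tuple[np.ndarray, int]:
    word, ok = window_codes(encode(sequence), index.k)
    counts = np.bincount(index.code_to_col[word[ok]], minlength=index.n_columns)
    return counts, int(ok.sum())


def count_fragment(fragment: Fragment | str, index: DegenerateIndex) -> np.ndarray:
    """Degenerate k-mer frequency vector of one fragment.

    Counts every N-free length-k window, pools each word with its reverse
    complement, and divides by the number of countable windows so the vector
    sums to one (normalization to the length without Ns).
    """
    seq = fragment.sequence if isinstance(fragment, Fragment) else fragment
    counts, countable = _counts(seq, index)
    if countable == 0:
        ident = (
            f"fragment {fragment.genome_id}:{fragment.start}-{fragment.end}"
            if isinstance(fragment, Fragment)
            else "sequence"
        )
        raise FeatureError(f"{ident} has no countable (N-free) {index.k}-mer windows")
    return counts / countable


@dataclass
class FeatureMatrix:
    """Fragments x degenerate-k-mer frequency matrix.

    Rows follow the input fragment order; ``fragment_keys`` aligns each row
    with its (genome_id, start) provenance.  Normalization convention: counts
    divided by the number of countable N-free windows.
    """

    fragment_keys: list[tuple[str, int]]
    values: np.ndarray
    index: DegenerateIndex

    @property
    def n_fragments(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.index.canonical))
        df.insert(0, "genome_id", [g for g, _ in self.fragment_keys])
        df.insert(1, "start", [s for _, s in self.fragment_keys])
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# degenerate k-mer frequencies; k={self.index.k}; "
                "normalization=countable-N-free-windows; "
                "columns named by canonical (lexicographically smaller) pair member\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                fh.seek(0)
                k = None
            else:
                k = int(header.split("k=")[1].split(";")[0])
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        if k is None:
            k = len(df.columns[2])
        index = build_degenerate_index(k)
        keys = list(zip(df["genome_id"].astype(str), df["start"].astype(int)))
        values = df[list(index.canonical)].to_numpy(dtype=np.float64)
        return cls(keys, values, index)


def vectorize(
    fragments: Sequence[Fragment], index: DegenerateIndex
) -> FeatureMatrix:
    """Assemble per-fragment frequency vectors into a FeatureMatrix (input order)."""
    fragments = list(fragments)
    if not fragments:
        raise FeatureError("cannot vectorize an empty fragment list")
    rows = np.empty((len(fragments), index.n_columns), dtype=np.float64)
    keys: list[tuple[str, int]] = []
    for r, frag in enumerate(fragments):
        rows[r] = count_fragment(frag, index)
        keys.append((frag.genome_id, frag.start))
    return FeatureMatrix(keys, rows, index)


class DegenerateKmerVectorizer(TransformerMixin, BaseEstimator):
    """Transformer turning sequences/fragments into degenerate k-mer frequencies.

    Parameters
    ----------
    k : int, default=4
        Oligonucleotide length (1-8). k=4 gives 136 features, k=5 gives 512.
    """

    def __init__(self, k: int = 4):
        self.k = k

    def fit(self, X: Iterable[Fragment | str] | None = None, y=None):
        self.index_ = build_degenerate_index(self.k)
        self.n_features_out_ = self.index_.n_columns
        return self

    def transform(self, X: Iterable[Fragment | str]) -> np.ndarray:
        if not hasattr(self, "index_"):
            self.fit()
        items = list(X)
        if not items:
            raise FeatureError("cannot transform an empty collection")
        out = np.empty((len(items), self.index_.n_columns), dtype=np.float64)
        for r, item in enumerate(items):
            out[r] = count_fragment(item, self.index_)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "index_"):
            self.fit()
        return np.asarray(self.index_.canonical, dtype=object)


def mononucleotide_profile(
    freq_vector: np.ndarray, index: DegenerateIndex, *, tol: float = 1e-6
) -> np.ndarray:
    """Strand-symmetric base frequencies (pA, pC, pG, pT) implied by a vector.

    Degenerate pooling destroys strand information, so the only self-consistent
    mononucleotide model is strand-symmetric: p_A = p_T and p_C = p_G.  The G+C
    fraction is the GC-count-weighted mean of the set frequencies (GC count is
    identical for both members of a complementary pair).
    """
    freq_vector = np.asarray(freq_vector, dtype=np.float64)
    total = float(freq_vector.sum())
    if abs(total - 1.0) > tol:
        raise FeatureError(f"frequency vector sums to {total:.6g}, expected 1")
    p_gc = float(freq_vector @ index.gc_counts) / index.k
    p_gc = min(max(p_gc, 0.0), 1.0)
    p_at = 1.0 - p_gc
    return np.array([p_at / 2, p_gc / 2, p_gc / 2, p_at / 2])


def expected_frequencies(
    freq_vector: np.ndarray, index: DegenerateIndex
) -> np.ndarray:
    """Per-column frequencies expected from the vector's mononucleotide profile.

    For a set with GC count g and multiplicity m (1 for palindromes, 2
    otherwise) the expectation is m * ((1-pGC)/2)**(k-g) * (pGC/2)**g; both
    members of a pair contribute equal products under strand symmetry.
    """
    profile = mononucleotide_profile(freq_vector, index)
    p_gc = 2 * profile[1]
    g = index.gc_counts
    return (
        index.set_sizes
        * ((1.0 - p_gc) / 2) ** (index.k - g)
        * (p_gc / 2) ** g
    )


def observed_expected_ratios(
    freq_vector: np.ndarray, index: DegenerateIndex, *, tol: float = 1e-12
) -> np.ndarray:
    """Observed/expected ratio for every column, 0/0-guarded to 1."""
    freq_vector = np.asarray(freq_vector, dtype=np.float64)
    expected = expected_frequencies(freq_vector, index)
    both_zero = (expected < tol) & (freq_vector < tol)
    impossible = (expected < tol) & (freq_vector >= tol)
    if impossible.any():
        col = int(np.flatnonzero(impossible)[0])
        raise FeatureError(
            f"column {index.canonical[col]} observed {freq_vector[col]:.3g} but "
            "expected 0 under the mononucleotide model"
        )
    safe = np.where(expected < tol, 1.0, expected)
    ratios = freq_vector / safe
    ratios[both_zero] = 1.0
    return ratios


def observed_expected_ratio(
    freq_vector: np.ndarray, index: DegenerateIndex, column: int
) -> float:
    """Observed/expected ratio of one degenerate set (>1 over-, <1 underrepresented)."""
    if not 0 <= column < index.n_columns:
        raise FeatureError(f"column {column} out of range [0, {index.n_columns})")
    return float(observed_expected_ratios(freq_vector, index)[column])
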