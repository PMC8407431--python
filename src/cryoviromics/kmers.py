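"""Reference-free sample comparison from canonical tetranucleotide profiles.

Every 4-mer is pooled with its reverse complement into a canonical class
(the lexicographically smaller of the pair), collapsing strand orientation:
16 palindromic classes plus 120 complementary pairs = 136 classes. Profiles
are compared by Bray-Curtis dissimilarity and ordinated by principal
coordinates (classical MDS on the double-centered distance matrix).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "KmerProfile",
    "canonical_kmers",
    "reverse_complement",
    "tetranucleotide_profile",
    "profiles_to_frame",
    "profile_distance_matrix",
    "pca_ordination",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


def _kmer_of_code(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _build_canonical_map(k: int) -> tuple[list[str], np.ndarray]:
    """All canonical k-mer classes (sorted) and a code -> class-index table."""
    n = 4 ** k
    canon_of_code = []
    for code in range(n):
        kmer = _kmer_of_code(code, k)
        canon_of_code.append(min(kmer, reverse_complement(kmer)))
    classes = sorted(set(canon_of_code))
    index = {c: i for i, c in enumerate(classes)}
    table = np.array([index[c] for c in canon_of_code], dtype=np.int64)
    return classes, table


_CANONICAL_CACHE: dict[int, tuple[list[str], np.ndarray]] = {}


def canonical_kmers(k: int = 4) -> list[str]:
    """Sorted canonical k-mer classes (136 classes for k=4)."""
    if k not in _CANONICAL_CACHE:
        _CANONICAL_CACHE[k] = _build_canonical_map(k)
    return _CANONICAL_CACHE[k][0]


_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


@dataclass(frozen=True)
class KmerProfile:
    """Normalized canonical k-mer frequency vector for one sample."""

    sample_id: str
    freqs: np.ndarray
    total_kmers: int
    k: int = 4


def tetranucleotide_profile(
    sequences: Iterable[str],
    sample_id: str = "",
    k: int = 4,
    canonical: bool = True,
) -> KmerProfile:
    """Count sliding k-mer windows (step 1) over a set of sequences.

    Windows containing anything outside ACGT (case-insensitive) contribute
    nothing — the window simply restarts past the offending character. With
    ``canonical=True`` (default) each k-mer is pooled with its reverse
    complement; otherwise all 4**k orientations are kept separate.
    """
    classes, table = _CANONICAL_CACHE.setdefault(k, _build_canonical_map(k))
    n_raw = 4 ** k
    counts = np.zeros(n_raw, dtype=np.int64)
    for seq in sequences:
        codes = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if codes.size < k:
            continue
        valid = codes >= 0
        window_codes = np.zeros(codes.size - k + 1, dtype=np.int64)
        window_valid = np.ones(codes.size - k + 1, dtype=bool)
        for offset in range(k):
            sl = slice(offset, codes.size - k + 1 + offset)
            window_codes = window_codes * 4 + np.where(valid[sl], codes[sl], 0)
            window_valid &= valid[sl]
        if window_valid.any():
            counts += np.bincount(window_codes[window_valid], minlength=n_raw)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no valid k-mer window in input sequences")
    if canonical:
        pooled = np.bincount(table, weights=counts, minlength=len(classes))
        freqs = pooled / total
    else:
        freqs = counts / total
    return KmerProfile(sample_id=sample_id, freqs=freqs, total_kmers=total, k=k)


def profiles_to_frame(profiles: Sequence[KmerProfile]) -> pd.DataFrame:
    """Samples x classes frequency table."""
    if not profiles:
        raise ValueError("no profiles")
    k = profiles[0].k
    canonical = len(profiles[0].freqs) != 4 ** k
    cols = canonical_kmers(k) if canonical else [_kmer_of_code(c, k) for c in range(4 ** k)]
    return pd.DataFrame(
        np.vstack([p.freqs for p in profiles]),
        index=[p.sample_id for p in profiles],
        columns=cols,
    )


def profile_distance_matrix(profiles: Sequence[KmerProfile] | pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample k-mer frequency vectors."""
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    condensed = pdist(frame.to_numpy(dtype=float), metric="braycurtis")
    return pd.DataFrame(squareform(condensed), index=frame.index, columns=frame.index)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude loading of each
    component is made positive."""
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def pca_ordination(
    profiles: Sequence[KmerProfile] | pd.DataFrame,
    n_components: int = 2,
    method: str = "pcoa",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Ordination of sample profiles.

    ``method="pcoa"`` (default): principal coordinates of the Bray-Curtis
    distance matrix — Gower double centering of -D^2/2 followed by
    eigendecomposition; components ordered by eigenvalue, explained-variance
    fractions taken over the positive eigenvalues. ``method="pca"``:
    ordinary PCA of the centered frequency matrix via SVD.

    Returns (coordinates DataFrame with columns PC1.., explained-variance
    fractions).
    """
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    n = frame.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for ordination")
    if n_components > n:
        raise ValueError("fewer samples than requested components")
    if method == "pcoa":
        d = profile_distance_matrix(frame).to_numpy()
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        eigvals, eigvecs = np.linalg.eigh(b)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        positive = eigvals > 1e-12 * max(eigvals.max(), 1.0)
        explained = np.where(positive, eigvals, 0.0) / eigvals[positive].sum()
        coords = eigvecs[:, :n_components] * np.sqrt(np.clip(eigvals[:n_components], 0.0, None))
        explained = explained[:n_components]
    elif method == "pca":
        x = frame.to_numpy(dtype=float)
        centered = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        var = s ** 2
        explained = (var / var.sum())[:n_components]
        coords = (u * s)[:, :n_components]
    else:
        raise ValueError(f"unknown ordination method {method!r}")
    coords = _fix_signs(coords)
    out = pd.DataFrame(
        coords,
        index=frame.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return out, explained
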