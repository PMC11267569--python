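"""Chaos-game representation (CGR) of DNA and its frequency rasterization (FCGR).

The chaos game maps a DNA sequence onto the unit square ``[-1, 1]^2`` by an
iterated midpoint rule: each nucleotide pulls the current point halfway toward
its assigned corner.  All points whose generating subsequence ends with the
same length-``k`` suffix land in the same dyadic sub-square, so counting points
on a ``2^k x 2^k`` grid recovers k-mer frequencies.  The resulting integer
count image (the FCGR) is the input representation for the classifier.

Corner convention: A upper-left ``(-1, +1)``, C lower-left ``(-1, -1)``,
G lower-right ``(+1, -1)``, T upper-right ``(+1, +1)``.  Images are row-major
with row 0 at the top (the ``y = +1`` edge), so a rendered array looks like
the conventional CGR plot.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CORNERS",
    "SequenceRecord",
    "FCGRImage",
    "InvalidAlphabetError",
    "normalize_residues",
    "nucleotide_corner",
    "cgr_encode",
    "fcgr_rasterize",
    "encode_sequence",
    "kmer_counts",
    "kmer_suffix_cell",
    "gc_content",
    "FCGREncoder",
]

#: Fixed corner assignment of the four nucleotides on [-1, 1]^2.
CORNERS: dict[str, tuple[float, float]] = {
    "A": (-1.0, 1.0),
    "C": (-1.0, -1.0),
    "G": (1.0, -1.0),
    "T": (1.0, 1.0),
}

_CANONICAL = frozenset("ACGT")


class InvalidAlphabetError(ValueError):
    """A residue outside {A, C, G, T} was found under the strict policy."""

    def __init__(self, char: str, position: int | None = None, record_id: str | None = None):
        self.char = char
        self.position = position
        self.record_id = record_id
        where = f" at position {position}" if position is not None else ""
        who = f" in record '{record_id}'" if record_id else ""
        super().__init__(f"invalid nucleotide {char!r}{where}{who}; expected A/C/G/T")


def normalize_residues(raw: str, policy: str = "strict", record_id: str | None = None) -> str:
    """Case-fold, map U->T, and apply the non-ACGT policy.

    ``policy='strict'`` raises :class:`InvalidAlphabetError` naming the first
    offending character and its (0-based) position; ``policy='skip'`` silently
    drops non-canonical characters.
    """
    if policy not in ("strict", "skip"):
        raise ValueError(f"unknown non-ACGT policy {policy!r}; use 'strict' or 'skip'")
    s = raw.upper().replace("U", "T")
    if all(c in _CANONICAL for c in s):
        return s
    if policy == "strict":
        for i, c in enumerate(s):
            if c not in _CANONICAL:
                raise InvalidAlphabetError(c, i, record_id)
    return "".join(c for c in s if c in _CANONICAL)


@dataclass
class SequenceRecord:
    """One labeled DNA sequence: the raw input unit of the whole pipeline."""

    id: str
    residues: str
    label: str | None = None

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class FCGRImage:
    """An ``N x N`` grid of CGR point counts for one sequence.

    ``counts`` is integer and row-major with row 0 at the top; ``normalization``
    records how :meth:`as_array` scales it (``raw``, ``per_total``, ``per_max``).
    The stored counts are always raw so the image stays lossless.
    """

    resolution: int
    counts: np.ndarray
    total_points: int
    normalization: str = "raw"
    record_id: str | None = None

    def __post_init__(self):
        if self.normalization not in ("raw", "per_total", "per_max"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.counts.shape != (self.resolution, self.resolution):
            raise ValueError("counts shape does not match resolution")

    def as_array(self) -> np.ndarray:
        """Return the image as float64 under its normalization."""
        c = self.counts.astype(np.float64)
        if self.normalization == "per_total":
            return c / self.total_points if self.total_points else c
        if self.normalization == "per_max":
            m = c.max()
            return c / m if m > 0 else c
        return c


def nucleotide_corner(symbol: str) -> tuple[float, float]:
    """Corner of the CGR square assigned to one canonical nucleotide."""
    try:
        return CORNERS[symbol]
    except KeyError:
        raise InvalidAlphabetError(symbol) from None


def cgr_encode(residues: str, policy: str = "strict") -> np.ndarray:
    """CGR trajectory of a sequence: an ``(n, 2)`` array of (x, y) points.

    Point ``i`` is the midpoint of point ``i-1`` (start ``(0, 0)``) and the
    corner of residue ``i``.  An empty sequence yields an empty trajectory.
    Every point of a sequence started at the origin lies strictly inside the
    open square.
    """
    s = normalize_residues(residues, policy)
    pts = np.empty((len(s), 2), dtype=np.float64)
    x, y = 0.0, 0.0
    for i, ch in enumerate(s):
        cx, cy = CORNERS[ch]
        x = (x + cx) / 2.0
        y = (y + cy) / 2.0
        pts[i, 0] = x
        pts[i, 1] = y
    return pts


def fcgr_rasterize(traj: np.ndarray, resolution: int, normalization: str = "raw",
                   record_id: str | None = None) -> FCGRImage:
    """Bin a CGR trajectory onto an ``N x N`` grid of point counts.

    Cells are half-open: ``col = floor((x+1)/2 * N)``, ``row = floor((1-y)/2 * N)``,
    both clamped into ``[0, N-1]`` so the top/right boundaries map to the last
    cell.  The raw counts always sum to the number of trajectory points.
    """
    if resolution < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    traj = np.asarray(traj, dtype=np.float64).reshape(-1, 2)
    n = traj.shape[0]
    counts = np.zeros((resolution, resolution), dtype=np.int64)
    if n:
        col = np.floor((traj[:, 0] + 1.0) / 2.0 * resolution).astype(np.int64)
        row = np.floor((1.0 - traj[:, 1]) / 2.0 * resolution).astype(np.int64)
        np.clip(col, 0, resolution - 1, out=col)
        np.clip(row, 0, resolution - 1, out=row)
        np.add.at(counts, (row, col), 1)
    return FCGRImage(resolution, counts, n, normalization, record_id)


def encode_sequence(residues: str, resolution: int = 64, normalization: str = "raw",
                    policy: str = "strict", record_id: str | None = None) -> FCGRImage:
    """Sequence -> trajectory -> FCGR image in one call."""
    return fcgr_rasterize(cgr_encode(residues, policy), resolution, normalization, record_id)


def kmer_counts(residues: str, k: int) -> dict[str, int]:
    """Exact sliding-window k-mer counts; empty mapping when ``k > len``.

    This is the brute-force oracle for the FCGR/k-mer equivalence: at
    ``N = 2^k`` every grid cell counts trajectory points whose suffix is one
    particular k-mer.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(residues):
        return {}
    return dict(Counter(residues[i:i + k] for i in range(len(residues) - k + 1)))


# Bit values of each nucleotide along x (toward +1) and y (toward +1).
_XBIT = {"A": 0, "C": 0, "G": 1, "T": 1}
_YBIT = {"A": 1, "C": 0, "G": 0, "T": 1}


def kmer_suffix_cell(kmer: str, resolution: int) -> tuple[int, int]:
    """Closed-form (row, col) cell holding every CGR point whose length-k
    suffix is ``kmer``, on the ``N = 2^k`` grid.

    The last character of the suffix selects the quadrant (most significant
    bit); earlier characters refine recursively.
    """
    k = len(kmer)
    if k < 1 or resolution != 2 ** k:
        raise ValueError(f"resolution must equal 2^len(kmer) = {2 ** k}, got {resolution}")
    col = 0
    ybits = 0
    for t, ch in enumerate(reversed(kmer)):  # last char first = most significant
        if ch not in _CANONICAL:
            raise InvalidAlphabetError(ch, k - 1 - t)
        col += _XBIT[ch] << (k - 1 - t)
        ybits += _YBIT[ch] << (k - 1 - t)
    return resolution - 1 - ybits, col


def gc_content(residues: str) -> float:
    """Fraction of G+C residues; errors on an empty sequence."""
    if not residues:
        raise ValueError("gc_content is undefined for an empty sequence")
    return (residues.count("G") + residues.count("C")) / len(residues)


class FCGREncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: DNA sequences -> stacked FCGR count images.

    Parameters
    ----------
    resolution : int, default 64
        Grid size N; 64 corresponds to 6-mer resolution.
    policy : {'strict', 'skip'}
        Handling of non-ACGT characters (after case-folding and U->T).
    normalization : {'raw', 'per_total', 'per_max'}
        Scaling applied in the output array.  The classifier applies its own
        input scaling, so the default here is raw counts.
    """

    def __init__(self, resolution: int = 64, policy: str = "strict", normalization: str = "raw"):
        self.resolution = resolution
        self.policy = policy
        self.normalization = normalization

    def fit(self, X=None, y=None):
        if self.resolution < 1:
            raise ValueError(f"resolution must be >= 1, got {self.resolution}")
        return self

    def transform(self, X) -> np.ndarray:
        """Encode an iterable of sequences (str or SequenceRecord) into an
        ``(n_samples, N, N)`` float array."""
        self.fit()
        imgs = []
        for item in X:
            if isinstance(item, SequenceRecord):
                seq, rid = item.residues, item.id
            else:
                seq, rid = str(item), None
            img = encode_sequence(seq, self.resolution, self.normalization, self.policy, rid)
            imgs.append(img.as_array())
        if not imgs:
            return np.empty((0, self.resolution, self.resolution))
        return np.stack(imgs)
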