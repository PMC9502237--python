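"""Plain bitvector with rank/select support.

This is the succinct backbone of the coordinate-lift map: a bit sequence
packed into little-endian 64-bit words plus a per-word cumulative popcount
directory, giving O(1) ``rank1`` and near-O(1) ``select1`` after a single
linear build pass.

Conventions (fixed across the package):

* ``rank1(i)`` counts set bits in the half-open prefix ``[0, i)``,
  defined for ``0 <= i <= len(bv)``.
* ``select1(k)`` is 1-based in ``k`` and returns the 0-based position of
  the k-th set bit, defined for ``1 <= k <= rank1(len(bv))``.

These match the conventions of the SDSL family of succinct libraries, so
``rank1(select1(k)) == k - 1`` for every valid ``k``.
"""

from __future__ import annotations

from typing import Iterable, Union

import numpy as np

__all__ = ["BitVec"]

_WORD = 64


class BitVec:
    """Immutable bit sequence with rank/select queries.

    Parameters
    ----------
    bits
        Anything convertible to a 1-D boolean numpy array (list of 0/1,
        bool array, string of '0'/'1' is *not* accepted — convert first).
    """

    __slots__ = ("_length", "_words", "_cum")

    def __init__(self, bits: Union[np.ndarray, Iterable[int]]):
        arr = np.asarray(bits)
        if arr.dtype == object or arr.ndim != 1:
            arr = np.fromiter((int(b) for b in bits), dtype=np.uint8)
        arr = arr.astype(bool, copy=False)
        self._length = int(arr.size)
        packed = np.packbits(arr.view(np.uint8), bitorder="little")
        n_words = (self._length + _WORD - 1) // _WORD
        buf = np.zeros(n_words * 8, dtype=np.uint8)
        buf[: packed.size] = packed
        self._words = buf.view("<u8")
        self._build_rank_directory()

    def _build_rank_directory(self) -> None:
        counts = np.bitwise_count(self._words).astype(np.int64)
        self._cum = np.zeros(self._words.size + 1, dtype=np.int64)
        np.cumsum(counts, out=self._cum[1:])

    @classmethod
    def _from_words(cls, words: np.ndarray, length: int) -> "BitVec":
        """Rebuild from packed little-endian 64-bit words (deserialization)."""
        bv = cls.__new__(cls)
        bv._length = int(length)
        bv._words = np.ascontiguousarray(words, dtype="<u8")
        n_words = (bv._length + _WORD - 1) // _WORD
        if bv._words.size != n_words:
            raise ValueError(
                f"word count {bv._words.size} inconsistent with length {length}"
            )
        # Mask stray bits beyond `length` so popcounts are trustworthy.
        rem = bv._length % _WORD
        if rem and n_words:
            w = bv._words.copy()
            w[-1] &= np.uint64((1 << rem) - 1)
            bv._words = w
        bv._build_rank_directory()
        return bv

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return self._length

    def __getitem__(self, i: int) -> int:
        if not 0 <= i < self._length:
            raise IndexError(f"bit index {i} out of range [0, {self._length})")
        return int((self._words[i >> 6] >> np.uint64(i & 63)) & np.uint64(1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BitVec):
            return NotImplemented
        return self._length == other._length and bool(
            np.array_equal(self._words, other._words)
        )

    def __hash__(self):  # pragma: no cover - not used as dict key
        return hash((self._length, self._words.tobytes()))

    def __repr__(self) -> str:
        if self._length <= 64:
            s = "".join(str(self[i]) for i in range(self._length))
            return f"BitVec({s!r})"
        return f"BitVec(length={self._length}, popcount={self.popcount})"

    # -- queries ------------------------------------------------------------------

    @property
    def popcount(self) -> int:
        """Total number of set bits."""
        return int(self._cum[-1])

    def rank1(self, i: int) -> int:
        """Number of set bits in positions ``[0, i)``; ``0 <= i <= len``."""
        if not 0 <= i <= self._length:
            raise IndexError(f"rank index {i} out of range [0, {self._length}]")
        w, rem = i >> 6, i & 63
        r = int(self._cum[w])
        if rem:
            r += int(self._words[w] & np.uint64((1 << rem) - 1)).bit_count()
        return r

    def rank0(self, i: int) -> int:
        """Number of clear bits in positions ``[0, i)``."""
        return i - self.rank1(i)

    def select1(self, k: int) -> int:
        """0-based position of the k-th set bit; ``1 <= k <= popcount``."""
        if not 1 <= k <= self.popcount:
            raise IndexError(f"select ordinal {k} out of range [1, {self.popcount}]")
        w = int(np.searchsorted(self._cum, k, side="left")) - 1
        word = int(self._words[w])
        r = k - int(self._cum[w])  # rank of the wanted bit inside this word
        for _ in range(r - 1):
            word &= word - 1  # clear lowest set bit
        return (w << 6) + ((word & -word).bit_length() - 1)

    def select_consecutive(self, k: int, n: int) -> np.ndarray:
        """Positions of the k-th through (k+n-1)-th set bits as an int array.

        Equivalent to ``[select1(k+j) for j in range(n)]`` but walks the
        packed words once, which matters when classifying every reference
        base under a long CIGAR.
        """
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        if k < 1 or k + n - 1 > self.popcount:
            raise IndexError("select range out of bounds")
        w0 = int(np.searchsorted(self._cum, k, side="left")) - 1
        out = np.empty(n, dtype=np.int64)
        filled = 0
        skip = k - 1 - int(self._cum[w0])  # set bits to discard in the first word
        w = w0
        n_words = self._words.size
        while filled < n and w < n_words:
            word = int(self._words[w])
            if skip:
                for _ in range(skip):
                    word &= word - 1
                skip = 0
            base = w << 6
            while word and filled < n:
                out[filled] = base + ((word & -word).bit_length() - 1)
                filled += 1
                word &= word - 1
            w += 1
        return out

    def get_bits(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized bit lookup at an array of positions (bool array)."""
        pos = np.asarray(positions, dtype=np.int64)
        words = self._words[pos >> 6]
        return ((words >> (pos & 63).astype(np.uint64)) & np.uint64(1)).astype(bool)

    def to_bool_array(self) -> np.ndarray:
        """Unpack to a dense boolean array (used for bulk scans/export)."""
        bits = np.unpackbits(
            self._words.view(np.uint8), bitorder="little", count=self._length
        )
        return bits.view(bool)

    def ones_positions(self) -> np.ndarray:
        """Sorted positions of all set bits."""
        return np.flatnonzero(self.to_bool_array())

    # -- serialization helpers ----------------------------------------------------

    @property
    def words(self) -> np.ndarray:
        """The packed little-endian 64-bit words (read-only view)."""
        v = self._words.view()
        v.flags.writeable = False
        return v
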