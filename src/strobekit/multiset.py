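"""Ordered multiset with logarithmic search, used by the sliding-window
modulo-link (MAMD) constructor.

Keys are ``(value, position)`` pairs kept in sorted order in a flat
array. Every search — membership for insert/delete, successor,
predecessor, min, max — is a binary search whose comparisons are
counted, so the per-seed work of the sliding-window constructor can be
measured and compared against the ``Theta(W)`` linear scan. Physical
element moves inside the backing array are O(W) memmoves but perform
no key comparisons; a self-balancing tree would make them logarithmic
too without changing any result or any comparison count reported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["OpCounter", "OrderedMultiset"]


@dataclass
class OpCounter:
    """Tally of ordered-multiset work.

    ``ops`` counts multiset operations (insert / delete / query);
    ``comparisons`` counts key comparisons inside binary searches.
    """

    ops: int = 0
    comparisons: int = 0

    def reset(self) -> None:
        self.ops = 0
        self.comparisons = 0


@dataclass
class OrderedMultiset:
    """Sorted multiset of orderable keys with counted binary search."""

    counter: OpCounter = field(default_factory=OpCounter)
    _keys: list = field(default_factory=list, repr=False)

    def __len__(self) -> int:
        return len(self._keys)

    def _bisect_left(self, key) -> int:
        lo, hi = 0, len(self._keys)
        while lo < hi:
            mid = (lo + hi) // 2
            self.counter.comparisons += 1
            if self._keys[mid] < key:
                lo = mid + 1
            else:
                hi = mid
        return lo

    def add(self, key) -> None:
        self.counter.ops += 1
        self._keys.insert(self._bisect_left(key), key)

    def remove(self, key) -> None:
        """Remove one occurrence of ``key``; KeyError if absent."""
        self.counter.ops += 1
        i = self._bisect_left(key)
        if i == len(self._keys) or self._keys[i] != key:
            raise KeyError(key)
        del self._keys[i]

    def min(self):
        self.counter.ops += 1
        if not self._keys:
            raise KeyError("empty multiset")
        return self._keys[0]

    def max(self):
        self.counter.ops += 1
        if not self._keys:
            raise KeyError("empty multiset")
        return self._keys[-1]

    def successor(self, key):
        """Smallest element >= key, or None."""
        self.counter.ops += 1
        i = self._bisect_left(key)
        return self._keys[i] if i < len(self._keys) else None

    def predecessor(self, key):
        """Largest element < key, or None."""
        self.counter.ops += 1
        i = self._bisect_left(key)
        return self._keys[i - 1] if i > 0 else None
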