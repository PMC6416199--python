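"""Word symmetry distances WSD1 and WSD2.

The distance of a k-mer spectrum from perfect strand symmetry is measured by
rearranging the frequency-sorted arrangement of all 4**k words (A1) into the
pair-adjacent arrangement (A2, complementary pairs made adjacent, pairs
ordered by their larger frequency). Rearrangement proceeds pair by pair in
A2 order: whenever the two members of a complementary pair are not adjacent
in the current arrangement, the later member is removed and reinserted
immediately after the earlier one. WSD1 counts the moves (an Ulam-style
permutation distance); WSD2 sums the *step* of each move — the number of
words strictly between the pair members immediately before the move — so
that widely separated pairs, i.e. strongly asymmetric frequencies, weigh
more. Both are normalized by closed-form maxima (nWSD1, nWSD2).

Tie-breaking in A1 must be consistent with A2 for the rearrangement to
terminate exactly at A2. The full sort key is: descending count(w), then
descending count(revcomp(w)), then ascending canonical pair key
(lexicographic min of {w, revcomp(w)}), then the pair leader before its
follower. Exactly tied complementary pairs therefore land adjacent and
contribute zero distance — "same frequency" is perfect symmetry for that
pair.

The production step computation tracks surviving A1 positions and riders
attached to their anchors with Fenwick trees, giving O((n + moves) log n);
``greedy_transform_naive`` is a literal list simulation kept as an
independent oracle for testing.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .kmer_core import KmerTable, code_to_word, rc_code_table, word_to_code

__all__ = [
    "Arrangement",
    "Move",
    "WsdProfile",
    "build_a1",
    "build_a2",
    "greedy_transform",
    "greedy_transform_naive",
    "max_ulam",
    "max_wsd2",
    "compute_wsd",
    "ulam_lower_bound",
]


@dataclass
class Arrangement:
    """An ordered permutation of all 4**k words, stored as base-4 codes."""

    k: int
    codes: np.ndarray
    source: str = "custom"  # A1 | A2 | custom

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        n = 4**self.k
        if self.codes.shape != (n,):
            raise ValueError(f"arrangement must hold exactly {n} words")
        if not np.array_equal(np.sort(self.codes), np.arange(n)):
            raise ValueError("arrangement must contain every word exactly once")

    @classmethod
    def from_words(cls, words: list[str], source: str = "custom") -> "Arrangement":
        k = len(words[0])
        codes = np.array([word_to_code(w) for w in words], dtype=np.int64)
        return cls(k=k, codes=codes, source=source)

    def words(self) -> list[str]:
        return [code_to_word(int(c), self.k) for c in self.codes]

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class Move:
    """One relocation: ``mover`` reinserted immediately after ``anchor``."""

    mover: str
    anchor: str
    step: int  # words strictly between the pair just before the move; >= 1
    move_index: int


@dataclass
class WsdProfile:
    """Per-order word symmetry distances with normalizers and move log."""

    k: int
    wsd1: int
    wsd2: int
    max_ulam: int | None = None
    max_wsd2: int | None = None
    nwsd1: float | None = None
    nwsd2: float | None = None
    moves: list[Move] = field(default_factory=list)


def max_ulam(k: int) -> int:
    """Maximum possible number of moves (maximum Ulam distance) at order k.

    (4**k - 2)/2 for odd k — every pair but the last left in place must
    move; (4**k - 4**(k/2))/2 for even k — every pair moves, and the
    4**(k/2) self-complementary words never do.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = 4**k
    if k % 2:
        return (n - 2) // 2
    return (n - 4 ** (k // 2)) // 2


def max_wsd2(k: int) -> int:
    """Maximum possible WSD2 at order k (closed form).

    4**k (4**k - 2)/4 for odd k; (4**k + 4**(k/2) - 2)(4**k - 4**(k/2))/4
    for even k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = 4**k
    if k % 2:
        return n * (n - 2) // 4
    h = 4 ** (k // 2)
    return (n + h - 2) * (n - h) // 4


def build_a1(table: KmerTable) -> Arrangement:
    """Arrangement A1: all 4**k words sorted from highest to lowest count.

    Words with equal counts are ordered by the counts of their reverse
    complements; residual ties fall back to the canonical pair rule (see
    module docstring). Zero-count words are included — "all possible
    k-mers" — and cluster pair-adjacent at the tail.
    """
    k = table.k
    n = 4**k
    counts = table.dense()
    rc = rc_code_table(k)
    rc_counts = counts[rc]
    pair_key = np.minimum(np.arange(n, dtype=np.int64), rc)
    # lexsort: last key is primary
    order = np.lexsort((np.arange(n), pair_key, -rc_counts, -counts))
    return Arrangement(k=k, codes=order.astype(np.int64), source="A1")


def build_a2(a1: Arrangement, table: KmerTable | None = None) -> Arrangement:
    """Arrangement A2: complementary pairs made adjacent.

    Units (pairs, plus self-complementary singletons) are ordered by the A1
    position of each unit's earliest member — equivalent to ordering pairs
    by their larger frequency under the A1 tie rules; within a pair the
    member earlier in A1 precedes its partner. ``table`` is accepted for
    interface symmetry and only checked for a matching order.
    """
    if table is not None and table.k != a1.k:
        raise ValueError("table order does not match arrangement order")
    k = a1.k
    n = 4**k
    rc = rc_code_table(k)
    pos = np.empty(n, dtype=np.int64)
    pos[a1.codes] = np.arange(n)
    is_leader = pos <= pos[rc]  # self-complementary words lead themselves
    leaders = np.nonzero(is_leader)[0]
    leaders = leaders[np.argsort(pos[leaders], kind="stable")]
    out = np.empty(n, dtype=np.int64)
    i = 0
    for c in leaders:
        out[i] = c
        i += 1
        partner = rc[c]
        if partner != c:
            out[i] = partner
            i += 1
    return Arrangement(k=k, codes=out, source="A2")


class _Fenwick:
    """Binary indexed tree over fixed slots, for prefix sums under updates."""

    __slots__ = ("n", "tree")

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)

    @classmethod
    def ones(cls, n: int) -> "_Fenwick":
        # O(n) build of the all-ones tree by parent accumulation
        fw = cls(n)
        tree = fw.tree
        for i in range(1, n + 1):
            tree[i] += 1
            j = i + (i & -i)
            if j <= n:
                tree[j] += tree[i]
        return fw

    def add(self, i: int, delta: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += delta
            i += i & -i

    def prefix(self, i: int) -> int:
        # sum of slots [0, i]
        i += 1
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & -i
        return s

    def range(self, lo: int, hi: int) -> int:
        if lo > hi:
            return 0
        return self.prefix(hi) - (self.prefix(lo - 1) if lo > 0 else 0)


class RearrangementError(RuntimeError):
    """The move procedure failed to terminate at A2 (inconsistent tie rules)."""


def greedy_transform(
    a1: Arrangement, a2: Arrangement, keep_moves: bool = True
) -> WsdProfile:
    """Run the pair-by-pair move procedure from A1 to A2.

    Pairs are processed in A2 order; the member later in the current
    arrangement is reinserted immediately after the earlier one, recording
    as step the number of words strictly between them just before the move.
    Already-adjacent pairs generate no move. The final arrangement is
    reconstructed and asserted equal to A2.

    Relies on two facts provable from the procedure: anchors (earlier pair
    members) never move, and a moved word rides immediately after its anchor
    forever after. The words strictly between an anchor at A1 position pa
    and its unmoved partner at A1 position pm are therefore the unmoved
    words with A1 position in (pa, pm) plus the riders whose anchors sit in
    that window.
    """
    if a1.k != a2.k:
        raise ValueError("arrangements must share the same order")
    k = a1.k
    n = 4**k
    rc = rc_code_table(k)
    pos = np.empty(n, dtype=np.int64)
    pos[a1.codes] = np.arange(n)
    unmoved = _Fenwick.ones(n)
    anchored = _Fenwick(n)
    moves: list[Move] = []
    wsd1 = 0
    wsd2 = 0
    moved = np.zeros(n, dtype=bool)
    rider_at: dict[int, int] = {}  # anchor A1 position -> mover code
    a2_codes = a2.codes
    i = 0
    while i < n:
        c = int(a2_codes[i])
        partner = int(rc[c])
        if partner == c:
            i += 1
            continue
        i += 2
        pa, pm = int(pos[c]), int(pos[partner])
        mover, anchor = (partner, c) if pa < pm else (c, partner)
        if pa > pm:
            pa, pm = pm, pa
        step = unmoved.range(pa + 1, pm - 1) + anchored.range(pa + 1, pm - 1)
        if step == 0:
            continue
        wsd1 += 1
        wsd2 += step
        unmoved.add(pm, -1)
        anchored.add(pa, +1)
        moved[mover] = True
        rider_at[pa] = mover
        if keep_moves:
            moves.append(
                Move(
                    mover=code_to_word(mover, k),
                    anchor=code_to_word(anchor, k),
                    step=step,
                    move_index=wsd1 - 1,
                )
            )
    # reconstruct the final arrangement and check it is exactly A2
    final = np.empty(n, dtype=np.int64)
    j = 0
    for idx in range(n):
        c = int(a1.codes[idx])
        if moved[c]:
            continue
        final[j] = c
        j += 1
        if idx in rider_at:
            final[j] = rider_at[idx]
            j += 1
    if not np.array_equal(final, a2_codes):
        raise RearrangementError(
            "move procedure did not terminate at A2; A1/A2 tie rules inconsistent"
        )
    return WsdProfile(k=k, wsd1=wsd1, wsd2=wsd2, moves=moves)


def greedy_transform_naive(a1: Arrangement, a2: Arrangement) -> WsdProfile:
    """Literal explicit-list simulation of the move procedure.

    Quadratic; retained purely as an independent oracle for the Fenwick
    implementation on small orders.
    """
    if a1.k != a2.k:
        raise ValueError("arrangements must share the same order")
    k = a1.k
    rc = rc_code_table(k)
    cur = [int(c) for c in a1.codes]
    moves: list[Move] = []
    a2_codes = [int(c) for c in a2.codes]
    i = 0
    while i < len(a2_codes):
        c = a2_codes[i]
        partner = int(rc[c])
        if partner == c:
            i += 1
            continue
        i += 2
        ia, ib = cur.index(c), cur.index(partner)
        if ia > ib:
            ia, ib = ib, ia
        step = ib - ia - 1
        if step == 0:
            continue
        mover = cur.pop(ib)
        cur.insert(ia + 1, mover)
        moves.append(
            Move(
                mover=code_to_word(mover, k),
                anchor=code_to_word(cur[ia], k),
                step=step,
                move_index=len(moves),
            )
        )
    if cur != a2_codes:
        raise RearrangementError("naive simulation did not terminate at A2")
    return WsdProfile(
        k=k, wsd1=len(moves), wsd2=sum(m.step for m in moves), moves=moves
    )


def ulam_lower_bound(a1: Arrangement, a2: Arrangement) -> int:
    """n - LCS(A1, A2): the minimum number of single-word remove-and-reinsert
    moves needed to transform A1 into A2. Computed via longest increasing
    subsequence in O(n log n); exposed for audit of the greedy move count.
    """
    n = len(a1.codes)
    pos2 = np.empty(n, dtype=np.int64)
    pos2[a2.codes] = np.arange(n)
    seq = pos2[a1.codes]
    tails: list[int] = []
    for x in seq:
        j = bisect_left(tails, x)
        if j == len(tails):
            tails.append(int(x))
        else:
            tails[j] = int(x)
    return n - len(tails)


def compute_wsd(table: KmerTable, keep_moves: bool = True) -> WsdProfile:
    """Full word-symmetry-distance profile for one k-mer table.

    Composes build_a1 -> build_a2 -> greedy_transform and fills the
    closed-form normalizers.
    """
    a1 = build_a1(table)
    a2 = build_a2(a1, table)
    profile = greedy_transform(a1, a2, keep_moves=keep_moves)
    profile.max_ulam = max_ulam(table.k)
    profile.max_wsd2 = max_wsd2(table.k)
    profile.nwsd1 = profile.wsd1 / profile.max_ulam
    profile.nwsd2 = profile.wsd2 / profile.max_wsd2
    return profile
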