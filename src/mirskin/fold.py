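"""RNA secondary-structure prediction for hairpin candidates.

The contract every caller relies on is narrow: given a sequence, return a
deterministic minimum-free-energy dot-bracket structure and its energy in
kcal/mol (<= 0).  Two engines satisfy it:

``vienna``
    ViennaRNA's Python bindings (the default whenever importable) —
    full nearest-neighbour thermodynamics.
``nussinov``
    A built-in Nussinov-style dynamic program over base-pair energies
    (GC = -3, AU = -2, GU = -1 kcal/mol-like units, minimum loop 3) so
    the package runs with zero native dependencies.  Energies are cruder
    than a thermodynamic model but ordering properties (real hairpins
    fold lower than shuffles) hold.

Sequences flow through the pipeline as DNA (T); they are converted to U
for the engines and for display only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

try:  # pragma: no cover - exercised indirectly
    import RNA as _vienna
except ImportError:  # pragma: no cover
    _vienna = None

_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -1.0,
    ("T", "G"): -1.0,
}
_MIN_LOOP = 3


@dataclass(frozen=True)
class FoldResult:
    sequence: str  # DNA alphabet, as given
    structure: str  # dot-bracket, same length
    mfe: float  # kcal/mol, <= 0

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure length != sequence length")
        pair_table(self.structure)  # raises if unbalanced

    @property
    def rna(self) -> str:
        """The sequence in RNA alphabet (display convention)."""
        return self.sequence.replace("T", "U")


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired); raises on unbalanced
    brackets."""
    stack: list[int] = []
    table = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure symbol {c!r}")
    if stack:
        raise ValueError(f"unmatched '(' at position {stack[-1]}")
    return table


def hairpin_loop_span(structure: str) -> tuple[int, int]:
    """Half-open span of the terminal loop of the dominant hairpin.

    A hairpin loop is the region enclosed by a pair with no paired bases
    inside; when the structure has several, the one with the deepest
    enclosing stem wins (ties to the leftmost).  Raises if the structure
    has no pairs at all.
    """
    table = pair_table(structure)
    best: tuple[int, int, int] | None = None  # (depth, start, end)
    depth = 0
    i = 0
    n = len(structure)
    # scan: depth at position = number of enclosing pairs
    depths = [0] * n
    d = 0
    for i, c in enumerate(structure):
        if c == "(":
            d += 1
            depths[i] = d
        elif c == ")":
            depths[i] = d
            d -= 1
        else:
            depths[i] = d
    for i in range(n):
        j = table[i]
        if j > i and all(table[k] == -1 for k in range(i + 1, j)):
            cand = (depths[i], -(i + 1))
            if best is None or cand > (best[0], -best[1]):
                best = (depths[i], i + 1, j)
    if best is None:
        raise ValueError("structure contains no base pairs (no hairpin loop)")
    return best[1], best[2]


def _fold_vienna(seq: str) -> FoldResult:
    structure, mfe = _vienna.fold(seq.replace("T", "U"))
    return FoldResult(seq, structure, round(float(mfe), 2))


def _fold_nussinov(seq: str) -> FoldResult:
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    INF = float("inf")
    E = [[0.0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1][j]
            cand = E[i][j - 1]
            if cand < best:
                best = cand
            pe = _PAIR_ENERGY.get((seq[i], seq[j]))
            if pe is not None:
                cand = E[i + 1][j - 1] + pe
                if cand < best:
                    best = cand
            for k in range(i + 1, j):
                cand = E[i][k] + E[k + 1][j]
                if cand < best:
                    best = cand
            E[i][j] = best
    # deterministic traceback mirroring the recurrence's preference order
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= _MIN_LOOP:
            continue
        e = E[i][j]
        pe = _PAIR_ENERGY.get((seq[i], seq[j]))
        if pe is not None and e == E[i + 1][j - 1] + pe:
            struct[i], struct[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        if e == E[i + 1][j]:
            stack.append((i + 1, j))
            continue
        if e == E[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if e == E[i][k] + E[k + 1][j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return FoldResult(seq, "".join(struct), float(E[0][n - 1]))


def available_engines() -> tuple[str, ...]:
    return ("vienna", "nussinov") if _vienna is not None else ("nussinov",)


def fold_rna(sequence: str, engine: str = "auto") -> FoldResult:
    """Fold a sequence; deterministic for fixed (sequence, engine).

    engine: "vienna", "nussinov", or "auto" (vienna when importable).
    Non-ACGT symbols are rejected.
    """
    seq = sequence.upper().replace("U", "T")
    if not seq or set(seq) - set("ACGT"):
        raise ValueError("sequence must be non-empty over A/C/G/T(U)")
    if engine == "auto":
        engine = "vienna" if _vienna is not None else "nussinov"
    if engine == "vienna":
        if _vienna is None:
            raise RuntimeError("ViennaRNA bindings not importable")
        return _fold_vienna(seq)
    if engine == "nussinov":
        return _fold_nussinov(seq)
    raise ValueError(f"unknown folding engine {engine!r}")
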