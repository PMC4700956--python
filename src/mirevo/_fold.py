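"""Maximum-pairing RNA secondary structure engine.

A Nussinov-style dynamic program maximising the number of base pairs
(Watson-Crick plus G·U wobble, minimum hairpin loop of 3 nt). The engine
is exposed behind a narrow interface -- ``fold(seq) -> [(structure,
energy), ...]`` -- so a thermodynamic backend could be swapped in without
touching callers. "Energy" here is the negated pair count: lower is
better, matching the sign convention of free-energy folders.

Suboptimal structures are alternative co-optimal tracebacks sampled with
a seeded RNG, so the full call is deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# nucleotide encoding: A=0 C=1 G=2 T/U=3, anything else 4 (unpairable)
_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _v in ((b"Aa", 0), (b"Cc", 1), (b"Gg", 2), (b"TtUu", 3)):
    for _c in _b:
        _ENC[_c] = _v

# pairable matrix over the 5 codes: AU/UA, GC/CG, GU/UG
_CANPAIR = np.zeros((5, 5), dtype=np.bool_)
for _i, _j in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CANPAIR[_i, _j] = True

MIN_LOOP = 3


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to the internal integer alphabet."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def can_pair(a: str, b: str) -> bool:
    """True if bases *a* and *b* form a WC or G·U pair (T treated as U)."""
    return bool(_CANPAIR[_ENC[ord(a)], _ENC[ord(b)]])


@njit(cache=True)
def _fill(enc, canpair, min_loop):  # pragma: no cover - exercised via fold()
    n = enc.shape[0]
    tbl = np.zeros((n, n), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = tbl[i + 1, j]
            if tbl[i, j - 1] > best:
                best = tbl[i, j - 1]
            if canpair[enc[i], enc[j]]:
                v = tbl[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = tbl[i, k] + tbl[k + 1, j]
                if v > best:
                    best = v
            tbl[i, j] = best
    return tbl


def _traceback(tbl, enc, min_loop, rng=None):
    """One traceback through the filled table.

    Deterministic (first option in preference order pair > left-unpaired >
    right-unpaired > bifurcation) when ``rng`` is None, otherwise a uniform
    choice among all co-optimal options at each cell.
    """
    n = enc.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or tbl[i, j] == 0:
            continue
        opts = []
        if j - i > min_loop and _CANPAIR[enc[i], enc[j]] and tbl[i + 1, j - 1] + 1 == tbl[i, j]:
            opts.append(("P", 0))
        if tbl[i + 1, j] == tbl[i, j]:
            opts.append(("L", 0))
        if tbl[i, j - 1] == tbl[i, j]:
            opts.append(("R", 0))
        for k in range(i + 1, j):
            if tbl[i, k] + tbl[k + 1, j] == tbl[i, j]:
                opts.append(("B", k))
        kind, k = opts[0] if rng is None else opts[int(rng.integers(len(opts)))]
        if kind == "P":
            partner[i], partner[j] = j, i
            stack.append((i + 1, j - 1))
        elif kind == "L":
            stack.append((i + 1, j))
        elif kind == "R":
            stack.append((i, j - 1))
        else:
            stack.append((i, k))
            stack.append((k + 1, j))
    return partner


def partner_to_dotbracket(partner: np.ndarray) -> str:
    out = []
    for i, p in enumerate(partner):
        if p < 0:
            out.append(".")
        elif p > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def pairing_map(structure: str) -> np.ndarray:
    """Partner index per position (-1 unpaired) from a dot-bracket string.

    Raises ``ValueError`` on unbalanced structures.
    """
    partner = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure: unmatched ')'")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure: unmatched '('")
    return partner


def fold(seq: str, n_suboptimal: int = 10, seed: int = 0):
    """Fold *seq*, returning ``[(dot_bracket, energy), ...]``.

    The first entry is the deterministic maximum-pairing structure; up to
    ``n_suboptimal`` further entries are distinct co-optimal tracebacks.
    Energy is ``-n_pairs`` (engine units).
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    enc = encode(seq)
    n = len(seq)
    if n < MIN_LOOP + 2:
        return [("." * n, 0.0)]
    tbl = _fill(enc, _CANPAIR, MIN_LOOP)
    energy = -float(tbl[0, n - 1])
    structures = [partner_to_dotbracket(_traceback(tbl, enc, MIN_LOOP))]
    seen = set(structures)
    rng = np.random.default_rng(seed)
    for _ in range(n_suboptimal):
        s = partner_to_dotbracket(_traceback(tbl, enc, MIN_LOOP, rng=rng))
        if s not in seen:
            seen.add(s)
            structures.append(s)
    return [(s, energy) for s in structures]
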