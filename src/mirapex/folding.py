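"""Single-hairpin RNA secondary-structure folding.

Plant pre-miRNA calling only needs stem-loop (single hairpin) topologies:
one chain of nested base pairs with stacked helices, bulges and internal
loops, closed by a terminal hairpin loop.  This module implements a minimum
free energy (MFE) search restricted to that topology under a
nearest-neighbour energy model: a stacking table over the six canonical
pair types (Watson-Crick plus G:U) and additive loop penalties.

Energies are handled internally as integers in deci-kcal/mol (tenths of a
kcal/mol) so that dynamic programming and exhaustive enumeration produce
bit-identical optima; the public API reports kcal/mol floats.

The energy model lives in :class:`EnergyModel` and is deliberately
pluggable — an external folding engine can be substituted wherever a
``(structure, mfe)`` pair is consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

MAX_FOLD_LEN = 400

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

#: pair-type index by (base_i, base_j): AU UA GC CG GU UG, -1 = unpairable
PAIR_INDEX = np.full((4, 4), -1, dtype=np.int64)
for _k, (_a, _b) in enumerate([(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]):
    PAIR_INDEX[_a, _b] = _k

# Stacking free energies in deci-kcal/mol, Turner-style magnitudes.
# Rows: outer pair (i,j); columns: inner pair (i+1, j-1).
_STACK = np.array(
    [
        #  AU   UA   GC   CG   GU   UG
        [ -9, -11, -22, -21,  -6, -14],  # AU
        [-13,  -9, -24, -21, -10, -13],  # UA
        [-21, -22, -33, -24, -14, -21],  # GC
        [-21, -24, -34, -33, -21, -25],  # CG
        [-13, -14, -25, -21,  -5, -13],  # GU
        [-10, -11, -22, -21,  -6,  -9],  # UG
    ],
    dtype=np.int64,
)

_INF = np.int64(1) << 28


def _hairpin_table(max_len: int, min_loop: int) -> np.ndarray:
    """Hairpin-loop closing penalty by unpaired loop length (deci-kcal)."""
    tab = np.full(max_len + 1, _INF, dtype=np.int64)
    for length in range(min_loop, max_len + 1):
        tab[length] = min(60 + 5 * (length - 3), 110)
    return tab


def _bulge_table(max_interior: int) -> np.ndarray:
    tab = np.full(max_interior + 1, _INF, dtype=np.int64)
    for n in range(1, max_interior + 1):
        tab[n] = 45 + 6 * (n - 1)
    return tab


def _internal_table(max_interior: int) -> np.ndarray:
    tab = np.full((max_interior + 1, max_interior + 1), _INF, dtype=np.int64)
    for n1 in range(1, max_interior + 1):
        for n2 in range(1, max_interior + 1):
            tab[n1, n2] = 30 + 6 * (n1 + n2) + 12 * abs(n1 - n2)
    return tab


@dataclass(frozen=True)
class EnergyModel:
    """Energy tables (deci-kcal/mol) and topology limits for hairpin folding.

    ``max_interior`` caps the number of unpaired bases on either side of an
    internal loop or bulge between consecutive stem pairs; ``min_loop`` is
    the minimum hairpin-loop size (3, the steric minimum).
    """

    min_loop: int = 3
    max_interior: int = 10
    stack: np.ndarray = field(default_factory=lambda: _STACK.copy())
    hairpin: np.ndarray = field(
        default_factory=lambda: _hairpin_table(MAX_FOLD_LEN, 3)
    )
    bulge: np.ndarray = field(default_factory=lambda: _bulge_table(10))
    internal: np.ndarray = field(default_factory=lambda: _internal_table(10))

    def loop_penalty(self, n1: int, n2: int) -> int:
        """Penalty between consecutive pairs with n1/n2 unpaired bases."""
        if n1 == 0 and n2 == 0:
            raise ValueError("stack, not a loop")
        if n1 == 0 or n2 == 0:
            return int(self.bulge[max(n1, n2)])
        return int(self.internal[n1, n2])


DEFAULT_MODEL = EnergyModel()


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string to 0..3 codes (T treated as U)."""
    try:
        return np.array([_BASE_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - trivial message path
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


@njit(cache=True)
def _fill(codes, pair_index, stack, hairpin, bulge, internal, min_loop, max_interior):
    n = codes.shape[0]
    inf = _INF
    v = np.full((n, n), inf, dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pair_index[codes[i], codes[j]]
            if pt < 0:
                continue
            best = hairpin[j - i - 1]
            kmax = min(i + 1 + max_interior, j - min_loop - 1)
            for k in range(i + 1, kmax + 1):
                n1 = k - i - 1
                lmin = max(k + min_loop + 1, j - 1 - max_interior)
                for l in range(lmin, j):
                    if v[k, l] >= inf:
                        continue
                    n2 = j - l - 1
                    if n1 == 0 and n2 == 0:
                        pt2 = pair_index[codes[k], codes[l]]
                        pen = stack[pt, pt2]
                    elif n1 == 0:
                        pen = bulge[n2]
                    elif n2 == 0:
                        pen = bulge[n1]
                    else:
                        pen = internal[n1, n2]
                    e = pen + v[k, l]
                    if e < best:
                        best = e
            v[i, j] = best
    return v


def _traceback(codes: np.ndarray, v: np.ndarray, i: int, j: int,
               model: EnergyModel) -> list[tuple[int, int]]:
    """Recover the chain of nested pairs achieving v[i, j]."""
    pairs = []
    while True:
        pairs.append((i, j))
        target = int(v[i, j])
        if target == int(model.hairpin[j - i - 1]):
            return pairs
        pt = int(PAIR_INDEX[codes[i], codes[j]])
        found = False
        kmax = min(i + 1 + model.max_interior, j - model.min_loop - 1)
        for k in range(i + 1, kmax + 1):
            n1 = k - i - 1
            lmin = max(k + model.min_loop + 1, j - 1 - model.max_interior)
            for l in range(lmin, j):
                if v[k, l] >= _INF:
                    continue
                n2 = j - l - 1
                if n1 == 0 and n2 == 0:
                    pen = int(model.stack[pt, PAIR_INDEX[codes[k], codes[l]]])
                elif n1 == 0 or n2 == 0:
                    pen = int(model.bulge[max(n1, n2)])
                else:
                    pen = int(model.internal[n1, n2])
                if pen + int(v[k, l]) == target:
                    i, j = k, l
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - DP/traceback invariant
            raise RuntimeError("traceback failed to re-derive DP optimum")


def fold_hairpin(seq: str, model: EnergyModel = DEFAULT_MODEL) -> tuple[str, float]:
    """Fold one sequence into its MFE single-hairpin structure.

    Returns ``(dot_bracket, mfe_kcal_per_mol)``.  When no structure has a
    stabilising (negative) free energy the open chain is returned with an
    MFE of 0.0.  Input may be RNA or DNA (T is read as U); sequences longer
    than ``MAX_FOLD_LEN`` are refused.
    """
    if len(seq) > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    n = len(seq)
    open_chain = ("." * n, 0.0)
    if n < model.min_loop + 2:
        return open_chain
    codes = encode(seq)
    v = _fill(codes, PAIR_INDEX, model.stack, model.hairpin, model.bulge,
              model.internal, model.min_loop, model.max_interior)
    best = int(v.min())
    if best >= 0:
        return open_chain
    i, j = np.unravel_index(int(v.argmin()), v.shape)
    pairs = _traceback(codes, v, int(i), int(j), model)
    structure = ["."] * n
    for a, b in pairs:
        structure[a] = "("
        structure[b] = ")"
    return "".join(structure), best / 10.0


def pair_chain(structure: str) -> list[tuple[int, int]]:
    """Outermost-to-innermost nested pair list of a single-hairpin structure."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            pairs.append((stack.pop(), pos))
    pairs.reverse()
    return pairs


def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (both directions)."""
    table: dict[int, int] = {}
    for a, b in pair_chain(structure):
        table[a] = b
        table[b] = a
    return table
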