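"""Brute-force single-hairpin folding oracle for tests.

Independent of the package's dynamic program: explicitly enumerates every
nested pair chain (helix with bulges/internal loops, closed by a hairpin
loop) admissible under the same topology limits, scores each chain with a
standalone energy function over the same integer tables, and minimises.
Exponential — only for short sequences.
"""

from __future__ import annotations

from mirapex.folding import DEFAULT_MODEL, PAIR_INDEX, EnergyModel, encode


def chain_energy(seq: str, chain: list[tuple[int, int]],
                 model: EnergyModel = DEFAULT_MODEL) -> int:
    """Deci-kcal energy of one outermost-to-innermost pair chain."""
    codes = encode(seq)
    total = 0
    for (i, j), (k, l) in zip(chain, chain[1:]):
        n1, n2 = k - i - 1, j - l - 1
        if n1 == 0 and n2 == 0:
            pt = PAIR_INDEX[codes[i], codes[j]]
            pt2 = PAIR_INDEX[codes[k], codes[l]]
            total += int(model.stack[pt, pt2])
        else:
            total += model.loop_penalty(n1, n2)
    inner_i, inner_j = chain[-1]
    total += int(model.hairpin[inner_j - inner_i - 1])
    return total


def enumerate_chains(seq: str, model: EnergyModel = DEFAULT_MODEL):
    """Yield every admissible nested pair chain of the sequence."""
    codes = encode(seq)
    n = len(codes)

    def extend(chain):
        i, j = chain[-1]
        if j - i - 1 >= model.min_loop:
            yield chain
        for k in range(i + 1, min(i + 2 + model.max_interior, j)):
            for l in range(j - 1, max(k + model.min_loop, j - 2 - model.max_interior), -1):
                if l <= k + model.min_loop:
                    continue
                if PAIR_INDEX[codes[k], codes[l]] >= 0:
                    yield from extend(chain + [(k, l)])

    for i in range(n):
        for j in range(i + model.min_loop + 1, n):
            if PAIR_INDEX[codes[i], codes[j]] >= 0:
                yield from extend([(i, j)])


def brute_force_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL
                    ) -> tuple[int, list[tuple[int, int]] | None]:
    """(best deci-kcal energy, best chain) over all single-hairpin chains.

    Returns (0, None) when no chain is stabilising, matching the folder's
    open-chain convention.
    """
    best, best_chain = 0, None
    for chain in enumerate_chains(seq, model):
        e = chain_energy(seq, chain, model)
        if e < best:
            best, best_chain = e, chain
    return best, best_chain
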