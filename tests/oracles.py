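"""Independent oracles used by the tests.

The folding oracle enumerates every nested structure explicitly (no
dynamic programming) and reports the minimum total pair weight, so it
shares no code path with the production folder.
"""

from typing import Iterator, List, Tuple

from mircurate.hairpin import FoldParams


def enumerate_structures(
    seq: str, i: int, j: int, params: FoldParams
) -> Iterator[List[Tuple[int, int]]]:
    """All nested pair sets on the half-open window [i, j)."""
    if j - i < 2:
        yield []
        return
    for rest in enumerate_structures(seq, i + 1, j, params):
        yield rest  # i unpaired
    for k in range(i + params.min_loop + 1, j):
        if params.weight(seq[i], seq[k]) is not None:
            for left in enumerate_structures(seq, i + 1, k, params):
                for right in enumerate_structures(seq, k + 1, j, params):
                    yield [(i, k)] + left + right


def brute_force_min_energy(seq: str, params: FoldParams = FoldParams()) -> float:
    """Minimum energy over the exhaustive structure enumeration."""
    best = 0.0
    for pairs in enumerate_structures(seq, 0, len(seq), params):
        energy = sum(params.weight(seq[i], seq[j]) for i, j in pairs)
        best = min(best, energy)
    return best
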