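"""Independent oracles used by the unit and acceptance suites.

These deliberately avoid the library's scanning/editing code paths: runs are
found by a direct left-to-right walk, and minimal edit counts by exhaustive
enumeration of all substitution sets of growing size.
"""

from itertools import combinations, product

from promforge.domestication import DEFAULT_CONFIG, is_clean


def brute_force_runs(seq: str, min_len: int):
    """Maximal homopolymer runs via a direct walk (no regex)."""
    upper = seq.upper()
    out = []
    i = 0
    while i < len(upper):
        j = i
        while j < len(upper) and upper[j] == upper[i]:
            j += 1
        if j - i >= min_len:
            out.append((i, j - i, upper[i]))
        i = j
    return out


def brute_min_edits(seq: str, config=DEFAULT_CONFIG, max_k: int = 3) -> int:
    """Smallest number of single-base substitutions that cleans *seq*."""
    if is_clean(seq, config):
        return 0
    n = len(seq)
    for k in range(1, max_k + 1):
        for positions in combinations(range(n), k):
            refs = [seq[p].upper() for p in positions]
            for bases in product("ACGT", repeat=k):
                if any(b == r for b, r in zip(bases, refs)):
                    continue
                cand = list(seq)
                for p, b in zip(positions, bases):
                    cand[p] = b
                if is_clean("".join(cand), config):
                    return k
    raise AssertionError(f"no fix within {max_k} edits")
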