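"""Independent brute-force alignment scorer used as a test oracle.

Exhaustive recursion with memoization over explicit alignment operations:
the query must be consumed end-to-end, the reference may be entered and left
at any position, gaps are affine (a length-k run costs open + (k-1)*extend,
and a gap of the other kind re-opens). Written separately from the
production dynamic-programming kernels and kept deliberately naive.
"""

from functools import lru_cache


def glocal_score_oracle(query: str, ref: str, match: int = 2, mismatch: int = -4,
                        gap_open: int = -6, gap_extend: int = -1) -> int:
    m, n = len(query), len(ref)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> int:
        if i == m:
            return 0  # any remaining reference tail is free
        options = []
        if j < n:
            s = match if (query[i] == ref[j] and query[i] != "N") else mismatch
            options.append(s + best(i + 1, j + 1, "M"))
            options.append((gap_extend if prev == "D" else gap_open) + best(i, j + 1, "D"))
        options.append((gap_extend if prev == "I" else gap_open) + best(i + 1, j, "I"))
        return max(options)

    result = max(best(0, j0, "") for j0 in range(n + 1))
    best.cache_clear()
    return result
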