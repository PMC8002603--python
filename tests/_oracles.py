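"""Independent brute-force oracles shared by unit and acceptance tests."""

from __future__ import annotations

from hacsplice.mapper import revcomp


def oracle_longest_run(read: str, query: str, search_rc: bool = True):
    """Exhaustive enumeration of all ungapped (read offset, query offset) runs.

    Returns (w, q_start, strand) under the tie rules: longest run, then
    smaller q_start, then forward strand; None when no common base exists.
    """
    best = None
    strands = [("+", read)] + ([("-", revcomp(read))] if search_rc else [])
    for strand, r in strands:
        for i in range(len(r)):
            for j in range(len(query)):
                w = 0
                while i + w < len(r) and j + w < len(query) and r[i + w] == query[j + w]:
                    w += 1
                if w == 0:
                    continue
                cand = (w, j + 1, strand)
                if best is None:
                    best = cand
                    continue
                better = (
                    cand[0] > best[0]
                    or (cand[0] == best[0] and cand[1] < best[1])
                    or (cand[0] == best[0] and cand[1] == best[1] and cand[2] == "+" and best[2] == "-")
                )
                if better:
                    best = cand
    return best
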