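"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or closed form,
sharing no code path with the implementation it checks.
"""

from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}

PAIR_SCORE = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}


def all_orf_spans(seq: str) -> list[tuple[int, int]]:
    """Every AUG..stop span (stop included) over the three forward frames,
    where the AUG is the first one of its span."""
    spans = []
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in STOPS:
                if starts:
                    spans.append((starts[0], i + 3))
                starts = []
    return spans


def best_orf_span(seq: str) -> tuple[int, int] | None:
    """Longest span; ties to the smallest start coordinate."""
    spans = all_orf_spans(seq)
    if not spans:
        return None
    return max(spans, key=lambda s: (s[1] - s[0], -s[0]))


def exhaustive_align_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Maximum global alignment score by explicit enumeration of all paths.

    A gap run of length L costs gap_open + gap_extend*(L-1); end gaps are
    penalized.  Exponential: use only for len <= 5.
    """

    def gap_cost(prev_gap: bool) -> float:
        return gap_extend if prev_gap else gap_open

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, matrix[a[i], b[j]] + rec(i + 1, j + 1, "m"))
        if i < len(a):
            best = max(best, -gap_cost(last == "d") + rec(i + 1, j, "d"))
        if j < len(b):
            best = max(best, -gap_cost(last == "i") + rec(i, j + 1, "i"))
        return best

    return rec(0, 0, "m")


def enumerate_hairpins(
    window: str,
    min_loop: int = 3,
    max_interior: int = 10,
    interior_penalty: float = 1.0,
) -> list[tuple[float, tuple]]:
    """All legal single hairpins (nested pair chains) with their scores."""
    n = len(window)
    results: list[tuple[float, tuple]] = []

    def extend(chain: list, score: float) -> None:
        results.append((score, tuple(chain)))
        i, j = chain[-1]
        for i2 in range(i + 1, j):
            left = i2 - i - 1
            if left > max_interior:
                break
            for j2 in range(j - 1, i2, -1):
                right = j - j2 - 1
                if left + right > max_interior:
                    break
                if j2 - i2 - 1 < min_loop:
                    continue
                ps = PAIR_SCORE.get((window[i2], window[j2]))
                if ps is None:
                    continue
                extend(chain + [(i2, j2)], score + ps - interior_penalty * (left + right))

    for i in range(n):
        for j in range(i + min_loop + 1, n):
            ps = PAIR_SCORE.get((window[i], window[j]))
            if ps is not None:
                extend([(i, j)], ps)
    return results


def best_hairpin_score(window: str, **kw) -> float | None:
    all_h = enumerate_hairpins(window, **kw)
    return max(s for s, _ in all_h) if all_h else None


def tree_path_distances(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of an skbio TreeNode by explicit traversal."""
    tips = list(tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            out[(a.name, b.name)] = a.distance(b)
    return out
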