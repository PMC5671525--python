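"""Single stem-loop (hairpin) prediction 3' of a candidate shift site.

The stimulatory element of a -1 frameshift site is an RNA structure a few
nucleotides downstream of the slippery heptamer; for the sites analysed
here it is a stem-loop.  What matters for reporting is the pairing pattern
— how many base pairs, how many consecutive Watson-Crick pairs at the stem
base, how many of those are G:C — not a free energy, so the folder uses a
deliberately transparent additive scoring scheme rather than a
nearest-neighbor thermodynamic model:

* pair scores G:C = 3, A:U = 2, G:U (wobble) = 1;
* each unpaired interior nucleotide (bulge or internal loop) costs
  ``interior_penalty`` (default 1);
* hairpin loops must be at least ``min_loop`` nt (default 3);
* pseudoknots are excluded: one hairpin, nested pairs only.

The optimum over all legal single hairpins in a window is found by dynamic
programming over outermost pairs and is exactly checkable against brute
force enumeration on small windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_io import to_dna

__all__ = [
    "FoldConfig",
    "Hairpin",
    "best_hairpin",
    "stem_metrics",
    "dot_bracket",
    "parse_dot_bracket",
]

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}
LEGAL_PAIRS = WC_PAIRS | WOBBLE_PAIRS

NEG_INF = float("-inf")


@dataclass
class FoldConfig:
    pair_scores: dict = field(
        default_factory=lambda: {
            ("G", "C"): 3.0, ("C", "G"): 3.0,
            ("A", "T"): 2.0, ("T", "A"): 2.0,
            ("G", "T"): 1.0, ("T", "G"): 1.0,
        }
    )
    interior_penalty: float = 1.0  # per unpaired interior nt (bulge/internal loop)
    min_loop: int = 3
    #: max unpaired interior nt between consecutive stem pairs (both sides combined)
    max_interior: int = 10
    min_score: float = 4.0  # below this, report "no hairpin"
    window: int = 80  # fold window length, from heptamer end
    max_window: int = 200


@dataclass
class Hairpin:
    region_start: int  # 0-based genome index of the folded window
    window: str  # DNA letters
    pairs: list  # [(i, j), ...] window-local, i < j, outermost first
    score: float
    base_run_wc: int = 0
    base_run_gc: int = 0
    loop_len: int = 0

    def __post_init__(self) -> None:
        self.base_run_wc, self.base_run_gc, _, self.loop_len = stem_metrics(self)

    @property
    def total_bp(self) -> int:
        return len(self.pairs)

    @property
    def structure(self) -> str:
        return dot_bracket(self)

    @property
    def first_paired_index(self) -> int:
        """Window-local index of the 5'-most paired base."""
        return self.pairs[0][0]


def _pair_score(w: str, i: int, j: int, config: FoldConfig) -> float | None:
    return config.pair_scores.get((w[i], w[j]))


def best_hairpin(window: str, config: FoldConfig | None = None, region_start: int = 0) -> Hairpin | None:
    """Maximum-score single hairpin in ``window``, or None below threshold.

    Ties break deterministically: lowest start index of the outermost pair,
    then the larger number of pairs, then the innermost enumeration order.
    """
    config = config or FoldConfig()
    w = to_dna(window)
    n = len(w)
    if n < 2 * 1 + config.min_loop + 2:
        raise ValueError(f"window too short to fold ({n} nt)")
    if n > config.max_window:
        raise ValueError(f"window longer than configured maximum ({n} > {config.max_window})")

    # H[(i, j)] = (score, npairs, inner) for the best hairpin whose outermost
    # pair is (i, j); inner is the next pair inward or None.
    H: dict[tuple[int, int], tuple[float, int, tuple[int, int] | None]] = {}
    for span in range(config.min_loop + 1, n):  # span = j - i
        for i in range(0, n - span):
            j = i + span
            ps = _pair_score(w, i, j, config)
            if ps is None:
                continue
            best: tuple[float, int, tuple[int, int] | None] | None = None
            if j - i - 1 >= config.min_loop:
                best = (ps, 1, None)
            for left in range(0, config.max_interior + 1):
                i2 = i + 1 + left
                if i2 >= j:
                    break
                for right in range(0, config.max_interior - left + 1):
                    j2 = j - 1 - right
                    if j2 <= i2:
                        break
                    sub = H.get((i2, j2))
                    if sub is None:
                        continue
                    cand_score = ps + sub[0] - config.interior_penalty * (left + right)
                    cand = (cand_score, sub[1] + 1, (i2, j2))
                    if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                        best = cand
            if best is not None:
                H[(i, j)] = best

    top: tuple[int, int] | None = None
    for (i, j), (score, npairs, _inner) in H.items():
        if score < config.min_score:
            continue
        if top is None:
            top = (i, j)
            continue
        ts, tn, _ = H[top]
        # higher score, then lower start, then more pairs, then lower end
        if (-score, i, -npairs, j) < (-ts, top[0], -tn, top[1]):
            top = (i, j)
    if top is None:
        return None

    pairs = []
    node: tuple[int, int] | None = top
    while node is not None:
        pairs.append(node)
        node = H[node][2]
    return Hairpin(region_start=region_start, window=w, pairs=pairs, score=H[top][0])


def stem_metrics(h: Hairpin) -> tuple[int, int, int, int]:
    """(base_run_wc, base_run_gc, total_bp, loop_len) of a hairpin.

    The base run is counted from the outermost pair inward and is broken by
    the first non-Watson-Crick pair or by any unpaired interruption; only
    WC pairs count, and ``base_run_gc`` counts the G:C pairs within it.
    """
    pairs = h.pairs
    if not pairs:
        return 0, 0, 0, 0
    run_wc = run_gc = 0
    prev = None
    for (i, j) in pairs:
        if prev is not None and (i != prev[0] + 1 or j != prev[1] - 1):
            break  # bulge or internal loop interrupts the base run
        nt = (h.window[i], h.window[j])
        if nt not in WC_PAIRS:
            break
        run_wc += 1
        if nt in (("G", "C"), ("C", "G")):
            run_gc += 1
        prev = (i, j)
    inner_i, inner_j = pairs[-1]
    return run_wc, run_gc, len(pairs), inner_j - inner_i - 1


def dot_bracket(h: Hairpin) -> str:
    """Dot-parenthesis rendering of the hairpin over its window."""
    chars = ["."] * len(h.window)
    for i, j in h.pairs:
        if chars[i] != "." or chars[j] != ".":
            raise ValueError("index appears in more than one pair")
        chars[i], chars[j] = "(", ")"
    s = "".join(chars)
    # sanity: nested by construction
    assert s.count("(") == s.count(")") == len(h.pairs)
    return s


def parse_dot_bracket(structure: str) -> list[tuple[int, int]]:
    """Pair list from a dot-parenthesis string (outermost pair first)."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' in structure")
    return sorted(pairs)
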