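"""Independent brute-force oracles used to check the fast implementations.

Everything here is written for clarity at tiny n, not speed: exhaustive
substring enumeration for grounding, bitmask DP over all one-to-one
assignments for matching, all-pairs loops for validation.  These functions
never call the code paths they are used to verify.
"""

from __future__ import annotations

import re
from functools import lru_cache


def brute_force_validate(frames):
    """All-pairs span check: (redundant pairs, overlap pairs) by frame_id."""
    redundant, overlaps = [], []
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            a, b = frames[i], frames[j]
            if (a.start, a.end, a.entity_text) == (b.start, b.end, b.entity_text):
                redundant.append((a.frame_id, b.frame_id))
            elif max(a.start, b.start) < min(a.end, b.end):
                overlaps.append((a.frame_id, b.frame_id))
    return redundant, overlaps


def _ws_pattern(needle: str) -> re.Pattern:
    return re.compile(r"\s+".join(re.escape(t) for t in needle.split()), re.IGNORECASE)


def brute_force_ground(region: str, entity_texts: list[str]) -> list[tuple[int, int]]:
    """Leftmost-unconsumed grounding by exhaustive substring enumeration.

    For each entity text in order, enumerate every candidate span of the
    region per tier (exact / case-insensitive / whitespace-normalized), and
    take the leftmost candidate of the first tier with any candidate free of
    previously consumed spans.  Items with no free candidate are skipped.
    """
    consumed: list[tuple[int, int]] = []

    def free(s, e):
        return all(max(s, cs) >= min(e, ce) for cs, ce in consumed)

    out = []
    for needle in entity_texts:
        n = len(needle)
        tiers: list[list[tuple[int, int]]] = [
            [(s, s + n) for s in range(len(region) - n + 1) if region[s : s + n] == needle],
            [
                (s, s + n)
                for s in range(len(region) - n + 1)
                if region[s : s + n].lower() == needle.lower()
            ],
        ]
        if needle.split():
            pat = _ws_pattern(needle)
            tiers.append(
                [
                    (s, e)
                    for s in range(len(region))
                    for e in range(s + 1, len(region) + 1)
                    if pat.fullmatch(region, s, e)
                ]
            )
        span = None
        for candidates in tiers:
            for s, e in sorted(candidates):
                if free(s, e):
                    span = (s, e)
                    break
            if span:
                break
        if span:
            consumed.append(span)
            out.append(span)
    return out


_GROUND_VOCAB = ["aspirin", "rash", "mg", "daily", "held", "BID", "dose", "81"]


def random_grounding_instance(rng):
    """A random (region, entity_texts) pair exercising all grounding tiers.

    The region is vocabulary words joined by variable whitespace; items are
    single words or bigrams, sometimes case-mangled (case-insensitive tier),
    sometimes with collapsed/extra inner whitespace (normalized tier), and
    sometimes absent from the region entirely (drop path).  Repeated items
    exercise the leftmost-unconsumed rule.
    """
    words = [rng.choice(_GROUND_VOCAB) for _ in range(rng.randint(3, 12))]
    seps = [rng.choice([" ", "  ", " \t ", "\n"]) for _ in words[:-1]]
    region = words[0] + "".join(s + w for s, w in zip(seps, words[1:]))
    items = []
    for _ in range(rng.randint(1, 6)):
        kind = rng.random()
        if kind < 0.15:
            items.append("notintext")
            continue
        i = rng.randrange(len(words))
        if kind < 0.55 or i == len(words) - 1:
            needle = words[i]
        else:
            needle = words[i] + rng.choice([" ", "  "]) + words[i + 1]
        mangle = rng.random()
        if mangle < 0.3:
            needle = needle.upper() if mangle < 0.15 else needle.capitalize()
        items.append(needle)
    return region, items


def brute_force_max_tp(gold, pred, mode: str, label_key: str | None) -> int:
    """Maximum number of one-to-one compatible (gold, pred) pairs."""

    def label(f):
        return f.attributes.get(label_key) if label_key else None

    def compatible(g, p):
        if label(g) != label(p):
            return False
        if mode == "strict":
            return (g.start, g.end) == (p.start, p.end)
        return max(g.start, p.start) < min(g.end, p.end)

    compat = [[compatible(g, p) for p in pred] for g in gold]
    n_pred = len(pred)

    @lru_cache(maxsize=None)
    def best(i: int, used: int) -> int:
        if i == len(gold):
            return 0
        result = best(i + 1, used)
        for j in range(n_pred):
            if compat[i][j] and not (used >> j) & 1:
                result = max(result, 1 + best(i + 1, used | (1 << j)))
        return result

    return best(0, 0)
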