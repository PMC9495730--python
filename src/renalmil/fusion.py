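"""Decision fusion: per-patch majority-with-discard, then slide-level voting.

Each concentric test patch set yields three per-scale predicted labels. The
fusion rule keeps the label that at least two of the three classifiers agree
on, and discards the patch when all three disagree — a patch on which the
scales cannot corroborate each other carries no reliable subtype evidence.
Surviving patch labels are then aggregated per slide by majority vote.

Two implementations of the patch rule are provided: the published
pseudocode's Boyer–Moore-style counter with a final membership check
(``fuse_patch``) and a direct mode-with-tie-discard rule
(``fuse_patch_bruteforce``). The test suite asserts their equivalence over
every vote triple, guarding against a mis-transcribed counter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DISCARD",
    "INDETERMINATE",
    "PatchDecision",
    "SlidePrediction",
    "fuse_patch",
    "fuse_patch_bruteforce",
    "aggregate_slide",
]

#: sentinel outcome for a patch whose three scale votes are pairwise distinct
DISCARD = "DISCARD"
#: sentinel slide label when every patch of the slide was discarded
INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True, eq=False)
class PatchDecision:
    """Fused outcome for one concentric patch set.

    ``votes`` is the ordered triple (400-scale, 200-scale, 100-scale
    predicted labels); ``outcome`` is a class label or DISCARD.
    ``probabilities`` optionally carries the per-scale class-probability rows
    (used only for slide-level tie-breaking).
    """

    set_id: str
    slide_id: str
    votes: tuple[str, str, str]
    outcome: str
    probabilities: tuple | None = None


@dataclass(frozen=True)
class SlidePrediction:
    slide_id: str
    label: str  # class label or INDETERMINATE
    class_fractions: dict[str, float]
    n_patches: int
    n_discarded: int
    tie_flag: bool = False


def fuse_patch(votes: tuple[str, str, str]) -> str:
    """Published counter form: Boyer–Moore vote then membership check.

    Vote/Count scan over the three decisions, then the surviving candidate is
    kept only if it equals the first or second decision; otherwise the patch
    is discarded. Returns the majority label (>= 2 occurrences) or DISCARD
    when all three votes are pairwise distinct.
    """
    if len(votes) != 3:
        raise ValueError(f"expected exactly 3 votes, got {len(votes)}")
    vote = None
    count = 0
    for decision in votes:
        if count == 0:
            vote = decision
        if vote == decision:
            count += 1
        else:
            count -= 1
    if vote != votes[0] and vote != votes[1]:
        return DISCARD
    return vote


def fuse_patch_bruteforce(votes: tuple[str, str, str]) -> str:
    """Contract form: the label occurring >= 2 times, else DISCARD."""
    if len(votes) != 3:
        raise ValueError(f"expected exactly 3 votes, got {len(votes)}")
    label, n = Counter(votes).most_common(1)[0]
    return label if n >= 2 else DISCARD


def aggregate_slide(
    decisions: list[PatchDecision],
    class_set: list[str],
) -> SlidePrediction:
    """Majority vote over a slide's non-discarded patch outcomes.

    Fractions are reported over non-discarded patches. Ties between
    top-count classes are broken by the higher mean predicted probability
    across the tied class's supporting patches (falling back to class-set
    order when probabilities are unavailable); the tie is flagged. A slide
    whose every patch was discarded is INDETERMINATE.
    """
    if not decisions:
        raise ValueError("cannot aggregate an empty decision list")
    slide_ids = {d.slide_id for d in decisions}
    if len(slide_ids) != 1:
        raise ValueError(f"decisions span multiple slides: {sorted(slide_ids)}")
    slide_id = decisions[0].slide_id
    kept = [d for d in decisions if d.outcome != DISCARD]
    n_discarded = len(decisions) - len(kept)
    if not kept:
        logger.warning("slide %s: all %d patches discarded; INDETERMINATE", slide_id, len(decisions))
        return SlidePrediction(
            slide_id=slide_id,
            label=INDETERMINATE,
            class_fractions={c: 0.0 for c in class_set},
            n_patches=len(decisions),
            n_discarded=n_discarded,
        )
    counts = Counter(d.outcome for d in kept)
    fractions = {c: counts.get(c, 0) / len(kept) for c in class_set}
    top = max(counts.values())
    leaders = [c for c in class_set if counts.get(c, 0) == top]
    tie = len(leaders) > 1
    if tie:
        label = _break_tie(leaders, kept, class_set)
    else:
        label = leaders[0]
    return SlidePrediction(
        slide_id=slide_id,
        label=label,
        class_fractions=fractions,
        n_patches=len(decisions),
        n_discarded=n_discarded,
        tie_flag=tie,
    )


def _break_tie(leaders: list[str], kept: list[PatchDecision], class_set: list[str]) -> str:
    scores = {}
    for c in leaders:
        support = [d for d in kept if d.outcome == c and d.probabilities is not None]
        if not support:
            continue
        idx = class_set.index(c)
        vals = []
        for d in support:
            for row in d.probabilities:
                vals.append(float(np.asarray(row)[idx]))
        scores[c] = float(np.mean(vals))
    if scores:
        best = max(scores.values())
        for c in leaders:  # class-set order among equal scores: deterministic
            if scores.get(c, -1.0) == best:
                return c
    return leaders[0]
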