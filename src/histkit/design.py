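"""Greedy design of synthetic histone tails under a learned objective.

Starting from an anchor sequence (by default the wild-type tail carrying the
G4D substitution), each round scores every allowed single-substitution
neighbor with the repression model and accepts the best one if it improves
the predicted score by at least ``min_improvement``, stopping at the mutation
budget or when no neighbor qualifies.  A companion routine ranks natural
tails that carry a required anchor substitution by predicted score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import CANONICAL_AA, ReferenceHistone, SubstitutionVariant, apply_variants, fraction_difference
from .refs import H4_TAIL


def default_anchor(wt_tail: str = H4_TAIL) -> str:
    """The wild-type tail with G4D applied - the design search's start state."""
    ref = ReferenceHistone(family="tail", sequence=wt_tail)
    g4d = SubstitutionVariant(4, wt_tail[3], "D")
    return apply_variants(ref, {g4d})


@dataclass
class DesignConfig:
    """Greedy-search configuration.

    ``candidates``: allowed substitutions as (position, alt) pairs; ``None``
    allows all 19 alternatives at every position.  ``anchor_variant`` names
    the substitution that defines the anchor state; reverting it is forbidden
    by default.
    """

    anchor: str = field(default_factory=default_anchor)
    candidates: set[tuple[int, str]] | None = None
    max_mutations: int = 8
    min_improvement: float = 0.0
    wt_tail: str = H4_TAIL
    anchor_variant: SubstitutionVariant | None = None
    forbid_anchor_reversion: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_mutations < 1:
            raise ValueError("max_mutations must be >= 1")
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")
        if self.anchor_variant is None and self.forbid_anchor_reversion:
            # infer the anchor substitution from anchor vs wt when unique
            diffs = [
                (i + 1, w, a)
                for i, (w, a) in enumerate(zip(self.wt_tail, self.anchor))
                if w != a
            ]
            if len(diffs) == 1:
                pos, w, a = diffs[0]
                self.anchor_variant = SubstitutionVariant(pos, w, a)


@dataclass
class DesignStep:
    sequence: str
    score: float
    mutation: SubstitutionVariant | None  # None for the anchor state


@dataclass
class DesignTrajectory:
    """Ordered greedy steps; scores are non-decreasing along the path."""

    steps: list[DesignStep]
    wt_tail: str

    @property
    def final_sequence(self) -> str:
        return self.steps[-1].sequence

    @property
    def final_score(self) -> float:
        return self.steps[-1].score

    def divergence_from_wt(self) -> float:
        return fraction_difference(self.final_sequence, self.wt_tail)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": i,
                    "mutation": str(s.mutation) if s.mutation else "anchor",
                    "sequence": s.sequence,
                    "score": s.score,
                }
                for i, s in enumerate(self.steps)
            ]
        )


def enumerate_neighbors(
    seq: str, config: DesignConfig
) -> list[tuple[SubstitutionVariant, str]]:
    """All allowed single-substitution neighbors in deterministic order.

    Order: position ascending, then alternative residue alphabetical.
    Substitutions to the residue already present are excluded, as is
    reverting the anchor substitution when configured.
    """
    if config.candidates is not None and not config.candidates:
        raise ValueError("empty candidate set")
    out = []
    banned: tuple[int, str] | None = None
    if config.forbid_anchor_reversion and config.anchor_variant is not None:
        banned = (config.anchor_variant.position, config.anchor_variant.wt_aa)
    for pos in range(1, len(seq) + 1):
        current = seq[pos - 1]
        for alt in CANONICAL_AA:
            if alt == current:
                continue
            if config.candidates is not None and (pos, alt) not in config.candidates:
                continue
            if banned is not None and (pos, alt) == banned:
                continue
            mutant = seq[: pos - 1] + alt + seq[pos:]
            out.append((SubstitutionVariant(pos, current, alt), mutant))
    return out


def greedy_search(model, config: DesignConfig) -> DesignTrajectory:
    """Iterative greedy maximization of the predicted repression score.

    ``model`` is anything exposing ``predict(list[str]) -> array``.  At each
    round all neighbors are scored in one batch; the first-encountered argmax
    (lowest position, then alphabetical alternative) is accepted iff it beats
    the current score by at least ``min_improvement``.
    """
    current = config.anchor
    current_score = float(np.asarray(model.predict([current]))[0])
    steps = [DesignStep(sequence=current, score=current_score, mutation=None)]
    for _round in range(config.max_mutations):
        neighbors = enumerate_neighbors(current, config)
        if not neighbors:
            break
        scores = np.asarray(model.predict([s for _, s in neighbors]), dtype=float)
        best = int(np.argmax(scores))
        if scores[best] - current_score < config.min_improvement:
            break
        mutation, current = neighbors[best]
        current_score = float(scores[best])
        steps.append(DesignStep(sequence=current, score=current_score, mutation=mutation))
    return DesignTrajectory(steps=steps, wt_tail=config.wt_tail)


def nominate_natural(
    model,
    tails: dict[str, str],
    required: SubstitutionVariant,
    wt: str = H4_TAIL,
) -> pd.DataFrame:
    """Rank natural tails carrying a required substitution by predicted score.

    Tails whose residue at ``required.position`` is not ``required.alt_aa``
    are excluded (the wild type itself is therefore excluded).  Returns a
    table (id, sequence, score, delta_wt) sorted by score descending.
    """
    kept = {
        k: s
        for k, s in tails.items()
        if len(s) >= required.position and s[required.position - 1] == required.alt_aa
    }
    if not kept:
        warnings.warn(f"no tails carry {required}; empty nomination table")
        return pd.DataFrame(columns=["sequence", "score", "delta_wt"])
    ids = list(kept)
    scores = np.asarray(model.predict([kept[i] for i in ids]), dtype=float)
    wt_score = float(np.asarray(model.predict([wt]))[0])
    return pd.DataFrame(
        {"sequence": [kept[i] for i in ids], "score": scores, "delta_wt": scores - wt_score},
        index=ids,
    ).sort_values("score", ascending=False)


def divergence_report(designed: str, wt: str) -> tuple[float, str]:
    """Fraction of differing positions plus a match/mismatch midline.

    The midline uses ``|`` for identities and ``.`` for substitutions, as in
    a pairwise tail alignment display.
    """
    frac = fraction_difference(designed, wt)
    midline = "".join("|" if a == b else "." for a, b in zip(designed, wt))
    return frac, midline
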