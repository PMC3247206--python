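"""InParanoid-style reciprocal-best-hit ortholog seeds and in-paralogs.

Two species' sequence sets are compared through a bitscore table.
A cross-species pair in which each member is the other's top-scoring
match (a mutual best hit) seeds an ortholog group; within-species
sequences scoring at least as close to a seed as the seed pair scores
to each other join the group as in-paralogs, with a confidence scaled
between the seed-pair score and the seed's self-score.  This is the
documented core of the InParanoid procedure, not a clone of its full
bootstrap/merging machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import pandas as pd


@dataclass
class ScoreTable:
    """Symmetric-access bitscore map with per-species id sets.

    Asymmetric score pairs (a->b differing from b->a, as search tools
    report) are averaged; pairs at or below ``min_bitscore`` are
    dropped.
    """

    species_a: set[str]
    species_b: set[str]
    scores: dict[frozenset, float] = field(default_factory=dict)
    min_bitscore: float = 40.0

    @classmethod
    def from_hits(
        cls,
        cross_hits: pd.DataFrame,
        species_a: set[str],
        species_b: set[str],
        self_hits: pd.DataFrame | None = None,
        min_bitscore: float = 40.0,
    ) -> "ScoreTable":
        table = cls(
            species_a=set(species_a), species_b=set(species_b),
            min_bitscore=min_bitscore,
        )
        acc: dict[frozenset, list[float]] = {}
        frames = [cross_hits] if self_hits is None else [cross_hits, self_hits]
        for frame in frames:
            for row in frame.itertuples(index=False):
                key = frozenset((row.query_id, row.subject_id))
                acc.setdefault(key, []).append(float(row.bitscore))
        for key, vals in acc.items():
            score = sum(vals) / len(vals)
            if score > min_bitscore:
                table.scores[key] = score
        return table

    def get(self, a: str, b: str) -> float | None:
        return self.scores.get(frozenset((a, b)) if a != b else frozenset((a,)))

    def self_score(self, a: str) -> float | None:
        return self.scores.get(frozenset((a,)))

    def cross_partners(self, x: str) -> list[tuple[str, float]]:
        """Cross-species partners of x with scores, best first
        (ties by partner id)."""
        other = self.species_b if x in self.species_a else self.species_a
        pairs = []
        for key, score in self.scores.items():
            if x in key and len(key) == 2:
                (partner,) = key - {x}
                if partner in other:
                    pairs.append((partner, score))
        pairs.sort(key=lambda ps: (-ps[1], ps[0]))
        return pairs

    def within_partners(self, x: str) -> list[tuple[str, float]]:
        own = self.species_a if x in self.species_a else self.species_b
        pairs = []
        for key, score in self.scores.items():
            if x in key and len(key) == 2:
                (partner,) = key - {x}
                if partner in own:
                    pairs.append((partner, score))
        pairs.sort(key=lambda ps: (-ps[1], ps[0]))
        return pairs


@dataclass
class ParalogGroup:
    seed_a: str
    seed_b: str
    seed_score: float
    #: member id -> confidence in [0, 1]; seeds carry 1.0
    members_a: dict[str, float] = field(default_factory=dict)
    members_b: dict[str, float] = field(default_factory=dict)

    @property
    def size_a(self) -> int:
        return len(self.members_a)

    @property
    def size_b(self) -> int:
        return len(self.members_b)


def mutual_best_hits(table: ScoreTable) -> list[tuple[str, str, float]]:
    """Ortholog seed pairs: mutual best cross-species hits.

    Ties in "best" are broken by lexicographic partner id, so the
    result is deterministic.  Seeds form a matching: no id occurs in
    two pairs.
    """
    best: dict[str, str] = {}
    for x in sorted(table.species_a | table.species_b):
        partners = table.cross_partners(x)
        if partners:
            best[x] = partners[0][0]
    seeds = []
    for a in sorted(table.species_a):
        b = best.get(a)
        if b is not None and best.get(b) == a:
            seeds.append((a, b, table.get(a, b)))
    return seeds


def cluster_inparalogs(
    table: ScoreTable, seeds: list[tuple[str, str, float]]
) -> list[ParalogGroup]:
    """Attach within-species in-paralogs to each ortholog seed pair.

    x (species A) joins seed (a, b) when score(x, a) >= score(a, b).
    Confidence is (score(x,a) - score(a,b)) / (score(a,a) - score(a,b))
    when the self-score is known (clamped to [0, 1]), else the ratio
    score(x,a)/score(a,a) capped at 1 — degenerating to 1.0 when no
    self-score exists at all.  A sequence eligible for several groups
    goes to the one where its confidence is highest (ties: higher seed
    score, then lexicographic seed id).
    """
    groups = [
        ParalogGroup(seed_a=a, seed_b=b, seed_score=s,
                     members_a={a: 1.0}, members_b={b: 1.0})
        for a, b, s in seeds
    ]
    seeded = {a for a, _, _ in seeds} | {b for _, b, _ in seeds}
    # candidate assignments: (candidate id, group idx, confidence)
    assignments: dict[str, tuple[float, float, str, int]] = {}
    for gi, grp in enumerate(groups):
        for seed, species in ((grp.seed_a, "A"), (grp.seed_b, "B")):
            seed_cross = grp.seed_score
            self_s = table.self_score(seed)
            for x, score_xs in table.within_partners(seed):
                if x in seeded or score_xs < seed_cross:
                    continue
                if self_s is not None and self_s > seed_cross:
                    conf = (score_xs - seed_cross) / (self_s - seed_cross)
                    conf = min(max(conf, 0.0), 1.0)
                elif self_s is not None and self_s > 0:
                    conf = min(score_xs / self_s, 1.0)
                else:
                    conf = 1.0
                key = (conf, seed_cross, grp.seed_a, gi)
                prev = assignments.get(x)
                # higher confidence, then higher seed score, then
                # lexicographically earlier seed id
                if (
                    prev is None
                    or (key[0], key[1]) > (prev[0], prev[1])
                    or ((key[0], key[1]) == (prev[0], prev[1]) and key[2] < prev[2])
                ):
                    assignments[x] = key
    for x, (conf, _, _, gi) in assignments.items():
        grp = groups[gi]
        if x in table.species_a:
            grp.members_a[x] = round(conf, 3)
        else:
            grp.members_b[x] = round(conf, 3)
    return groups


def group_size_distribution(groups: list[ParalogGroup]) -> Counter:
    """2-D tally of (size_a, size_b) over groups."""
    return Counter((g.size_a, g.size_b) for g in groups)


def n_groups_larger_than(tally: Counter, k: int) -> int:
    """Number of groups whose size in either species exceeds k."""
    return sum(n for (sa, sb), n in tally.items() if sa > k or sb > k)
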