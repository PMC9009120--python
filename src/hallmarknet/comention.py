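"""Sentence-level co-mention counting, Ochiai scoring, curation, and ranking.

Hallmark–disease association strength is measured by the Ochiai
coefficient, a cosine-type co-occurrence score

    OC(H, D) = n_HD / sqrt(n_H * n_D)

where n_H and n_D are the numbers of corpus sentences mentioning the
hallmark and the disease respectively, and n_HD the number co-mentioning
both.  The score normalises for uneven study density: a heavily studied
disease does not dominate simply by being mentioned often.

Downstream steps implemented here: removal of rarely mentioned diseases
(fewer than 250 associated sentences by default), manual-curation
overrides that zero unconfirmed pairs, and per-hallmark top-k ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .lexicon import Matcher

logger = logging.getLogger(__name__)

__all__ = [
    "CoMentionCounts",
    "ScoreMatrix",
    "CurationTable",
    "read_corpus",
    "count_mentions",
    "filter_rare_diseases",
    "ochiai_score",
    "apply_curation",
    "rank_top_k",
]

#: Curation mask states.
UNTESTED = "untested"
CONFIRMED = "confirmed"
ZEROED = "zeroed"


@dataclass
class CoMentionCounts:
    """Sentence-level mention tallies for hallmarks, ARDs, and pairs."""

    n_h: dict[str, int]
    n_d: dict[str, int]
    n_hd: dict[tuple[str, str], int]
    total_sentences: int
    skipped_rows: int = 0

    def __post_init__(self) -> None:
        for (h, d), n in self.n_hd.items():
            cap = min(self.n_h.get(h, 0), self.n_d.get(d, 0))
            if n < 0 or n > cap:
                raise ValueError(f"n_HD({h},{d})={n} exceeds min(n_H, n_D)={cap}")
        if any(v < 0 for v in self.n_h.values()) or any(v < 0 for v in self.n_d.values()):
            raise ValueError("negative mention counts")

    def comention_volume(self, hallmark: str) -> int:
        """Total co-mention sentences for one hallmark, summed over ARDs."""
        return sum(n for (h, _), n in self.n_hd.items() if h == hallmark)


@dataclass
class ScoreMatrix:
    """Hallmark x ARD score matrix with a curation mask.

    ``scores`` is a DataFrame (rows = hallmarks, columns = ARD ids) of
    values in [0, 1]; ``mask`` has the same shape with entries in
    {"untested", "confirmed", "zeroed"}.  Zeroed cells have score 0.
    """

    scores: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.mask.index) or not self.scores.columns.equals(
            self.mask.columns
        ):
            raise ValueError("scores and mask must share index and columns")
        vals = self.scores.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("scores outside [0, 1]")
        zeroed = self.mask.to_numpy() == ZEROED
        if (self.scores.to_numpy()[zeroed] != 0).any():
            raise ValueError("zeroed cells must have score 0")

    @property
    def hallmarks(self) -> list[str]:
        return list(self.scores.index)

    @property
    def ards(self) -> list[str]:
        return list(self.scores.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (hallmark_id, ard_id, score, mask)."""
        long = self.scores.stack().rename("score").reset_index()
        long.columns = ["hallmark_id", "ard_id", "score"]
        long["mask"] = self.mask.stack().to_numpy()
        return long


@dataclass
class CurationTable:
    """Bookkeeping of the manual sentence-curation effort.

    For each (hallmark, ARD) pair the table records how many
    co-mentioning sentences were labelled "confirmed association",
    "no association", "irrelevant", or "error" by curators.
    """

    counts: dict[tuple[str, str], dict[str, int]]

    LABELS = ("confirmed", "no_assoc", "irrelevant", "error")

    def __post_init__(self) -> None:
        for pair, labels in self.counts.items():
            for lab, n in labels.items():
                if n < 0:
                    raise ValueError(f"negative label count for {pair}: {lab}={n}")

    def confirmed(self, hallmark: str, ard: str) -> int | None:
        row = self.counts.get((hallmark, ard))
        return None if row is None else row.get("confirmed", 0)

    @classmethod
    def from_file(cls, path: str | Path) -> "CurationTable":
        df = pd.read_csv(path, sep="\t")
        counts = {
            (r.hallmark_id, r.ard_id): {
                "confirmed": int(r.n_confirmed),
                "no_assoc": int(r.n_no_assoc),
                "irrelevant": int(r.n_irrelevant),
                "error": int(r.n_error),
            }
            for r in df.itertuples()
        }
        return cls(counts)


def read_corpus(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (doc_id, sentence) rows from two-column tab-delimited text."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            yield tuple(line.split("\t", 1))  # type: ignore[misc]


def count_mentions(
    corpus: Iterable[tuple[str, str]],
    hallmark_matcher: Matcher,
    ard_matcher: Matcher,
) -> CoMentionCounts:
    """Tally sentence-level mentions and co-mentions over a corpus.

    Each corpus row is one sentence.  A sentence counts once toward
    n_H / n_D per mentioned entity (duplicate synonym hits collapse) and
    once toward n_HD for every (hallmark, ARD) pair it co-mentions.
    Malformed rows are skipped with a logged warning.
    """
    n_h: dict[str, int] = {e: 0 for e in hallmark_matcher.entity_ids}
    n_d: dict[str, int] = {e: 0 for e in ard_matcher.entity_ids}
    n_hd: dict[tuple[str, str], int] = {}
    total = 0
    skipped = 0
    for row in corpus:
        try:
            _doc_id, sentence = row
        except (TypeError, ValueError):
            skipped += 1
            logger.warning("skipping unreadable corpus row: %r", row)
            continue
        total += 1
        hs = hallmark_matcher.match(sentence)
        ds = ard_matcher.match(sentence)
        for h in hs:
            n_h[h] += 1
        for d in ds:
            n_d[d] += 1
        for h in hs:
            for d in ds:
                n_hd[(h, d)] = n_hd.get((h, d), 0) + 1
    if skipped:
        logger.warning("skipped %d unreadable corpus rows", skipped)
    return CoMentionCounts(n_h=n_h, n_d=n_d, n_hd=n_hd, total_sentences=total, skipped_rows=skipped)


def filter_rare_diseases(
    counts: CoMentionCounts, min_sentences: int = 250
) -> tuple[CoMentionCounts, list[str]]:
    """Drop ARDs with fewer than *min_sentences* associated sentences.

    Returns the filtered counts and the sorted list of excluded ARD ids.
    """
    if min_sentences < 0:
        raise ValueError("min_sentences must be >= 0")
    excluded = sorted(d for d, n in counts.n_d.items() if n < min_sentences)
    keep = set(counts.n_d) - set(excluded)
    filtered = CoMentionCounts(
        n_h=dict(counts.n_h),
        n_d={d: n for d, n in counts.n_d.items() if d in keep},
        n_hd={(h, d): n for (h, d), n in counts.n_hd.items() if d in keep},
        total_sentences=counts.total_sentences,
        skipped_rows=counts.skipped_rows,
    )
    return filtered, excluded


def ochiai_score(counts: CoMentionCounts, squared: bool = False) -> ScoreMatrix:
    """Compute the Ochiai coefficient matrix OC(H,D) = n_HD / sqrt(n_H * n_D).

    Cells where either marginal count is zero score 0.  With
    ``squared=True`` the squared variant n_HD^2 / (n_H * n_D) is
    returned instead (a sensitivity option; same ordering per hallmark
    only when marginals are shared, so use with care).
    """
    hallmarks = sorted(counts.n_h)
    ards = sorted(counts.n_d)
    scores = pd.DataFrame(0.0, index=hallmarks, columns=ards)
    for h in hallmarks:
        nh = counts.n_h[h]
        if nh == 0:
            continue
        for d in ards:
            nd = counts.n_d[d]
            nhd = counts.n_hd.get((h, d), 0)
            if nd == 0 or nhd == 0:
                continue
            oc = nhd / math.sqrt(nh * nd)
            scores.loc[h, d] = oc * oc if squared else oc
    mask = pd.DataFrame(UNTESTED, index=hallmarks, columns=ards)
    return ScoreMatrix(scores=scores, mask=mask)


def apply_curation(
    scores: ScoreMatrix,
    curation: CurationTable,
    counts: CoMentionCounts | None = None,
    volume_threshold: int = 2500,
    comention_volume: Mapping[str, int] | None = None,
) -> ScoreMatrix:
    """Zero unconfirmed pairs according to the manual-curation evidence rule.

    A nonzero-scoring pair is *confirmed* when its count of
    "confirmed association" sentences reaches the required evidence:
    one sentence for hallmarks with fewer than *volume_threshold*
    co-mentioning sentences in total, three otherwise.  Unconfirmed
    pairs are set to score 0 (mask "zeroed"); confirmed pairs keep
    their score (mask "confirmed").  Pairs absent from the curation
    table stay "untested" with a logged warning.  Hallmark co-mention
    volumes come from *counts* or, alternatively, *comention_volume*.
    The operation is idempotent.
    """
    if comention_volume is None:
        if counts is None:
            raise ValueError("provide counts or comention_volume")
        comention_volume = {h: counts.comention_volume(h) for h in scores.hallmarks}
    new_scores = scores.scores.copy()
    new_mask = scores.mask.copy()
    for h in scores.hallmarks:
        required = 1 if comention_volume.get(h, 0) < volume_threshold else 3
        for d in scores.ards:
            if new_scores.loc[h, d] == 0 and new_mask.loc[h, d] != ZEROED:
                continue
            confirmed = curation.confirmed(h, d)
            if confirmed is None:
                logger.warning("pair (%s, %s) missing from curation table", h, d)
                continue
            if confirmed >= required:
                new_mask.loc[h, d] = CONFIRMED
            else:
                new_scores.loc[h, d] = 0.0
                new_mask.loc[h, d] = ZEROED
    return ScoreMatrix(scores=new_scores, mask=new_mask)


def rank_top_k(scores: ScoreMatrix, k: int = 30) -> dict[str, list[tuple[str, float]]]:
    """Per hallmark, the top-k ARDs by score, descending.

    Ties break lexicographically on ARD id; zero-score (including
    curation-zeroed) pairs are never ranked.  If fewer than *k* ARDs
    have nonzero score, all of them are returned with a logged warning.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for h in scores.hallmarks:
        row = scores.scores.loc[h]
        nonzero = [(d, float(s)) for d, s in row.items() if s > 0]
        nonzero.sort(key=lambda t: (-t[1], t[0]))
        if len(nonzero) < k:
            logger.warning(
                "hallmark %s: only %d ARDs with nonzero score (< k=%d)", h, len(nonzero), k
            )
        out[h] = nonzero[:k]
    return out
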