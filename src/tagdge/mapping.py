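"""Tag-to-gene assignment against the virtual reference.

Each distinct clean tag is assigned at the best available tier, in
priority order: perfect sense > one-mismatch sense > perfect antisense
> one-mismatch antisense.  Antisense comparison is against the reverse
complement of the reference tag.  A tag matching more than one gene at
its winning tier is ambiguous and contributes to no gene's expression
value; antisense hits are tallied separately from sense expression,
since they indicate transcription of the opposite strand rather than
abundance of the annotated transcript.

Exact matching behaves as a dictionary lookup; one-mismatch matching is
equivalent to enumerating the 63 single-substitution neighbours of each
query tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import pandas as pd

from .processing import TagLibrary, format_pct
from .reference import TAG_LENGTH, VirtualTag

__all__ = [
    "TagAssignment",
    "MappingSummary",
    "MATCH_CLASSES",
    "match_tags",
    "gene_counts",
    "reverse_complement",
]

MATCH_CLASSES = (
    "perfect_sense",
    "mismatch1_sense",
    "perfect_antisense",
    "mismatch1_antisense",
    "ambiguous",
    "unmatched",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TagAssignment:
    tag: str
    gene_id: Optional[str]  # None when unmatched or ambiguous
    match_class: str
    n_candidate_genes: int
    candidates: tuple[str, ...] = ()


@dataclass
class MappingSummary:
    """Distinct-tag counts per match class and their percentages of all
    distinct clean tags."""

    class_counts: dict[str, int]
    class_pct: dict[str, float]
    distinct: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "match_class": list(self.class_counts),
                "distinct_tags": list(self.class_counts.values()),
                "pct": [self.class_pct[c] for c in self.class_counts],
            }
        )


def _neighbors(tag: str) -> Iterator[str]:
    """All 63 (3 x 21) single-substitution variants of a 21-mer."""
    for i, base in enumerate(tag):
        for sub in "ACGT":
            if sub != base:
                yield tag[:i] + sub + tag[i + 1 :]


def match_tags(
    library: TagLibrary,
    reference: Sequence[VirtualTag],
    max_mismatch: int = 1,
) -> tuple[list[TagAssignment], MappingSummary]:
    """Assign every distinct clean tag to a gene or declare it
    ambiguous/unmatched.

    Assignment is deterministic and independent of input order: at each
    tier the candidate genes are collected as a sorted set and the tag
    is assigned only when exactly one gene remains.
    """
    if not reference:
        raise ValueError("reference tag set is empty")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")

    sense: dict[str, set[str]] = {}
    anti: dict[str, set[str]] = {}
    for vt in reference:
        if len(vt.tag) != TAG_LENGTH:
            raise ValueError(
                f"reference tag {vt.tag!r} has length {len(vt.tag)}, "
                f"expected {TAG_LENGTH}"
            )
        sense.setdefault(vt.tag, set()).add(vt.gene_id)
        anti.setdefault(reverse_complement(vt.tag), set()).add(vt.gene_id)

    assignments: list[TagAssignment] = []
    for tag in library.counts:
        if len(tag) != TAG_LENGTH:
            raise ValueError(
                f"query tag {tag!r} has length {len(tag)}, expected {TAG_LENGTH}"
            )
        neighbors = list(_neighbors(tag)) if max_mismatch >= 1 else []

        tiers: list[tuple[str, set[str]]] = [
            ("perfect_sense", sense.get(tag, set()))
        ]
        if max_mismatch >= 1:
            tiers.append(
                (
                    "mismatch1_sense",
                    set().union(*(sense.get(n, set()) for n in neighbors)),
                )
            )
        tiers.append(("perfect_antisense", anti.get(tag, set())))
        if max_mismatch >= 1:
            tiers.append(
                (
                    "mismatch1_antisense",
                    set().union(*(anti.get(n, set()) for n in neighbors)),
                )
            )

        for tier_class, genes in tiers:
            if genes:
                candidates = tuple(sorted(genes))
                if len(candidates) == 1:
                    assignments.append(
                        TagAssignment(tag, candidates[0], tier_class, 1, candidates)
                    )
                else:
                    assignments.append(
                        TagAssignment(
                            tag, None, "ambiguous", len(candidates), candidates
                        )
                    )
                break
        else:
            assignments.append(TagAssignment(tag, None, "unmatched", 0))

    class_counts = {c: 0 for c in MATCH_CLASSES}
    for a in assignments:
        class_counts[a.match_class] += 1
    distinct = len(assignments)
    class_pct = {
        c: format_pct(100.0 * n / distinct) if distinct else 0.0
        for c, n in class_counts.items()
    }
    return assignments, MappingSummary(class_counts, class_pct, distinct)


def gene_counts(
    assignments: Sequence[TagAssignment], library: TagLibrary
) -> pd.DataFrame:
    """Per-gene expression from sense-assigned tags.

    Antisense-assigned tag counts are tallied in a separate column and
    excluded from the expression value; ambiguous and unmatched tags
    contribute to neither.
    """
    sense_total: dict[str, int] = {}
    anti_total: dict[str, int] = {}
    for a in assignments:
        if a.gene_id is None:
            continue
        n = library.counts[a.tag]
        if a.match_class in ("perfect_sense", "mismatch1_sense"):
            sense_total[a.gene_id] = sense_total.get(a.gene_id, 0) + n
        else:
            anti_total[a.gene_id] = anti_total.get(a.gene_id, 0) + n
    genes = sorted(set(sense_total) | set(anti_total))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "count": [sense_total.get(g, 0) for g in genes],
            "antisense_count": [anti_total.get(g, 0) for g in genes],
        }
    )
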