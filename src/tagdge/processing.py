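"""Clean-tag extraction and library-level summaries.

Raw DGE reads (49 bp: a 21-base CATG-anchored tag followed by the 3'
adaptor) are reduced to a multiset of clean 21-mers.  A read is clean
when its leading 21-mer starts with CATG and contains no ambiguous
base; reads that are adaptor sequence from the start are tallied as
adaptor-only.  The module also computes the copy-number distribution of
distinct tags (the standard library-quality table) and a sequencing
saturation curve: genes detected as a function of tags sampled.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import ANCHOR, TAG_LENGTH, VirtualTag

__all__ = [
    "TagLibrary",
    "CopyNumberDistribution",
    "COPY_NUMBER_BINS",
    "clean_tags",
    "copy_number_distribution",
    "saturation_curve",
    "read_raw_reads",
    "write_library_tsv",
    "read_library_tsv",
]

_VALID_BASES = frozenset("ACGT")

# (label, low, high) with inclusive bounds on the tag copy number
COPY_NUMBER_BINS = (
    ("<2", 1, 1),
    ("2-5", 2, 5),
    ("6-10", 6, 10),
    ("11-20", 11, 20),
    ("21-50", 21, 50),
    ("51-100", 51, 100),
    (">100", 101, None),
)


@dataclass
class TagLibrary:
    """Per-library clean-tag counts.

    ``total_clean`` is the library size used to normalise the
    differential test (the N1 or N2 of the two-library comparison).
    """

    name: str = ""
    counts: Counter = field(default_factory=Counter)
    total_raw: int = 0
    adaptor_only: int = 0

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> int:
        return sum(1 for c in self.counts.values() if c >= 1)

    @property
    def distinct_multicopy(self) -> int:
        """Distinct tags seen at least twice ("unique tags" after
        excluding single-copy tags)."""
        return sum(1 for c in self.counts.values() if c >= 2)


@dataclass(frozen=True)
class CopyNumberDistribution:
    labels: tuple[str, ...]
    counts: tuple[int, ...]
    percentages: tuple[float, ...]
    distinct: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.labels, "distinct_tags": self.counts, "pct": self.percentages}
        )


def _is_clean(tag: str) -> bool:
    return tag.startswith(ANCHOR) and not (set(tag) - _VALID_BASES)


def clean_tags(
    reads: Iterable[str], adaptor: str = "", name: str = ""
) -> TagLibrary:
    """Reduce raw reads to a clean-tag library.

    The leading 21-mer of each read is kept when it starts with CATG and
    has no ambiguous base.  Failing reads whose prefix equals the start
    of ``adaptor`` are counted as adaptor-only; everything else failing
    the anchor check is dropped as low quality.
    """
    lib = TagLibrary(name=name)
    for read in reads:
        read = read.upper()
        lib.total_raw += 1
        tag = read[:TAG_LENGTH]
        if len(tag) < TAG_LENGTH:
            continue
        if _is_clean(tag):
            lib.counts[tag] += 1
        elif adaptor and read.startswith(adaptor[:TAG_LENGTH]):
            lib.adaptor_only += 1
    if lib.total_raw == 0:
        warnings.warn(f"empty read input for library {name!r}")
    return lib


def format_pct(value: float) -> float:
    """Percentage rounded to 2 decimals (round-half-even)."""
    return round(value, 2)


def copy_number_distribution(library: TagLibrary) -> CopyNumberDistribution:
    """Bin distinct tags by copy number; percentages over distinct tags."""
    counts = []
    for _, low, high in COPY_NUMBER_BINS:
        n = sum(
            1
            for c in library.counts.values()
            if c >= low and (high is None or c <= high)
        )
        counts.append(n)
    distinct = library.distinct
    pct = [format_pct(100.0 * n / distinct) if distinct else 0.0 for n in counts]
    return CopyNumberDistribution(
        labels=tuple(label for label, _, _ in COPY_NUMBER_BINS),
        counts=tuple(counts),
        percentages=tuple(pct),
        distinct=distinct,
    )


def saturation_curve(
    library: TagLibrary,
    reference: Sequence[VirtualTag],
    step: int = 100_000,
    seed: int = 0,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Genes detected vs. sequencing depth, by seeded subsampling.

    Tags are drawn without replacement in a random order; after every
    ``step`` tags (and at the full depth) the number of distinct genes
    with at least one sense- or antisense-matched tag is recorded.  The
    curve is non-decreasing by construction and plateaus once every
    detectable gene has been seen.
    """
    from .mapping import match_tags

    if not reference:
        raise ValueError("reference tag set is empty")
    if step < 1:
        raise ValueError("step must be >= 1")

    depth = library.total_clean
    if depth == 0:
        return pd.DataFrame(columns=["tags_sampled", "genes_detected"])

    assignments, _ = match_tags(library, reference, max_mismatch=max_mismatch)
    gene_of = {
        a.tag: a.gene_id for a in assignments if a.gene_id is not None
    }

    tags = list(library.counts.keys())
    reps = np.fromiter(library.counts.values(), dtype=np.int64, count=len(tags))
    order = np.repeat(np.arange(len(tags)), reps)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)

    seen_genes: set[str] = set()
    rows = []
    checkpoints = set(range(step, depth + 1, step)) | {depth}
    for i, tag_idx in enumerate(order, start=1):
        gene = gene_of.get(tags[tag_idx])
        if gene is not None:
            seen_genes.add(gene)
        if i in checkpoints:
            rows.append((i, len(seen_genes)))
    return pd.DataFrame(rows, columns=["tags_sampled", "genes_detected"])


def read_raw_reads(path) -> list[str]:
    """Read raw reads from FASTQ or a 1-column TSV/plain list of tags."""
    path = str(path)
    if path.endswith((".fastq", ".fq")):
        from Bio import SeqIO

        return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_library_tsv(library: TagLibrary, path) -> None:
    pd.DataFrame(
        sorted(library.counts.items()), columns=["tag", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_library_tsv(path, name: str = "") -> TagLibrary:
    df = pd.read_csv(path, sep="\t")
    lib = TagLibrary(name=name)
    lib.counts = Counter(dict(zip(df["tag"], df["count"].astype(int))))
    lib.total_raw = int(df["count"].sum())
    return lib
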