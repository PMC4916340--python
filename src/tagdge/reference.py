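"""Virtual reference-tag extraction from transcript sequences.

A DGE tag library anchors every sequenced tag at an NlaIII restriction
site (CATG); MmeI then cuts 17 bp downstream, so each transcript
contributes a predictable 21-base "virtual tag" (CATG + 17 bases) from
its 3'-most usable CATG site.  Building the set of virtual tags for a
transcriptome gives the reference against which sequenced tags are
matched.  A 21-mer shared verbatim by more than one gene cannot be
assigned uniquely and is flagged ambiguous.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

ANCHOR = "CATG"
DOWNSTREAM = 17
TAG_LENGTH = len(ANCHOR) + DOWNSTREAM  # 21

__all__ = [
    "VirtualTag",
    "ReferenceSummary",
    "extract_virtual_tags",
    "summarize_reference",
    "read_transcripts",
    "write_tags_tsv",
    "read_tags_tsv",
]


@dataclass(frozen=True)
class VirtualTag:
    """A CATG-anchored 21-base reference tag tied to one gene.

    ``site_rank`` is 1 for the 3'-most usable CATG site and increases
    toward the 5' end.  ``ambiguous`` is set when the identical 21-mer
    is extracted from more than one gene.
    """

    gene_id: str
    tag: str
    site_offset: int
    site_rank: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LENGTH:
            raise ValueError(f"tag must be {TAG_LENGTH} bases, got {len(self.tag)}")
        if not self.tag.startswith(ANCHOR):
            raise ValueError(f"tag must start with {ANCHOR}: {self.tag}")


@dataclass(frozen=True)
class ReferenceSummary:
    n_genes_total: int
    n_genes_with_catg: int
    n_unambiguous_tags: int
    n_ambiguous_tags: int

    @property
    def pct_genes_with_catg(self) -> float:
        if self.n_genes_total == 0:
            return 0.0
        return round(100.0 * self.n_genes_with_catg / self.n_genes_total, 2)


def read_transcripts(fasta_path) -> dict[str, str]:
    """Read a transcript FASTA into an id -> uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def _usable_sites(seq: str) -> list[int]:
    """0-based offsets of CATG sites with >= 17 downstream bases and no N
    in the 21-base window, ordered 3' -> 5'."""
    sites = []
    start = seq.find(ANCHOR)
    while start != -1:
        window = seq[start : start + TAG_LENGTH]
        if len(window) == TAG_LENGTH and "N" not in window:
            sites.append(start)
        start = seq.find(ANCHOR, start + 1)
    sites.reverse()
    return sites


def extract_virtual_tags(
    transcripts: Mapping[str, str], sites_per_gene: int = 1
) -> list[VirtualTag]:
    """Extract up to ``sites_per_gene`` virtual tags per transcript.

    Sites are taken from the 3' end inward; a CATG with fewer than 17
    downstream bases, or with an N inside the 21-base window, is skipped
    in favour of the next site toward 5'.  Identical 21-mers appearing
    in more than one gene are all flagged ambiguous.
    """
    if sites_per_gene < 1:
        raise ValueError("sites_per_gene must be >= 1")
    if not transcripts:
        warnings.warn("empty transcript set: no virtual tags extracted")
        return []

    raw: list[VirtualTag] = []
    for gene_id, seq in transcripts.items():
        seq = seq.upper()
        for rank, offset in enumerate(_usable_sites(seq)[:sites_per_gene], start=1):
            raw.append(
                VirtualTag(
                    gene_id=gene_id,
                    tag=seq[offset : offset + TAG_LENGTH],
                    site_offset=offset,
                    site_rank=rank,
                )
            )

    genes_by_tag: dict[str, set[str]] = defaultdict(set)
    for vt in raw:
        genes_by_tag[vt.tag].add(vt.gene_id)

    return [
        VirtualTag(
            gene_id=vt.gene_id,
            tag=vt.tag,
            site_offset=vt.site_offset,
            site_rank=vt.site_rank,
            ambiguous=len(genes_by_tag[vt.tag]) > 1,
        )
        for vt in raw
    ]


def summarize_reference(
    tags: Iterable[VirtualTag], n_genes_total: int
) -> ReferenceSummary:
    """Tally CATG-bearing genes and unambiguous/ambiguous tag counts."""
    tags = list(tags)
    genes = {vt.gene_id for vt in tags}
    if n_genes_total < len(genes):
        raise ValueError(
            f"n_genes_total={n_genes_total} is less than the "
            f"{len(genes)} distinct genes present in the tag set"
        )
    n_ambiguous = sum(1 for vt in tags if vt.ambiguous)
    return ReferenceSummary(
        n_genes_total=n_genes_total,
        n_genes_with_catg=len(genes),
        n_unambiguous_tags=len(tags) - n_ambiguous,
        n_ambiguous_tags=n_ambiguous,
    )


def write_tags_tsv(tags: Iterable[VirtualTag], path) -> None:
    pd.DataFrame(
        [
            (vt.gene_id, vt.tag, vt.site_offset, vt.site_rank, vt.ambiguous)
            for vt in tags
        ],
        columns=["gene_id", "tag", "site_offset", "site_rank", "ambiguous"],
    ).to_csv(path, sep="\t", index=False)


def read_tags_tsv(path) -> list[VirtualTag]:
    df = pd.read_csv(path, sep="\t", dtype={"ambiguous": bool})
    return [
        VirtualTag(
            gene_id=str(r.gene_id),
            tag=str(r.tag),
            site_offset=int(r.site_offset),
            site_rank=int(r.site_rank),
            ambiguous=bool(r.ambiguous),
        )
        for r in df.itertuples()
    ]
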