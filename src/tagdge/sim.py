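"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a two-library DGE tag-profiling experiment:

* a transcriptome whose CATG content is controlled, so the fraction of
  genes yielding a virtual tag is known;
* two tag libraries drawn from per-gene abundances (log-normal, then
  renormalised — heavy-tailed, matching the preponderance of low-copy
  tags in real libraries), with a designated fraction of genes perturbed
  by a known log2 effect (half up, half down, keeping the library
  composition comparable), per-base substitution errors, and a fraction
  of tags emitted from the reverse-complement strand (antisense
  transcription is a real feature of DGE libraries, on the order of a
  fifth of tags);
* OJIP fluorescence transients built from saturating-exponential phases
  so that the standard marks (Fo at 50 us, Fj at 2 ms, Fi at 30 ms,
  Fm at the plateau) take exactly the requested values;
* qPCR Ct tables whose delta-delta-Ct estimate returns the designed
  fold changes exactly at zero noise.

All randomness flows from a single integer seed; identical
configurations give bit-identical artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .jip import FluorTransient
from .reference import ANCHOR, DOWNSTREAM, TAG_LENGTH, extract_virtual_tags

__all__ = [
    "SimConfig",
    "SimTruth",
    "DEFAULT_ADAPTOR",
    "simulate_transcriptome",
    "simulate_tag_libraries",
    "simulate_ojip",
    "simulate_qpcr",
    "write_fasta",
    "write_fastq",
    "default_ojip_grid",
]

# fixed stand-in for the proprietary GEX 3' adaptor; any constant works
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTGAAAAAAA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_READ_LENGTH = 49


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated two-library tag experiment."""

    seed: int = 0
    n_genes: int = 200
    transcript_length_range: tuple[int, int] = (300, 2000)
    catg_probability: float = 1.0
    depth_per_library: int = 100_000
    deg_fraction: float = 0.05
    log2_effect: float = 2.0
    error_rate: float = 0.001
    antisense_fraction: float = 0.18
    abundance_dispersion: float = 1.5
    adaptor: str = DEFAULT_ADAPTOR

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.depth_per_library < 0:
            raise ValueError("depth_per_library must be >= 0")
        for name in (
            "catg_probability",
            "deg_fraction",
            "error_rate",
            "antisense_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.transcript_length_range
        if lo < TAG_LENGTH + 1 or hi < lo:
            raise ValueError(
                "transcript_length_range must be an increasing pair with "
                f"minimum > {TAG_LENGTH}"
            )
        if self.abundance_dispersion < 0:
            raise ValueError("abundance_dispersion must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated libraries.

    ``table`` has one row per gene: true relative abundance in each
    condition (each column sums to 1), the designed log2 fold change
    (0 for unperturbed genes) and the DEG indicator.  ``emitted_counts``
    records how many sense/antisense tag reads were actually drawn per
    gene and library, for exact bookkeeping tests.
    """

    table: pd.DataFrame
    emitted_counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def _random_seq_without_anchor(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random uint8 base array with every CATG occurrence scrubbed."""
    arr = rng.choice(_BASES, size=length)
    anchor = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)
    while True:
        view = np.lib.stride_tricks.sliding_window_view(arr, len(anchor))
        hits = np.nonzero((view == anchor).all(axis=1))[0]
        if hits.size == 0:
            return arr
        for pos in hits:
            arr[pos] = rng.choice(_BASES[_BASES != arr[pos]])


def simulate_transcriptome(config: SimConfig) -> dict[str, str]:
    """Generate ``n_genes`` transcripts; a fraction ``catg_probability``
    are guaranteed one usable CATG site (>= 17 downstream bases), the
    rest are guaranteed CATG-free."""
    rng = _rng(config.seed, 0)
    lo, hi = config.transcript_length_range
    transcripts: dict[str, str] = {}
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene_id = f"gene{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        arr = _random_seq_without_anchor(rng, length)
        if rng.random() < config.catg_probability:
            # place the anchor so that >= 17 bases remain downstream
            pos = int(rng.integers(0, length - TAG_LENGTH + 1))
            arr[pos : pos + len(ANCHOR)] = np.frombuffer(
                ANCHOR.encode(), dtype=np.uint8
            )
            # scrubbing may be needed again downstream of the insertion?
            # no: inserting CATG cannot be undone, and extra accidental
            # anchors created at the junction are harmless (3'-most wins)
        transcripts[gene_id] = arr.tobytes().decode()
    return transcripts


def _apply_substitutions(
    reads: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-base substitution errors on a (n_reads, 21) uint8 array."""
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err:
        # draw a uniformly random *different* base at each error site
        shifts = rng.integers(1, 4, size=n_err)
        idx = np.searchsorted(_BASES, reads[mask])
        reads[mask] = _BASES[(idx + shifts) % 4]
    return reads


_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def _revcomp_rows(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][:, ::-1]


def _draw_library(
    tag_matrix: np.ndarray,
    abundances: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Draw one library of reads.  Returns (reads, sense counts,
    antisense counts) per gene."""
    n_genes = tag_matrix.shape[0]
    counts = rng.multinomial(config.depth_per_library, abundances)
    gene_idx = np.repeat(np.arange(n_genes), counts)
    rng.shuffle(gene_idx)

    reads = tag_matrix[gene_idx].copy()
    anti = rng.random(len(gene_idx)) < config.antisense_fraction
    if anti.any():
        reads[anti] = _revcomp_rows(reads[anti])
    reads = _apply_substitutions(reads, config.error_rate, rng)

    adaptor = (config.adaptor * 3)[: _READ_LENGTH - TAG_LENGTH]
    read_strings = [
        row.tobytes().decode() + adaptor for row in reads
    ]
    sense_counts = np.bincount(gene_idx[~anti], minlength=n_genes)
    anti_counts = np.bincount(gene_idx[anti], minlength=n_genes)
    return read_strings, sense_counts, anti_counts


def simulate_tag_libraries(
    transcripts: Mapping[str, str],
    config: SimConfig,
    abundances: Optional[Mapping[str, float]] = None,
) -> tuple[list[str], list[str], SimTruth]:
    """Draw two 49-bp read libraries from known per-gene abundances.

    Abundances are log-normal (scale ``abundance_dispersion``) and
    renormalised; genes without a usable CATG tag receive abundance 0
    (they cannot emit a tag).  A ``deg_fraction`` of taggable genes is
    perturbed in condition 2 by ``2**±log2_effect``, half up and half
    down.  Reads are the gene's canonical 21-base tag — reverse
    complemented with probability ``antisense_fraction``, substituted
    per base at ``error_rate`` — padded with the 3' adaptor to 49 bases.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    genes = list(transcripts)
    vtags = {vt.gene_id: vt.tag for vt in extract_virtual_tags(transcripts)}

    rng = _rng(config.seed, 1)
    if abundances is None:
        raw = np.where(
            [g in vtags for g in genes],
            rng.lognormal(0.0, config.abundance_dispersion, size=len(genes)),
            0.0,
        )
    else:
        raw = np.array([abundances.get(g, 0.0) for g in genes], dtype=float)
        bad = [g for g, a in zip(genes, raw) if a > 0 and g not in vtags]
        if bad:
            raise ValueError(
                f"genes with nonzero abundance but no usable CATG tag: {bad[:5]}"
            )
    if raw.sum() <= 0:
        raise ValueError("no gene has positive abundance")
    a1 = raw / raw.sum()

    taggable = np.nonzero(a1 > 0)[0]
    n_deg = int(round(config.deg_fraction * taggable.size))
    deg_idx = rng.choice(taggable, size=n_deg, replace=False)
    log2fc = np.zeros(len(genes))
    half = n_deg // 2
    log2fc[deg_idx[:half]] = config.log2_effect
    log2fc[deg_idx[half:]] = -config.log2_effect
    a2 = a1 * np.exp2(log2fc)
    a2 /= a2.sum()

    if config.depth_per_library == 0:
        warnings.warn("depth_per_library is 0: libraries are empty")
        reads1, reads2 = [], []
        zero = np.zeros(len(genes), dtype=int)
        s1 = a1_anti = s2 = a2_anti = zero
    else:
        tag_matrix = np.zeros((len(genes), TAG_LENGTH), dtype=np.uint8)
        for i, g in enumerate(genes):
            if g in vtags:
                tag_matrix[i] = np.frombuffer(vtags[g].encode(), dtype=np.uint8)
        reads1, s1, a1_anti = _draw_library(tag_matrix, a1, config, rng)
        reads2, s2, a2_anti = _draw_library(tag_matrix, a2, config, rng)

    truth = SimTruth(
        table=pd.DataFrame(
            {
                "gene_id": genes,
                "abundance_1": a1,
                "abundance_2": a2,
                "log2fc": log2fc,
                "is_deg": log2fc != 0,
            }
        ),
        emitted_counts=pd.DataFrame(
            {
                "gene_id": genes,
                "lib1_sense": s1,
                "lib1_antisense": a1_anti,
                "lib2_sense": s2,
                "lib2_antisense": a2_anti,
            }
        ),
    )
    return reads1, reads2, truth


def default_ojip_grid() -> np.ndarray:
    """The instrument acquisition grid: 10 us steps to 2 ms, then 1 ms
    steps to 1 s."""
    fast = np.arange(10e-6, 2e-3 + 1e-9, 10e-6)
    slow = np.arange(3e-3, 1.0 + 1e-9, 1e-3)
    return np.concatenate([fast, slow])


_OJIP_TAUS = (4e-4, 6e-3, 1.2e-1)  # phase half-times for J, I, P rises
_OJIP_T0 = 50e-6  # rise onset: Fo is read here


def simulate_ojip(
    marks: Sequence[float],
    noise_sd: float = 0.0,
    grid: Optional[np.ndarray] = None,
    seed: int = 0,
) -> FluorTransient:
    """Build an O-J-I-P transient passing exactly through the target
    marks (Fo, Fj, Fi, Fm) at 50 us, 2 ms, 30 ms and the final plateau.

    The curve is Fo plus a sum of three saturating exponential phases
    starting at 50 us; the amplitudes solve a 3x3 linear system so the
    trace hits Fj, Fi and Fm at their defining times.  Optional Gaussian
    noise of standard deviation ``noise_sd`` is added pointwise.
    """
    fo, fj, fi, fm = (float(v) for v in marks)
    if not fo <= fj <= fi <= fm:
        raise ValueError(
            f"marks must be non-decreasing (Fo <= Fj <= Fi <= Fm), got "
            f"({fo}, {fj}, {fi}, {fm})"
        )
    if grid is None:
        grid = default_ojip_grid()
    grid = np.asarray(grid, dtype=float)

    anchor_times = np.array([2e-3, 3e-2, grid[-1]])
    phases = 1.0 - np.exp(
        -np.maximum(anchor_times[:, None] - _OJIP_T0, 0.0) / np.array(_OJIP_TAUS)
    )
    amplitudes = np.linalg.solve(phases, np.array([fj, fi, fm]) - fo)

    t = np.maximum(grid - _OJIP_T0, 0.0)
    F = fo + (1.0 - np.exp(-t[:, None] / np.array(_OJIP_TAUS))) @ amplitudes
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, size=F.shape)
    return FluorTransient(time=grid, F=F)


def simulate_qpcr(
    true_fold_changes: Mapping[str, float],
    reference_ct: float = 20.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table (gene, group, bio_rep, tech_rep, ct) whose delta-delta-Ct
    estimate equals the designed fold changes exactly at zero noise.

    Each gene's control dCt is drawn once (uniform 1-8 cycles above the
    reference); the treatment Ct is shifted by -log_eff(fold).  Gaussian
    noise of ``noise_sd`` cycles is added to every well, reference wells
    included.
    """
    folds = dict(true_fold_changes)
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    log_eff = np.log(efficiency)
    rows = []
    base_dct = {g: float(rng.uniform(1.0, 8.0)) for g in folds}
    for group in ("control", "treatment"):
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                rows.append(("GAPDH", group, bio, tech, reference_ct))
                for gene, fold in folds.items():
                    ct = reference_ct + base_dct[gene]
                    if group == "treatment":
                        ct -= np.log(fold) / log_eff
                    rows.append((gene, group, bio, tech, ct))
    df = pd.DataFrame(rows, columns=["gene", "group", "bio_rep", "tech_rep", "ct"])
    if noise_sd > 0:
        df["ct"] = df["ct"] + rng.normal(0.0, noise_sd, size=len(df))
    return df


def write_fasta(transcripts: Mapping[str, str], path_or_handle) -> None:
    def _write(fh):
        for gene_id, seq in transcripts.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _write(fh)


def write_fastq(reads: Sequence[str], path, prefix: str = "read") -> None:
    """Write reads as FASTQ with a constant dummy quality string."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads, start=1):
            fh.write(f"@{prefix}{i}\n{read}\n+\n{'I' * len(read)}\n")
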