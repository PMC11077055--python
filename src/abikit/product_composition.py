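"""Length and nucleotide-content profiling of sequenced polymerase products.

Protein-primed terminal-transferase products keep the priming residue on the
5' end of the original strand, so after proteinase digestion only the
*complementary* strand receives adaptors and is sequenced.  Reported base
frequencies are therefore complement-mapped back to the original strand
(A<->T, C<->G) when ``strand_mode="complement"``.

Frequencies are pooled over all bases of all reads; N bases are excluded from
the denominator (the N fraction is reported separately).  Per-read counts are
also emitted, matching the surface of a standard per-read composition table.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.read_id!r}: invalid base(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CompositionSummary:
    """Sample-level composition: pooled original-strand base frequencies and
    the read-length distribution."""

    label: str
    read_count: int
    frequencies: dict[str, float]
    n_fraction: float
    length_quantiles: dict[str, float]
    per_read: pd.DataFrame = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label": self.label,
            "read_count": self.read_count,
            "frequencies": self.frequencies,
            "n_fraction": self.n_fraction,
            "length_quantiles": self.length_quantiles,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a 4-line FASTQ (plain or .gz); qualities are checked but unused."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    reads: list[ReadRecord] = []
    try:
        with opener(path, "rt") as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                reads.append(ReadRecord(title.split()[0], seq.upper()))
    except ValueError as exc:
        # FastqGeneralIterator validates structure; localize the failure
        raise ValueError(
            f"{path}: malformed FASTQ near record {len(reads) + 1} "
            f"(approx. line {4 * len(reads) + 1}): {exc}"
        ) from exc
    return reads


def base_counts(sequence: str) -> dict[str, int]:
    """Counts of A, C, G, T and N in one sequence."""
    seq = sequence.upper()
    return {b: seq.count(b) for b in (*BASES, "N")}


def to_original_strand(counts: Mapping[str, int | float]) -> dict[str, int | float]:
    """Complement-map counts (A<->T, C<->G); N unchanged.  An involution."""
    return {_COMPLEMENT[b]: v for b, v in counts.items()}


def per_read_table(
    reads: Sequence[ReadRecord], strand_mode: str = "as_is"
) -> pd.DataFrame:
    """Per-read length and base counts (complement-mapped when requested)."""
    _check_mode(strand_mode)
    rows = []
    for read in reads:
        counts = base_counts(read.sequence)
        if strand_mode == "complement":
            counts = to_original_strand(counts)
        rows.append((read.read_id, len(read), *[counts[b] for b in (*BASES, "N")]))
    return pd.DataFrame(rows, columns=["read_id", "length", *BASES, "N"])


def sample_summary(
    reads: Sequence[ReadRecord],
    strand_mode: str = "as_is",
    label: str = "",
    min_len: int | None = None,
    max_len: int | None = None,
) -> CompositionSummary:
    """Pooled base frequencies and length quantiles over all reads.

    ``strand_mode="complement"`` reports original-strand frequencies when the
    sequenced strand is the complement of the synthesized product.  Optional
    length filters restrict the read set (no filtering by default).
    """
    _check_mode(strand_mode)
    if min_len is not None or max_len is not None:
        reads = [
            r
            for r in reads
            if (min_len is None or len(r) >= min_len)
            and (max_len is None or len(r) <= max_len)
        ]
    if not reads:
        raise ValueError("no reads to summarize")
    table = per_read_table(reads, strand_mode)
    totals = table[[*BASES, "N"]].sum()
    informative = int(totals[list(BASES)].sum())
    if informative:
        freqs = {b: float(totals[b]) / informative for b in BASES}
        total = sum(freqs.values())
        assert math.isclose(total, 1.0, abs_tol=1e-12)
    else:
        freqs = {b: float("nan") for b in BASES}
    lengths = table["length"].to_numpy()
    quantiles = {
        "min": float(lengths.min()),
        "q1": float(np.quantile(lengths, 0.25)),
        "median": float(np.quantile(lengths, 0.5)),
        "q3": float(np.quantile(lengths, 0.75)),
        "max": float(lengths.max()),
        "mean": float(lengths.mean()),
    }
    return CompositionSummary(
        label=label,
        read_count=len(reads),
        frequencies=freqs,
        n_fraction=float(totals["N"]) / float(totals.sum()),
        length_quantiles=quantiles,
        per_read=table,
    )


def _check_mode(strand_mode: str) -> None:
    if strand_mode not in ("as_is", "complement"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
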