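"""Partitioning a merged protein set into homolog families.

Two proteins are called homologous when their best local alignment (BLOSUM62,
affine gaps) reaches at least ``min_identity`` over the alignment columns AND
covers at least ``min_coverage`` of *both* full-length sequences
(bidirectional coverage).  Homolog families are the connected components of
the resulting graph — the classic greedy single-linkage protein clustering
used for gene-sharing analyses.  Identity counts identical aligned residue
pairs over *all* alignment columns, gap columns included.

For desk-scale inputs (<= 2,000 proteins by default) every pair is aligned;
for larger sets a shared-k-mer prefilter can be enabled to restrict alignment
to candidate pairs.  The prefilter is a heuristic: a homologous pair with no
shared exact k-mer would be missed, so exact mode is the default wherever it
is affordable.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .proteome_io import Protein, ProteomeSet

logger = logging.getLogger(__name__)

#: above this many proteins, candidate generation defaults to the k-mer prefilter
EXACT_MODE_MAX_PROTEINS = 2000


@dataclass(frozen=True)
class ClusteringParams:
    """Thresholds and scoring for homolog-family clustering.

    Defaults mirror common homology-search practice: identity >= 0.3 and
    bidirectional coverage >= 0.7 on a BLOSUM62 local alignment with gap
    open 11 / extend 1.
    """

    min_identity: float = 0.3
    min_coverage: float = 0.7
    coverage_mode: str = "both_sequences"
    graph_mode: str = "connected_component"
    prefilter_k: int = 5
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in [0, 1]")
        if self.prefilter_k < 3:
            raise ValueError("prefilter_k must be >= 3")
        if self.coverage_mode != "both_sequences":
            raise ValueError(f"unsupported coverage_mode {self.coverage_mode!r}")
        if self.graph_mode != "connected_component":
            raise ValueError(f"unsupported graph_mode {self.graph_mode!r}")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass(frozen=True)
class PairStats:
    """Summary of the best local alignment of one protein pair.

    identity
        identical aligned residue pairs / total alignment columns (gap
        columns included).
    coverage_a, coverage_b
        fraction of each full-length sequence spanned by the aligned region.
    score
        raw alignment score (substitution-matrix units).
    """

    identity: float
    coverage_a: float
    coverage_b: float
    score: float


class HomologFamilies:
    """A partition of protein ids into named homolog families.

    Family names are deterministic: each family is named after its
    lexicographically smallest member id.
    """

    def __init__(self, families: Iterable[Iterable[str]]):
        self.families: dict[str, frozenset[str]] = {}
        self.family_of: dict[str, str] = {}
        for members in families:
            fam = frozenset(members)
            if not fam:
                raise ValueError("empty family")
            name = min(fam)
            if name in self.families:
                raise ValueError(f"family name collision on {name!r}")
            self.families[name] = fam
            for pid in fam:
                if pid in self.family_of:
                    raise ValueError(f"protein {pid!r} assigned to two families")
                self.family_of[pid] = name

    def __len__(self) -> int:
        return len(self.families)

    def __getitem__(self, family_id: str) -> frozenset[str]:
        return self.families[family_id]

    def validate_partition(self, protein_ids: Iterable[str]) -> None:
        """Assert the families exactly partition ``protein_ids``."""
        expected = set(protein_ids)
        covered = set(self.family_of)
        if covered != expected:
            raise AssertionError(
                "families do not partition the protein set: "
                f"{len(expected - covered)} uncovered, {len(covered - expected)} extra"
            )

    def size_histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(len(f) for f in self.families.values()).items()))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tfamily_id\n")
            for pid in sorted(self.family_of):
                fh.write(f"{pid}\t{self.family_of[pid]}\n")

    @classmethod
    def from_tsv(cls, path) -> "HomologFamilies":
        groups: dict[str, set[str]] = defaultdict(set)
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "protein_id\tfamily_id":
                raise ValueError(f"{path}: unexpected header {header!r}")
            for line in fh:
                pid, fam = line.rstrip("\n").split("\t")
                groups[fam].add(pid)
        return cls(groups.values())


def _make_aligner(params: ClusteringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(params.substitution_matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    a: Protein | str,
    b: Protein | str,
    params: ClusteringParams = ClusteringParams(),
    aligner: Align.PairwiseAligner | None = None,
) -> PairStats:
    """Best local alignment of two protein sequences, as :class:`PairStats`.

    A gap of length L scores ``-(gap_open + (L - 1) * gap_extend)``.
    Symmetric under argument swap up to exchanging coverage_a/coverage_b.
    """
    seq_a = a.sequence if isinstance(a, Protein) else a
    seq_b = b.sequence if isinstance(b, Protein) else b
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = _make_aligner(params)
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    # local alignment: only internal gaps contribute columns
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    identities = counts.identities
    blocks_a, blocks_b = alignment.aligned
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    return PairStats(
        identity=identities / columns if columns else 0.0,
        coverage_a=span_a / len(seq_a),
        coverage_b=span_b / len(seq_b),
        score=float(alignment.score),
    )


def candidate_pairs(
    ps: ProteomeSet,
    params: ClusteringParams = ClusteringParams(),
    exact: bool | None = None,
) -> Iterator[tuple[str, str]]:
    """Yield unordered candidate protein-id pairs, each exactly once.

    In exact mode (default for <= 2,000 proteins) every pair is yielded.  In
    prefilter mode only pairs sharing at least one exact k-mer of length
    ``prefilter_k`` are yielded.  Pairs are emitted in sorted order for
    determinism.
    """
    ids = sorted(p.protein_id for p in ps)
    if exact is None:
        exact = len(ids) <= EXACT_MODE_MAX_PROTEINS
    if exact:
        yield from itertools.combinations(ids, 2)
        return
    k = params.prefilter_k
    by_kmer: dict[str, list[str]] = defaultdict(list)
    for pid in ids:
        seq = ps[pid].sequence
        for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            by_kmer[kmer].append(pid)
    seen: set[tuple[str, str]] = set()
    for bucket in by_kmer.values():
        for pair in itertools.combinations(bucket, 2):
            if pair not in seen:
                seen.add(pair)
    yield from sorted(seen)


def build_homolog_graph(
    ps: ProteomeSet,
    params: ClusteringParams = ClusteringParams(),
    exact: bool | None = None,
) -> set[tuple[str, str]]:
    """Edge set over protein ids: pairs passing identity + bidirectional coverage."""
    aligner = _make_aligner(params)
    edges: set[tuple[str, str]] = set()
    for pid_a, pid_b in candidate_pairs(ps, params, exact=exact):
        stats = align_pair(ps[pid_a], ps[pid_b], params, aligner=aligner)
        if (
            stats.identity >= params.min_identity
            and stats.coverage_a >= params.min_coverage
            and stats.coverage_b >= params.min_coverage
        ):
            edges.add((pid_a, pid_b))
    return edges


def connected_components(
    edges: Iterable[tuple[str, str]], protein_ids: Iterable[str]
) -> HomologFamilies:
    """Homolog families = connected components; isolated proteins -> singletons."""
    graph = nx.Graph()
    graph.add_nodes_from(protein_ids)
    for a, b in edges:
        if a not in graph or b not in graph:
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown protein")
        graph.add_edge(a, b)
    return HomologFamilies(nx.connected_components(graph))


def cluster_proteins(
    ps: ProteomeSet,
    params: ClusteringParams = ClusteringParams(),
    exact: bool | None = None,
) -> HomologFamilies:
    """Full homolog-family pipeline: candidates -> alignments -> components."""
    edges = build_homolog_graph(ps, params, exact=exact)
    families = connected_components(edges, ps.protein_ids)
    families.validate_partition(ps.protein_ids)
    logger.info(
        "clustered %d proteins into %d families (size histogram %s)",
        len(ps),
        len(families),
        families.size_histogram(),
    )
    return families
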