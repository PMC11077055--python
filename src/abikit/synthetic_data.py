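"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its spec plus a mandatory seed
(byte-identical reruns) and emits machine-readable truth next to the data:

* :func:`gen_proteomes` — phage proteomes with planted homolog families at a
  controlled substitution rate, paralogs, cross-cluster shared families and
  singletons; truth = phage -> cluster and protein -> family labels.
* :func:`gen_plaque_table` — spot-assay counts over an eight-step 10-fold
  dilution series implied by known protection values; truth = protection.
* :func:`gen_product_reads` — terminal-transferase-like reads with specified
  base probabilities and a primer(10-40 nt, mode 18)+extension length model
  reaching a target mean near 100 nt; either the original or the
  complementary strand is emitted; truth = base probabilities.
* :func:`gen_densitometry` — an intensity-by-length profile on a 10-40 nt
  grid constructed to have an exact, known weighted mean length.

Family sequence evolution is i.i.d. substitution from a uniform replacement
model (optional i.i.d. indels), which keeps pairwise identity analytically
controllable for threshold tests; it does not emulate real phage evolution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .adduct_quant import DensitometryProfile
from .defense_profiles import DEFAULT_VOLUME_ML, EMPTY_VECTOR, SpotCount
from .product_composition import ReadRecord
from .proteome_io import PhageRecord, Protein, ProteomeSet

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
DNA = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# proteomes with planted homolog families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeSimSpec:
    """Planted-structure phage proteome simulation.

    Each of ``n_clusters`` phage clusters owns ``core_families`` homolog
    families carried by every member phage (mutated copies at
    ``substitution_rate``); ``shared_families`` families are carried by every
    phage of every cluster; each phage additionally carries unrelated
    singleton proteins at ``singleton_fraction`` of its proteome, and with
    probability ``paralog_prob`` a second copy of a core family.
    """

    n_clusters: int = 3
    phages_per_cluster: int = 4
    core_families: int = 30
    shared_families: int = 2
    singleton_fraction: float = 0.2
    substitution_rate: float = 0.1
    length_mean: float = 120.0
    length_sd: float = 30.0
    min_length: int = 30
    paralog_prob: float = 0.05
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.phages_per_cluster < 1:
            raise ValueError("need at least one cluster and one phage per cluster")
        if self.core_families < 1:
            raise ValueError("need at least one core family per cluster")
        for name in ("singleton_fraction", "substitution_rate", "paralog_prob",
                     "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _random_protein(rng: np.random.Generator, spec: ProteomeSimSpec) -> str:
    length = max(spec.min_length, int(round(rng.normal(spec.length_mean, spec.length_sd))))
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, seq: str, spec: ProteomeSimSpec) -> str:
    chars = np.array(list(seq))
    hits = rng.random(len(chars)) < spec.substitution_rate
    for i in np.flatnonzero(hits):
        choices = AMINO_ACIDS[AMINO_ACIDS != chars[i]]
        chars[i] = rng.choice(choices)
    out = "".join(chars)
    if spec.indel_rate > 0:
        kept = []
        for c in out:
            r = rng.random()
            if r < spec.indel_rate / 2:  # deletion
                continue
            kept.append(c)
            if r > 1 - spec.indel_rate / 2:  # insertion after
                kept.append(str(rng.choice(AMINO_ACIDS)))
        out = "".join(kept) or out[:1]
    return out


def gen_proteomes(spec: ProteomeSimSpec) -> tuple[ProteomeSet, dict]:
    """Generate a :class:`ProteomeSet` plus truth labels.

    Truth dict keys: ``phage_cluster`` (phage_id -> cluster label) and
    ``protein_family`` (protein_id -> planted family label; singletons get
    their own unique labels).
    """
    rng = np.random.default_rng(spec.seed)
    ancestors: dict[str, str] = {}
    for c in range(spec.n_clusters):
        for f in range(spec.core_families):
            ancestors[f"c{c}_fam{f:03d}"] = _random_protein(rng, spec)
    for f in range(spec.shared_families):
        ancestors[f"shared_fam{f:03d}"] = _random_protein(rng, spec)

    phages: list[PhageRecord] = []
    proteins: list[Protein] = []
    phage_cluster: dict[str, str] = {}
    protein_family: dict[str, str] = {}
    for c in range(spec.n_clusters):
        cluster = f"cluster{c}"
        fam_ids = [f"c{c}_fam{f:03d}" for f in range(spec.core_families)] + [
            f"shared_fam{f:03d}" for f in range(spec.shared_families)
        ]
        for p in range(spec.phages_per_cluster):
            phage_id = f"phage_c{c}_{p:02d}"
            phages.append(PhageRecord(phage_id, family="Simviridae", genus=cluster))
            phage_cluster[phage_id] = cluster
            idx = 0
            for fam in fam_ids:
                copies = 1 + (rng.random() < spec.paralog_prob)
                for _ in range(copies):
                    pid = f"{phage_id}|p{idx:04d}"
                    proteins.append(
                        Protein(pid, phage_id, _mutate(rng, ancestors[fam], spec))
                    )
                    protein_family[pid] = fam
                    idx += 1
            n_family_proteins = idx
            n_singletons = int(round(
                spec.singleton_fraction / (1 - spec.singleton_fraction)
                * n_family_proteins
            )) if spec.singleton_fraction < 1 else 0
            for s in range(n_singletons):
                pid = f"{phage_id}|p{idx:04d}"
                proteins.append(Protein(pid, phage_id, _random_protein(rng, spec)))
                protein_family[pid] = f"{phage_id}_singleton{s:03d}"
                idx += 1
    truth = {"phage_cluster": phage_cluster, "protein_family": protein_family,
             "spec": asdict(spec)}
    return ProteomeSet(proteins, phages), truth


def write_proteomes(
    ps: ProteomeSet, truth: dict, out_dir: str | Path
) -> None:
    """Write per-phage FASTA files, the taxonomy manifest and the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("phage_id\tfamily\tsubfamily\tgenus\n")
        for p in ps.phages:
            fh.write(f"{p.phage_id}\t{p.family}\t{p.subfamily}\t{p.genus}\n")
    for phage in ps.phage_ids:
        with open(out / f"{phage}.faa", "w") as fh:
            for prot in ps.proteins_of(phage):
                # strip the phage prefix: re-reading will restore it
                token = prot.protein_id.split("|", 1)[1]
                fh.write(f">{token}\n{prot.sequence}\n")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# plaque-count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssaySimSpec:
    """Spot-assay simulation from known protection values.

    ``protection`` maps (phage_id, system) to the true log10 protection.
    The empty-vector control is generated automatically.  The default vector
    titer (4e9 PFU/ml) makes every expected spot count an integer for the
    default 2.5 ul spot volume, so noiseless tables round-trip exactly.
    """

    protection: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("phageA", "abi"): 3.0}
    )
    replicates: int = 3
    vector_titer: float = 4e9
    poisson: bool = False
    n_dilutions: int = 8
    volume_ml: float = DEFAULT_VOLUME_ML
    lawn_threshold: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.protection.values()):
            raise ValueError("protection values must be >= 0")
        if self.replicates < 1 or self.n_dilutions < 1:
            raise ValueError("need >= 1 replicate and dilution")


def gen_plaque_table(spec: AssaySimSpec) -> tuple[list[SpotCount], dict]:
    """Generate spot counts; truth = the protection mapping."""
    rng = np.random.default_rng(spec.seed)
    spots: list[SpotCount] = []
    samples: dict[tuple[str, str], float] = {}
    for (phage, system), prot in sorted(spec.protection.items()):
        samples[(phage, system)] = spec.vector_titer * 10.0 ** (-prot)
        samples.setdefault((phage, EMPTY_VECTOR), spec.vector_titer)
    for (phage, system), titer_true in sorted(samples.items()):
        for rep in range(1, spec.replicates + 1):
            for d in range(0, -spec.n_dilutions, -1):
                expected = titer_true * spec.volume_ml * 10.0**d
                if spec.poisson:
                    if expected > spec.lawn_threshold:
                        plaques, lawn = None, True
                    else:
                        plaques, lawn = int(rng.poisson(expected)), False
                else:
                    if expected > spec.lawn_threshold:
                        plaques, lawn = None, True
                    else:
                        plaques, lawn = int(round(expected)), False
                spots.append(
                    SpotCount(
                        phage_id=phage,
                        system=system,
                        replicate=rep,
                        dilution_exponent=d,
                        volume_ml=spec.volume_ml,
                        plaques=plaques,
                        lawn=lawn,
                    )
                )
    truth = {
        "protection": {f"{p}::{s}": v for (p, s), v in spec.protection.items()},
        "vector_titer": spec.vector_titer,
    }
    return spots, truth


def write_plaque_table(
    spots: list[SpotCount], truth: dict, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "spots.tsv", "w") as fh:
        fh.write("phage_id\tsystem\treplicate\tdilution_exponent\tvolume_ml\tplaques\n")
        for s in spots:
            plaques = "L" if s.lawn else str(s.plaques)
            fh.write(
                f"{s.phage_id}\t{s.system}\t{s.replicate}\t{s.dilution_exponent}"
                f"\t{s.volume_ml:g}\t{plaques}\n"
            )
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# polymerase-product reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimSpec:
    """Terminal-transferase product read simulation.

    Primer lengths follow a discretized triangular distribution on
    [10, 40] nt peaking at 18 nt; extension lengths are Gamma-distributed
    (shape 2) so total lengths reach ``target_mean_length``.  Bases are
    i.i.d. at ``base_probs`` (original-strand probabilities); when
    ``strand="complementary"`` the reverse complement is emitted, emulating
    sequencing of the complementary strand only.
    """

    n_reads: int = 10_000
    base_probs: tuple[float, float, float, float] = (0.5, 0.45, 0.03, 0.02)
    target_mean_length: float = 100.0
    strand: str = "complementary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("need at least one read")
        if not math.isclose(sum(self.base_probs), 1.0, abs_tol=1e-9):
            raise ValueError("base probabilities must sum to 1")
        if self.strand not in ("original", "complementary"):
            raise ValueError(f"unknown strand {self.strand!r}")


def gen_product_reads(spec: ReadSimSpec) -> tuple[list[ReadRecord], dict]:
    """Generate reads; truth = original-strand base probabilities."""
    rng = np.random.default_rng(spec.seed)
    primer = np.floor(rng.triangular(10, 18, 41, size=spec.n_reads)).astype(int)
    ext_mean = max(spec.target_mean_length - primer.mean(), 0.0)
    if ext_mean > 0:
        extension = np.round(rng.gamma(2.0, ext_mean / 2.0, size=spec.n_reads)).astype(int)
    else:
        extension = np.zeros(spec.n_reads, dtype=int)
    lengths = primer + extension
    reads = []
    for i, length in enumerate(lengths):
        seq = "".join(rng.choice(DNA, size=int(length), p=spec.base_probs))
        if spec.strand == "complementary":
            seq = seq.translate(_COMPLEMENT)[::-1]
        reads.append(ReadRecord(f"read_{i:06d}", seq))
    truth = {
        "base_probs": dict(zip("ACGT", spec.base_probs)),
        "strand": spec.strand,
        "n_reads": spec.n_reads,
        "mean_length": float(lengths.mean()),
    }
    return reads, truth


def write_reads(
    reads: list[ReadRecord], truth: dict, out_dir: str | Path, name: str = "reads"
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{name}.fastq", "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r)}\n")
    (out / f"{name}.truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# densitometry profiles
# ---------------------------------------------------------------------------

def gen_densitometry(
    target_mean: float = 18.3,
    grid: tuple[int, int] = (10, 40),
    peak: int = 18,
    seed: int = 0,
) -> tuple[DensitometryProfile, dict]:
    """Intensity-by-length profile on a [10, 40] nt grid with an exact known
    weighted mean.

    A triangular base shape peaking at ``peak`` is blended with a point mass
    at a grid endpoint so the intensity-weighted mean equals ``target_mean``
    exactly.
    """
    lo, hi = grid
    if not lo <= target_mean <= hi:
        raise ValueError("target mean must lie inside the length grid")
    lengths = np.arange(lo, hi + 1, dtype=float)
    base = np.where(
        lengths <= peak,
        (lengths - lo + 1) / (peak - lo + 1),
        (hi - lengths + 1) / (hi - peak + 1),
    ).astype(float)  # triangular, peak at `peak`
    base /= base.sum()
    m0 = float((base * lengths).sum())
    anchor = lo if target_mean < m0 else hi
    lam = (m0 - target_mean) / (m0 - anchor) if m0 != anchor else 0.0
    weights = (1 - lam) * base
    weights[int(anchor - lo)] += lam
    profile = DensitometryProfile(tuple(lengths), tuple(weights))
    truth = {"weighted_mean": target_mean, "grid": [lo, hi]}
    return profile, truth


def write_densitometry(
    profile: DensitometryProfile, truth: dict, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "densitometry.tsv", "w") as fh:
        fh.write("length_nt\tintensity\n")
        for l, i in zip(profile.lengths, profile.intensities):
            fh.write(f"{l:g}\t{i:.12g}\n")
    (out / "densitometry.truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True)
    )
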