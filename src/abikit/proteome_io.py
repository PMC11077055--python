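"""Reading, validating and merging phage proteomes and their taxonomy manifest.

A "proteome" here is simply the set of protein sequences annotated on one
phage genome, supplied as an amino-acid multi-FASTA (one file per phage).
The taxonomy manifest is a TSV with columns ``phage_id``, ``family``,
``subfamily`` and ``genus``; taxonomy fields may be empty.  All proteomes
are merged into one indexed :class:`ProteomeSet` so that homolog-family
clustering can run on the pooled protein set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the 20 standard amino acids plus X (unknown residue)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

MANIFEST_COLUMNS = ("phage_id", "family", "subfamily", "genus")


@dataclass(frozen=True)
class Protein:
    """One protein of one phage.

    ``protein_id`` is globally unique within a :class:`ProteomeSet`; ids read
    from FASTA are prefixed with the phage id (``"<phage>|<header token>"``)
    because raw GenBank-style headers do not guarantee uniqueness across
    merged proteomes.
    """

    protein_id: str
    phage_id: str
    sequence: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class PhageRecord:
    """Taxonomy annotation of one phage; any taxonomy field may be empty."""

    phage_id: str
    family: str = ""
    subfamily: str = ""
    genus: str = ""


class ProteomeSet:
    """All proteins of all phages, in deterministic (manifest, record) order."""

    def __init__(self, proteins: Sequence[Protein], phages: Sequence[PhageRecord]):
        self.phages: list[PhageRecord] = list(phages)
        self.proteins: list[Protein] = list(proteins)
        self._phage_ids = [p.phage_id for p in self.phages]
        known = set(self._phage_ids)
        if len(known) != len(self._phage_ids):
            raise ValueError("duplicate phage_id in manifest")
        self._by_id: dict[str, Protein] = {}
        self._by_phage: dict[str, list[Protein]] = {pid: [] for pid in self._phage_ids}
        for prot in self.proteins:
            if prot.protein_id in self._by_id:
                raise ValueError(f"duplicate protein_id {prot.protein_id!r}")
            if prot.phage_id not in known:
                raise ValueError(
                    f"protein {prot.protein_id!r} references phage "
                    f"{prot.phage_id!r} absent from the manifest"
                )
            self._by_id[prot.protein_id] = prot
            self._by_phage[prot.phage_id].append(prot)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    def __getitem__(self, protein_id: str) -> Protein:
        return self._by_id[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    # -- accessors ----------------------------------------------------------
    @property
    def phage_ids(self) -> list[str]:
        return list(self._phage_ids)

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    def proteins_of(self, phage_id: str) -> list[Protein]:
        return list(self._by_phage[phage_id])

    def proteome_size(self, phage_id: str) -> int:
        return len(self._by_phage[phage_id])

    def phage_of(self, protein_id: str) -> str:
        return self._by_id[protein_id].phage_id

    # -- serialization ------------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        """Write the merged proteome as unwrapped FASTA (``>protein_id``)."""
        with open(path, "w") as fh:
            for prot in self.proteins:
                fh.write(f">{prot.protein_id}\n{prot.sequence}\n")

    def to_index_json(self, path: str | Path) -> None:
        index = {
            "phages": [vars(p) for p in self.phages],
            "proteome_sizes": {pid: self.proteome_size(pid) for pid in self._phage_ids},
            "n_proteins": len(self),
            "proteins": {p.protein_id: p.phage_id for p in self.proteins},
        }
        Path(path).write_text(json.dumps(index, indent=1, sort_keys=True))


def _validate_sequence(record_id: str, raw: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):  # common annotation artifact: trailing stop codon
        seq = seq[:-1]
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"record {record_id!r}: invalid residue(s) {sorted(bad)!r} "
            "(allowed: 20 standard amino acids, X, terminal *)"
        )
    return seq


def read_proteome_fasta(path: str | Path, phage_id: str) -> list[Protein]:
    """Parse one phage's amino-acid FASTA into :class:`Protein` records.

    Headers are truncated at the first whitespace and prefixed with
    ``phage_id`` to guarantee global uniqueness.  Sequences are uppercased;
    a single terminal ``*`` is stripped; any other character outside the
    20 amino acids + X raises a ``ValueError`` naming the record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or non-FASTA file")
    proteins = []
    seen: set[str] = set()
    for rec in records:
        token = rec.id
        pid = f"{phage_id}|{token}"
        if pid in seen:
            raise ValueError(f"{path}: duplicate record id {token!r}")
        seen.add(pid)
        proteins.append(Protein(pid, phage_id, _validate_sequence(token, str(rec.seq))))
    return proteins


def load_manifest(path: str | Path) -> list[PhageRecord]:
    """Load the taxonomy manifest TSV (phage_id, family, subfamily, genus)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"manifest {path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    if df["phage_id"].duplicated().any():
        dups = df.loc[df["phage_id"].duplicated(), "phage_id"].tolist()
        raise ValueError(f"manifest {path}: duplicated phage_id(s) {dups}")
    return [
        PhageRecord(r.phage_id, r.family, r.subfamily, r.genus)
        for r in df.itertuples(index=False)
    ]


def merge_proteomes(
    fasta_paths: Mapping[str, str | Path],
    manifest: Sequence[PhageRecord] | str | Path,
) -> ProteomeSet:
    """Merge per-phage FASTA files into one :class:`ProteomeSet`.

    Ordering is deterministic: phages in manifest order, proteins in file
    record order.  A phage present in the FASTA mapping but absent from the
    manifest is an error; a manifest phage with no FASTA is retained with an
    empty proteome (warning) so that matrix dimensions match the manifest.
    """
    if not isinstance(manifest, (list, tuple)):
        manifest = load_manifest(manifest)
    manifest_ids = [p.phage_id for p in manifest]
    unknown = sorted(set(fasta_paths) - set(manifest_ids))
    if unknown:
        raise ValueError(f"phage(s) {unknown} have FASTA files but no manifest row")
    proteins: list[Protein] = []
    for pid in manifest_ids:
        if pid in fasta_paths:
            proteins.extend(read_proteome_fasta(fasta_paths[pid], pid))
        else:
            logger.warning("phage %s has no proteome FASTA; retained empty", pid)
    return ProteomeSet(proteins, manifest)
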