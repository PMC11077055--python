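"""Proteome composition distance (PCD) between phages.

For phages *i* and *j* the directed similarity is the number of proteins of
*i* that fall in homolog families also containing at least one protein of
*j*, normalized to the proteome size of *i*::

    sim(i, j) = (# proteins of i in families shared with j) / |proteome_i|

so sim(i, i) = 1 for any phage with at least one protein.  The symmetric
distance is::

    dist(i, j) = 1 - (sim(i, j) + sim(j, i)) / 2

PCD is a dissimilarity, not a metric: the triangle inequality is not
guaranteed and no such assertion is made.

An alternative similarity ("families" definition) counts shared *families*
instead of member proteins, normalized to the number of distinct families of
phage *i*; it is provided for comparison because the two readings of
"overlapped cluster" differ whenever a phage carries paralogs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .homolog_families import HomologFamilies
from .proteome_io import ProteomeSet

logger = logging.getLogger(__name__)

SIM_DEFINITIONS = ("proteins", "families")


def phage_similarity(
    fams: HomologFamilies,
    ps: ProteomeSet,
    i: str,
    j: str,
    definition: str = "proteins",
) -> float:
    """Directed proteome similarity sim(i, j) in [0, 1]."""
    if definition not in SIM_DEFINITIONS:
        raise ValueError(f"unknown sim definition {definition!r}")
    fams_i = [fams.family_of[p.protein_id] for p in ps.proteins_of(i)]
    fams_j = {fams.family_of[p.protein_id] for p in ps.proteins_of(j)}
    if not fams_i:
        logger.warning("phage %s has an empty proteome; sim(%s, %s) = 0", i, i, j)
        return 0.0
    if definition == "proteins":
        return sum(f in fams_j for f in fams_i) / len(fams_i)
    distinct_i = set(fams_i)
    return len(distinct_i & fams_j) / len(distinct_i)


def similarity_matrix(
    fams: HomologFamilies, ps: ProteomeSet, definition: str = "proteins"
) -> pd.DataFrame:
    """Full (generally asymmetric) sim(i, j) matrix in manifest order."""
    ids = ps.phage_ids
    mat = pd.DataFrame(
        [[phage_similarity(fams, ps, i, j, definition) for j in ids] for i in ids],
        index=ids,
        columns=ids,
        dtype=float,
    )
    return mat


def pcd_matrix(sim: pd.DataFrame) -> pd.DataFrame:
    """Symmetric PCD matrix dist = 1 - (sim + sim.T) / 2, zero diagonal."""
    if sim.shape[0] != sim.shape[1] or list(sim.index) != list(sim.columns):
        raise ValueError("similarity matrix must be square with matching labels")
    values = sim.to_numpy(dtype=float)
    dist = 1.0 - (values + values.T) / 2.0
    # sim(i,i) = 1 for non-empty proteomes; empty proteomes get dist(i,i) = 0 too
    np.fill_diagonal(dist, 0.0)
    out = pd.DataFrame(dist, index=sim.index, columns=sim.columns)
    _check_distance(out)
    return out


def _check_distance(dist: pd.DataFrame) -> None:
    values = dist.to_numpy()
    if not np.array_equal(values, values.T):
        raise AssertionError("PCD matrix not symmetric")
    if (values < -1e-12).any() or (values > 1 + 1e-12).any():
        raise AssertionError("PCD values outside [0, 1]")


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    """Serialize a labelled square matrix as TSV with 6 decimal places."""
    mat.to_csv(path, sep="\t", float_format="%.6f", index_label="phage_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="phage_id")
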