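"""Phage titers, efficiency of plaquing (EOP) and log10 protection.

A spot assay drops a small volume (default 2.5 ul) of each step of a 10-fold
dilution series on a bacterial lawn.  The titer of a sample is computed from
the most dilute spot whose plaque count is countable (3-300 plaques by
default)::

    titer [PFU/ml] = plaques / (volume_ml * 10**dilution_exponent)

EOP is the titer on the defense-carrying host divided by the titer on the
empty-vector host; the protection value is -log10 of the arithmetic mean of
the replicate EOPs.  When every spot of a sample is zero, the titer is
censored at a detection limit of half a plaque at the most concentrated spot,
and the censoring propagates: a censored numerator gives an EOP upper bound
("<=") and hence a protection lower bound (">=").  Censoring flags are never
dropped; every value in the pipeline carries one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SPOT_COLUMNS = (
    "phage_id",
    "system",
    "replicate",
    "dilution_exponent",
    "volume_ml",
    "plaques",
)

#: label of the no-defense control sample
EMPTY_VECTOR = "empty_vector"

DEFAULT_COUNTABLE = (3, 300)
DEFAULT_VOLUME_ML = 0.0025  # 2.5 ul spots


@dataclass(frozen=True)
class SpotCount:
    """One spot of one dilution of one (phage, system, replicate) sample.

    ``plaques`` is a non-negative count, or None with ``lawn=True`` when the
    spot is confluent (too many to count).
    """

    phage_id: str
    system: str
    replicate: int
    dilution_exponent: int
    plaques: int | None
    volume_ml: float = DEFAULT_VOLUME_ML
    lawn: bool = False

    def __post_init__(self) -> None:
        if self.dilution_exponent > 0:
            raise ValueError("dilution_exponent must be <= 0 (10-fold series)")
        if self.volume_ml <= 0:
            raise ValueError("spotted volume must be positive")
        if self.lawn == (self.plaques is not None):
            raise ValueError("spot must have either a plaque count or the lawn flag")
        if self.plaques is not None and self.plaques < 0:
            raise ValueError("plaque count must be >= 0")


@dataclass(frozen=True)
class Titer:
    """PFU/ml; ``censored`` means the value is an upper detection limit."""

    value: float
    censored: bool = False


@dataclass(frozen=True)
class EOP:
    """Efficiency of plaquing; ``censored`` means "<= value"."""

    value: float
    censored: bool = False


@dataclass(frozen=True)
class Protection:
    """log10 protection; ``censored`` means ">= value" (EOP was a bound)."""

    value: float
    censored: bool = False


def titer(
    spots: Sequence[SpotCount],
    countable: tuple[int, int] = DEFAULT_COUNTABLE,
) -> Titer:
    """Titer of one sample from its dilution series.

    Preference order: the most dilute spot in the countable window; failing
    that, the most dilute non-lawn spot with >= 1 plaque; if every counted
    spot is zero, a censored titer at 0.5 plaques / (volume * 10**d_max)
    with d_max the most concentrated dilution spotted.
    """
    if not spots:
        raise ValueError("no spots for sample")
    key = {(s.phage_id, s.system, s.replicate) for s in spots}
    if len(key) != 1:
        raise ValueError(f"spots from multiple samples: {sorted(key)}")
    lo, hi = countable
    counted = [s for s in spots if not s.lawn]
    in_window = [s for s in counted if lo <= s.plaques <= hi]
    pool = in_window or [s for s in counted if s.plaques >= 1]
    if pool:
        best = min(pool, key=lambda s: s.dilution_exponent)  # most dilute
        return Titer(best.plaques / (best.volume_ml * 10.0**best.dilution_exponent))
    # all counted spots were zero (lawn-only series would be a malformed assay)
    if not counted:
        raise ValueError("sample has only lawn spots; titer undeterminable")
    top = max(spots, key=lambda s: s.dilution_exponent)  # most concentrated
    return Titer(0.5 / (top.volume_ml * 10.0**top.dilution_exponent), censored=True)


def eop(titer_system: Titer, titer_vector: Titer) -> EOP:
    """EOP = titer(system) / titer(vector); numerator censoring propagates."""
    if titer_vector.censored:
        raise ValueError("empty-vector control titer is censored; control failed")
    if titer_vector.value <= 0:
        raise ValueError("empty-vector titer must be positive")
    return EOP(titer_system.value / titer_vector.value, censored=titer_system.censored)


def protection(eops: Sequence[EOP], geometric: bool = False) -> Protection:
    """-log10 of the arithmetic mean of replicate EOPs.

    Censored replicates contribute their bound; the result is then flagged as
    a lower bound.  A geometric-mean variant is available for sensitivity
    analysis via ``geometric=True``.
    """
    return _protection(eops, geometric=geometric)


def _protection(eops: Sequence[EOP], geometric: bool = False) -> Protection:
    if not eops:
        raise ValueError("protection requires at least one replicate EOP")
    values = [e.value for e in eops]
    if geometric:
        mean = float(np.exp(np.mean(np.log(values))))
    else:
        mean = float(np.mean(values))
    if mean <= 0:
        raise ValueError("mean EOP must be positive (censor zero counts upstream)")
    return Protection(-math.log10(mean), censored=any(e.censored for e in eops))


def read_spot_table(path: str | Path) -> list[SpotCount]:
    """Parse the spot-count TSV; plaques column accepts "L" for lawn."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    spots = []
    for row in df.itertuples(index=False):
        lawn = row.plaques.strip().upper() == "L"
        spots.append(
            SpotCount(
                phage_id=row.phage_id,
                system=row.system,
                replicate=int(row.replicate),
                dilution_exponent=int(row.dilution_exponent),
                volume_ml=float(row.volume_ml),
                plaques=None if lawn else int(row.plaques),
                lawn=lawn,
            )
        )
    return spots


def eop_table(
    spots: Iterable[SpotCount],
    countable: tuple[int, int] = DEFAULT_COUNTABLE,
    geometric: bool = False,
) -> pd.DataFrame:
    """Per-(phage, system, replicate) titers and EOPs, vector-matched.

    Returns a DataFrame with columns phage_id, system, replicate,
    titer_system, titer_vector, eop, censored.
    """
    by_sample: dict[tuple[str, str, int], list[SpotCount]] = {}
    for s in spots:
        by_sample.setdefault((s.phage_id, s.system, s.replicate), []).append(s)
    titers = {key: titer(group, countable) for key, group in by_sample.items()}
    rows = []
    for (phage, system, rep), t_sys in sorted(titers.items()):
        if system == EMPTY_VECTOR:
            continue
        t_vec = titers.get((phage, EMPTY_VECTOR, rep))
        if t_vec is None:
            raise ValueError(
                f"no {EMPTY_VECTOR} control for phage {phage!r} replicate {rep}"
            )
        e = eop(t_sys, t_vec)
        rows.append((phage, system, rep, t_sys.value, t_vec.value, e.value, e.censored))
    return pd.DataFrame(
        rows,
        columns=[
            "phage_id",
            "system",
            "replicate",
            "titer_system",
            "titer_vector",
            "eop",
            "censored",
        ],
    )


def protection_table(eops: pd.DataFrame, geometric: bool = False) -> pd.DataFrame:
    """Replicate-averaged protection per (phage, system)."""
    rows = []
    for (phage, system), grp in eops.groupby(["phage_id", "system"], sort=True):
        reps = [EOP(v, c) for v, c in zip(grp["eop"], grp["censored"])]
        p = _protection(reps, geometric=geometric)
        rows.append((phage, system, p.value, p.censored))
    return pd.DataFrame(rows, columns=["phage_id", "system", "protection", "censored"])


def plot_protection_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Render the protection matrix as a heat map image (values are always
    also emitted as text; the image is a convenience view)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.3 * matrix.shape[0])
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    fig.colorbar(im, ax=ax, label="log10 protection")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def protection_matrix(
    prot: pd.DataFrame,
    phage_order: Sequence[str],
    systems: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Phage x system matrix of protection values, rows in dendrogram leaf
    order.  Untested cells are NaN (distinct from zero protection)."""
    if systems is None:
        systems = sorted(prot["system"].unique())
    mat = pd.DataFrame(np.nan, index=list(phage_order), columns=list(systems))
    for row in prot.itertuples(index=False):
        if row.phage_id in mat.index and row.system in mat.columns:
            mat.loc[row.phage_id, row.system] = row.protection
    return mat
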