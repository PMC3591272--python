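"""Readers/writers for the pipeline's external formats, plus shared domain types.

Coordinate conventions used everywhere in this package:

* Offsets within a cloned 3' end sequence are 0-based and count from the first
  base after the stop codon (``utr_start`` is therefore always 0).
* Windows are half-open ``[start, end)``.
* ``cleavage_site`` is the *inclusive* offset of the last transcribed base
  (the base immediately 5' of the poly(A) tail).

All tabular formats are plain TSV; single-cell data use a TSV/CSV export as the
contract format (no binary FCS parsing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ValidationError",
    "ReconciliationError",
    "TimeCourse",
    "Construct",
    "CellPopulation",
    "CleavageProfile",
    "BACKGROUND_ROLES",
    "load_plate_timecourses",
    "write_plate_timecourses",
    "load_construct_library",
    "write_construct_library",
    "write_expression_table",
    "write_cleavage_table",
    "read_cleavage_table",
    "load_cell_table",
    "write_cell_table",
]


class FormatError(ValueError):
    """A file does not have the expected structure (e.g. a missing column)."""


class ValidationError(ValueError):
    """File contents violate a precondition (bad characters, bad ordering...)."""


class ReconciliationError(ValueError):
    """Two inputs that must describe the same entities disagree."""


#: Well roles recognised in a plate layout.  ``media_blank`` provides the OD
#: background; the mCherry-only strain provides the YFP channel background and
#: the YFP-only strain the mCherry channel background.
BACKGROUND_ROLES = ("media_blank", "yfp_background_strain", "mcherry_background_strain")

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeCourse:
    """One well's OD/YFP/mCherry series over time.

    ``mask`` flags valid points (True = keep); masked-out points are excluded
    from every downstream computation.
    """

    well_id: str
    strain_id: str
    times: np.ndarray
    od: np.ndarray
    yfp: np.ndarray
    mcherry: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        n = len(self.times)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        for name in ("od", "yfp", "mcherry", "mask"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"well {self.well_id!r}: series {name!r} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if n < 4:
            raise ValidationError(f"well {self.well_id!r}: need >= 4 time points, got {n}")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError(f"well {self.well_id!r}: times are not strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.times)

    def valid(self) -> np.ndarray:
        """Indices of unmasked (valid) points."""
        return np.flatnonzero(self.mask)

    def with_mask(self, mask: np.ndarray) -> "TimeCourse":
        return replace(self, mask=np.asarray(mask, dtype=bool))


@dataclass
class Construct:
    """A cloned 3' end sequence: stop codon to the next ORF (up to 1 kb)."""

    gene_id: str
    sequence: str
    cleavage_site: int | None = None
    orientation: str | None = None  # "tandem" | "convergent"
    intergenic_length: int | None = None
    expression: float | None = None
    #: First base after the stop codon; fixed at 0 by convention.
    utr_start: int = 0

    def __post_init__(self) -> None:
        self.sequence = _normalise_sequence(self.sequence, self.gene_id)
        if len(self.sequence) > 1000:
            raise ValidationError(
                f"{self.gene_id}: cloned sequence is {len(self.sequence)} bp, limit is 1000"
            )
        if self.cleavage_site is not None:
            self.cleavage_site = int(self.cleavage_site)
            if not 0 <= self.cleavage_site < len(self.sequence):
                raise ValidationError(
                    f"{self.gene_id}: cleavage_site {self.cleavage_site} outside "
                    f"[0, {len(self.sequence)})"
                )
        if self.orientation is not None and self.orientation not in ("tandem", "convergent"):
            raise ValidationError(
                f"{self.gene_id}: orientation must be 'tandem' or 'convergent', "
                f"got {self.orientation!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def utr_sequence(self) -> str | None:
        """Transcribed 3' UTR, ``[0, cleavage_site]`` inclusive; None if unknown."""
        if self.cleavage_site is None:
            return None
        return self.sequence[: self.cleavage_site + 1]


@dataclass
class CellPopulation:
    """Single-cell fluorescence/scatter records for one strain in one condition."""

    strain_id: str
    condition: float  # galactose concentration, percent
    fsc: np.ndarray
    ssc: np.ndarray
    yfp: np.ndarray
    mcherry: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fsc", "ssc", "yfp", "mcherry"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.fsc)
        if n < 1:
            raise ValidationError(f"{self.strain_id}: empty cell population")
        for name in ("ssc", "yfp", "mcherry"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{self.strain_id}: channel {name!r} length mismatch")
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{self.strain_id}: negative values in channel {name!r}")
        if np.any(self.fsc < 0):
            raise ValidationError(f"{self.strain_id}: negative values in channel 'fsc'")

    @property
    def n_cells(self) -> int:
        return len(self.fsc)

    def subset(self, keep: np.ndarray) -> "CellPopulation":
        keep = np.asarray(keep)
        return CellPopulation(
            strain_id=self.strain_id,
            condition=self.condition,
            fsc=self.fsc[keep],
            ssc=self.ssc[keep],
            yfp=self.yfp[keep],
            mcherry=self.mcherry[keep],
        )


@dataclass
class CleavageProfile:
    """Per-position read counts downstream of a stop codon, with a main site.

    ``main_site`` is the position with the highest count; ties break to the
    most upstream (smallest) position.  ``passes_depth`` is a strict ``>``
    comparison against the depth threshold.
    """

    gene_id: str
    counts: dict[int, int]
    main_site: int
    total_reads: int
    passes_depth: bool

    @classmethod
    def from_counts(
        cls, gene_id: str, counts: Mapping[int, int], depth_threshold: int = 1000
    ) -> "CleavageProfile":
        if not counts:
            raise ValidationError(f"{gene_id}: empty cleavage count map")
        counts = {int(p): int(c) for p, c in counts.items()}
        total = sum(counts.values())
        max_count = max(counts.values())
        main = min(p for p, c in counts.items() if c == max_count)
        return cls(
            gene_id=gene_id,
            counts=counts,
            main_site=main,
            total_reads=total,
            passes_depth=total > depth_threshold,
        )

    def fractions(self) -> dict[int, float]:
        return {p: c / self.total_reads for p, c in self.counts.items()}


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _normalise_sequence(seq: str, label: str) -> str:
    seq = str(seq).strip().upper()
    for i, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValidationError(f"{label}: non-ACGT character {base!r} at position {i}")
    return seq


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{what}: missing required column {col!r}")


# ---------------------------------------------------------------------------
# Plate-reader tables
# ---------------------------------------------------------------------------


def load_plate_timecourses(
    path: str | Path, layout: Mapping[str, Mapping[str, str]]
) -> tuple[list[TimeCourse], dict[str, TimeCourse]]:
    """Read a plate-fluorometer table into per-well :class:`TimeCourse` objects.

    Parameters
    ----------
    path:
        TSV with columns ``time``, ``well``, ``od``, ``yfp``, ``mcherry``.
    layout:
        Maps each well id to ``{"role": ..., "strain": ...}`` where role is
        ``sample`` or one of :data:`BACKGROUND_ROLES`.

    Returns
    -------
    (samples, backgrounds):
        Sample wells as a list sorted by well id, background wells keyed by role.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ("time", "well", "od", "yfp", "mcherry"), str(path))
    samples: list[TimeCourse] = []
    backgrounds: dict[str, TimeCourse] = {}
    for well, sub in df.groupby("well", sort=True):
        well = str(well)
        if well not in layout:
            raise ValidationError(f"well {well!r} present in {path} but absent from layout")
        entry = layout[well]
        role = entry.get("role", "sample")
        sub = sub.sort_values("time")
        times = sub["time"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"well {well!r}: non-increasing/duplicated timestamps")
        tc = TimeCourse(
            well_id=well,
            strain_id=str(entry.get("strain", role)),
            times=times,
            od=sub["od"].to_numpy(dtype=float),
            yfp=sub["yfp"].to_numpy(dtype=float),
            mcherry=sub["mcherry"].to_numpy(dtype=float),
        )
        if role == "sample":
            samples.append(tc)
        elif role in BACKGROUND_ROLES:
            if role in backgrounds:
                raise ValidationError(f"duplicate background role {role!r} (well {well!r})")
            backgrounds[role] = tc
        else:
            raise ValidationError(f"well {well!r}: unknown role {role!r}")
    return samples, backgrounds


def write_plate_timecourses(
    timecourses: Iterable[TimeCourse], path: str | Path
) -> None:
    """Write time courses to the TSV layout read by :func:`load_plate_timecourses`."""
    frames = []
    for tc in timecourses:
        frames.append(
            pd.DataFrame(
                {
                    "time": tc.times,
                    "well": tc.well_id,
                    "od": tc.od,
                    "yfp": tc.yfp,
                    "mcherry": tc.mcherry,
                }
            )
        )
    if not frames:
        raise ValidationError("no time courses to write")
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Construct libraries (FASTA + annotation TSV)
# ---------------------------------------------------------------------------

_ANNOT_OPTIONAL = ("expression", "cleavage_site", "orientation", "intergenic_length")


def load_construct_library(
    fasta: str | Path,
    annot: str | Path,
    expression_scale: str = "linear",
) -> list[Construct]:
    """Load cloned constructs from a FASTA plus an annotation TSV.

    The annotation mirrors a per-strain expression table: one row per gene
    with at least a ``gene_id`` column; ``expression``, ``cleavage_site``,
    ``orientation`` and ``intergenic_length`` are attached when present.
    ``expression_scale`` records whether the table's expression column is
    ``"linear"`` or ``"log"``; log values are exponentiated on load so that
    in-memory expression is always linear a.u.
    """
    if expression_scale not in ("linear", "log"):
        raise ValueError("expression_scale must be 'linear' or 'log'")
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    table = pd.read_csv(annot, sep="\t", float_precision="round_trip")
    _require_columns(table, ("gene_id",), str(annot))
    table = table.set_index(table["gene_id"].astype(str))
    orphan_fasta = sorted(set(records) - set(table.index))
    orphan_annot = sorted(set(table.index) - set(records))
    if orphan_fasta or orphan_annot:
        raise ReconciliationError(
            "FASTA/annotation mismatch; FASTA-only ids: "
            f"{orphan_fasta}; annotation-only ids: {orphan_annot}"
        )
    constructs = []
    for gene_id in sorted(records):
        row = table.loc[gene_id]
        kwargs: dict = {}
        for col in _ANNOT_OPTIONAL:
            if col in table.columns and not pd.isna(row[col]):
                kwargs[col] = row[col]
        if "expression" in kwargs:
            value = float(kwargs["expression"])
            kwargs["expression"] = math.exp(value) if expression_scale == "log" else value
        if "intergenic_length" in kwargs:
            kwargs["intergenic_length"] = int(kwargs["intergenic_length"])
        constructs.append(Construct(gene_id=gene_id, sequence=records[gene_id], **kwargs))
    return constructs


def write_construct_library(
    constructs: Sequence[Construct], fasta: str | Path, annot: str | Path
) -> None:
    """Write constructs as FASTA + annotation TSV (inverse of the loader)."""
    if not constructs:
        raise ValidationError("no constructs to write")
    recs = [
        SeqRecord(Seq(c.sequence), id=c.gene_id, description="") for c in constructs
    ]
    SeqIO.write(recs, str(fasta), "fasta")
    rows = []
    for c in constructs:
        rows.append(
            {
                "gene_id": c.gene_id,
                "expression": c.expression,
                "cleavage_site": c.cleavage_site,
                "orientation": c.orientation,
                "intergenic_length": c.intergenic_length,
            }
        )
    pd.DataFrame(rows).to_csv(annot, sep="\t", index=False, float_format="%.17g")


def write_expression_table(constructs: Sequence[Construct], path: str | Path) -> None:
    """Write the three-column per-strain expression table (name, expression, sequence)."""
    if not constructs:
        raise ValidationError("no constructs to write")
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in constructs],
            "expression": [c.expression for c in constructs],
            "sequence": [c.sequence for c in constructs],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cleavage profiles (BED-like TSV)
# ---------------------------------------------------------------------------


def write_cleavage_table(profiles: Iterable[CleavageProfile], path: str | Path) -> None:
    """Write cleavage profiles as a BED-like TSV.

    One row per (gene, position): ``gene_id``, ``position`` (0-based offset
    from the first base after the stop codon, inclusive last transcribed
    base), ``read_count``, ``is_main_site``; sorted by gene then position.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("refusing to write an empty cleavage table")
    rows = []
    for prof in sorted(profiles, key=lambda p: p.gene_id):
        for pos in sorted(prof.counts):
            rows.append(
                {
                    "gene_id": prof.gene_id,
                    "position": pos,
                    "read_count": prof.counts[pos],
                    "is_main_site": int(pos == prof.main_site),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cleavage_table(
    path: str | Path, depth_threshold: int = 1000
) -> list[CleavageProfile]:
    """Read back a cleavage table written by :func:`write_cleavage_table`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ("gene_id", "position", "read_count", "is_main_site"), str(path))
    profiles = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        counts = dict(zip(sub["position"].astype(int), sub["read_count"].astype(int)))
        prof = CleavageProfile.from_counts(str(gene_id), counts, depth_threshold)
        flagged = set(sub.loc[sub["is_main_site"] == 1, "position"].astype(int))
        if flagged != {prof.main_site}:
            raise ValidationError(
                f"{gene_id}: is_main_site flag {sorted(flagged)} inconsistent with "
                f"counts (argmax {prof.main_site})"
            )
        profiles.append(prof)
    return profiles


# ---------------------------------------------------------------------------
# Single-cell tables
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ("strain", "condition", "fsc", "ssc", "yfp", "mcherry")


def load_cell_table(path: str | Path) -> list[CellPopulation]:
    """Read a per-cell TSV into populations grouped by (strain, condition)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, _CELL_COLUMNS, str(path))
    pops = []
    for (strain, cond), sub in df.groupby(["strain", "condition"], sort=True):
        pops.append(
            CellPopulation(
                strain_id=str(strain),
                condition=float(cond),
                fsc=sub["fsc"].to_numpy(),
                ssc=sub["ssc"].to_numpy(),
                yfp=sub["yfp"].to_numpy(),
                mcherry=sub["mcherry"].to_numpy(),
            )
        )
    return pops


def write_cell_table(populations: Iterable[CellPopulation], path: str | Path) -> None:
    frames = []
    for pop in populations:
        frames.append(
            pd.DataFrame(
                {
                    "strain": pop.strain_id,
                    "condition": pop.condition,
                    "fsc": pop.fsc,
                    "ssc": pop.ssc,
                    "yfp": pop.yfp,
                    "mcherry": pop.mcherry,
                }
            )
        )
    if not frames:
        raise ValidationError("no cell populations to write")
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.17g")
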