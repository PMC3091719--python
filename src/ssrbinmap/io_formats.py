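"""Readers and writers for the external file formats shared by every stage.

The pipeline speaks four plain-text formats:

* FASTA for unigene/EST sequences (via Biopython).
* A genotype CSV dialect for full-sib marker tables: one row per marker,
  ``marker_id,seg_type,phase,<ind1>,<ind2>,...`` where ``seg_type`` is one of
  the four outbred segregation configurations (``lmxll``, ``nnxnp``,
  ``hkxhk``, ``abxcd``), ``phase`` is ``coupling``/``repulsion``/``unknown``
  and calls use the familiar two-letter linkage codes with ``--`` for
  missing data.
* A map TSV with columns ``linkage_group``, ``marker``, ``position`` (cM).
* Result TSVs (SSR catalogue, bin-assignment report).

Sequence coordinates are 0-based half-open throughout; map positions are
floating-point centimorgans and linkage groups are numbered from 1.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

MISSING = "--"

#: Legal call codes for each segregation configuration.
SEG_TYPES: Mapping[str, frozenset[str]] = {
    "lmxll": frozenset({"lm", "ll"}),
    "nnxnp": frozenset({"nn", "np"}),
    "hkxhk": frozenset({"hh", "hk", "kk"}),
    "abxcd": frozenset({"ac", "ad", "bc", "bd"}),
}

PHASES = frozenset({"coupling", "repulsion", "unknown"})


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence over {A, C, G, T, N} with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  Duplicate
    identifiers raise :class:`FormatError`; an empty file yields an empty
    list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class GenotypeTable:
    """Markers x individuals call matrix with per-marker segregation metadata.

    ``calls`` is a string DataFrame indexed by marker id with individual ids
    as columns; ``seg_type`` and ``phase`` are Series over the same marker
    index.  Every call must be legal for its marker's segregation type or
    the missing code ``--``.
    """

    calls: pd.DataFrame
    seg_type: pd.Series
    phase: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.phase is None:
            self.phase = pd.Series("unknown", index=self.calls.index)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_markers(self) -> int:
        return len(self.calls.index)

    @property
    def n_individuals(self) -> int:
        return len(self.calls.columns)

    def missing_fraction_per_individual(self) -> pd.Series:
        return (self.calls == MISSING).mean(axis=0)

    def subset(self, markers: Sequence[str] | None = None,
               individuals: Sequence[str] | None = None) -> "GenotypeTable":
        calls = self.calls
        if markers is not None:
            calls = calls.loc[list(markers)]
        if individuals is not None:
            calls = calls[list(individuals)]
        return GenotypeTable(
            calls=calls.copy(),
            seg_type=self.seg_type.loc[calls.index].copy(),
            phase=self.phase.loc[calls.index].copy(),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].unique()
            raise FormatError(f"duplicate marker ids: {list(dups)}")
        if self.calls.columns.has_duplicates:
            dups = self.calls.columns[self.calls.columns.duplicated()].unique()
            raise FormatError(f"duplicate individual ids: {list(dups)}")
        offenders: list[str] = []
        for marker in self.calls.index:
            st = self.seg_type.loc[marker]
            if st not in SEG_TYPES:
                raise FormatError(f"unknown seg_type {st!r} for marker {marker!r}")
            ph = self.phase.loc[marker]
            if ph not in PHASES:
                raise FormatError(f"unknown phase {ph!r} for marker {marker!r}")
            legal = SEG_TYPES[st]
            row = self.calls.loc[marker]
            for ind, call in row.items():
                if call != MISSING and call not in legal:
                    offenders.append(
                        f"marker {marker!r}, individual {ind!r}: "
                        f"call {call!r} illegal for {st}"
                    )
        if offenders:
            raise FormatError(
                "illegal genotype calls:\n  " + "\n  ".join(offenders)
            )


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read the genotype CSV dialect (header: marker_id,seg_type,phase,inds...)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"empty genotype file: {path}") from None
        if header[:3] != ["marker_id", "seg_type", "phase"]:
            raise FormatError(
                "genotype header must start with 'marker_id,seg_type,phase', "
                f"got {header[:3]}"
            )
        individuals = header[3:]
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append(row)
    markers = [r[0] for r in rows]
    calls = pd.DataFrame(
        [r[3:] for r in rows], index=markers, columns=individuals, dtype=str
    )
    seg_type = pd.Series([r[1] for r in rows], index=markers, dtype=str)
    phase = pd.Series([r[2] for r in rows], index=markers, dtype=str)
    return GenotypeTable(calls=calls, seg_type=seg_type, phase=phase)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["marker_id", "seg_type", "phase", *table.individual_ids])
        for marker in table.marker_ids:
            writer.writerow(
                [marker, table.seg_type.loc[marker], table.phase.loc[marker],
                 *table.calls.loc[marker].tolist()]
            )


# -- linkage map tables --------------------------------------------------

MAP_COLUMNS = ["linkage_group", "marker", "position"]


def validate_map(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort a map table (group asc, position asc)."""
    missing = [c for c in MAP_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"map table missing columns: {missing}")
    table = table[MAP_COLUMNS].copy()
    table["linkage_group"] = table["linkage_group"].astype(int)
    table["position"] = table["position"].astype(float)
    if (table["linkage_group"] < 1).any():
        raise FormatError("linkage groups are numbered from 1")
    if (table["position"] < 0).any():
        raise FormatError("map positions must be >= 0 cM")
    if table["marker"].duplicated().any():
        dups = table.loc[table["marker"].duplicated(), "marker"].unique()
        raise FormatError(f"duplicate markers in map: {list(dups)}")
    table = table.sort_values(
        ["linkage_group", "position", "marker"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def read_map(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_map(table)


def write_map(table: pd.DataFrame, path: str | Path) -> None:
    validate_map(table).to_csv(path, sep="\t", index=False)


# -- result writers ------------------------------------------------------

def write_catalog(catalog: Iterable, path: str | Path) -> None:
    """Write an SSR catalogue (iterable of ``ssr_miner.SSRLocus``) as TSV."""
    rows = []
    for loc in catalog:
        rows.append({
            "unigene_id": loc.unigene_id,
            "start": loc.start,
            "end": loc.end,
            "unit": loc.unit,
            "canonical": loc.canonical if loc.canonical is not None else "",
            "unit_len": loc.unit_len,
            "n_repeats": loc.n_repeats,
            "compound": int(loc.compound),
        })
    cols = ["unigene_id", "start", "end", "unit", "canonical", "unit_len",
            "n_repeats", "compound"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_assignments(results: Iterable, path: str | Path,
                      classes: Mapping[str, str] | None = None) -> None:
    """Write a bin-assignment report as TSV.

    Columns are ``marker``, ``parent`` (F/M), ``bin_code`` (``/``-joined for
    intermediate or ambiguous assignments), ``status`` and ``class``
    (validation class A-D when supplied via *classes*, else empty).
    """
    rows = []
    for res in results:
        key = (res.marker_id, res.parent)
        rows.append({
            "marker": res.marker_id,
            "parent": res.parent,
            "bin_code": "/".join(res.bin_codes),
            "status": res.status,
            "class": (classes or {}).get(key, (classes or {}).get(res.marker_id, "")),
        })
    cols = ["marker", "parent", "bin_code", "status", "class"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
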