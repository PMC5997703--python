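"""Aligned mitochondrial haplotypes and per-sample metadata.

Alignments are stored column-collinear with the revised Cambridge Reference
Sequence (rCRS, 16,569 bp): coordinates throughout the package are 1-based,
closed intervals in rCRS space, and no indel re-mapping is attempted —
mitogenome consensus sequences are conventionally reported against rCRS.

The alphabet is restricted to {A, C, G, T, N, -}. Any IUPAC ambiguity code
other than A/C/G/T is mapped to N on input, because every downstream
statistic treats only the four called bases as informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    AlignmentError,
    CoordinateError,
    FormatError,
    MetadataError,
)

ALPHABET = b"ACGTN-"
HVR1_START = 16059
HVR1_END = 16365

SPATIAL_GROUPS = ("CISB", "TRAB", "YAK", "OTHER")
TEMPORAL_GROUPS = ("Early", "Middle", "Late", "Modern")

#: Default age boundaries (years BP) separating Early/Middle/Late bins.
#: Chosen midway between the reported group mean ages (7,000 / 4,800 /
#: 3,000 BP); real datasets should carry an explicit temporal_group column.
DEFAULT_TEMPORAL_EDGES = (5900.0, 3900.0)

METADATA_COLUMNS = [
    "sample_id",
    "site",
    "spatial_group",
    "temporal_group",
    "age_bp",
    "d13C",
    "d15N",
    "haplogroup",
]

# byte-level translation: keep ACGTN-, lowercase -> uppercase, any other
# IUPAC symbol -> N
_TRANS = np.full(256, ord("N"), dtype=np.uint8)
for _b in b"ACGTN-":
    _TRANS[_b] = _b
    _TRANS[ord(chr(_b).lower())] = _b


@dataclass
class HaplotypeAlignment:
    """Aligned haplotypes over rCRS coordinates.

    Parameters
    ----------
    sample_ids
        Unique sequence identifiers, in input order.
    matrix
        ``(n_samples, length)`` uint8 array of ASCII codes over the
        alphabet ``{A, C, G, T, N, -}``.
    coord_offset
        1-based rCRS position of the first alignment column.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    coord_offset: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.sample_ids)} ids for {self.matrix.shape[0]} rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("sample ids are not unique")
        if self.coord_offset < 1:
            raise CoordinateError("coord_offset must be >= 1 (1-based rCRS)")
        bad = ~np.isin(self.matrix, np.frombuffer(ALPHABET, dtype=np.uint8))
        if bad.any():
            raise AlignmentError("alignment contains symbols outside {A,C,G,T,N,-}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, sample_id: str) -> str:
        i = self.sample_ids.index(sample_id)
        return self.matrix[i].tobytes().decode("ascii")

    def subset(self, sample_ids: Sequence[str]) -> "HaplotypeAlignment":
        """Row subset preserving the requested order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return HaplotypeAlignment(
            list(sample_ids), self.matrix[idx].copy(), self.coord_offset
        )

    def slice_rcrs(self, start: int, end: int) -> "HaplotypeAlignment":
        """Columns ``start..end`` (1-based rCRS, closed interval)."""
        if start > end:
            raise CoordinateError(f"empty interval: start={start} > end={end}")
        lo = self.coord_offset
        hi = self.coord_offset + self.length - 1
        if start < lo or end > hi:
            raise CoordinateError(
                f"range {start}-{end} outside alignment span {lo}-{hi}"
            )
        a = start - self.coord_offset
        b = end - self.coord_offset + 1
        return HaplotypeAlignment(
            list(self.sample_ids), self.matrix[:, a:b].copy(), start
        )


def read_alignment(path: str | Path, coord_offset: int = 1) -> HaplotypeAlignment:
    """Read an aligned FASTA file into a :class:`HaplotypeAlignment`.

    Bases are uppercased; IUPAC ambiguity codes other than A/C/G/T become N.
    Input order is preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(
            f"sequences have unequal lengths {sorted(lengths)}; input must be aligned"
        )
    ids = [r.id for r in records]
    raw = np.frombuffer(
        b"".join(bytes(str(r.seq), "ascii") for r in records), dtype=np.uint8
    )
    matrix = _TRANS[raw].reshape(len(records), lengths.pop())
    return HaplotypeAlignment(ids, matrix, coord_offset)


def write_alignment(aln: HaplotypeAlignment, path: str | Path, wrap: int = 70) -> None:
    """Write the alignment as wrapped FASTA."""
    records = [
        SeqRecord(Seq(aln.matrix[i].tobytes().decode("ascii")), id=sid, description="")
        for i, sid in enumerate(aln.sample_ids)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def extract_hvr1(
    aln: HaplotypeAlignment, start: int = HVR1_START, end: int = HVR1_END
) -> HaplotypeAlignment:
    """Extract the hypervariable region I sub-alignment.

    Defaults to rCRS 16059–16365 (307 columns), the HVRI window used for
    cross-study comparisons of control-region haplotypes.
    """
    return aln.slice_rcrs(start, end)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Expected columns: sample_id, site, spatial_group, temporal_group,
    age_bp, d13C, d15N, haplogroup. age_bp/d13C/d15N may be empty
    (modern samples or missing measurements).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata missing columns: {missing}")
    validate_metadata(df)
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


def validate_metadata(df: pd.DataFrame) -> None:
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample ids: {dups}")
    bad_sp = set(df["spatial_group"].dropna()) - set(SPATIAL_GROUPS)
    if bad_sp:
        raise MetadataError(f"unknown spatial groups: {sorted(bad_sp)}")
    bad_tmp = set(df["temporal_group"].dropna()) - set(TEMPORAL_GROUPS)
    if bad_tmp:
        raise MetadataError(f"unknown temporal groups: {sorted(bad_tmp)}")
    ages = pd.to_numeric(df["age_bp"], errors="coerce")
    if (ages.dropna() < 0).any():
        raise MetadataError("age_bp must be >= 0")
    # Modern <=> no age (or age 0)
    modern = df["temporal_group"] == "Modern"
    if ((ages.notna()) & (ages > 0) & modern).any():
        raise MetadataError("Modern samples must have null or zero age_bp")


def is_ancient(df: pd.DataFrame) -> pd.Series:
    """Boolean mask of ancient (non-Modern) samples."""
    return df["temporal_group"] != "Modern"


def assign_groups(
    meta: pd.DataFrame,
    scheme: str,
    temporal_edges: tuple[float, float] = DEFAULT_TEMPORAL_EDGES,
) -> dict[str, list[str]]:
    """Partition ancient samples under a grouping scheme.

    Parameters
    ----------
    scheme
        ``"single"`` — all ancients in one group ``SIB``;
        ``"spatial"`` — copy spatial_group, excluding OTHER from the three
        named regional groups;
        ``"temporal"`` — bin age_bp against two strictly decreasing edges:
        ``age >= edges[0]`` is Early, ``edges[1] <= age < edges[0]`` is
        Middle, younger is Late (an age equal to an edge goes to the
        older group).

    Returns
    -------
    dict mapping group label to the list of sample ids, disjoint across
    groups; under ``single`` the partition is exhaustive over ancients.
    """
    ancients = meta.loc[is_ancient(meta)]
    if scheme == "single":
        return {"SIB": ancients["sample_id"].tolist()}
    if scheme == "spatial":
        groups: dict[str, list[str]] = {}
        for label in ("CISB", "TRAB", "YAK"):
            groups[label] = ancients.loc[
                ancients["spatial_group"] == label, "sample_id"
            ].tolist()
        return groups
    if scheme == "temporal":
        e1, e2 = temporal_edges
        if not e1 > e2:
            raise MetadataError(
                f"temporal edges must be strictly decreasing, got {temporal_edges}"
            )
        ages = pd.to_numeric(ancients["age_bp"], errors="coerce")
        if ages.isna().any():
            bad = ancients.loc[ages.isna(), "sample_id"].tolist()
            raise MetadataError(f"temporal scheme requires age_bp; missing for {bad}")
        groups = {"Early": [], "Middle": [], "Late": []}
        for sid, age in zip(ancients["sample_id"], ages):
            if age >= e1:
                groups["Early"].append(sid)
            elif age >= e2:
                groups["Middle"].append(sid)
            else:
                groups["Late"].append(sid)
        return groups
    raise ValueError(f"unknown grouping scheme: {scheme!r}")
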