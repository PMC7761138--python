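"""Readers and writers for the pipeline's on-disk formats.

Four kinds of input are handled: protein sequences (FASTA), per-residue
structural feature tables (the SPIDER2 ``.spd3`` whitespace dialect or a
generic headered TSV), site-label files mapping ``(protein_id, position)``
to a pupylation call, and the flat TSV serialization of an encoded dataset.

All residue coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "CHANNELS",
    "ProteinRecord",
    "ResidueFeatures",
    "ResidueProfile",
    "SiteLabel",
    "read_fasta",
    "write_fasta",
    "read_profile",
    "write_profile_tsv",
    "read_site_labels",
    "write_site_labels",
    "enumerate_lysines",
]

#: The 20 standard one-letter amino-acid codes; X marks an unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical order of the eight per-residue structural channels: predicted
#: accessible surface area, helix/strand/coil probabilities, and the four
#: backbone angles (phi, psi about the backbone bonds; theta, tau defined on
#: consecutive C-alpha atoms). Every feature vector follows this order.
CHANNELS = ("asa", "ph", "pe", "pc", "phi", "psi", "theta", "tau")

# spd3 column layout: index, AA, SS class, ASA, Phi, Psi, Theta, Tau, P(C), P(E), P(H)
_SPD3_COLUMNS = ("#", "AA", "SS", "ASA", "Phi", "Psi", "Theta", "Tau", "P(C)", "P(E)", "P(H)")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _wrap_angle(x: float) -> float:
    """Wrap an angle in degrees into [-180, 180]."""
    wrapped = (x + 180.0) % 360.0 - 180.0
    # keep +180 as +180 rather than mapping it to -180
    if wrapped == -180.0 and x > 0:
        return 180.0
    return wrapped


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier.

    The identifier is the FASTA header token up to the first whitespace.
    Candidate sites are the lysine (K) residues of ``sequence``.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record requires a non-empty id")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in AMINO_ACIDS + "X"]
        if bad:
            pos, c = bad[0]
            raise FormatError(
                f"protein {self.id!r}: non-amino-acid character {c!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def lysine_positions(self) -> list[int]:
        """1-based positions of every K residue, ascending."""
        return [i + 1 for i, c in enumerate(self.sequence) if c == "K"]


@dataclass(frozen=True)
class ResidueFeatures:
    """The eight structural channels of one residue.

    asa is in Å² as emitted by the profile tool (non-negative); ph/pe/pc are
    helix/strand/coil probabilities in [0, 1]; the four angles are in degrees,
    wrapped into [-180, 180] on ingest.
    """

    aa: str
    asa: float
    ph: float
    pe: float
    pc: float
    phi: float
    psi: float
    theta: float
    tau: float

    def __post_init__(self) -> None:
        for name in CHANNELS:
            try:
                object.__setattr__(self, name, float(getattr(self, name)))
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric value {getattr(self, name)!r} for channel "
                    f"{name} of residue {self.aa!r}"
                ) from None
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise FormatError(f"non-finite structural feature for residue {self.aa!r}")
        if self.asa < 0:
            raise FormatError(f"negative ASA {self.asa} for residue {self.aa!r}")
        for name in ("ph", "pe", "pc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"{name}={v} outside [0, 1] for residue {self.aa!r}")
        for name in ("phi", "psi", "theta", "tau"):
            v = getattr(self, name)
            if not -180.0 <= v <= 180.0:
                object.__setattr__(self, name, _wrap_angle(v))

    def as_array(self) -> np.ndarray:
        """Channel values in canonical :data:`CHANNELS` order."""
        return np.array([getattr(self, c) for c in CHANNELS], dtype=float)


@dataclass
class ResidueProfile:
    """A per-residue structural feature table aligned to one protein."""

    protein_id: str
    rows: list[ResidueFeatures]

    def __len__(self) -> int:
        return len(self.rows)

    def to_matrix(self) -> np.ndarray:
        """(n_residues, 8) matrix in canonical channel order."""
        return np.vstack([r.as_array() for r in self.rows])

    def validate_against(self, record: ProteinRecord) -> None:
        """Check alignment with a sequence; mismatch is a hard error.

        Silent misalignment would corrupt every downstream feature, so
        length or residue-identity disagreement raises rather than truncates.
        """
        if len(self.rows) != record.length:
            raise FormatError(
                f"profile for {self.protein_id!r} has {len(self.rows)} rows "
                f"but sequence {record.id!r} has {record.length} residues"
            )
        for i, (row, aa) in enumerate(zip(self.rows, record.sequence), start=1):
            if row.aa != aa:
                raise FormatError(
                    f"profile/sequence mismatch for {record.id!r} at position {i}: "
                    f"profile says {row.aa!r}, sequence says {aa!r}"
                )
        sums = np.array([r.ph + r.pe + r.pc for r in self.rows])
        off = np.abs(sums - 1.0) > 0.05
        if off.any():
            warnings.warn(
                f"profile {self.protein_id!r}: helix/strand/coil probabilities sum to "
                f"{sums[off][0]:.3f} at position {int(np.flatnonzero(off)[0]) + 1} "
                "(|sum - 1| > 0.05)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SiteLabel:
    """A candidate lysine site, optionally labeled.

    label is 1 for pupylated, 0 for non-pupylated, None when the site is
    enumerated for prediction only.
    """

    protein_id: str
    position: int
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"site position must be 1-based positive, got {self.position}")
        if self.label not in (None, 0, 1):
            raise FormatError(f"site label must be 0, 1 or absent, got {self.label!r}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    Sequences are upper-cased; gap (``-``) and stop (``*``) characters are
    stripped with a warning. Duplicate identifiers and non-amino-acid
    characters other than X are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise FormatError(f"duplicate FASTA id {pid!r} in {path}")
        seen.add(pid)
        seq = str(entry.seq).upper()
        if "-" in seq or "*" in seq:
            warnings.warn(f"FASTA {pid!r}: stripping gap/stop characters", stacklevel=2)
            seq = seq.replace("-", "").replace("*", "")
        records.append(ProteinRecord(id=pid, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def _read_profile_spd3(path: Path, protein_id: str) -> ResidueProfile:
    rows: list[ResidueFeatures] = []
    with open(path) as fh:
        lines = fh.readlines()
    body = [
        (n, ln)
        for n, ln in enumerate(lines, start=1)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    expected_index = 1
    for lineno, line in body:
        parts = line.split()
        if len(parts) < 11:
            raise FormatError(f"{path}:{lineno}: expected 11 spd3 columns, got {len(parts)}")
        try:
            idx = int(parts[0])
            asa, phi, psi, theta, tau, pc, pe, ph = (float(v) for v in parts[3:11])
            if not all(np.isfinite([asa, phi, psi, theta, tau, pc, pe, ph])):
                raise ValueError("non-finite value")
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        if idx != expected_index:
            raise FormatError(
                f"{path}:{lineno}: index column not consecutive from 1 "
                f"(expected {expected_index}, got {idx})"
            )
        expected_index += 1
        rows.append(
            ResidueFeatures(
                aa=parts[1].upper(), asa=asa, ph=ph, pe=pe, pc=pc,
                phi=phi, psi=psi, theta=theta, tau=tau,
            )
        )
    if not rows:
        raise FormatError(f"{path}: profile has no residue rows")
    return ResidueProfile(protein_id=protein_id, rows=rows)


def _read_profile_tsv(path: Path, protein_id: str) -> ResidueProfile:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ("aa",) + CHANNELS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing TSV columns {missing}; need {list(required)}")
    if len(frame) == 0:
        raise FormatError(f"{path}: profile has no residue rows")
    rows: list[ResidueFeatures] = []
    for i, rec in enumerate(frame.itertuples(index=False), start=2):  # line 1 is the header
        try:
            vals = {c: float(getattr(rec, c)) for c in CHANNELS}
        except (TypeError, ValueError):
            raise FormatError(f"{path}:{i}: non-numeric cell") from None
        if not all(np.isfinite(v) for v in vals.values()):
            raise FormatError(f"{path}:{i}: non-numeric cell")
        rows.append(ResidueFeatures(aa=str(rec.aa).upper(), **vals))
    return ResidueProfile(protein_id=protein_id, rows=rows)


def read_profile(path: str | Path, dialect: str = "spd3", protein_id: str | None = None) -> ResidueProfile:
    """Read a per-residue structural feature table.

    dialect ``spd3`` is the SPIDER2 whitespace table (columns index, AA,
    SS class, ASA, Phi, Psi, Theta, Tau, P(C), P(E), P(H); the categorical
    SS class is ignored); ``tsv`` is a headered tab-separated file with
    columns ``aa`` plus the eight canonical channel names. Both are mapped
    to canonical channel order ``(asa, ph, pe, pc, phi, psi, theta, tau)``.

    protein_id defaults to the file stem.
    """
    path = Path(path)
    pid = protein_id if protein_id is not None else path.stem.split(".")[0]
    if dialect == "spd3":
        return _read_profile_spd3(path, pid)
    if dialect == "tsv":
        return _read_profile_tsv(path, pid)
    raise ValueError(f"unknown profile dialect {dialect!r}; expected 'spd3' or 'tsv'")


def write_profile_tsv(profile: ResidueProfile, path: str | Path) -> None:
    """Write a profile in the tsv dialect with full float precision.

    Round-trips through :func:`read_profile` reproduce every numeric field.
    """
    with open(path, "w") as fh:
        fh.write("aa\t" + "\t".join(CHANNELS) + "\n")
        for row in profile.rows:
            vals = "\t".join(repr(getattr(row, c)) for c in CHANNELS)
            fh.write(f"{row.aa}\t{vals}\n")


def read_site_labels(path: str | Path) -> list[SiteLabel]:
    """Read a site-label TSV with columns protein_id, position, label."""
    frame = pd.read_csv(path, sep="\t")
    required = ["protein_id", "position", "label"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing label columns {missing}")
    labels = [
        SiteLabel(protein_id=str(r.protein_id), position=int(r.position), label=int(r.label))
        for r in frame.itertuples(index=False)
    ]
    seen: set[tuple[str, int]] = set()
    for lab in labels:
        key = (lab.protein_id, lab.position)
        if key in seen:
            raise FormatError(f"{path}: duplicate site label for {key}")
        seen.add(key)
    return labels


def write_site_labels(labels: Iterable[SiteLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for lab in labels:
            fh.write(f"{lab.protein_id}\t{lab.position}\t{lab.label}\n")


def enumerate_lysines(
    record: ProteinRecord, labels: Optional[Sequence[SiteLabel]] = None
) -> list[SiteLabel]:
    """Enumerate every K residue of a protein as a candidate site.

    With labels given, sites named in them carry their binary call and any
    label pointing at a non-K residue is an error; sites not named stay
    unlabeled. Without labels all sites are emitted unlabeled (prediction
    mode). Output is ascending by position, one entry per K.
    """
    by_pos: dict[int, int] = {}
    if labels is not None:
        for lab in labels:
            if lab.protein_id != record.id:
                continue
            if lab.position > record.length or record.sequence[lab.position - 1] != "K":
                raise FormatError(
                    f"label for protein {record.id!r} position {lab.position} "
                    "does not point at a lysine"
                )
            by_pos[lab.position] = lab.label
    return [
        SiteLabel(protein_id=record.id, position=pos, label=by_pos.get(pos))
        for pos in record.lysine_positions()
    ]
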