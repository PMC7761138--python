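"""Residue-window extraction and feature-vector assembly.

A candidate lysine is represented by a fixed-width window of residues
centred on it (default 6 on each side, width 13). Windows that run past a
protein terminus are completed by mirroring: the missing slot at offset
``-i`` takes the residue (and all its structural features) at offset
``+i``, reflecting about the central K, and symmetrically downstream.
Each window is flattened slot-major / channel-minor into a numeric vector
(default 13 slots x 8 channels = 104 features), which is the unit fed to
cleaning, training and cross-validation.

Feature scaling is per-column min-max to [0, 1], fit on whichever portion
of the data the caller designates as training; values outside the fitted
range are clipped and a constant column maps to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CHANNELS,
    ProteinRecord,
    ResidueFeatures,
    ResidueProfile,
    SiteLabel,
    enumerate_lysines,
)

__all__ = [
    "WindowSpec",
    "SiteWindow",
    "FeatureVector",
    "NormalizationParams",
    "LabeledDataset",
    "CHANNEL_SUBSETS",
    "extract_window",
    "assemble_vector",
    "build_dataset",
    "fit_normalization",
    "apply_normalization",
    "select_features",
]

#: Named channel groupings used by the feature-ablation harness: accessible
#: surface area alone, the secondary-structure probability triple (SSpre),
#: each single channel, the four-angle torsion group, ASA+SSpre, and all.
CHANNEL_SUBSETS: dict[str, tuple[str, ...]] = {
    "asa": ("asa",),
    "sspre": ("ph", "pe", "pc"),
    "ph": ("ph",),
    "pe": ("pe",),
    "pc": ("pc",),
    "torsion": ("phi", "psi", "theta", "tau"),
    "phi": ("phi",),
    "psi": ("psi",),
    "theta": ("theta",),
    "tau": ("tau",),
    "asa+sspre": ("asa", "ph", "pe", "pc"),
    "all": CHANNELS,
}


@dataclass(frozen=True)
class WindowSpec:
    """Geometry and channel selection of the residue window.

    flank is the number of residues taken on each side of the central K,
    so the window width is 2*flank + 1 (always odd).
    """

    flank: int = 6
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError(f"flank must be a positive integer, got {self.flank}")
        if not self.channels:
            raise ValueError("channels must be non-empty")
        unknown = [c for c in self.channels if c not in CHANNELS]
        if unknown:
            raise ValueError(f"unknown channels {unknown}; valid channels are {list(CHANNELS)}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channels in {self.channels}")

    @property
    def width(self) -> int:
        return 2 * self.flank + 1

    @property
    def n_features(self) -> int:
        return self.width * len(self.channels)

    def feature_names(self) -> list[str]:
        """Slot-major, channel-minor names: ``slot{-flank..+flank}_{channel}``."""
        return [
            f"slot{o:+d}_{c}"
            for o in range(-self.flank, self.flank + 1)
            for c in self.channels
        ]

    @classmethod
    def from_width(cls, width: int, channels: tuple[str, ...] = CHANNELS) -> "WindowSpec":
        if width < 3 or width % 2 == 0:
            raise ValueError(f"window width must be odd and >= 3, got {width}")
        return cls(flank=(width - 1) // 2, channels=channels)


@dataclass
class SiteWindow:
    """One extracted window: (aa, features) per slot plus a mirroring mask."""

    protein_id: str
    position: int
    residues: list[tuple[str, ResidueFeatures]]
    mirrored_mask: list[bool]

    @property
    def width(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(aa for aa, _ in self.residues)


@dataclass
class FeatureVector:
    """A window flattened to numbers, with its label and site provenance."""

    values: np.ndarray
    label: Optional[int]
    protein_id: str
    position: int


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature (min, max) of a min-max scaling fit."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __len__(self) -> int:
        return len(self.minimum)


@dataclass
class LabeledDataset:
    """A matrix of site feature vectors with labels and provenance.

    The unit of cleaning, cross-validation and training. ``X`` holds raw or
    normalized feature values (``normalization`` records which); ``y`` is
    1/0 per site, with -1 marking unlabeled prediction-mode sites.
    """

    X: np.ndarray
    y: np.ndarray
    protein_ids: list[str]
    positions: list[int]
    feature_names: list[str]
    normalization: Optional[NormalizationParams] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n, d = self.X.shape
        if not (len(self.y) == len(self.protein_ids) == len(self.positions) == n):
            raise ValueError("dataset rows, labels and provenance lengths disagree")
        if len(self.feature_names) != d:
            raise ValueError(
                f"{d} feature columns but {len(self.feature_names)} feature names"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("dataset contains non-finite feature values")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.y == 0))

    def require_labels(self) -> None:
        if np.any(self.y < 0):
            raise ValueError("operation requires a fully labeled dataset")

    def take(self, indices: Sequence[int]) -> "LabeledDataset":
        """Row subset preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            protein_ids=[self.protein_ids[i] for i in idx],
            positions=[self.positions[i] for i in idx],
            feature_names=list(self.feature_names),
            normalization=self.normalization,
        )

    def site_ids(self) -> list[tuple[str, int]]:
        return list(zip(self.protein_ids, self.positions))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame.insert(0, "label", self.y)
        frame.insert(0, "position", self.positions)
        frame.insert(0, "protein_id", self.protein_ids)
        return frame

    def write_tsv(self, path: str | Path) -> None:
        """One row per site: provenance columns, label, feature columns."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LabeledDataset":
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        meta = ["protein_id", "position", "label"]
        missing = [c for c in meta if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing dataset columns {missing}")
        features = [c for c in frame.columns if c not in meta]
        return cls(
            X=frame[features].to_numpy(dtype=float),
            y=frame["label"].to_numpy(dtype=int),
            protein_ids=[str(v) for v in frame["protein_id"]],
            positions=[int(v) for v in frame["position"]],
            feature_names=features,
        )


def extract_window(
    record: ProteinRecord,
    profile: ResidueProfile,
    position: int,
    spec: WindowSpec = WindowSpec(),
) -> SiteWindow:
    """Extract the residue window centred on the lysine at ``position``.

    Slots whose absolute position falls outside the protein are filled by
    mirror reflection about the central K: slot ``-i`` takes the residue at
    ``+i`` and vice versa. When both ``-i`` and ``+i`` are unavailable (the
    protein is shorter than flank+1 on both sides) the slot copies the K
    residue itself, with a warning — a degenerate case for very short
    proteins.
    """
    if not 1 <= position <= record.length:
        raise ValueError(f"position {position} out of range for protein {record.id!r}")
    if record.sequence[position - 1] != "K":
        raise ValueError(
            f"residue at position {position} of {record.id!r} is "
            f"{record.sequence[position - 1]!r}, not K"
        )
    profile.validate_against(record)

    def in_range(p: int) -> bool:
        return 1 <= p <= record.length

    residues: list[tuple[str, ResidueFeatures]] = []
    mask: list[bool] = []
    warned = False
    for offset in range(-spec.flank, spec.flank + 1):
        direct = position + offset
        if in_range(direct):
            take, mirrored = direct, False
        else:
            reflected = position - offset
            if in_range(reflected):
                take, mirrored = reflected, True
            else:
                take, mirrored = position, True
                warned = True
        residues.append((record.sequence[take - 1], profile.rows[take - 1]))
        mask.append(mirrored)
    if warned:
        warnings.warn(
            f"window at {record.id!r}:{position} could not be filled by mirroring "
            "(protein shorter than the window on both sides); unfilled slots copy "
            "the central lysine",
            stacklevel=2,
        )
    return SiteWindow(protein_id=record.id, position=position, residues=residues, mirrored_mask=mask)


def assemble_vector(
    window: SiteWindow,
    spec: WindowSpec = WindowSpec(),
    label: Optional[int] = None,
) -> FeatureVector:
    """Flatten a window slot-major, channel-minor into a numeric vector."""
    if window.width != spec.width:
        raise ValueError(f"window width {window.width} does not match spec width {spec.width}")
    chan_idx = [CHANNELS.index(c) for c in spec.channels]
    values = np.empty(spec.n_features, dtype=float)
    k = 0
    for slot, (aa, feats) in enumerate(window.residues):
        arr = feats.as_array()
        for ci in chan_idx:
            v = arr[ci]
            if not np.isfinite(v):
                offset = slot - spec.flank
                raise ValueError(
                    f"non-finite feature at slot {offset:+d} channel {CHANNELS[ci]} "
                    f"of {window.protein_id!r}:{window.position}"
                )
            values[k] = v
            k += 1
    return FeatureVector(
        values=values, label=label, protein_id=window.protein_id, position=window.position
    )


def build_dataset(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ResidueProfile],
    labels: Optional[Sequence[SiteLabel]] = None,
    spec: WindowSpec = WindowSpec(),
) -> LabeledDataset:
    """Encode every lysine of every protein into one dataset.

    Sites without a label are stored with y = -1 (prediction mode).
    """
    vectors: list[FeatureVector] = []
    for record in records:
        if record.id not in profiles:
            raise KeyError(f"no structural profile provided for protein {record.id!r}")
        profile = profiles[record.id]
        for site in enumerate_lysines(record, labels):
            window = extract_window(record, profile, site.position, spec)
            vectors.append(assemble_vector(window, spec, label=site.label))
    if not vectors:
        raise ValueError("no lysine sites found in the input proteins")
    return LabeledDataset(
        X=np.vstack([v.values for v in vectors]),
        y=np.array([-1 if v.label is None else v.label for v in vectors], dtype=int),
        protein_ids=[v.protein_id for v in vectors],
        positions=[v.position for v in vectors],
        feature_names=spec.feature_names(),
    )


def fit_normalization(dataset: LabeledDataset) -> NormalizationParams:
    """Fit per-feature min-max parameters on a dataset (>= 2 rows)."""
    if len(dataset) < 2:
        raise ValueError("normalization requires at least 2 vectors")
    return NormalizationParams(
        minimum=dataset.X.min(axis=0).copy(), maximum=dataset.X.max(axis=0).copy()
    )


def apply_normalization(dataset: LabeledDataset, params: NormalizationParams) -> LabeledDataset:
    """Scale each feature to [0, 1] with the fitted min/max.

    Values outside the fitted range clip to 0/1; a constant feature maps
    to 0. Idempotent once the data are inside the fitted range.
    """
    if len(params) != dataset.n_features:
        raise ValueError(
            f"normalization params cover {len(params)} features "
            f"but dataset has {dataset.n_features}"
        )
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = np.clip((dataset.X - params.minimum) / safe, 0.0, 1.0)
    scaled[:, span == 0] = 0.0
    return LabeledDataset(
        X=scaled,
        y=dataset.y.copy(),
        protein_ids=list(dataset.protein_ids),
        positions=list(dataset.positions),
        feature_names=list(dataset.feature_names),
        normalization=params,
    )


def select_features(
    dataset: LabeledDataset,
    channels: Optional[Iterable[str]] = None,
    names: Optional[Iterable[str]] = None,
) -> LabeledDataset:
    """Restrict a dataset to a channel subset or an explicit column list.

    ``channels`` may be canonical channel names or a named grouping from
    :data:`CHANNEL_SUBSETS` (e.g. ``"sspre"``, ``"torsion"``). Column order
    and labels are preserved.
    """
    if (channels is None) == (names is None):
        raise ValueError("provide exactly one of channels= or names=")
    if channels is not None:
        wanted: list[str] = []
        for c in channels:
            if c in CHANNEL_SUBSETS and c not in CHANNELS:
                wanted.extend(CHANNEL_SUBSETS[c])
            elif c in CHANNELS:
                wanted.append(c)
            else:
                raise ValueError(
                    f"unknown channel {c!r}; valid names are {sorted(set(CHANNELS) | set(CHANNEL_SUBSETS))}"
                )
        keep = [
            i for i, n in enumerate(dataset.feature_names) if n.rsplit("_", 1)[1] in wanted
        ]
    else:
        names = list(names)
        unknown = [n for n in names if n not in dataset.feature_names]
        if unknown:
            raise ValueError(f"unknown feature names {unknown}")
        keep = [i for i, n in enumerate(dataset.feature_names) if n in names]
    if not keep:
        raise ValueError("feature selection produced an empty dataset")
    return LabeledDataset(
        X=dataset.X[:, keep],
        y=dataset.y.copy(),
        protein_ids=list(dataset.protein_ids),
        positions=list(dataset.positions),
        feature_names=[dataset.feature_names[i] for i in keep],
        normalization=None,
    )
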