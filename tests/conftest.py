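"""Shared fixtures: hand-built sequences/profiles and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from pupstruct.encoding import LabeledDataset, WindowSpec
from pupstruct.io_formats import CHANNELS, ProteinRecord, ResidueFeatures, ResidueProfile


def make_profile(record: ProteinRecord, rng: np.random.Generator | None = None,
                 constant: float | None = None) -> ResidueProfile:
    """A valid profile aligned to ``record``.

    With ``constant`` set, every numeric channel holds that value (probability
    channels hold constant/3 to stay on the simplex); otherwise channels are
    drawn from their natural ranges with the given generator.
    """
    rows = []
    rng = rng if rng is not None else np.random.default_rng(0)
    for aa in record.sequence:
        if constant is not None:
            rows.append(ResidueFeatures(aa=aa, asa=constant, ph=constant / 3,
                                        pe=constant / 3, pc=constant / 3,
                                        phi=constant, psi=constant,
                                        theta=constant, tau=constant))
        else:
            ph, pe, pc = rng.dirichlet((1, 1, 1))
            phi, psi, theta, tau = rng.uniform(-180, 180, 4)
            rows.append(ResidueFeatures(aa=aa, asa=float(abs(rng.normal(60, 25))),
                                        ph=ph, pe=pe, pc=pc,
                                        phi=phi, psi=psi, theta=theta, tau=tau))
    return ResidueProfile(protein_id=record.id, rows=rows)


def random_protein(rng: np.random.Generator, length: int, pid: str = "p") -> ProteinRecord:
    """A random sequence guaranteed to contain at least one lysine."""
    letters = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(letters[i] for i in rng.integers(0, 20, length))
    if "K" not in seq:
        i = int(rng.integers(0, length))
        seq = seq[:i] + "K" + seq[i + 1 :]
    return ProteinRecord(id=pid, sequence=seq)


def make_dataset(X: np.ndarray, y: np.ndarray) -> LabeledDataset:
    """Wrap bare arrays as a dataset with synthetic provenance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return LabeledDataset(
        X=X,
        y=np.asarray(y, dtype=int),
        protein_ids=[f"p{i}" for i in range(len(X))],
        positions=[1] * len(X),
        feature_names=[f"f{j}" for j in range(X.shape[1])],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def default_spec() -> WindowSpec:
    return WindowSpec()
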