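"""Amino-acid property scales.

The shipped fixture is the polar requirement, Woese's chromatographic
hydrophilicity measure, on which Asp (13.0) and Glu (12.5) take the two
largest values — the reason the random-code ensemble pins their minimum
multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .codons import AA_INDEX, AMINO_ACIDS, N_AA


@dataclass(frozen=True)
class PropertyScale:
    """A real-valued property defined for all 20 amino acids."""

    name: str
    values: np.ndarray  # indexed by the internal amino-acid order

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (N_AA,):
            raise ValueError("a property scale needs exactly 20 values")
        if not np.all(np.isfinite(v)):
            raise ValueError("property values must be finite")
        object.__setattr__(self, "values", v)

    def value(self, aa: str) -> float:
        return float(self.values[AA_INDEX[aa]])

    def as_dict(self) -> dict:
        return {a: float(self.values[i]) for i, a in enumerate(AMINO_ACIDS)}

    @classmethod
    def from_mapping(cls, name: str, mapping: dict) -> "PropertyScale":
        missing = set(AMINO_ACIDS) - set(mapping)
        if missing:
            raise ValueError(f"scale {name!r} missing amino acids: {sorted(missing)}")
        vals = np.array([mapping[a] for a in AMINO_ACIDS], dtype=np.float64)
        return cls(name, vals)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "PropertyScale":
        """Read a two-column CSV (amino_acid, value)."""
        df = pd.read_csv(path)
        mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
        return cls.from_mapping(name or str(path), mapping)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"amino_acid": list(AMINO_ACIDS), "value": self.values}
        ).to_csv(path, index=False)


def polar_requirement() -> PropertyScale:
    """The polar-requirement scale (Woese's values, as used in the
    classic error-minimization literature)."""
    ref = resources.files("codescape.data") / "polar_requirement.csv"
    with resources.as_file(ref) as path:
        scale = PropertyScale.from_csv(path, name="polar requirement")
    return scale
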