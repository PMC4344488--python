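"""Pentamer-based DNA shape prediction.

Four structural parameters -- minor groove width (MGW, Angstrom),
propeller twist (ProT, degrees), roll (degrees) and helix twist (HelT,
degrees) -- are assigned to the center position of each overlapping
pentamer of a sequence.  The first and last two positions of a sequence
have no covering pentamer and are undefined.

The packaged default table is SYNTHETIC: a physically motivated additive
model (A/T-rich pentamers narrow the minor groove and increase negative
propeller twist, purine-pyrimidine steps modulate roll) with a small
deterministic pentamer-specific component.  It reproduces the realistic
dynamic ranges of the four parameters but is not derived from structural
data; it exists so that shape-feature pipelines are fully testable
without redistribution of an external query table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SHAPE_FEATURES",
    "ShapeTable",
    "predict_shape",
    "synthetic_shape_table",
    "uniform_shape_table",
]

SHAPE_FEATURES = ("MGW", "ProT", "Roll", "HelT")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class ShapeTable:
    """Map 5-mer -> (MGW, ProT, Roll, HelT) at the pentamer center.

    Lookups for reverse-complement pentamers follow the table's own values;
    no symmetrization is implied.
    """

    values: dict[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if len(k) != 5 or any(b not in _BASES for b in k):
                raise ValueError(f"invalid pentamer key {k!r}")
            if len(v) != 4:
                raise ValueError(f"pentamer {k}: expected 4 shape values")
        self._array: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, pentamer: str) -> tuple[float, float, float, float]:
        return self.values[pentamer.upper()]

    def as_array(self) -> np.ndarray:
        """(1024, 4) array indexed by base-4 encoding of the pentamer."""
        if self._array is None:
            arr = np.full((1024, 4), np.nan)
            for k, v in self.values.items():
                idx = 0
                for b in k:
                    idx = idx * 4 + _BASE_INDEX[b]
                arr[idx] = v
            self._array = arr
        return self._array

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, *v) for k, v in sorted(self.values.items())]
        return pd.DataFrame(rows, columns=["pentamer", *SHAPE_FEATURES])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ShapeTable":
        return cls({r.pentamer: (r.MGW, r.ProT, r.Roll, r.HelT) for r in df.itertuples()})


def encode(seq: str) -> np.ndarray:
    """Base -> 0..3 integer encoding; raises on ambiguous characters."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"ambiguous base {exc.args[0]!r} in sequence") from None


def predict_shape(sequence: str, table: ShapeTable) -> np.ndarray:
    """Per-position shape features for a sequence; shape (L, 4).

    Position i (2 <= i <= L-3) receives table[seq[i-2 .. i+2]]; the two
    terminal positions at each end are NaN.  Sequences shorter than 5 bases
    are rejected.
    """
    if len(sequence) < 5:
        raise ValueError("sequence must be at least 5 bases for pentamer lookup")
    codes = encode(sequence)
    # sliding base-4 pentamer indices
    kernel = np.array([256, 64, 16, 4, 1])
    windows = np.lib.stride_tricks.sliding_window_view(codes, 5)
    idx = windows @ kernel
    out = np.full((len(sequence), 4), np.nan)
    out[2: len(sequence) - 2] = table.as_array()[idx]
    if np.isnan(out[2: len(sequence) - 2]).any():
        raise KeyError("shape table is missing a pentamer present in the sequence")
    return out


def uniform_shape_table(mgw: float = 5.0, prot: float = -8.0,
                        roll: float = 0.0, helt: float = 34.5) -> ShapeTable:
    """Degenerate table mapping every pentamer to the same vector (tests)."""
    vals = (mgw, prot, roll, helt)
    return ShapeTable({"".join(p): vals for p in itertools.product(_BASES, repeat=5)})


def synthetic_shape_table(seed: int = 20150129) -> ShapeTable:
    """The packaged synthetic pentamer table (see module docstring).

    Deterministic: an additive base/step model plus a small seeded
    pentamer-specific term.  Approximate ranges: MGW 2.8-6.3 A,
    ProT -16 to -4 deg, Roll -7 to +7 deg, HelT 33-37 deg.
    """
    rng = np.random.default_rng(seed)
    pos_weight = np.array([0.45, 0.8, 1.0, 0.8, 0.45])
    mgw_base = {"A": -0.55, "T": -0.55, "C": 0.40, "G": 0.40}
    prot_base = {"A": -1.3, "T": -1.3, "C": 0.9, "G": 0.9}
    values: dict[str, tuple[float, float, float, float]] = {}
    for p in itertools.product(_BASES, repeat=5):
        penta = "".join(p)
        jitter = rng.normal(0.0, 1.0, size=4)
        mgw = 5.0 + sum(w * mgw_base[b] for w, b in zip(pos_weight, penta)) + 0.12 * jitter[0]
        prot = -9.0 + sum(w * prot_base[b] for w, b in zip(pos_weight, penta)) + 0.4 * jitter[1]
        # roll driven by the two central dinucleotide steps: pyr-pur steps roll positive
        roll = 0.0
        for a, b in (penta[1:3], penta[2:4]):
            pur_a, pur_b = a in "AG", b in "AG"
            roll += 2.2 if (not pur_a and pur_b) else (-2.2 if (pur_a and not pur_b) else 0.0)
        roll += 0.6 * jitter[2]
        helt = 34.8 + 0.5 * jitter[3] + (0.6 if penta[2] in "AT" else -0.3)
        values[penta] = (round(mgw, 3), round(prot, 3), round(roll, 3), round(helt, 3))
    return ShapeTable(values)
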