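"""Built-in hydropathy scales.

Two residue-level hydrophobicity tables are shipped:

* ``kyte_doolittle`` — the Kyte & Doolittle (1982) hydropathy values,
  where hydrophobic residues are positive (I = 4.5) and charged residues
  negative (R = -4.5).
* ``wimley_white_interface`` — the Wimley & White (1996) water-to-POPC
  interface transfer free energies (kcal/mol, pH-7 charge states).  The
  published convention is that *favourable* membrane partitioning is
  negative, so the values are negated at load time: after loading, every
  scale in this module reads "higher = more hydrophobic".

A user-supplied scale can be loaded from a two-column whitespace- or
tab-delimited text file (residue letter, value) via :func:`load_scale_file`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle 1982 hydropathy index.
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Wimley & White 1996 interface scale, ΔG water→POPC interface (kcal/mol),
# pH-7 charge states (Asp-, Glu-, His0). Raw published orientation:
# negative = favourable partitioning (hydrophobic).
_WIMLEY_WHITE_INTERFACE_RAW = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}


@dataclass(frozen=True)
class HydropathyScale:
    """A residue → hydrophobicity lookup table.

    ``values`` always follows the orientation "higher = more hydrophobic";
    ``raw_values`` keeps the published numbers for provenance.
    """

    name: str
    values: dict[str, float]
    raw_values: dict[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - set(self.values))
            extra = sorted(set(self.values) - set(AMINO_ACIDS))
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"amino acids (missing {missing}, unexpected {extra})"
            )
        if self.raw_values is None:
            object.__setattr__(self, "raw_values", dict(self.values))

    def lookup_array(self) -> np.ndarray:
        """A 128-slot float array indexed by ASCII code (NaN = invalid)."""
        arr = np.full(128, np.nan)
        for aa, v in self.values.items():
            arr[ord(aa)] = v
        return arr

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())


KYTE_DOOLITTLE = HydropathyScale("kyte_doolittle", dict(_KYTE_DOOLITTLE))
WIMLEY_WHITE_INTERFACE = HydropathyScale(
    "wimley_white_interface",
    {aa: -v for aa, v in _WIMLEY_WHITE_INTERFACE_RAW.items()},
    raw_values=dict(_WIMLEY_WHITE_INTERFACE_RAW),
)

BUILTIN_SCALES: dict[str, HydropathyScale] = {
    s.name: s for s in (KYTE_DOOLITTLE, WIMLEY_WHITE_INTERFACE)
}


def get_scale(name_or_scale: str | HydropathyScale) -> HydropathyScale:
    """Resolve a scale by name or pass a scale object through."""
    if isinstance(name_or_scale, HydropathyScale):
        return name_or_scale
    try:
        return BUILTIN_SCALES[name_or_scale]
    except KeyError:
        raise KeyError(
            f"unknown scale {name_or_scale!r}; "
            f"built-ins: {sorted(BUILTIN_SCALES)}"
        ) from None


def load_scale_file(path, name: str = "custom") -> HydropathyScale:
    """Load a two-column (letter, value) text file as a scale.

    The file is taken at face value: no sign flip is applied, so the file
    must already follow the higher-is-more-hydrophobic orientation.
    """
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            letter, value = line.split()[:2]
            values[letter] = float(value)
    return HydropathyScale(name, values)
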