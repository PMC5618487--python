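"""Per-residue physicochemical property tables and their standard conversion.

Correlation features compare residues through numeric property scales
(hydrophobicity, hydrophilicity, mass, ...). Before use, every scale is put
through the standard conversion

    h(R_i) = (h0(R_i) - mean_20) / sd_20

where the mean and (population, denominator-20) standard deviation run over
the 20 canonical residues. The converted scale has zero mean and unit
population SD, and is a fixed point of the conversion: applying it again
changes nothing.

The built-in registry ships a nine-property default ("default9"); every
operation downstream takes the table as an explicit parameter, so any
n-property set (n >= 1) works identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .seqio import ALPHABET

PathLike = Union[str, Path]

_TOL = 1e-12

# Raw per-residue scales, values in alphabetical single-letter order
# (A C D E F G H I K L M N P Q R S T V W Y).
#
# hydrophobicity      : classic pseudo-composition hydrophobicity scale
# hydrophilicity      : Hopp & Woods (1981)
# side_chain_mass     : side-chain molecular mass (Da)
# pK_COOH             : pK of the alpha-carboxyl group
# pK_NH3              : pK of the alpha-amino group
# isoelectric_point   : pI at 25 C
# flexibility         : Bhaskaran & Ponnuswamy (1988) average flexibility
# rigidity            : derived scale, 2 - Vihinen et al. (1994) normalized
#                       flexibility (higher = more rigid backbone)
# side_chain_volume   : normalized van der Waals volume, Fauchere et al. (1988)
_DEFAULT9_RAW: dict[str, tuple[float, ...]] = {
    "hydrophobicity": (
        0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38, -1.50, 1.06,
        0.64, -0.78, 0.12, -0.85, -2.53, -0.18, -0.05, 1.08, 0.81, 0.26,
    ),
    "hydrophilicity": (
        -0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
        -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3,
    ),
    "side_chain_mass": (
        15.0, 47.0, 59.0, 73.0, 91.0, 1.0, 82.0, 57.0, 73.0, 57.0,
        75.0, 58.0, 42.0, 72.0, 101.0, 31.0, 45.0, 43.0, 130.0, 107.0,
    ),
    "pK_COOH": (
        2.35, 1.71, 1.88, 2.19, 2.58, 2.34, 1.78, 2.32, 2.20, 2.36,
        2.28, 2.18, 1.99, 2.17, 2.18, 2.21, 2.15, 2.29, 2.38, 2.20,
    ),
    "pK_NH3": (
        9.87, 10.78, 9.60, 9.67, 9.24, 9.60, 8.97, 9.76, 8.90, 9.60,
        9.21, 9.09, 10.60, 9.13, 9.09, 9.15, 9.12, 9.74, 9.39, 9.11,
    ),
    "isoelectric_point": (
        6.11, 5.02, 2.98, 3.08, 5.91, 6.06, 7.64, 6.04, 9.47, 6.04,
        5.74, 5.41, 6.30, 5.65, 10.76, 5.68, 5.60, 6.02, 5.88, 5.63,
    ),
    "flexibility": (
        0.357, 0.346, 0.511, 0.497, 0.314, 0.544, 0.323, 0.462, 0.466, 0.365,
        0.295, 0.463, 0.509, 0.493, 0.529, 0.507, 0.444, 0.386, 0.305, 0.420,
    ),
    "rigidity": (
        1.016, 1.094, 0.932, 0.906, 1.085, 0.969, 1.050, 1.073, 0.898, 1.065,
        1.048, 0.952, 0.951, 0.963, 0.992, 0.954, 1.003, 1.069, 1.096, 1.071,
    ),
    "side_chain_volume": (
        1.00, 2.43, 2.78, 3.78, 5.89, 0.00, 4.66, 4.00, 4.77, 4.00,
        4.43, 2.95, 2.72, 3.95, 6.13, 1.60, 2.60, 3.00, 8.08, 6.47,
    ),
}


class ConstantPropertyError(ValueError):
    """A property row has zero spread; standardization would divide by zero."""


def standardize(raw: np.ndarray) -> np.ndarray:
    """Apply the standard conversion row-wise to an (n, 20) matrix.

    Each row is mapped to ``(x - mean) / sd`` with the population standard
    deviation (denominator 20). The output has zero mean and unit population
    SD per row, and the conversion is idempotent.

    Raises
    ------
    ConstantPropertyError
        If a row is constant (zero spread); the message names the row index.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[1] != 20:
        raise ValueError(f"expected 20 residue columns, got {raw.shape[1]}")
    means = raw.mean(axis=1, keepdims=True)
    sds = raw.std(axis=1, keepdims=True)  # population SD, ddof=0
    zero = np.flatnonzero(sds.ravel() < _TOL)
    if zero.size:
        raise ConstantPropertyError(
            f"property row {zero[0]} has zero spread across the 20 residues"
        )
    return (raw - means) / sds


@dataclass(frozen=True)
class PropertyTable:
    """n physicochemical properties x 20 residues, raw and standardized.

    ``raw_values`` and ``standardized_values`` are (n, 20) arrays with columns
    in alphabetical residue order. ``standardized_values`` is computed at
    construction and satisfies: zero mean per row, unit population SD per
    row, fixed point of :func:`standardize`.
    """

    property_names: tuple[str, ...]
    raw_values: np.ndarray
    standardized_values: np.ndarray = field(init=False, repr=False)
    name: str = "custom"

    def __post_init__(self) -> None:
        raw = np.atleast_2d(np.asarray(self.raw_values, dtype=float))
        if len(self.property_names) != raw.shape[0]:
            raise ValueError("property_names length does not match rows")
        if len(set(self.property_names)) != len(self.property_names):
            raise ValueError("duplicate property name")
        if raw.shape[0] < 1:
            raise ValueError("need at least one property")
        if not np.isfinite(raw).all():
            raise ValueError("non-numeric or non-finite property value")
        try:
            std = standardize(raw)
        except ConstantPropertyError as err:
            idx = int(str(err).split()[2])
            raise ConstantPropertyError(
                f"property {self.property_names[idx]!r} has zero spread"
            ) from None
        object.__setattr__(self, "raw_values", raw)
        object.__setattr__(self, "standardized_values", std)

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    def standardized_for(self, sequence: str) -> np.ndarray:
        """Standardized values along a sequence: (n, L) array.

        Assumes the sequence has already been validated against the
        canonical alphabet.
        """
        codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        index = _RESIDUE_INDEX[codes]
        if (index < 0).any():
            bad = sequence[int(np.flatnonzero(index < 0)[0])]
            raise KeyError(f"residue {bad!r} not in the canonical alphabet")
        return self.standardized_values[:, index]

    def to_tsv(self, path: PathLike) -> None:
        """Write the raw table: header of 20 residue letters, one property per line."""
        with Path(path).open("w") as handle:
            handle.write("property\t" + "\t".join(ALPHABET) + "\n")
            for name, row in zip(self.property_names, self.raw_values):
                handle.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# residue letter -> column index, -1 for anything else
_RESIDUE_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate(ALPHABET):
    _RESIDUE_INDEX[ord(_ch)] = _i


def _table_from_mapping(
    mapping: Mapping[str, Sequence[float]], name: str
) -> PropertyTable:
    names = tuple(mapping)
    raw = np.array([mapping[k] for k in names], dtype=float)
    return PropertyTable(property_names=names, raw_values=raw, name=name)


#: Built-in named property sets.
REGISTRY: dict[str, Mapping[str, Sequence[float]]] = {"default9": _DEFAULT9_RAW}


def load_property_table(source: PathLike = "default9") -> PropertyTable:
    """Load a property table from a registry name or a TSV file.

    The TSV format is: a header row ``property<TAB>A<TAB>C...<TAB>Y`` (20
    residue letters in alphabetical order), then one property per line with
    its 20 numeric values. Standardization is applied on load.

    Raises
    ------
    ValueError
        Missing residue column, non-numeric entry, or duplicate property name.
    """
    if isinstance(source, str) and source in REGISTRY:
        return _table_from_mapping(REGISTRY[source], name=source)
    path = Path(source)
    with path.open() as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty property table")
    header = lines[0].split("\t")
    if header[0].lower() != "property" or header[1:] != list(ALPHABET):
        raise ValueError(
            f"{path}: header must be 'property' followed by the 20 residues "
            "in alphabetical order"
        )
    names: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 21:
            raise ValueError(
                f"{path}: line {lineno}: expected 1 name + 20 values, got {len(parts)}"
            )
        if parts[0] in names:
            raise ValueError(f"{path}: duplicate property name {parts[0]!r}")
        try:
            values = [float(v) for v in parts[1:]]
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric entry") from None
        names.append(parts[0])
        rows.append(values)
    return PropertyTable(
        property_names=tuple(names), raw_values=np.array(rows), name=path.stem
    )
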