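"""Pseudo-dipeptide composition encoding of protein sequences.

A sequence of length L is mapped to a (400 + n*lambda)-dimensional vector:

* the first 400 components carry the normalized adjacent-dipeptide
  frequencies f_u = count(u) / (L - 1), u ranging over the 400 ordered
  residue pairs AA, AC, ..., YY (first residue major, alphabetical);
* the remaining n*lambda components carry sequence-order information through
  tiered correlation factors. For lag (tier) t in 1..lambda and property k,

      tau_{(t-1)n + k} = 1/(L - t) * sum_{i=1}^{L-t} h_k(R_i) * h_k(R_{i+t})

  with h_k the standardized property values.

The blocks are merged with weight omega and a common normalizer:

      P_u = f_u / D            (u <= 400)
      P_u = omega * tau_u / D  (u > 400),   D = sum_i f_i + omega * sum_j tau_j

so the full vector sums to 1 whenever D != 0. Since sum_i f_i = 1 exactly,
D = 1 + omega * T with T the total correlation mass; standardized properties
can be negative, so on adversarial inputs D may vanish — that case raises
rather than emitting unbounded features.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .physchem import PropertyTable, load_property_table
from .seqio import ALPHABET, ProteinRecord

PathLike = Union[str, Path]

#: The 400 ordered dipeptides, first-residue major: AA, AC, ..., AY, CA, ..., YY.
DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(ALPHABET, repeat=2)
)

_NORMALIZER_TOL = 1e-9


class EncodingError(ValueError):
    """Raised when a record cannot be encoded under the given parameters."""


@dataclass(frozen=True)
class EncoderParams:
    """Parameters of the pseudo-dipeptide encoding.

    lam : maximum residue-pair lag (tier depth), lam >= 1. A sequence must
        satisfy L > lam to be encodable.
    omega : weight of the correlation block relative to the dipeptide block,
        omega >= 0. omega = 0 reduces the encoding to pure dipeptide
        composition (correlation components all zero).
    table : the physicochemical property table supplying n.
    """

    lam: int
    omega: float
    table: PropertyTable

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")

    @property
    def n_properties(self) -> int:
        return self.table.n_properties

    @property
    def dimension(self) -> int:
        """Total feature count: 400 + n * lambda."""
        return 400 + self.n_properties * self.lam

    def feature_names(self) -> list[str]:
        """Component labels: the 400 dipeptides, then tier-major correlation names."""
        names = list(DIPEPTIDES)
        for tier in range(1, self.lam + 1):
            for prop in self.table.property_names:
                names.append(f"tier{tier}_{prop}")
        return names


@dataclass(frozen=True)
class FeatureVector:
    """One encoded sequence: values aligned with their component names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")

    def __len__(self) -> int:
        return len(self.values)


def _residue_codes(record: ProteinRecord) -> np.ndarray:
    codes = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    index = _RESIDUE_INDEX[codes]
    if (index < 0).any():
        pos = int(np.flatnonzero(index < 0)[0])
        raise EncodingError(
            f"record {record.id!r}: non-canonical residue "
            f"{record.sequence[pos]!r} at position {pos + 1}"
        )
    return index


_RESIDUE_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate(ALPHABET):
    _RESIDUE_INDEX[ord(_ch)] = _i


def dipeptide_frequencies(record: ProteinRecord) -> np.ndarray:
    """Normalized occurrence frequencies of the 400 adjacent dipeptides.

    Component for dipeptide d is count(d) / (L - 1); the 400 components sum
    to exactly 1. Requires L >= 2.
    """
    if record.length < 2:
        raise EncodingError(f"record {record.id!r}: no dipeptides (L < 2)")
    codes = _residue_codes(record)
    pair_index = codes[:-1] * 20 + codes[1:]
    counts = np.bincount(pair_index, minlength=400)
    return counts / (record.length - 1)


def correlation_factor(
    record: ProteinRecord, tier: int, property_index: int, table: PropertyTable
) -> float:
    """The tier-t correlation factor for one property (1-based property index).

    Averages h(R_i) * h(R_{i+t}) over all residue pairs at lag t, using the
    standardized property values. Requires L > tier.
    """
    if not 1 <= property_index <= table.n_properties:
        raise ValueError(f"property_index {property_index} out of range")
    if tier < 1:
        raise ValueError(f"tier must be >= 1, got {tier}")
    if record.length <= tier:
        raise EncodingError(
            f"record {record.id!r}: sequence shorter than lag "
            f"(L={record.length} <= tier={tier})"
        )
    h = table.standardized_for(record.sequence)[property_index - 1]
    return float(np.mean(h[:-tier] * h[tier:]))


def correlation_factors(record: ProteinRecord, params: EncoderParams) -> np.ndarray:
    """All n*lambda correlation factors, tier-major (tier 1 props 1..n, tier 2, ...)."""
    if record.length <= params.lam:
        raise EncodingError(
            f"record {record.id!r}: sequence length {record.length} "
            f"<= lambda {params.lam}; cannot compute all correlation tiers"
        )
    h = params.table.standardized_for(record.sequence)  # (n, L)
    taus = np.empty((params.lam, params.n_properties))
    for tier in range(1, params.lam + 1):
        taus[tier - 1] = np.mean(h[:, :-tier] * h[:, tier:], axis=1)
    return taus.ravel()


def encode(record: ProteinRecord, params: EncoderParams) -> FeatureVector:
    """Encode one record as a (400 + n*lambda)-dimensional pseudo-dipeptide vector.

    Raises
    ------
    EncodingError
        If L <= lambda, or if the normalizer D = 1 + omega * sum(tau) is
        numerically zero or negative ("degenerate normalization").
    """
    freqs = dipeptide_frequencies(record)
    taus = correlation_factors(record, params)
    denom = freqs.sum() + params.omega * taus.sum()
    if denom <= _NORMALIZER_TOL:
        raise EncodingError(
            f"record {record.id!r}: degenerate normalization "
            f"(D = {denom:.3e} <= {_NORMALIZER_TOL})"
        )
    values = np.concatenate([freqs, params.omega * taus]) / denom
    return FeatureVector(values=values, names=tuple(params.feature_names()))


def encode_matrix(
    records: Sequence[ProteinRecord],
    params: EncoderParams,
    fail_fast: bool = True,
) -> pd.DataFrame:
    """Encode many records into a DataFrame (rows = record ids, named columns).

    Row order preserves input order. With ``fail_fast=False``, records that
    fail to encode are dropped and collected on the returned frame's
    ``attrs["failures"]`` as (id, reason) pairs instead of raising.
    """
    names = params.feature_names()
    rows: list[np.ndarray] = []
    ids: list[str] = []
    failures: list[tuple[str, str]] = []
    for record in records:
        try:
            rows.append(encode(record, params).values)
            ids.append(record.id)
        except EncodingError as err:
            if fail_fast:
                raise
            failures.append((record.id, str(err)))
    matrix = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(names))),
        index=pd.Index(ids, name="id"),
        columns=names,
    )
    matrix.attrs["failures"] = failures
    return matrix


def parameter_grid(
    lam_range: tuple[int, int] = (1, 30),
    omega_range: tuple[float, float] = (0.05, 0.70),
    omega_step: float = 0.05,
) -> list[tuple[int, float]]:
    """Enumerate the (lambda, omega) tuning grid.

    Defaults: lambda = 1..30 step 1 and omega = 0.05..0.70 step 0.05,
    i.e. 30 x 14 = 420 combinations.
    """
    lams = range(lam_range[0], lam_range[1] + 1)
    n_omega = int(round((omega_range[1] - omega_range[0]) / omega_step)) + 1
    omegas = [round(omega_range[0] + i * omega_step, 10) for i in range(n_omega)]
    return [(lam, omega) for lam in lams for omega in omegas]


def write_matrix(matrix: pd.DataFrame, params: EncoderParams, path: PathLike) -> None:
    """Write a feature matrix as TSV with a JSON sidecar recording the parameters."""
    path = Path(path)
    matrix.to_csv(path, sep="\t")
    sidecar = {
        "lam": params.lam,
        "omega": params.omega,
        "property_set": params.table.name,
        "n_properties": params.n_properties,
        "dimension": params.dimension,
    }
    path.with_suffix(path.suffix + ".params.json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def read_matrix(path: PathLike) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0)
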