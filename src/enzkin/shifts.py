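"""Chemical-shift compatibility scoring of structure models.

A structure model whose predicted NMR chemical shifts sit close to the
experimentally assigned shifts is more compatible with the solution
structure than one whose predictions deviate.  The statistic here is the
mean absolute relative deviation over shared atoms,

    D = mean over shared (residue, atom) of |delta_pred - delta_exp| / |delta_exp|,

reported pooled and per nucleus (1H, 13C, 15N); lower D means a more
compatible model.  Because "normalized and averaged" admits variants, a
signed mean and a per-nucleus-then-pooled average are available behind
flags; the default (absolute values, pooled over atoms) is this package's
documented choice.

Shift prediction itself is out of scope; tables arrive as CSV with columns
``residue_index, atom_name, nucleus, shift_ppm``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "SHIFT_COLUMNS",
    "NUCLEI",
    "ShiftTableError",
    "ShiftDeviation",
    "read_shift_csv",
    "write_shift_csv",
    "validate_shift_table",
    "normalized_shift_deviation",
    "rank_models",
]

SHIFT_COLUMNS = ("residue_index", "atom_name", "nucleus", "shift_ppm")
NUCLEI = ("1H", "13C", "15N")


class ShiftTableError(ValueError):
    """Malformed shift table or empty comparison."""


@dataclass(frozen=True)
class ShiftDeviation:
    """Normalized deviation statistic for one experimental/predicted pair."""

    pooled: float
    per_nucleus: dict = field(default_factory=dict)
    n_matched: int = 0
    n_unmatched_experimental: int = 0
    n_unmatched_predicted: int = 0
    n_excluded_zero: int = 0


def validate_shift_table(table: pd.DataFrame, name: str = "shift table") -> pd.DataFrame:
    """Check columns, finiteness, nucleus codes and (residue, atom) uniqueness."""
    missing = set(SHIFT_COLUMNS) - set(table.columns)
    if missing:
        raise ShiftTableError(f"{name}: missing columns {sorted(missing)}")
    out = table.loc[:, list(SHIFT_COLUMNS)].copy()
    out["atom_name"] = out["atom_name"].astype(str).str.upper()
    out["nucleus"] = out["nucleus"].astype(str)
    bad_nuc = set(out["nucleus"]) - set(NUCLEI)
    if bad_nuc:
        raise ShiftTableError(f"{name}: unknown nucleus codes {sorted(bad_nuc)}")
    if not np.all(np.isfinite(out["shift_ppm"].to_numpy(dtype=float))):
        raise ShiftTableError(f"{name}: non-finite shift_ppm values")
    if out.duplicated(subset=["residue_index", "atom_name"]).any():
        raise ShiftTableError(f"{name}: duplicate (residue_index, atom_name) keys")
    return out


def read_shift_csv(path: Union[str, os.PathLike]) -> pd.DataFrame:
    return validate_shift_table(pd.read_csv(path), name=str(path))


def write_shift_csv(table: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    validate_shift_table(table).to_csv(path, index=False)


def normalized_shift_deviation(
    experimental: pd.DataFrame,
    predicted: pd.DataFrame,
    signed: bool = False,
    pool_by_nucleus: bool = False,
) -> ShiftDeviation:
    """Mean (absolute) relative shift deviation over shared atoms.

    Atoms are matched by exact (residue_index, uppercased atom_name) keys.
    Atoms with a zero experimental shift are excluded with a warning
    (division guard); an empty intersection is an error.  With ``signed``
    the absolute value is not taken (systematic offsets can cancel); with
    ``pool_by_nucleus`` the pooled value is the unweighted mean of the
    per-nucleus means instead of the mean over all atoms.
    """
    exp = validate_shift_table(experimental, "experimental")
    pred = validate_shift_table(predicted, "predicted")
    merged = exp.merge(
        pred, on=["residue_index", "atom_name"], suffixes=("_exp", "_pred")
    )
    n_matched = len(merged)
    if n_matched == 0:
        raise ShiftTableError("no shared (residue_index, atom_name) keys to compare")
    zero = merged["shift_ppm_exp"] == 0.0
    n_zero = int(zero.sum())
    if n_zero:
        warnings.warn(
            f"excluding {n_zero} atom(s) with zero experimental shift",
            stacklevel=2,
        )
        merged = merged.loc[~zero]
        if merged.empty:
            raise ShiftTableError("all shared atoms have zero experimental shift")
    dev = (merged["shift_ppm_pred"] - merged["shift_ppm_exp"]) / merged[
        "shift_ppm_exp"
    ].abs()
    if not signed:
        dev = dev.abs()
    per_nucleus = {
        nuc: float(dev[merged["nucleus_exp"] == nuc].mean())
        for nuc in NUCLEI
        if (merged["nucleus_exp"] == nuc).any()
    }
    if pool_by_nucleus:
        pooled = float(np.mean(list(per_nucleus.values())))
    else:
        pooled = float(dev.mean())
    return ShiftDeviation(
        pooled=pooled,
        per_nucleus=per_nucleus,
        n_matched=n_matched,
        n_unmatched_experimental=len(exp) - n_matched,
        n_unmatched_predicted=len(pred) - n_matched,
        n_excluded_zero=n_zero,
    )


def rank_models(
    experimental: pd.DataFrame,
    predictions: dict[str, pd.DataFrame],
    signed: bool = False,
    pool_by_nucleus: bool = False,
) -> list[tuple[str, ShiftDeviation]]:
    """Models ordered by ascending pooled D; ties broken by model id.

    The ordering is invariant under the input dictionary's iteration
    order, and each entry carries the full per-nucleus breakdown.
    """
    if not predictions:
        raise ShiftTableError("no predicted tables supplied")
    scored = [
        (model_id, normalized_shift_deviation(
            experimental, table, signed=signed, pool_by_nucleus=pool_by_nucleus))
        for model_id, table in predictions.items()
    ]
    scored.sort(key=lambda item: (item[1].pooled, item[0]))
    return scored
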