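"""Optical signal <-> concentration conversion and trace-file I/O.

A single-wavelength spectrophotometric assay sees the combined Beer–Lambert
absorbance of substrate and product,

    A = (eps_S * S + eps_P * P) * path + baseline,

and the closed-assay mass balance S + P = S0 makes the inversion a 2x2
linear solve.  The substrate and product must differ optically
(eps_S != eps_P), otherwise the reaction is invisible.

Also implements the Ellman (DTNB) free-thiol arithmetic: absorbance of
released 5-thio-2-nitrobenzoate at 412 nm with the standard molar
extinction coefficient 13,600 M^-1 cm^-1 converted to mol SH per mol
protein.

Trace files use a fixed plain-text dialect: a ``#key=value`` header block
followed by two comma-separated columns ``time_s,signal``.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from typing import Optional, TextIO, Union

import numpy as np

__all__ = [
    "DTNB_EXTINCTION_M1CM1",
    "SpectroError",
    "OpticalConstants",
    "ProgressCurve",
    "concentration_to_absorbance",
    "absorbance_to_concentrations",
    "free_sulfhydryl_per_protein",
    "read_trace_csv",
    "write_trace_csv",
]

#: Molar extinction coefficient of 5-thio-2-nitrobenzoate at 412 nm (Ellman assay).
DTNB_EXTINCTION_M1CM1 = 13_600.0


class SpectroError(ValueError):
    """Invalid optical metadata or signal/metadata mismatch."""


@dataclass(frozen=True)
class OpticalConstants:
    """Per-wavelength extinction coefficients and cuvette geometry.

    eps_s, eps_p : M^-1 cm^-1 extinction coefficients of substrate/product.
    path_cm : optical path length (standard cuvette = 1 cm).
    baseline : additive absorbance offset (AU).
    """

    eps_s: float
    eps_p: float
    path_cm: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_s < 0 or self.eps_p < 0:
            raise SpectroError("extinction coefficients must be >= 0")
        if self.eps_s == self.eps_p:
            raise SpectroError(
                "eps_S == eps_P: substrate and product are optically "
                "indistinguishable at this wavelength"
            )
        if self.path_cm <= 0:
            raise SpectroError("path length must be > 0")


@dataclass
class ProgressCurve:
    """One timed trace with its assay metadata.

    ``signal_units`` is ``"AU"`` (absorbance; ``optics`` required) or
    ``"M"`` (already a substrate concentration).
    """

    curve_id: str
    times: np.ndarray
    signal: np.ndarray
    s0: float
    e0: float
    signal_units: str = "AU"
    optics: Optional[OpticalConstants] = None
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.signal.shape != self.times.shape:
            raise SpectroError(
                f"curve {self.curve_id!r}: times and signal must be equal-length "
                "1-D arrays"
            )
        if self.times.size and (self.times[0] < 0 or np.any(np.diff(self.times) <= 0)):
            raise SpectroError(
                f"curve {self.curve_id!r}: times must be strictly increasing from t >= 0"
            )
        if not (self.s0 > 0 and self.e0 > 0):
            raise SpectroError(f"curve {self.curve_id!r}: S0 and E0 must be > 0")
        if self.signal_units not in ("AU", "M"):
            raise SpectroError(
                f"curve {self.curve_id!r}: signal_units must be 'AU' or 'M'"
            )
        if self.signal_units == "AU" and self.optics is None:
            raise SpectroError(
                f"curve {self.curve_id!r}: absorbance signal requires optics metadata"
            )

    def __len__(self) -> int:
        return self.times.size


def concentration_to_absorbance(s, p, optics: OpticalConstants):
    """Beer–Lambert absorbance A = (eps_S*S + eps_P*P)*path + baseline."""
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(s < 0) or np.any(p < 0):
        raise SpectroError("concentrations must be non-negative")
    a = (optics.eps_s * s + optics.eps_p * p) * optics.path_cm + optics.baseline
    return a if a.ndim else float(a)


def _estimate_noise_sd(signal: np.ndarray) -> float:
    """Noise scale from second differences (model-free, trend-insensitive)."""
    if signal.size < 4:
        return 0.0
    return float(np.std(np.diff(signal, 2)) / math.sqrt(6.0))


def absorbance_to_concentrations(curve: ProgressCurve, noise_sd: Optional[float] = None):
    """Invert a trace to (S(t), P(t)) under the mass balance S + P = S0.

    Solves ``{A = (eps_S*S + eps_P*P)*path + baseline; S + P = S0}`` per
    point.  Recovered concentrations are clipped to [0, S0] only when the
    violation is within 3x the (supplied or estimated) noise standard
    deviation; larger violations indicate a data/metadata mismatch and
    raise :class:`SpectroError`.  Curves already in concentration units are
    returned as-is (with P from mass balance).
    """
    if curve.signal_units == "M":
        s = np.asarray(curve.signal, dtype=float)
    else:
        optics = curve.optics
        if optics is None:
            raise SpectroError("optics metadata required to invert absorbance")
        # eps_S*S + eps_P*(S0 - S) = (A - baseline)/path
        reduced = (curve.signal - optics.baseline) / optics.path_cm
        s = (reduced - optics.eps_p * curve.s0) / (optics.eps_s - optics.eps_p)
        if noise_sd is None:
            noise_sd = _estimate_noise_sd(np.asarray(curve.signal, dtype=float))
        sd_conc = noise_sd / (abs(optics.eps_s - optics.eps_p) * optics.path_cm)
        # noise-tolerant clip band: 3 sigma plus the expected extreme of n
        # Gaussian draws, so honest noise at the 0/S0 boundaries never trips
        # the metadata-mismatch error while systematic offsets still do
        n = max(curve.signal.size, 2)
        tol = max((3.0 + math.sqrt(2.0 * math.log(n))) * sd_conc, 1e-9 * curve.s0)
        if np.any(s < -tol) or np.any(s > curve.s0 + tol):
            worst = float(max(np.max(s - curve.s0), np.max(-s)))
            raise SpectroError(
                f"curve {curve.curve_id!r}: recovered S leaves [0, S0] by "
                f"{worst:.3g} M (> tolerance {tol:.3g} M); check S0/eps/baseline "
                "metadata"
            )
    s = np.clip(s, 0.0, curve.s0)
    return s, curve.s0 - s


def free_sulfhydryl_per_protein(
    a412: float, protein_conc: float, path_cm: float = 1.0
) -> float:
    """Ellman assay: mol free SH per mol protein from absorbance at 412 nm.

    ``(A412 / (13600 * path)) / [protein]`` — the released thiolate
    concentration by Beer–Lambert, per mole of protein.
    """
    if a412 < 0:
        raise SpectroError("A412 must be >= 0")
    if protein_conc <= 0:
        raise SpectroError("protein concentration must be > 0")
    if path_cm <= 0:
        raise SpectroError("path length must be > 0")
    return (a412 / (DTNB_EXTINCTION_M1CM1 * path_cm)) / protein_conc


# ---------------------------------------------------------------------------
# trace CSV dialect

_MANDATORY_KEYS = ("curve_id", "S0_M", "E0_M", "signal_units")
_OPTICS_KEYS = ("eps_S", "eps_P", "path_cm", "baseline")
_CONDITION_KEYS = ("pH", "temperature_C", "wavelength_nm", "buffer")


def write_trace_csv(curve: ProgressCurve, path_or_file: Union[str, os.PathLike, TextIO]) -> None:
    """Write a trace in the ``#key=value`` + ``time_s,signal`` dialect (lossless)."""
    num = lambda x: format(float(x), ".17g")  # round-trips float64 exactly
    lines = [
        f"#curve_id={curve.curve_id}",
        f"#S0_M={num(curve.s0)}",
        f"#E0_M={num(curve.e0)}",
        f"#signal_units={curve.signal_units}",
    ]
    if curve.optics is not None:
        o = curve.optics
        lines += [
            f"#eps_S={num(o.eps_s)}",
            f"#eps_P={num(o.eps_p)}",
            f"#path_cm={num(o.path_cm)}",
            f"#baseline={num(o.baseline)}",
        ]
    for key in _CONDITION_KEYS:
        if key in curve.condition:
            lines.append(f"#{key}={curve.condition[key]}")
    lines.append("time_s,signal")
    for t, y in zip(curve.times, curve.signal):
        lines.append(f"{num(t)},{num(y)}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
    else:
        with open(path_or_file, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_trace_csv(path_or_file: Union[str, os.PathLike, TextIO]) -> ProgressCurve:
    """Read a trace written by :func:`write_trace_csv`.

    Raises :class:`SpectroError` naming the offending field on missing
    mandatory metadata, non-monotone time columns, or length mismatches.
    """
    if hasattr(path_or_file, "read"):
        text = path_or_file.read()
    else:
        with open(path_or_file, "r", encoding="utf-8") as fh:
            text = fh.read()
    meta: dict[str, str] = {}
    times: list[float] = []
    signal: list[float] = []
    saw_header = False
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise SpectroError(f"line {lineno}: malformed metadata line {line!r}")
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif line.lower().replace(" ", "") == "time_s,signal":
            saw_header = True
        else:
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectroError(f"line {lineno}: expected 'time,signal', got {line!r}")
            try:
                times.append(float(parts[0]))
                signal.append(float(parts[1]))
            except ValueError as exc:
                raise SpectroError(f"line {lineno}: non-numeric value") from exc
    if not saw_header:
        raise SpectroError("missing 'time_s,signal' column header")
    for key in _MANDATORY_KEYS:
        if key not in meta:
            raise SpectroError(f"missing mandatory metadata key {key!r}")
    units = meta["signal_units"]
    optics = None
    if any(k in meta for k in _OPTICS_KEYS) or units == "AU":
        try:
            optics = OpticalConstants(
                eps_s=float(meta["eps_S"]),
                eps_p=float(meta["eps_P"]),
                path_cm=float(meta.get("path_cm", "1.0")),
                baseline=float(meta.get("baseline", "0.0")),
            )
        except KeyError as exc:
            raise SpectroError(f"missing optics metadata key {exc.args[0]!r}") from exc
    condition = {}
    for key in _CONDITION_KEYS:
        if key in meta:
            if key in ("pH", "temperature_C", "wavelength_nm"):
                try:
                    condition[key] = float(meta[key])
                except ValueError:
                    condition[key] = meta[key]
            else:
                condition[key] = meta[key]
    return ProgressCurve(
        curve_id=meta["curve_id"],
        times=np.asarray(times),
        signal=np.asarray(signal),
        s0=float(meta["S0_M"]),
        e0=float(meta["E0_M"]),
        signal_units=units,
        optics=optics,
        condition=condition,
    )
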