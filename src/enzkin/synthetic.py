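"""Synthetic-data generators for every pipeline input.

The package's study conditions are those of a closed single-wavelength
deacylation assay: at least three initial substrate concentrations spanning
0.1–0.5 mM, nanomolar-to-micromolar enzyme, absorbance decay recorded as the
N4-acyl group is hydrolysed, and additive Gaussian photometric noise
(default sigma = 0.002 AU, a realistic bench spectrophotometer figure).
Every generator takes an explicit integer seed and is bit-reproducible.

Besides trace sets, the module plants toy multiple alignments with known
invariant columns (for the conservation stage) and paired
experimental/predicted chemical-shift tables with controlled relative error
(for the shift-compatibility statistic).  All default extinction
coefficients are synthetic order-of-magnitude nucleoside UV values, not
measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticParameters, substrate_timecourse
from .spectro import OpticalConstants, ProgressCurve, concentration_to_absorbance

__all__ = [
    "DEFAULT_S0_LIST",
    "DEFAULT_OPTICS",
    "TraceSetSpec",
    "TraceSet",
    "AlignmentSpec",
    "ShiftPairSpec",
    "generate_trace_set",
    "generate_panel",
    "generate_alignment",
    "generate_shift_pair",
]

#: Three initial substrate concentrations spanning the 0.1–0.5 mM assay range.
DEFAULT_S0_LIST = (1.0e-4, 2.5e-4, 5.0e-4)

#: Synthetic substrate/product extinction coefficients (M^-1 cm^-1), chosen as
#: order-of-magnitude nucleoside UV values; placeholders, not measured constants.
DEFAULT_OPTICS = OpticalConstants(eps_s=1.0e4, eps_p=1.0e3)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class TraceSetSpec:
    """Generating truth and assay design for one synthetic trace set."""

    params: KineticParameters
    seed: int
    s0_list: Sequence[float] = DEFAULT_S0_LIST
    e0: float = 1.0e-8
    optics: OpticalConstants = DEFAULT_OPTICS
    duration_s: Optional[float] = None
    n_points: int = 200
    noise_sd_au: float = 0.002

    def __post_init__(self) -> None:
        if len(self.s0_list) < 1 or any(s0 <= 0 for s0 in self.s0_list):
            raise ValueError("s0_list must contain positive concentrations")
        if self.e0 <= 0:
            raise ValueError("E0 must be > 0")
        if self.n_points < 20:
            raise ValueError("n_points must be >= 20")
        if self.noise_sd_au < 0:
            raise ValueError("noise_sd_au must be >= 0")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    def duration_for(self, s0: float) -> float:
        """Assay duration: 5*(Km+S0)/Vmax reaches >= 99% conversion."""
        if self.duration_s is not None:
            return self.duration_s
        vmax = self.params.kcat * self.e0
        return 5.0 * (self.params.km + s0) / vmax

    def truth_dict(self) -> dict:
        """JSON-serializable record of the generating truth (sidecar format)."""
        d = asdict(self)
        d["params"] = {
            "km": self.params.km,
            "kcat": self.params.kcat,
            "ki": self.params.ki,
        }
        d["s0_list"] = list(self.s0_list)
        d["optics"] = asdict(self.optics)
        return d


@dataclass(frozen=True)
class TraceSet:
    """Generated curves together with the spec that is their hidden truth."""

    curves: tuple
    spec: TraceSetSpec

    def __iter__(self):
        return iter(self.curves)

    def __len__(self) -> int:
        return len(self.curves)

    def __getitem__(self, i):
        return self.curves[i]


def generate_trace_set(spec: TraceSetSpec, label: str = "substrate") -> TraceSet:
    """Simulate one noisy absorbance trace per S0 in the spec.

    For each initial concentration the substrate time course is evaluated
    exactly under the product-inhibition model, converted to absorbance by
    Beer–Lambert, and perturbed with N(0, noise_sd^2) from a single seeded
    generator.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    curves = []
    for i, s0 in enumerate(spec.s0_list):
        duration = spec.duration_for(s0)
        times = np.linspace(0.0, duration, spec.n_points)
        s = substrate_timecourse(spec.params, s0, spec.e0, times)
        a = concentration_to_absorbance(s, s0 - s, spec.optics)
        if spec.noise_sd_au > 0:
            a = a + rng.normal(0.0, spec.noise_sd_au, size=a.shape)
        curves.append(
            ProgressCurve(
                curve_id=f"{label}__S0_{s0:g}M",
                times=times,
                signal=a,
                s0=s0,
                e0=spec.e0,
                signal_units="AU",
                optics=spec.optics,
                condition={"pH": 8.0, "temperature_C": 22.0,
                           "buffer": "50 mM potassium phosphate"},
            )
        )
    return TraceSet(curves=tuple(curves), spec=spec)


def generate_panel(
    panel: Sequence[tuple[str, KineticParameters]],
    seed: int,
    **assay_kwargs,
) -> dict[str, TraceSet]:
    """One trace set per (label, parameters) pair with a shared assay design.

    Per-substrate seeds are spawned deterministically from the base seed;
    substrates without a Ki are generated without product inhibition.
    Duplicate labels are rejected.
    """
    labels = [label for label, _ in panel]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate substrate labels in panel")
    children = np.random.SeedSequence(seed).spawn(len(panel))
    out: dict[str, TraceSet] = {}
    for (label, params), child in zip(panel, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        spec = TraceSetSpec(params=params, seed=child_seed, **assay_kwargs)
        out[label] = generate_trace_set(spec, label=label)
    return out


@dataclass(frozen=True)
class AlignmentSpec:
    """Design of a toy protein alignment with planted invariant columns."""

    reference_sequence: str
    n_sequences: int
    conserved_positions: frozenset = field(default_factory=frozenset)
    substitution_rate: float = 0.5
    gap_rate: float = 0.05
    seed: int = 0
    reference_id: str = "REF"

    def __post_init__(self) -> None:
        if not self.reference_sequence:
            raise ValueError("reference sequence must be non-empty")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        pos = frozenset(int(p) for p in self.conserved_positions)
        object.__setattr__(self, "conserved_positions", pos)
        if any(p < 1 or p > len(self.reference_sequence) for p in pos):
            raise ValueError("conserved_positions must be 1-based reference positions")
        for name in ("substitution_rate", "gap_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def generate_alignment(spec: AlignmentSpec) -> str:
    """Aligned FASTA text with the planted conservation structure.

    The reference sequence is row one (under ``spec.reference_id``).
    Columns mapped to ``conserved_positions`` carry the reference residue in
    every row; every other column is independently gapped (gap_rate) or
    substituted with a different residue (substitution_rate) per row.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference_sequence.upper()
    length = len(ref)
    conserved0 = {p - 1 for p in spec.conserved_positions}
    rows = [(spec.reference_id, ref)]
    for i in range(spec.n_sequences - 1):
        chars = list(ref)
        for j in range(length):
            if j in conserved0:
                continue
            if rng.random() < spec.gap_rate:
                chars[j] = "-"
            elif rng.random() < spec.substitution_rate:
                choices = _AMINO_ACIDS.replace(ref[j], "")
                chars[j] = choices[rng.integers(len(choices))]
        rows.append((f"seq{i + 1:03d}", "".join(chars)))
    return "".join(f">{rid}\n{seq}\n" for rid, seq in rows)


@dataclass(frozen=True)
class ShiftPairSpec:
    """Design of a paired experimental/predicted chemical-shift table."""

    n_residues: int
    seed: int = 0
    nuclei: tuple = ("1H", "13C", "15N")
    base_shift_ranges: Optional[dict] = None
    relative_error_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        bad = set(self.nuclei) - {"1H", "13C", "15N"}
        if bad:
            raise ValueError(f"unknown nuclei: {sorted(bad)}")
        if self.relative_error_sd < 0:
            raise ValueError("relative_error_sd must be >= 0")
        ranges = dict(self.base_shift_ranges or _DEFAULT_SHIFT_RANGES)
        for nuc, (lo, hi) in ranges.items():
            if hi <= lo:
                raise ValueError(f"shift range for {nuc} must have positive width")
        object.__setattr__(self, "base_shift_ranges", ranges)


# Typical protein backbone shift windows (ppm) per nucleus.
_DEFAULT_SHIFT_RANGES = {"1H": (6.0, 10.0), "13C": (40.0, 75.0), "15N": (100.0, 135.0)}

_ATOMS_BY_NUCLEUS = {"1H": ("H", "HA"), "13C": ("CA", "CB", "C"), "15N": ("N",)}


def generate_shift_pair(spec: ShiftPairSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(experimental, predicted) shift tables with planted relative error.

    Experimental shifts are drawn uniformly from the per-nucleus ranges;
    predicted shifts equal ``experimental * (1 + N(0, relative_error_sd^2))``
    atom by atom, from one seeded generator.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for res in range(1, spec.n_residues + 1):
        for nuc in spec.nuclei:
            lo, hi = spec.base_shift_ranges[nuc]
            for atom in _ATOMS_BY_NUCLEUS[nuc]:
                rows.append((res, atom, nuc, rng.uniform(lo, hi)))
    exp = pd.DataFrame(rows, columns=["residue_index", "atom_name", "nucleus", "shift_ppm"])
    pred = exp.copy()
    eps = rng.normal(0.0, spec.relative_error_sd, size=len(pred))
    pred["shift_ppm"] = pred["shift_ppm"] * (1.0 + eps)
    return exp, pred
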