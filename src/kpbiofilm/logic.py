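"""Boolean logic gates realized from analog biofilm responses.

Steady-state measurements pair an applied DC input voltage (swept over
-5..+5 V) with a normalized output response in [0, 1].  Inputs are encoded
to logical levels by a sign threshold (default 0 V), outputs are binarized
at the 0.5 cutoff (strictly greater -> 1), and bitwise operators over the
binarized channels realize AND, OR, XOR, XNOR, NAND and NOR gates.  Gate
quality is the fraction of the 4-row truth table reproduced; duplicate
output pairs (channels 1-2 vs 3-4) quantify reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, NormalizationError, ParameterError

__all__ = [
    "GATES",
    "LogicSignal",
    "GateSpec",
    "GateEvaluation",
    "binarize",
    "eval_gate",
    "normalize_output",
    "encode_inputs",
    "realize_gates",
    "ideal_truth_table",
]

# two-input Boolean semantics; inputs/outputs are 0/1 integers
GATES = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
    "XNOR": lambda a, b: 1 - (a ^ b),
    "NAND": lambda a, b: 1 - (a & b),
    "NOR": lambda a, b: 1 - (a | b),
}

_COMBOS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class LogicSignal:
    """One output channel: applied DC inputs (V) and normalized responses."""

    v_in: np.ndarray
    v_out_norm: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.v_in = np.asarray(self.v_in, dtype=float)
        self.v_out_norm = np.asarray(self.v_out_norm, dtype=float)
        if self.v_in.size != self.v_out_norm.size:
            raise DataError("v_in and v_out_norm must have equal length")
        if np.any((self.v_out_norm < 0) | (self.v_out_norm > 1)):
            raise DataError("v_out_norm must lie in [0, 1]; use normalize_output first")

    @classmethod
    def from_raw(cls, v_in: np.ndarray, v_out_raw_mv: np.ndarray, channel: str = "") -> "LogicSignal":
        return cls(v_in=v_in, v_out_norm=normalize_output(v_out_raw_mv), channel=channel)


@dataclass
class GateSpec:
    """A gate and the channels feeding it; output_id=None means the gate
    output is the bitwise combination of the input channels' binarized
    responses, otherwise the named channel's binarized response is the
    realized output."""

    gate: str
    input_ids: tuple[int, int]
    output_id: int | None = None

    def __post_init__(self) -> None:
        if self.gate not in GATES:
            raise ParameterError(f"gate must be one of {sorted(GATES)}")
        if len(set(self.input_ids)) != len(self.input_ids):
            raise ParameterError("input_ids must be distinct")


@dataclass
class GateEvaluation:
    spec: GateSpec
    truth_table: dict  # (x1, x2) -> realized bit (or None if unobserved)
    match_fraction: float
    duplicate_agreement: float
    missing_combos: tuple = field(default_factory=tuple)


def binarize(v_out_norm):
    """Threshold rule: 1 if value > 0.5, else 0 (the boundary maps to 0)."""
    arr = np.asarray(v_out_norm)
    out = (arr > 0.5).astype(int)
    return int(out) if np.isscalar(v_out_norm) else out


def eval_gate(spec: GateSpec, x: tuple[int, int]) -> int:
    """Ideal Boolean output of the gate on binary inputs."""
    a, b = x
    if a not in (0, 1) or b not in (0, 1):
        raise TypeError("gate inputs must be binary 0/1")
    return int(GATES[spec.gate](a, b))


def ideal_truth_table(gate: str) -> dict[tuple[int, int], int]:
    if gate not in GATES:
        raise ParameterError(f"gate must be one of {sorted(GATES)}")
    return {c: int(GATES[gate](*c)) for c in _COMBOS}


def normalize_output(v_out_raw) -> np.ndarray:
    """Min-max normalize a raw output sweep to [0, 1]."""
    v = np.asarray(v_out_raw, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise NormalizationError("constant output cannot be normalized")
    return (v - lo) / (hi - lo)


def encode_inputs(v_in, input_threshold: float = 0.0) -> np.ndarray:
    """Logical level of an applied DC input: 1 where v_in > threshold."""
    return (np.asarray(v_in, dtype=float) > input_threshold).astype(int)


def _realized_table(
    signals: list[LogicSignal],
    spec: GateSpec,
    pair: tuple[int, int],
    input_threshold: float,
) -> dict[tuple[int, int], int | None]:
    ia, ib = pair
    xa = encode_inputs(signals[ia].v_in, input_threshold)
    xb = encode_inputs(signals[ib].v_in, input_threshold)
    if spec.output_id is None:
        y = GATES[spec.gate](binarize(signals[ia].v_out_norm), binarize(signals[ib].v_out_norm))
    else:
        y = binarize(signals[spec.output_id].v_out_norm)
    table: dict[tuple[int, int], int | None] = {}
    for combo in _COMBOS:
        rows = (xa == combo[0]) & (xb == combo[1])
        if not rows.any():
            table[combo] = None
        else:  # majority vote over repeated measurements of the same combo
            table[combo] = int(round(float(np.mean(y[rows]))))
    return table


def realize_gates(
    signals: list[LogicSignal],
    specs: list[GateSpec],
    input_threshold: float = 0.0,
) -> list[GateEvaluation]:
    """Evaluate each gate spec against its ideal truth table.

    ``match_fraction`` is the fraction of observed input combinations whose
    realized bit equals the ideal table; unobserved combinations are flagged
    in ``missing_combos`` and excluded.  When at least four channels exist,
    ``duplicate_agreement`` compares the realized tables of the spec's
    channel pair and of the mirror pair shifted by two channels (pairs 1-2
    vs 3-4); otherwise it is NaN.
    """
    if len(signals) < 2:
        raise DataError("need at least 2 channels for two-input gates")
    out = []
    for spec in specs:
        ia, ib = spec.input_ids
        table = _realized_table(signals, spec, (ia, ib), input_threshold)
        ideal = ideal_truth_table(spec.gate)
        observed = [c for c in _COMBOS if table[c] is not None]
        missing = tuple(c for c in _COMBOS if table[c] is None)
        if not observed:
            raise DataError("no input combinations observed")
        match = float(np.mean([table[c] == ideal[c] for c in observed]))
        dup = np.nan
        mirror = (ia + 2, ib + 2)
        if max(mirror) < len(signals) and spec.output_id is None:
            table2 = _realized_table(signals, spec, mirror, input_threshold)
            both = [c for c in observed if table2[c] is not None]
            if both:
                dup = float(np.mean([table[c] == table2[c] for c in both]))
        out.append(
            GateEvaluation(
                spec=spec,
                truth_table=table,
                match_fraction=match,
                duplicate_agreement=dup,
                missing_combos=missing,
            )
        )
    return out
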