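"""Learnable-parameter and FLOP accounting, plus reduction arithmetic.

FLOP convention (fixed and used everywhere):

* convolution / linear nodes: 2 FLOPs per multiply-accumulate;
* bias add: 1 FLOP per output element;
* BatchNorm (inference form, scale + shift): 2 FLOPs per element;
* SiLU activation (sigmoid = exp + add + div, then multiply): 4 FLOPs/element;
* max-pool: k^2 - 1 comparisons per output element, 1 FLOP each;
* residual add: 1 FLOP per element;
* SimAM attention: 10 FLOPs per element (mean, centering, square, variance,
  normalized energy, sigmoid, modulation);
* nearest upsampling and concatenation: memory moves, 0 FLOPs.

Parameters count learnable arrays only (conv weights/biases and BN affine
pairs); BN running statistics are excluded.  GFLOPs are reported rounded to
one decimal before computing headline reduction percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_layers import Cost
from .model_builder import Model

FLOPS_PER_MAC = 2
BIAS_OPS = 1
BN_OPS = 2
ACT_OPS = 4
POOL_CMP_OPS = 1
ADD_OPS = 1
ATTN_OPS = 10


def cost_to_flops(cost: Cost) -> int:
    return (FLOPS_PER_MAC * cost.macs
            + BIAS_OPS * cost.bias_elems
            + BN_OPS * cost.bn_elems
            + ACT_OPS * cost.act_elems
            + POOL_CMP_OPS * cost.pool_cmps
            + ADD_OPS * cost.add_elems
            + ATTN_OPS * cost.attn_elems)


@dataclass
class ProfileRow:
    name: str
    kind: str
    params: int
    macs: int
    flops: int


@dataclass
class ProfileReport:
    rows: list[ProfileRow] = field(default_factory=list)
    input_size: int = 640

    @property
    def total_params(self) -> int:
        return sum(r.params for r in self.rows)

    @property
    def total_macs(self) -> int:
        return sum(r.macs for r in self.rows)

    @property
    def total_flops(self) -> int:
        return sum(r.flops for r in self.rows)

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    def group_totals(self, kind: str) -> tuple[int, int]:
        """(params, flops) summed over rows of one kind (e.g. all C3 blocks)."""
        rows = [r for r in self.rows if r.kind == kind]
        return sum(r.params for r in rows), sum(r.flops for r in rows)

    def as_dicts(self) -> list[dict]:
        return [vars(r) for r in self.rows]


def profile_model(model: Model, input_size: int | None = None) -> ProfileReport:
    """Per-node parameter and FLOP accounting at the given input size."""
    size = input_size or model.config.input_size
    if size % 32:
        raise ValueError("input_size must be divisible by 32")
    report = ProfileReport(input_size=size)
    for name, kind, params, cost in model.node_costs(size):
        report.rows.append(ProfileRow(name, kind, params, cost.macs,
                                      cost_to_flops(cost)))
    return report


def count_parameters(model: Model) -> ProfileReport:
    """Parameter part only (FLOP columns evaluated at the config input size)."""
    return profile_model(model)


def count_flops(model: Model, input_size: int) -> ProfileReport:
    return profile_model(model, input_size)


def summarize_reduction(a, b, ndigits: int = 2) -> dict:
    """Relative change from ``a`` to ``b`` (printed-metric or profile pair).

    reduction%   = 100 * (a - b) / a
    improvement% = 100 * (b - a) / a
    """
    a_val = a.gflops if isinstance(a, ProfileReport) else float(a)
    b_val = b.gflops if isinstance(b, ProfileReport) else float(b)
    if a_val == 0:
        raise ZeroDivisionError("reduction relative to zero is undefined")
    return {
        "reduction_pct": round(100.0 * (a_val - b_val) / a_val, ndigits),
        "improvement_pct": round(100.0 * (b_val - a_val) / a_val, ndigits),
    }


def headline_gflops(report: ProfileReport) -> float:
    """GFLOPs rounded to 1 decimal, the precision used for headline claims."""
    return round(report.gflops, 1)
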