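"""Parameter and FLOP accounting for built models.

Parameters are counted by enumerating every trainable scalar (convolution,
linear, batch-norm and layer-norm weights and biases).  FLOPs are counted
under the multiply-accumulate-equals-one convention by tracing an actual
forward pass: every convolution contributes ``k^2 * C_in/g * C_out * H_out *
W_out`` and every linear ``n_in * n_out`` per row, while normalisations,
activations, pooling, interpolation and elementwise fusions are excluded —
the convention common profilers use, which is also the only one consistent
with the published complexity figures of the classic UNet at a 256x256
input.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import build_variant
from .nn import Module
from .tensor import Tensor, count_macs


@dataclass
class ComplexityReport:
    variant: str
    params_total: int
    flops_total: int                  # MACs
    input_size: tuple[int, int]
    params_by_stage: dict[str, int] = field(default_factory=dict)

    @property
    def params_m(self) -> float:
        return self.params_total / 1e6

    @property
    def gflops(self) -> float:
        return self.flops_total / 1e9

    def as_dict(self) -> dict:
        return {"variant": self.variant, "params": self.params_total,
                "params_M": round(self.params_m, 4),
                "gflops": round(self.gflops, 4),
                "input_size": list(self.input_size),
                "params_by_stage": self.params_by_stage}


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars in a built model."""
    return sum(p.data.size for p in model.parameters())


def parameters_by_stage(model: Module) -> dict[str, int]:
    totals: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".", 1)[0]
        totals[top] = totals.get(top, 0) + p.data.size
    return totals


def count_flops(model: Module, input_size: tuple[int, int] = (256, 256)) -> int:
    """MAC count of one forward pass at the given input size (batch 1)."""
    h, w = input_size
    if h % 32 or w % 32:
        raise ValueError("input size must be divisible by 32")
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, h, w), dtype=np.float32))
    with count_macs() as box:
        model(x)
    if was_training:
        model.train()
    return box[0]


def complexity_report(model: Module, *, variant: str = "model",
                      input_size: tuple[int, int] = (256, 256),
                      flops: bool = True) -> ComplexityReport:
    return ComplexityReport(
        variant=variant,
        params_total=count_parameters(model),
        flops_total=count_flops(model, input_size) if flops else 0,
        input_size=tuple(input_size),
        params_by_stage=parameters_by_stage(model))


def complexity_table(variants: list[str],
                     input_size: tuple[int, int] = (256, 256), *,
                     flops: bool = True, seed: int = 0) -> list[ComplexityReport]:
    """One report per requested variant name (duplicates give duplicate rows)."""
    rows = []
    for name in variants:
        model = build_variant(name, seed=seed)
        rows.append(complexity_report(model, variant=name,
                                      input_size=input_size, flops=flops))
    return rows


def write_table(rows: list[ComplexityReport], path) -> None:
    path = Path(path)
    records = [r.as_dict() for r in rows]
    if path.suffix == ".csv":
        fields = ["variant", "params", "params_M", "gflops", "input_size"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for rec in records:
                rec = {k: rec[k] for k in fields}
                rec["input_size"] = "x".join(map(str, rec["input_size"]))
                writer.writerow(rec)
    else:
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
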